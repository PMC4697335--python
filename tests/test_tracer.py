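import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import butyflux as bf
from mc_oracle import mc_class_fractions, mc_distributions


def flux(theta, w_lys=0.0, w_rec=0.0, w_exo=0.0, w_gly=0.0, exo=(0, 0)):
    return bf.FluxConfig(
        theta_lys=theta,
        acetyl_inputs={
            "lysine_C1C2": w_lys,
            "recycled_donor_acetyl": w_rec,
            "exogenous_acetate": w_exo,
            "glycolysis": w_gly,
        },
        exogenous_acetate_pattern=exo,
    )


def methyl_label_mass(theta, w_rec):
    """Closed-form acetyl-pool methyl-label mass for [6-13C]lysine: the
    recycled source injects label via the C5-C6 butyryl half with weight
    w_rec*theta/2 and dilutes itself with factor w_rec*(1-theta)."""
    return w_rec * theta / 2.0 / (1.0 - w_rec * (1.0 - theta))


class TestPureLysineBranch:
    def test_6_label_gives_pure_c4_butyrate(self, model, label6):
        dists = bf.propagate_labels(model, label6, flux(1.0, w_lys=1.0))
        cf = bf.to_class_fractions(dists["butyrate"])
        assert (cf.p2, cf.p4, cf.p24) == (0.0, 1.0, 0.0)
        assert dists["butyrate"].p((0, 0, 0, 1)) == 1.0
        assert dists["acetate"].p((0, 0)) == 1.0

    def test_2_label_charges_acetate_pool(self, model):
        lab2 = bf.LabelingState.from_positions("lysine", [2], 6)
        dists = bf.propagate_labels(model, lab2, flux(1.0, w_lys=1.0))
        assert dists["acetate"].p((0, 1)) == 1.0  # methyl-labelled acetate
        assert dists["butyrate"].p((0, 0, 0, 0)) == 1.0


class TestRecyclingExchange:
    def test_6_label_with_recycling_populates_all_three_classes(self, model, label6):
        """Recycling of lysine-branch butyryl halves carries C6 into the
        acetyl pool: C2-only, C4-only and C2&C4 butyrate all appear, plus
        minor methyl-labelled acetate with unlabelled acetate dominating."""
        dists = bf.propagate_labels(model, label6, flux(0.7, w_lys=0.7, w_rec=0.3))
        cf = bf.to_class_fractions(dists["butyrate"])
        assert cf.p2 > 0 and cf.p4 > 0 and cf.p24 > 0
        assert cf.p4 > 0.5  # the main product stays [4-13C]butyrate
        ace = dists["acetate"]
        assert 0 < ace.p((0, 1)) < ace.p((0, 0))

    def test_pool_methyl_mass_matches_closed_form(self, model, label6):
        theta, w_rec = 0.7, 0.3
        dists = bf.propagate_labels(model, label6, flux(theta, w_lys=0.7, w_rec=w_rec))
        m = methyl_label_mass(theta, w_rec)
        assert dists["acetate"].p((0, 1)) == pytest.approx(m, abs=1e-9)

    def test_class_fractions_match_closed_form(self, model, label6):
        theta, w_rec = 0.6, 0.4
        dists = bf.propagate_labels(model, label6, flux(theta, w_lys=0.6, w_rec=w_rec))
        m = methyl_label_mass(theta, w_rec)
        lab4 = theta + (1 - theta) * m * (1 - m)
        lab2 = (1 - theta) * m * (1 - m)
        lab24 = (1 - theta) * m * m
        total = lab4 + lab2 + lab24
        cf = bf.to_class_fractions(dists["butyrate"])
        assert cf.p4 == pytest.approx(lab4 / total, abs=1e-9)
        assert cf.p2 == pytest.approx(lab2 / total, abs=1e-9)
        assert cf.p24 == pytest.approx(lab24 / total, abs=1e-9)

    def test_degenerate_closed_loop_raises(self, model, label6):
        with pytest.raises(bf.DegenerateFluxError):
            bf.propagate_labels(model, label6, flux(0.0, w_rec=1.0))


class TestExogenousAcetate:
    def test_labelled_acetate_feeding_reaches_butyrate(self, model):
        """Unlabelled lysine plus [2-13C]acetate: butyrate picks up C2/C4
        label through the condensation route only."""
        lab0 = bf.LabelingState.from_positions("lysine", [], 6)
        dists = bf.propagate_labels(
            model, lab0, flux(0.5, w_lys=0.5, w_exo=0.5, exo=(0, 1))
        )
        cf = bf.to_class_fractions(dists["butyrate"])
        assert cf.p2 > 0 and cf.p4 > 0 and cf.p24 > 0


class TestFructoselysine:
    def test_sugar_label_reaches_lactate_not_lysine_branch_butyrate(self, model):
        lab = bf.LabelingState.from_positions("fructoselysine", [12], 12)
        cfg = flux(1.0, w_lys=0.5, w_gly=0.5)
        dists = bf.propagate_labels(model, lab, cfg)
        # theta=1: butyrate is pure lysine-moiety, hence unlabelled
        assert dists["butyrate"].p((0, 0, 0, 0)) == 1.0
        # sugar C6 -> pyruvate C3 -> half the lactate labelled at C3
        assert dists["lactate"].p((0, 0, 1)) == pytest.approx(0.5)
        assert dists["lactate"].p((0, 0, 0)) == pytest.approx(0.5)
        # glycolytic acetyl from the C4-C6 triose carries the methyl label
        assert dists["acetate"].p((0, 1)) == pytest.approx(0.25)

    def test_lysine_moiety_label_behaves_like_lysine(self, model):
        lab = bf.LabelingState.from_positions("fructoselysine", [6], 12)
        dists = bf.propagate_labels(model, lab, flux(1.0, w_lys=1.0))
        assert dists["butyrate"].p((0, 0, 0, 1)) == 1.0


class TestInvariantsAndOracle:
    @given(
        theta=st.floats(0.05, 1.0),
        w_rec=st.floats(0.0, 0.9),
        pos=st.sampled_from([1, 2, 3, 4, 5, 6]),
    )
    @settings(max_examples=40)
    def test_distributions_are_probability_vectors(self, model, theta, w_rec, pos):
        lab = bf.LabelingState.from_positions("lysine", [pos], 6)
        cfg = flux(theta, w_lys=1.0 - w_rec, w_rec=w_rec)
        for dist in bf.propagate_labels(model, lab, cfg).values():
            assert abs(dist.probs.sum() - 1.0) < 1e-9
            assert np.all(dist.probs >= 0)

    def test_label_conservation_flux_consistent(self, model):
        """theta=1 with the lysine fragment as sole acetyl source: one
        butyrate and one acetate per lysine carry exactly the substrate's
        labelled atoms."""
        for pos in range(1, 7):
            lab = bf.LabelingState.from_positions("lysine", [pos], 6)
            dists = bf.propagate_labels(model, lab, flux(1.0, w_lys=1.0))
            total = bf.label_yield(dists, {"butyrate": 1.0, "acetate": 1.0})
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_p4_non_increasing_as_condensation_grows(self, model, label6):
        p4s = []
        for theta in np.linspace(1.0, 0.2, 9):
            cfg = flux(theta, w_lys=0.7, w_rec=0.3)
            cf = bf.to_class_fractions(
                bf.propagate_labels(model, label6, cfg)["butyrate"]
            )
            p4s.append(cf.p4)
        assert all(a >= b - 1e-12 for a, b in zip(p4s, p4s[1:]))

    @pytest.mark.parametrize(
        "pos, theta, weights",
        [
            (6, 0.7, (0.6, 0.3, 0.1, 0.0)),
            (2, 0.5, (0.5, 0.4, 0.0, 0.1)),
            (4, 0.35, (0.35, 0.45, 0.2, 0.0)),
        ],
    )
    def test_analytic_fixed_point_matches_monte_carlo(self, model, pos, theta, weights):
        lab = bf.LabelingState.from_positions("lysine", [pos], 6)
        cfg = flux(
            theta,
            w_lys=weights[0],
            w_rec=weights[1],
            w_exo=weights[2],
            w_gly=weights[3],
            exo=(0, 1),
        )
        dists = bf.propagate_labels(model, lab, cfg)
        but_mc, ace_mc, draws = mc_distributions(
            lab.pattern, theta, weights, exo_pattern=(0, 1), seed=42
        )
        n = draws.shape[0]
        for p_an, p_mc in zip(dists["butyrate"].probs, but_mc):
            se = np.sqrt(max(p_an * (1 - p_an), 1e-12) / n)
            assert abs(p_an - p_mc) < 4 * se + 5e-4

    def test_undefined_fractions_for_unlabelled(self, model):
        lab0 = bf.LabelingState.from_positions("lysine", [], 6)
        dists = bf.propagate_labels(model, lab0, flux(1.0, w_lys=1.0))
        with pytest.raises(bf.UndefinedFractionsError):
            bf.to_class_fractions(dists["butyrate"])


class TestToClassFractions:
    def test_point_mass_c4(self):
        probs = np.zeros(16)
        probs[1 << 3] = 1.0
        cf = bf.to_class_fractions(bf.IsotopomerDistribution("butyrate", probs))
        assert (cf.p2, cf.p4, cf.p24, cf.p_other) == (0.0, 1.0, 0.0, 0.0)

    def test_uniform_four_pattern_marginalization(self):
        """Uniform over {C2 only, C4 only, C2&C4, C1 only}: each observed
        class is 1/3, and 1/4 of labelled mass sits outside C2/C4."""
        probs = np.zeros(16)
        for idx in (1 << 1, 1 << 3, (1 << 1) | (1 << 3), 1 << 0):
            probs[idx] = 0.25
        cf = bf.to_class_fractions(bf.IsotopomerDistribution("butyrate", probs))
        assert cf.p2 == pytest.approx(1 / 3)
        assert cf.p4 == pytest.approx(1 / 3)
        assert cf.p24 == pytest.approx(1 / 3)
        assert cf.p_other == pytest.approx(0.25)

    def test_rejects_non_butyrate_length(self):
        probs = np.zeros(4)
        probs[0] = 1.0
        with pytest.raises(ValueError):
            bf.to_class_fractions(bf.IsotopomerDistribution("acetate", probs))


class TestFluxSplitFit:
    def test_exact_recovery_of_pure_lysine_branch(self, model, label6):
        observed = bf.ClassFractions(p2=0.0, p4=1.0, p24=0.0)
        res = bf.fit_flux_split(observed, model, label6)
        assert res.theta_lys == pytest.approx(1.0, abs=1e-6)
        assert res.residual < 1e-12
        assert res.non_identifiable  # w_rec is undetermined at theta=1

    def test_parameter_recovery_zero_noise(self, model, label6):
        true = flux(0.71, w_lys=0.65, w_rec=0.35)
        dists = bf.propagate_labels(model, label6, true)
        observed = bf.to_class_fractions(dists["butyrate"])
        res = bf.fit_flux_split(observed, model, label6)
        assert abs(res.theta_lys - 0.71) < 0.02
        assert res.residual < 1e-10

    def test_recovery_under_multiplicative_noise(self, model, label6):
        """Median |theta error| < 0.05 across 50 noisy replicates."""
        true = flux(0.7, w_lys=0.7, w_rec=0.3)
        errors = []
        for seed in range(50):
            obs = bf.gen_labeling_observation(
                model, label6, true, noise_sd=0.05, seed=seed
            )
            res = bf.FluxSplitModel(obs, model, label6).fit(grid_points=21)
            errors.append(abs(res.theta_lys - 0.7))
        assert np.median(errors) < 0.05

    def test_summary_mentions_parameters(self, model, label6):
        res = bf.fit_flux_split(bf.ClassFractions(0.0, 1.0, 0.0), model, label6)
        s = res.summary()
        assert "theta_lys" in s and "residual" in s
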