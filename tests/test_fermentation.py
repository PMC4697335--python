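import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import butyflux as bf


@pytest.fixture
def lysine_record():
    """Endpoint concentration changes of the lysine fermentation."""
    return bf.FermentationRecord(
        [
            ("lysine", 16.8, "substrate"),
            ("butyrate", 14.2, "product"),
            ("acetate", 15.6, "product"),
            ("NH3", 22.1, "product"),
        ]
    )


class TestCarbonRecovery:
    def test_lysine_endpoint_gives_87_percent(self, lysine_record):
        assert bf.carbon_recovery(lysine_record) == pytest.approx(88.0 / 100.8)
        assert bf.recovery_percent(lysine_record) == 87

    def test_stoichiometric_closure_is_unity(self):
        rec = bf.FermentationRecord(
            [
                ("lysine", 10.0, "substrate"),
                ("butyrate", 10.0, "product"),
                ("acetate", 10.0, "product"),
                ("ammonia", 20.0, "product"),
            ]
        )
        assert bf.carbon_recovery(rec) == pytest.approx(1.0)

    def test_fructoselysine_with_co2_counted(self):
        rec = bf.FermentationRecord(
            [
                ("fructoselysine", 10.0, "substrate"),
                ("butyrate", 20.0, "product"),
                ("lactate", 10.0, "product"),
                ("co2", 10.0, "product"),
            ]
        )
        assert bf.carbon_recovery(rec) == pytest.approx(1.0)

    @given(scale=st.floats(1e-3, 1e3))
    def test_homogeneous_degree_zero(self, scale):
        rec = bf.FermentationRecord(
            [
                ("lysine", 16.8 * scale, "substrate"),
                ("butyrate", 14.2 * scale, "product"),
                ("acetate", 15.6 * scale, "product"),
            ]
        )
        assert bf.carbon_recovery(rec) == pytest.approx(88.0 / 100.8)

    def test_needs_both_sides(self):
        with pytest.raises(ValueError):
            bf.carbon_recovery(
                bf.FermentationRecord([("lysine", 16.8, "substrate")])
            )

    def test_zero_substrate_carbon_raises(self):
        rec = bf.FermentationRecord(
            [("water", 10.0, "substrate"), ("butyrate", 1.0, "product")]
        )
        with pytest.raises(ZeroDivisionError):
            bf.carbon_recovery(rec)


class TestAmmoniaGap:
    def test_lysine_sequestration(self, lysine_record, lysine_equation):
        gap = bf.ammonia_gap(lysine_record, lysine_equation)
        assert gap.expected_mM == pytest.approx(33.6)
        assert gap.observed_mM == pytest.approx(22.1)
        assert gap.sequestered_mM == pytest.approx(11.5)
        assert not gap.over_recovery

    def test_exact_match_zero_gap(self, lysine_equation):
        rec = bf.FermentationRecord(
            [("lysine", 10.0, "substrate"), ("ammonia", 20.0, "product")]
        )
        gap = bf.ammonia_gap(rec, lysine_equation)
        assert gap.sequestered_mM == 0.0

    def test_over_recovery_flag(self, lysine_equation):
        rec = bf.FermentationRecord(
            [("lysine", 10.0, "substrate"), ("ammonia", 25.0, "product")]
        )
        gap = bf.ammonia_gap(rec, lysine_equation)
        assert gap.sequestered_mM < 0
        assert gap.over_recovery


class TestSpecificActivity:
    def test_zero_rate(self):
        assert bf.specific_activity(bf.ActivityAssay(dA_per_min=0.0)) == 0.0

    @pytest.mark.parametrize(
        "dA, protein, expected",
        [
            (15.1, 0.01, 100.0),
            (0.151, 0.001, 10.0),
        ],
    )
    def test_unit_chain(self, dA, protein, expected):
        """dA/min / (eps * path) [mM/min] * volume [ml] = umol/min = U."""
        assay = bf.ActivityAssay(
            dA_per_min=dA,
            epsilon_mM_cm=15.1,
            path_cm=1.0,
            assay_volume_ml=1.0,
            protein_mg=protein,
        )
        assert bf.specific_activity(assay) == pytest.approx(expected)

    @given(
        dA=st.floats(0.0, 100.0),
        protein=st.floats(1e-4, 10.0),
    )
    def test_linear_in_rate_inverse_in_protein(self, dA, protein):
        base = bf.specific_activity(
            bf.ActivityAssay(dA_per_min=dA, protein_mg=protein)
        )
        doubled = bf.specific_activity(
            bf.ActivityAssay(dA_per_min=2 * dA, protein_mg=protein)
        )
        halved_protein = bf.specific_activity(
            bf.ActivityAssay(dA_per_min=dA, protein_mg=2 * protein)
        )
        assert doubled == pytest.approx(2 * base)
        assert halved_protein == pytest.approx(base / 2)

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            bf.ActivityAssay(dA_per_min=1.0, protein_mg=0.0)


def test_record_from_dataframe_and_report(lysine_equation):
    df = pd.DataFrame(
        {
            "compound": ["lysine", "butyrate", "acetate", "NH3"],
            "delta_mM": [16.8, 14.2, 15.6, 22.1],
            "role": ["substrate", "product", "product", "product"],
        }
    )
    rec = bf.FermentationRecord.from_dataframe(df)
    report = bf.recovery_report(rec, lysine_equation)
    assert report["carbon_recovery_percent"] == 87
    assert report["ammonia_gap"]["sequestered_mM"] == pytest.approx(11.5)
    assert report["per_compound_carbon_mM"]["butyrate"] == pytest.approx(56.8)
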