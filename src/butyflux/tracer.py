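"""Steady-state positional ¹³C label propagation through the butyrogenic network.

The model mixes two butyrate-forming routes:

* the **lysine branch** — substrate carbons 3..6 pass intact into butyrate
  C1..C4 (cleavage between C2 and C3), contributing a fraction ``theta_lys``
  of butyrate;
* the **acetyl-CoA branch** — two acetyl units drawn independently from a
  well-mixed acetyl-CoA pool condense head-to-tail, the methyl carbon of each
  unit landing on butyrate C4 and C2 respectively.

The acetyl-CoA pool composition ``x`` is the fixed point of a linear mixing
equation over four sources: the lysine C1-C2 fragment (released as
acetoacetate by the cleavage enzyme and cleaved thiolytically), acetyl units
recycled through the acetoacetyl-CoA / butyryl-CoA CoA-transferase exchange
(which is what carries C6 label into butyrate C2 and into minor
methyl-labelled acetate), exogenous acetate, and glycolysis of the
fructoselysine sugar moiety. Because the recycled term reduces, after
marginalizing the condensation product, to a theta-weighted mixture of the
lysine-branch butyryl halves and the pool itself, the fixed point stays
linear in ``x`` and is solved by damped iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .errors import (
    ConvergenceError,
    DegenerateFluxError,
    UndefinedFractionsError,
)
from .pathway import PathwayModel, branch_carbon_fate, reaction_carbon_map

ACETYL_SOURCES = (
    "lysine_C1C2",
    "recycled_donor_acetyl",
    "exogenous_acetate",
    "glycolysis",
)

DEFAULT_TOL = 1e-10
MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LabelingState:
    """A single positional labelling pattern of one metabolite
    (1 = ¹³C at that carbon, IUPAC numbering)."""

    metabolite: str
    pattern: tuple[int, ...]

    def __post_init__(self):
        if any(b not in (0, 1) for b in self.pattern):
            raise ValueError("pattern entries must be 0/1")

    @classmethod
    def from_positions(
        cls, metabolite: str, positions: Sequence[int], n_carbons: int
    ) -> "LabelingState":
        pattern = [0] * n_carbons
        for p in positions:
            if not 1 <= p <= n_carbons:
                raise ValueError(f"position {p} outside 1..{n_carbons}")
            pattern[p - 1] = 1
        return cls(metabolite, tuple(pattern))

    @property
    def n_carbons(self) -> int:
        return len(self.pattern)


@dataclass
class IsotopomerDistribution:
    """Probability vector over the 2**n positional labelling states of an
    n-carbon metabolite. Index bit (i-1) encodes carbon i."""

    metabolite: str
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        n = self.probs.size
        if n & (n - 1):
            raise ValueError("probs length must be a power of two")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative probabilities")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.probs.sum():.12f}, not 1")

    @property
    def n_carbons(self) -> int:
        return int(np.log2(self.probs.size))

    def p(self, pattern: Sequence[int]) -> float:
        return float(self.probs[_index(pattern)])

    def expected_label_count(self) -> float:
        idx = np.arange(self.probs.size)
        popcount = np.array([bin(i).count("1") for i in idx])
        return float(self.probs @ popcount)

    def marginal(self, carbons: Sequence[int]) -> np.ndarray:
        """Marginal distribution over a subset of carbons (1-based),
        in the order given."""
        out = np.zeros(2 ** len(carbons))
        for i, p in enumerate(self.probs):
            sub = sum(((i >> (c - 1)) & 1) << j for j, c in enumerate(carbons))
            out[sub] += p
        return out


@dataclass(frozen=True)
class FluxConfig:
    """Flux split parameters of the two butyrate-forming routes.

    theta_lys
        Fraction of butyrate made directly on the lysine branch.
    acetyl_inputs
        Normalized weights of the acetyl-CoA pool sources
        (:data:`ACETYL_SOURCES`).
    phi_acetate_release
        Fraction of the acetyl-CoA pool exported as acetate; affects molar
        yield accounting, not isotopomer composition.
    exogenous_acetate_pattern
        Labelling of medium acetate (C1, C2), e.g. ``(0, 1)`` for
        [2-¹³C]acetate feeding.
    """

    theta_lys: float
    acetyl_inputs: Mapping[str, float]
    phi_acetate_release: float = 1.0
    exogenous_acetate_pattern: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if not 0.0 <= self.theta_lys <= 1.0:
            raise ValueError("theta_lys must lie in [0, 1]")
        if not 0.0 <= self.phi_acetate_release <= 1.0:
            raise ValueError("phi_acetate_release must lie in [0, 1]")
        w = dict.fromkeys(ACETYL_SOURCES, 0.0)
        for k, v in self.acetyl_inputs.items():
            if k not in w:
                raise ValueError(f"unknown acetyl-CoA source {k!r}")
            if v < 0:
                raise ValueError(f"negative weight for {k!r}")
            w[k] = float(v)
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"acetyl_inputs weights sum to {total}, not 1")
        object.__setattr__(self, "acetyl_inputs", w)

    def weight(self, source: str) -> float:
        return self.acetyl_inputs[source]


@dataclass(frozen=True)
class ClassFractions:
    """Fractions of labelled butyrate labelled at C2 only, C4 only and at
    both C2 and C4; ``p_other`` is the share of labelled molecules carrying
    label only at C1/C3, which the HMBC procedure does not see and which is
    excluded from the three-class normalization."""

    p2: float
    p4: float
    p24: float
    p_other: float = 0.0

    def __post_init__(self):
        for name in ("p2", "p4", "p24"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")
        s = self.p2 + self.p4 + self.p24
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {s}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p2, self.p4, self.p24])


# ---------------------------------------------------------------------------
# helpers


def _index(pattern: Sequence[int]) -> int:
    return int(sum(int(b) << i for i, b in enumerate(pattern)))


def _point(n_carbons: int, pattern: Sequence[int]) -> np.ndarray:
    v = np.zeros(2**n_carbons)
    v[_index(pattern)] = 1.0
    return v


def _apply_map(bits: Sequence[int], cmap: Mapping[int, int], n_out: int) -> tuple[int, ...]:
    out = [0] * n_out
    for src, dst in cmap.items():
        out[dst - 1] = int(bits[src - 1])
    return tuple(out)


class _TracerMaps:
    """Carbon-fate maps derived from a pathway model's atom maps."""

    def __init__(self, model: PathwayModel):
        fates, _ = branch_carbon_fate(model, "lysine", "lysine")
        self.lys_to_butyrate = fates["butyrate"]
        self.lys_to_acetyl = fates["acetyl-CoA"]
        if sorted(self.lys_to_butyrate) != [3, 4, 5, 6]:
            raise ValueError("packaged lysine branch must send carbons 3..6 to butyrate")
        if sorted(self.lys_to_acetyl) != [1, 2]:
            raise ValueError("packaged lysine branch must send carbons 1,2 to acetyl-CoA")
        # sugar moiety: fructoselysine -> glucose-6-P -> 2 pyruvate -> acetyl/CO2
        self.fl_to_lys = reaction_carbon_map(model, "frlB", "fructoselysine-6-phosphate", "lysine")
        self.fl_to_g6p = reaction_carbon_map(
            model, "frlB", "fructoselysine-6-phosphate", "glucose-6-phosphate"
        )
        self.g6p_to_pyr = [
            reaction_carbon_map(model, "glycolysis", "glucose-6-phosphate", f"pyruvate/{k}")
            for k in (1, 2)
        ]
        self.pyr_to_acetyl = reaction_carbon_map(model, "pfor", "pyruvate", "acetyl-CoA")
        self.pyr_to_lactate = reaction_carbon_map(model, "ldh", "pyruvate", "lactate")


# ---------------------------------------------------------------------------
# operations


def propagate_labels(
    model: PathwayModel,
    substrate_label: LabelingState,
    flux: FluxConfig,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
) -> dict[str, IsotopomerDistribution]:
    """Steady-state isotopomer distributions of acetyl-CoA, butyrate, acetate
    (and lactate when the substrate is fructoselysine).

    The acetyl-CoA pool solves ``x = const + w_rec*(1-theta_lys)*x`` by
    fixed-point iteration stopped when successive iterates differ by less
    than ``tol`` in max norm.

    Raises
    ------
    DegenerateFluxError
        When the recycled weight and theta_lys make the fixed point singular
        (a closed recycling loop with no label source).
    ConvergenceError
        If the iteration cap is reached (cannot happen for valid input).
    """
    maps = _TracerMaps(model)
    name = substrate_label.metabolite
    n = model.metabolite(name).n_carbons
    if substrate_label.n_carbons != n:
        raise ValueError(f"pattern length != {n} carbons of {name!r}")

    if name == "lysine":
        lys_bits = substrate_label.pattern
        sugar_acetyls = None
        lactate_patterns = None
    elif name == "fructoselysine":
        inv = maps.fl_to_lys  # FL6P carbon -> lysine carbon (1..6 -> 1..6)
        lys_bits = _apply_map(substrate_label.pattern, inv, 6)
        g6p_bits = _apply_map(substrate_label.pattern, maps.fl_to_g6p, 6)
        pyr_bits = [_apply_map(g6p_bits, m, 3) for m in maps.g6p_to_pyr]
        sugar_acetyls = [_apply_map(pb, maps.pyr_to_acetyl, 2) for pb in pyr_bits]
        lactate_patterns = [_apply_map(pb, maps.pyr_to_lactate, 3) for pb in pyr_bits]
    else:
        raise ValueError(f"unsupported labelled substrate {name!r}")

    theta = flux.theta_lys
    w_lys = flux.weight("lysine_C1C2")
    w_rec = flux.weight("recycled_donor_acetyl")
    w_exo = flux.weight("exogenous_acetate")
    w_gly = flux.weight("glycolysis")

    contraction = w_rec * (1.0 - theta)
    if 1.0 - contraction <= 1e-9:
        raise DegenerateFluxError(
            "recycled acetyl weight with theta_lys=0 closes the acetyl-CoA loop "
            "with no label source; the pool composition is undefined"
        )

    b_lb = _apply_map(lys_bits, maps.lys_to_butyrate, 4)  # lysine-branch butyrate
    acetyl_lys = _apply_map(lys_bits, maps.lys_to_acetyl, 2)

    d_lys = _point(2, acetyl_lys)
    halves = 0.5 * _point(2, b_lb[0:2]) + 0.5 * _point(2, b_lb[2:4])
    d_exo = _point(2, flux.exogenous_acetate_pattern)
    if sugar_acetyls is None:
        d_gly = _point(2, (0, 0))
    else:
        d_gly = 0.5 * _point(2, sugar_acetyls[0]) + 0.5 * _point(2, sugar_acetyls[1])

    const = w_lys * d_lys + w_rec * theta * halves + w_exo * d_exo + w_gly * d_gly

    x = const.copy()
    converged = False
    for _ in range(max_iter):
        x_new = const + contraction * x
        resid = float(np.max(np.abs(x_new - x)))
        x = x_new
        if resid < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"acetyl-CoA pool iteration did not converge (last residual {resid:g})",
            residual=resid,
        )
    x = x / x.sum()

    butyrate = theta * _point(4, b_lb) + (1.0 - theta) * np.kron(x, x)

    out = {
        "acetyl-CoA": IsotopomerDistribution("acetyl-CoA", x),
        "butyrate": IsotopomerDistribution("butyrate", butyrate),
        "acetate": IsotopomerDistribution("acetate", x.copy()),
    }
    if lactate_patterns is not None:
        lac = 0.5 * _point(3, lactate_patterns[0]) + 0.5 * _point(3, lactate_patterns[1])
        out["lactate"] = IsotopomerDistribution("lactate", lac)
    return out


def to_class_fractions(dist: IsotopomerDistribution, tol: float = 1e-12) -> ClassFractions:
    """Marginalize a butyrate isotopomer distribution to the three HMBC
    classes (C2 only / C4 only / C2 and C4) among labelled molecules.

    Raises
    ------
    UndefinedFractionsError
        If no labelled mass exists, or none of it sits on C2/C4.
    """
    if dist.n_carbons != 4:
        raise ValueError("class fractions are defined for 4-carbon butyrate only")
    probs = dist.probs
    c2 = 1 << 1
    c4 = 1 << 3
    idx = np.arange(16)
    has2 = (idx & c2).astype(bool)
    has4 = (idx & c4).astype(bool)
    labelled = float(probs[1:].sum())
    if labelled <= tol:
        raise UndefinedFractionsError("distribution is entirely unlabelled")
    m2 = float(probs[has2 & ~has4].sum())
    m4 = float(probs[~has2 & has4].sum())
    m24 = float(probs[has2 & has4].sum())
    observed = m2 + m4 + m24
    if observed <= tol:
        raise UndefinedFractionsError("no labelled mass at C2/C4; fractions undefined")
    p_other = (labelled - observed) / labelled
    return ClassFractions(m2 / observed, m4 / observed, m24 / observed, p_other)


def label_yield(
    dists: Mapping[str, IsotopomerDistribution], yields: Mapping[str, float]
) -> float:
    """Expected ¹³C atoms in products per substrate molecule, given molar
    yields (mol product per mol substrate). Used to check label conservation
    for flux-consistent configurations."""
    return sum(y * dists[m].expected_label_count() for m, y in yields.items())


# ---------------------------------------------------------------------------
# flux-split fitting (Model / Results)


@dataclass
class FluxSplitResults:
    """Fitted flux split with residual and identifiability diagnostics."""

    flux: FluxConfig
    residual: float
    non_identifiable: bool
    observed: ClassFractions
    predicted: ClassFractions
    n_evaluations: int = 0

    @property
    def theta_lys(self) -> float:
        return self.flux.theta_lys

    def summary(self) -> str:
        w = self.flux.acetyl_inputs
        lines = [
            "Flux split fit (butyrate HMBC class fractions)",
            "=" * 46,
            f"theta_lys (lysine-branch butyrate)   {self.flux.theta_lys:8.4f}",
            f"w recycled_donor_acetyl              {w['recycled_donor_acetyl']:8.4f}",
            f"w lysine_C1C2                        {w['lysine_C1C2']:8.4f}",
            f"w exogenous_acetate                  {w['exogenous_acetate']:8.4f}",
            f"w glycolysis                         {w['glycolysis']:8.4f}",
            f"residual (sum sq.)                   {self.residual:8.2e}",
            f"non-identifiable                     {self.non_identifiable}",
            "",
            f"observed  (p2, p4, p24) = ({self.observed.p2:.3f}, "
            f"{self.observed.p4:.3f}, {self.observed.p24:.3f})",
            f"predicted (p2, p4, p24) = ({self.predicted.p2:.3f}, "
            f"{self.predicted.p4:.3f}, {self.predicted.p24:.3f})",
        ]
        return "\n".join(lines)


class FluxSplitModel:
    """Fit (theta_lys, recycled weight) to observed butyrate class fractions.

    The free parameters are theta_lys and the recycled-acetyl weight; the
    lysine_C1C2 weight absorbs the remainder (exogenous acetate and
    glycolysis are fixed to the supplied values, default 0, matching the
    lysine-only labelling experiments).
    """

    W_REC_MAX = 0.98

    def __init__(
        self,
        observed: ClassFractions,
        model: PathwayModel,
        substrate_label: LabelingState,
        w_exogenous: float = 0.0,
        w_glycolysis: float = 0.0,
        exogenous_acetate_pattern: tuple[int, int] = (0, 0),
    ):
        self.observed = observed
        self.model = model
        self.substrate_label = substrate_label
        self.w_exo = float(w_exogenous)
        self.w_gly = float(w_glycolysis)
        self.exo_pattern = exogenous_acetate_pattern
        if self.w_exo + self.w_gly >= 1.0:
            raise ValueError("fixed source weights leave no mass for free sources")
        self._n_eval = 0

    def _config(self, theta: float, w_rec: float) -> FluxConfig:
        w_free = 1.0 - self.w_exo - self.w_gly
        w_rec = min(max(w_rec, 0.0), self.W_REC_MAX) * w_free
        return FluxConfig(
            theta_lys=min(max(theta, 0.0), 1.0),
            acetyl_inputs={
                "lysine_C1C2": w_free - w_rec,
                "recycled_donor_acetyl": w_rec,
                "exogenous_acetate": self.w_exo,
                "glycolysis": self.w_gly,
            },
            exogenous_acetate_pattern=self.exo_pattern,
        )

    def predict(self, theta: float, w_rec: float) -> ClassFractions:
        dists = propagate_labels(self.model, self.substrate_label, self._config(theta, w_rec))
        return to_class_fractions(dists["butyrate"])

    def loss(self, theta: float, w_rec: float) -> float:
        self._n_eval += 1
        try:
            pred = self.predict(theta, w_rec)
        except (UndefinedFractionsError, DegenerateFluxError):
            return np.inf
        return float(np.sum((pred.as_array() - self.observed.as_array()) ** 2))

    def fit(self, grid_points: int = 41, flat_tol: float = 1e-9) -> FluxSplitResults:
        """Grid search over (theta_lys, w_rec) followed by local refinement.

        When the minimum is degenerate (a flat ridge, e.g. a pure-[4-13C]
        observation which any theta explains once the recycled weight is 0),
        the selector deterministically prefers the largest theta_lys —
        attributing labelled butyrate to the direct lysine branch — and the
        result is flagged non-identifiable.
        """
        thetas = np.linspace(0.0, 1.0, grid_points)
        wrecs = np.linspace(0.0, self.W_REC_MAX, grid_points)
        best_loss, t0, w0 = np.inf, 0.0, 0.0
        for t in thetas:
            for w in wrecs:
                l = self.loss(t, w)
                # ties broken toward large theta, then small w_rec
                if l < best_loss - flat_tol or (
                    abs(l - best_loss) <= flat_tol and (t, -w) > (t0, -w0)
                ):
                    best_loss, t0, w0 = min(l, best_loss), t, w

        res = optimize.minimize(
            lambda p: self.loss(p[0], p[1]),
            x0=[t0, w0],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 500},
        )
        theta, w_rec = float(np.clip(res.x[0], 0, 1)), float(
            np.clip(res.x[1], 0, self.W_REC_MAX)
        )
        final = self.loss(theta, w_rec)
        if final >= best_loss:
            theta, w_rec, final = t0, w0, best_loss

        # flat-direction probe: the minimum is non-identifiable if moving
        # along some parameter direction leaves the loss unchanged
        non_ident = False
        for d_theta, d_wrec in ((0.05, 0.0), (0.0, 0.05)):
            probes = []
            for s in (-1.0, 1.0):
                t = float(np.clip(theta + s * d_theta, 0, 1))
                w = float(np.clip(w_rec + s * d_wrec, 0, self.W_REC_MAX))
                if (t, w) != (theta, w_rec):
                    probes.append(self.loss(t, w))
            if probes and max(probes) - final < flat_tol:
                non_ident = True

        cfg = self._config(theta, w_rec)
        return FluxSplitResults(
            flux=cfg,
            residual=final,
            non_identifiable=non_ident,
            observed=self.observed,
            predicted=self.predict(theta, w_rec),
            n_evaluations=self._n_eval,
        )


def fit_flux_split(
    observed: ClassFractions,
    model: PathwayModel,
    substrate_label: LabelingState,
    **kwargs,
) -> FluxSplitResults:
    """Convenience wrapper: build a :class:`FluxSplitModel` and fit it."""
    return FluxSplitModel(observed, model, substrate_label, **kwargs).fit()
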