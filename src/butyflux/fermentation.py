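"""Carbon recovery, ammonia sequestration and enzyme specific activity.

Carbon recovery is the fraction of consumed substrate carbon found in the
measured products, computed from concentration changes and carbon counts.
NH₃ carries no carbon and never enters the recovery; CO₂ counts one carbon
when it was measured. Recovery below 1 reflects anabolic assimilation plus
unmeasured products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import pandas as pd

from .chem import Metabolite
from .pathway import load_pathway
from .stoichiometry import BalancedEquation

#: Accepted spellings for compounds in input tables.
COMPOUND_ALIASES = {
    "nh3": "ammonia",
    "nh4": "ammonia",
    "ammonium": "ammonia",
    "h2o": "water",
    "l-lysine": "lysine",
    "l-lactate": "lactate",
    "carbon dioxide": "co2",
}


@lru_cache(maxsize=1)
def _packaged_metabolites() -> tuple[tuple[str, Metabolite], ...]:
    return tuple(load_pathway().metabolites.items())


def _default_formula_registry() -> dict[str, Metabolite]:
    return dict(_packaged_metabolites())


def canonical_compound(name: str) -> str:
    key = name.strip().lower()
    return COMPOUND_ALIASES.get(key, key)


@dataclass
class FermentationRecord:
    """Concentration changes of substrates and products over a fermentation.

    ``entries`` holds (compound, Δconcentration in mM, role); Δconcentration
    is the consumption magnitude for substrates and the production magnitude
    for products (both non-negative).
    """

    entries: list[tuple[str, float, str]]
    formulas: dict[str, Metabolite] = field(default_factory=dict)

    def __post_init__(self):
        registry = _default_formula_registry()
        registry.update(self.formulas)
        clean = []
        resolved: dict[str, Metabolite] = {}
        for compound, delta, role in self.entries:
            name = canonical_compound(compound)
            if role not in ("substrate", "product"):
                raise ValueError(f"role {role!r} must be substrate/product")
            if delta < 0:
                raise ValueError(
                    f"{name}: negative delta {delta}; supply consumption/production magnitudes"
                )
            if name not in registry:
                raise KeyError(f"no formula known for compound {name!r}")
            resolved[name] = registry[name]
            clean.append((name, float(delta), role))
        self.entries = clean
        self.formulas = resolved

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, formulas=None) -> "FermentationRecord":
        """Build from a table with columns (compound, delta_mM, role)."""
        need = {"compound", "delta_mM", "role"}
        if not need <= set(df.columns):
            raise ValueError(f"table must have columns {sorted(need)}")
        return cls(
            entries=[(r.compound, r.delta_mM, r.role) for r in df.itertuples()],
            formulas=formulas or {},
        )

    def side(self, role: str) -> list[tuple[str, float]]:
        return [(n, d) for n, d, r in self.entries if r == role]

    def carbon_mM(self, role: str) -> float:
        return sum(d * self.formulas[n].n_carbons for n, d in self.side(role))

    def per_compound_carbon(self) -> dict[str, float]:
        return {n: d * self.formulas[n].n_carbons for n, d, _ in self.entries}


def carbon_recovery(record: FermentationRecord) -> float:
    """Product carbon over substrate carbon (mM C / mM C).

    Raises
    ------
    ValueError
        If the record lacks a substrate or product, or substrate carbon is 0.
    """
    if not record.side("substrate") or not record.side("product"):
        raise ValueError("record needs at least one substrate and one product")
    denom = record.carbon_mM("substrate")
    if denom <= 0:
        raise ZeroDivisionError("substrate carbon is zero; recovery undefined")
    return record.carbon_mM("product") / denom


def recovery_percent(record: FermentationRecord) -> int:
    """Carbon recovery rounded to the nearest integer percent (display)."""
    return round(carbon_recovery(record) * 100)


@dataclass(frozen=True)
class AmmoniaGap:
    expected_mM: float
    observed_mM: float
    sequestered_mM: float
    over_recovery: bool  # observed exceeded the stoichiometric expectation


def ammonia_gap(record: FermentationRecord, equation: BalancedEquation) -> AmmoniaGap:
    """Stoichiometrically expected vs observed NH₃; the shortfall estimates
    ammonia sequestered into biomass during anabolism."""
    coeffs = {m.name: c for m, c in equation.products}
    if "ammonia" not in coeffs:
        raise ValueError("equation has no ammonia product")
    ref_delta = dict(record.side("substrate")).get(equation.reference)
    if ref_delta is None:
        raise ValueError(
            f"record has no substrate entry for reference {equation.reference!r}"
        )
    observed = dict(record.side("product")).get("ammonia", 0.0)
    expected = float(ref_delta * Fraction(coeffs["ammonia"]))
    seq = expected - observed
    return AmmoniaGap(
        expected_mM=expected,
        observed_mM=observed,
        sequestered_mM=seq,
        over_recovery=seq < 0,
    )


@dataclass(frozen=True)
class ActivityAssay:
    """Continuous spectrophotometric assay following product formation.

    The acetoacetyl-CoA transferase assay tracks A₃₁₀ with
    ε₃₁₀ = 15.1 mM⁻¹ cm⁻¹; activity is expressed in U (µmol min⁻¹) per mg
    total protein.
    """

    dA_per_min: float
    epsilon_mM_cm: float = 15.1
    path_cm: float = 1.0
    assay_volume_ml: float = 1.0
    protein_mg: float = 1.0

    def __post_init__(self):
        if self.epsilon_mM_cm <= 0 or self.path_cm <= 0 or self.assay_volume_ml <= 0:
            raise ValueError("epsilon, path length and volume must be positive")
        if self.protein_mg <= 0:
            raise ValueError("protein mass must be positive")


def specific_activity(assay: ActivityAssay) -> float:
    """U per mg protein: ΔA/min → mM/min via Beer-Lambert, × volume in ml
    gives µmol/min (U), divided by protein mass."""
    rate_mM_per_min = assay.dA_per_min / (assay.epsilon_mM_cm * assay.path_cm)
    units = rate_mM_per_min * assay.assay_volume_ml  # mM * ml = µmol → µmol/min
    return units / assay.protein_mg


def recovery_report(
    record: FermentationRecord, equation: BalancedEquation | None = None
) -> dict:
    """JSON-ready report: recovery, per-compound carbon, optional ammonia gap."""
    out = {
        "carbon_recovery": carbon_recovery(record),
        "carbon_recovery_percent": recovery_percent(record),
        "per_compound_carbon_mM": record.per_compound_carbon(),
    }
    if equation is not None:
        gap = ammonia_gap(record, equation)
        out["ammonia_gap"] = {
            "expected_mM": gap.expected_mM,
            "observed_mM": gap.observed_mM,
            "sequestered_mM": gap.sequestered_mM,
            "over_recovery": gap.over_recovery,
        }
    return out
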