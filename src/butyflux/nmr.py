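"""HMBC cross-peak quantification of butyrate positional isotopomers.

In an HMBC experiment without decoupling, the three-bond cross-peaks between
H-2 and C-4 and between H-4 and C-2 of butyrate are split by the large
one-bond coupling whenever the carbon attached to the observed proton is
itself ¹³C-enriched. The non-split H2-C4 peak therefore reports molecules
labelled at C4 only, the non-split H4-C2 peak molecules labelled at C2 only,
and the two split peaks both report the doubly labelled [2,4-¹³C] population.
Because the split peaks measure the same population, the factor equalizing
them calibrates away the per-proton sensitivity difference and the three
class fractions follow from the corrected integrals.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import UndefinedFractionsError
from .tracer import ClassFractions


@dataclass(frozen=True)
class HmbcIntegralSet:
    """The four HMBC integrals (arbitrary units, already summed over doublet
    components)."""

    h2c4_nonsplit: float
    h2c4_split: float
    h4c2_nonsplit: float
    h4c2_split: float

    def __post_init__(self):
        vals = (self.h2c4_nonsplit, self.h2c4_split, self.h4c2_nonsplit, self.h4c2_split)
        if any(v < 0 for v in vals):
            raise ValueError("integrals must be non-negative")

    def as_tuple(self):
        return (self.h2c4_nonsplit, self.h2c4_split, self.h4c2_nonsplit, self.h4c2_split)


@dataclass(frozen=True)
class HmbcEstimate:
    """Butyrate class fractions with the split-peak equalization factor."""

    fractions: ClassFractions
    equalization_factor: float
    no_double_label: bool = False  # both split peaks zero; factor defaulted to 1


def estimate_butyrate_fractions(integrals: HmbcIntegralSet) -> HmbcEstimate:
    """Estimate [2-¹³C]/[4-¹³C]/[2,4-¹³C]butyrate fractions from HMBC
    integrals.

    The factor ``f = h2c4_split / h4c2_split`` moves the H4-side integrals
    onto the H2-side scale; the corrected non-split H4-C2 integral then
    measures the C2-only population on a common scale and the three
    fractions are the corrected integrals normalized to their sum.

    Raises
    ------
    UndefinedFractionsError
        If all four integrals are zero.
    ValueError
        If exactly one split integral is zero (the split peaks must refer to
        the same doubly labelled population).
    """
    a, b, c, d = integrals.as_tuple()  # h2c4_ns, h2c4_s, h4c2_ns, h4c2_s
    if a == b == c == d == 0:
        raise UndefinedFractionsError("all four HMBC integrals are zero")
    no_double = False
    if b == 0 and d == 0:
        # no doubly labelled population to calibrate on; assume equal
        # per-proton sensitivity
        f = 1.0
        no_double = True
    elif b == 0 or d == 0:
        raise ValueError(
            "inconsistent integrals: exactly one split cross-peak is zero, but both "
            "report the same [2,4-13C] population"
        )
    else:
        f = b / d
    c_corrected = f * c
    total = a + b + c_corrected
    if total <= 0:
        raise UndefinedFractionsError("corrected integrals sum to zero")
    fractions = ClassFractions(p2=c_corrected / total, p4=a / total, p24=b / total)
    return HmbcEstimate(fractions=fractions, equalization_factor=f, no_double_label=no_double)


# ---------------------------------------------------------------------------
# chemical-shift assignment


@dataclass(frozen=True)
class ShiftTable:
    """Reference ¹³C chemical shifts, (compound, position) -> p.p.m."""

    entries: tuple[tuple[str, int, float], ...]

    def __post_init__(self):
        keys = [(c, p) for c, p, _ in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (compound, position) entries")
        if any(s <= 0 for _, _, s in self.entries):
            raise ValueError("shifts must be positive")

    @classmethod
    def default(cls) -> "ShiftTable":
        """The packaged table: C-6/C-2 of lysine, C-2/C-4 of butyrate and
        C-2 of acetate."""
        with resources.files("butyflux.data").joinpath("chemical_shifts.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ShiftTable":
        return cls(
            tuple(
                (str(r.compound), int(r.position), float(r.shift_ppm))
                for r in df.itertuples()
            )
        )


@dataclass(frozen=True)
class PeakAssignment:
    compound: str
    position: int
    shift_ppm: float
    distance_ppm: float
    ambiguous: bool = False
    candidates: tuple[tuple[str, int], ...] = ()


def assign_peak(shift: float, table: ShiftTable, tol: float = 0.2) -> PeakAssignment | None:
    """Assign a 1-D ¹³C peak to the nearest reference entry within ``tol``
    p.p.m.; returns None when nothing matches, and flags ambiguity when more
    than one entry falls within the tolerance."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    hits = [
        (abs(shift - s), compound, pos, s)
        for compound, pos, s in table.entries
        if abs(shift - s) <= tol
    ]
    if not hits:
        return None
    hits.sort()
    dist, compound, pos, ref = hits[0]
    return PeakAssignment(
        compound=compound,
        position=pos,
        shift_ppm=ref,
        distance_ppm=dist,
        ambiguous=len(hits) > 1,
        candidates=tuple((c, p) for _, c, p, _ in hits),
    )


# ---------------------------------------------------------------------------
# table I/O

INTEGRAL_COLUMNS = ("h2c4_nonsplit", "h2c4_split", "h4c2_nonsplit", "h4c2_split")


def read_integral_table(path_or_buf) -> pd.DataFrame:
    """Read an HMBC integral table (experiment_id + the four integral
    columns)."""
    df = pd.read_csv(path_or_buf)
    missing = [c for c in ("experiment_id", *INTEGRAL_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"integral table missing columns: {missing}")
    return df


def estimate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`estimate_butyrate_fractions` to each row of an integral
    table; returns fractions and factors per experiment."""
    rows = []
    for r in df.itertuples():
        est = estimate_butyrate_fractions(
            HmbcIntegralSet(r.h2c4_nonsplit, r.h2c4_split, r.h4c2_nonsplit, r.h4c2_split)
        )
        rows.append(
            {
                "experiment_id": r.experiment_id,
                "p2": est.fractions.p2,
                "p4": est.fractions.p4,
                "p24": est.fractions.p24,
                "equalization_factor": est.equalization_factor,
                "no_double_label": est.no_double_label,
            }
        )
    return pd.DataFrame(rows)
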