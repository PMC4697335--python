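"""Synthetic-data generators for exercising the pipeline end to end.

Everything here is a deterministic function of (spec, seed). The generators
emulate the study's measurement types, not its raw data:

* Gompertz-shaped fermentation time courses in which each product tracks
  substrate consumption through the coefficients of a balanced equation,
  with additive truncated-Gaussian measurement noise;
* HMBC integral quadruples constructed from true butyrate class fractions
  with independent per-proton attenuation factors on the H2 and H4 sides;
* noisy observed class fractions from the tracer model (multiplicative
  lognormal noise, renormalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fermentation import FermentationRecord
from .growth import GrowthCurve, gompertz
from .nmr import HmbcIntegralSet
from .pathway import PathwayModel
from .stoichiometry import BalancedEquation
from .tracer import (
    ClassFractions,
    FluxConfig,
    LabelingState,
    propagate_labels,
    to_class_fractions,
)


@dataclass
class SimulationSpec:
    """Conditions for the fermentation time-course generator.

    Defaults emulate the lysine fermentation: 16.8 mM substrate, growth at
    μmax = 0.1 h⁻¹ with a 5 h lag over a 48 h course (stationary after two
    days), and small additive measurement noise.
    """

    equation: BalancedEquation
    substrate_mM: float = 16.8
    gompertz_params: tuple[float, float, float] = (2.0, 0.1, 5.0)  # A, mu_max, lambda
    noise_sd: dict = field(default_factory=lambda: {"concentration": 0.0, "od": 0.0})
    attenuation: tuple[float, float] = (1.0, 1.0)
    n_timepoints: int = 25
    t_end_h: float = 48.0
    od0: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.substrate_mM <= 0 or self.n_timepoints < 2 or self.t_end_h <= 0:
            raise ValueError("spec sizes must be positive")
        if any(a <= 0 for a in self.attenuation):
            raise ValueError("attenuation factors must be positive")


def gen_growth_timecourse(
    spec: SimulationSpec,
) -> tuple[GrowthCurve, pd.DataFrame, FermentationRecord]:
    """Simulate substrate depletion, product formation and OD₆₀₀.

    The cumulative consumed substrate follows the Gompertz shape normalized
    to complete consumption at the final time point; each product is the
    consumed substrate times its stoichiometric coefficient relative to the
    reference. Gaussian noise (sd per observable class) is added and
    truncated at zero. Returns the OD curve, the full concentration table
    and the endpoint record (computed from the noiseless closure so that the
    record reflects the endpoint changes actually simulated).
    """
    rng = np.random.default_rng(spec.seed)
    A, mu, lam = spec.gompertz_params
    t = np.linspace(0.0, spec.t_end_h, spec.n_timepoints)
    y = gompertz(t, A, mu, lam)
    frac = y / y[-1]  # consumption fraction, 1 at the final point

    ref = spec.equation.reference
    ref_coeff = float(spec.equation.coefficient(ref))
    consumed = spec.substrate_mM * frac

    table = {"time_h": t, ref: spec.substrate_mM - consumed}
    products = {}
    for met, coeff in spec.equation.products:
        conc = consumed * float(coeff) / ref_coeff
        products[met.name] = conc
        table[met.name] = conc

    sd_c = float(spec.noise_sd.get("concentration", 0.0))
    sd_od = float(spec.noise_sd.get("od", 0.0))
    od = spec.od0 * np.exp(y)
    if sd_od > 0:
        od = np.maximum(od + rng.normal(0.0, sd_od, od.shape), 0.0)
    df = pd.DataFrame(table)
    if sd_c > 0:
        for col in df.columns[1:]:
            df[col] = np.maximum(df[col] + rng.normal(0.0, sd_c, len(df)), 0.0)
    df["od600"] = od

    curve = GrowthCurve(times=t, od=od, od0=spec.od0)
    entries = [(ref, float(spec.substrate_mM), "substrate")]
    entries += [(name, float(conc[-1]), "product") for name, conc in products.items()]
    record = FermentationRecord(entries=entries)
    return curve, df, record


def gen_hmbc_integrals(
    true_fractions: ClassFractions,
    total_signal: float = 10.0,
    attenuation: tuple[float, float] = (1.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> HmbcIntegralSet:
    """Construct the four HMBC integrals from true class fractions.

    Noiseless construction: the H2-side peaks carry (p4, p24) and the
    H4-side peaks (p2, p24), each side scaled by its attenuation factor and
    the total signal; additive Gaussian noise is truncated at zero. The
    estimator inverts this construction exactly at zero noise for any
    positive attenuation pair (provided p24 > 0, which calibrates the
    equalization factor).
    """
    a_h2, a_h4 = attenuation
    if a_h2 <= 0 or a_h4 <= 0:
        raise ValueError("attenuation factors must be positive")
    f = true_fractions
    vals = np.array(
        [
            a_h2 * f.p4 * total_signal,
            a_h2 * f.p24 * total_signal,
            a_h4 * f.p2 * total_signal,
            a_h4 * f.p24 * total_signal,
        ]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = np.maximum(vals + rng.normal(0.0, noise_sd, 4), 0.0)
    return HmbcIntegralSet(*map(float, vals))


def gen_labeling_observation(
    model: PathwayModel,
    substrate_label: LabelingState,
    flux: FluxConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ClassFractions:
    """Noisy observed butyrate class fractions from the tracer model:
    propagate → marginalize → multiplicative lognormal noise → renormalize."""
    dists = propagate_labels(model, substrate_label, flux)
    true = to_class_fractions(dists["butyrate"])
    if noise_sd <= 0:
        return true
    rng = np.random.default_rng(seed)
    noisy = true.as_array() * rng.lognormal(0.0, noise_sd, 3)
    noisy = noisy / noisy.sum()
    return ClassFractions(p2=float(noisy[0]), p4=float(noisy[1]), p24=float(noisy[2]))
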