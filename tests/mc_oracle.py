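"""Independent Monte-Carlo oracle for the steady-state label tracer.

Simulates the acetyl-CoA pool as a population of particles updated over
generations (each particle re-drawn from its source: the lysine C1-C2
fragment, a random half of a butyrate molecule from the previous generation
(the CoA-transferase/thiolase recycling exchange), exogenous acetate, or a
glycolytic acetyl unit), then samples butyrate molecules as a theta-mixture
of the lysine-branch pattern and condensations of two random pool particles.

This restates the model's *definition* by direct sampling; it shares no code
with the analytic fixed-point solver.
"""

from __future__ import annotations

import numpy as np


def mc_distributions(
    lys_pattern,
    theta,
    weights,  # (w_lysine_C1C2, w_recycled, w_exogenous, w_glycolysis)
    exo_pattern=(0, 0),
    gly_patterns=None,  # two (c1, c2) acetyl patterns, or None for unlabelled
    n_pool=100_000,
    n_draws=100_000,
    generations=40,
    seed=0,
):
    """Empirical (butyrate 16-state, acetate 4-state) distributions.

    Returns (butyrate_probs, acetate_probs, butyrate_draws) where
    butyrate_draws is the (n_draws, 4) boolean label matrix for downstream
    class-fraction counting.
    """
    rng = np.random.default_rng(seed)
    l = np.asarray(lys_pattern, dtype=bool)
    b_lb = l[2:6]  # lysine C3..C6 -> butyrate C1..C4
    a_lys = l[0:2]  # lysine C1..C2 -> acetyl C1..C2
    w = np.asarray(weights, dtype=float)
    assert abs(w.sum() - 1.0) < 1e-9

    pool = np.zeros((n_pool, 2), dtype=bool)
    for _ in range(generations):
        src = rng.choice(4, size=n_pool, p=w)
        new = np.zeros_like(pool)
        new[src == 0] = a_lys
        new[src == 2] = np.asarray(exo_pattern, dtype=bool)
        idx = np.flatnonzero(src == 3)
        if idx.size:
            if gly_patterns is None:
                new[idx] = False
            else:
                arr = np.asarray(gly_patterns, dtype=bool)
                new[idx] = arr[rng.integers(0, 2, idx.size)]
        idx = np.flatnonzero(src == 1)
        if idx.size:
            but = _sample_butyrate(rng, idx.size, theta, b_lb, pool)
            take_first = rng.integers(0, 2, idx.size).astype(bool)
            new[idx] = np.where(take_first[:, None], but[:, 0:2], but[:, 2:4])
        pool = new

    but = _sample_butyrate(rng, n_draws, theta, b_lb, pool)
    but_idx = but @ (1 << np.arange(4))
    butyrate_probs = np.bincount(but_idx, minlength=16) / n_draws
    ace_idx = pool @ (1 << np.arange(2))
    acetate_probs = np.bincount(ace_idx, minlength=4) / n_pool
    return butyrate_probs, acetate_probs, but


def _sample_butyrate(rng, n, theta, b_lb, pool):
    """theta-mixture of the lysine-branch pattern and pool condensations;
    unit B fills C1-C2, unit A fills C3-C4."""
    out = np.empty((n, 4), dtype=bool)
    is_lb = rng.random(n) < theta
    out[is_lb] = b_lb
    n_cond = int((~is_lb).sum())
    if n_cond:
        i_b = rng.integers(0, pool.shape[0], n_cond)
        i_a = rng.integers(0, pool.shape[0], n_cond)
        out[~is_lb, 0:2] = pool[i_b]
        out[~is_lb, 2:4] = pool[i_a]
    return out


def mc_class_fractions(but_draws):
    """Empirical (p2, p4, p24, n_labelled) from sampled butyrate labels."""
    has2 = but_draws[:, 1]
    has4 = but_draws[:, 3]
    observed = has2 | has4
    n_obs = int(observed.sum())
    if n_obs == 0:
        return None
    p2 = float((has2 & ~has4).sum()) / n_obs
    p4 = float((~has2 & has4).sum()) / n_obs
    p24 = float((has2 & has4).sum()) / n_obs
    return p2, p4, p24, n_obs


def random_flux_configs(rng, n):
    """Randomized tracer configurations over the experimentally relevant
    lysine label positions (2, 4, 6: the positions whose label can reach
    butyrate C2/C4, where the HMBC classes are defined)."""
    configs = []
    for _ in range(n):
        theta = rng.uniform(0.2, 0.95)
        w_rec = rng.uniform(0.05, 0.6)
        w_exo = rng.uniform(0.0, 0.2)
        w_gly = rng.uniform(0.0, 0.1)
        w_lys = 1.0 - w_rec - w_exo - w_gly
        pos = int(rng.choice([2, 4, 6]))
        exo = (0, 1) if rng.random() < 0.5 else (0, 0)
        configs.append(
            {
                "position": pos,
                "theta": theta,
                "weights": (w_lys, w_rec, w_exo, w_gly),
                "exo_pattern": exo,
            }
        )
    return configs
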