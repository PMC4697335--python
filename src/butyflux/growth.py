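"""Modified Gompertz growth-curve fitting and generation times.

The model (Zwietering parameterization) is fitted to the log-transformed
optical density y(t) = ln(OD(t)/OD₀):

    y(t) = A · exp(−exp(μmax·e/A · (λ − t) + 1))

with A the asymptotic ln-fold growth, μmax the maximum specific growth rate
(h⁻¹, the slope of the tangent at the inflection) and λ the lag time (h).
The generation time is ln 2 / μmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import NoGrowthError

_E = np.e

#: a curve whose total ln-fold change stays below this is treated as no growth
MIN_GROWTH_LOG_RATIO = 0.05


def gompertz(t, A, mu_max, lam):
    """Modified Gompertz curve on the ln(OD/OD0) scale."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp(mu_max * _E / A * (lam - t) + 1.0))


def generation_time(mu_max: float) -> float:
    """Doubling time ln2/μmax in hours."""
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    return float(np.log(2.0) / mu_max)


@dataclass
class GrowthCurve:
    """An OD₆₀₀ time course; ``od0`` is the baseline used for the log
    transform (defaults to the first reading)."""

    times: np.ndarray
    od: np.ndarray
    od0: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("negative OD values")
        if self.od0 is None:
            self.od0 = float(self.od[0])
        if self.od0 <= 0:
            raise ValueError("baseline od0 must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, od0: float | None = None) -> "GrowthCurve":
        """Columns (time_h, od600)."""
        if not {"time_h", "od600"} <= set(df.columns):
            raise ValueError("table must have columns time_h, od600")
        df = df.sort_values("time_h")
        return cls(df["time_h"].to_numpy(), df["od600"].to_numpy(), od0=od0)

    @property
    def log_ratio(self) -> np.ndarray:
        """y = ln(OD/OD0); zero ODs are floored at a tiny positive value."""
        od = np.maximum(self.od, 1e-12)
        return np.log(od / self.od0)


@dataclass
class GompertzResults:
    """Fitted growth parameters with uncertainties and diagnostics."""

    A: float
    mu_max: float
    lam: float
    rss: float
    converged: bool
    stderr: dict[str, float]
    n_obs: int
    curve: GrowthCurve

    @property
    def generation_time(self) -> float:
        return generation_time(self.mu_max)

    @property
    def params(self) -> dict[str, float]:
        return {"A": self.A, "mu_max": self.mu_max, "lambda": self.lam}

    def predict(self, times=None) -> np.ndarray:
        t = self.curve.times if times is None else np.asarray(times, float)
        return gompertz(t, self.A, self.mu_max, self.lam)

    def summary(self) -> str:
        se = self.stderr
        lines = [
            "Modified Gompertz fit on ln(OD/OD0)",
            "=" * 43,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
            f"{'A':<12}{self.A:>12.4f}{se.get('A', float('nan')):>12.4f}",
            f"{'mu_max /h':<12}{self.mu_max:>12.4f}{se.get('mu_max', float('nan')):>12.4f}",
            f"{'lambda h':<12}{self.lam:>12.4f}{se.get('lambda', float('nan')):>12.4f}",
            "-" * 43,
            f"generation time: {self.generation_time:.2f} h (= ln2/mu_max)",
            f"RSS: {self.rss:.3e}   n = {self.n_obs}   converged: {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.linspace(self.curve.times[0], self.curve.times[-1], 200)
        ax.plot(self.curve.times, self.curve.log_ratio, "o", label="observed")
        ax.plot(t, self.predict(t), "-", label="Gompertz fit")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("ln(OD/OD0)")
        ax.legend()
        return ax


class GompertzModel:
    """Nonlinear least-squares Gompertz model for one growth curve.

    Initial values come from the data: A₀ is the maximum of y, μ₀ the
    steepest finite-difference slope, λ₀ the time where the tangent at the
    steepest point crosses y = 0.
    """

    def __init__(self, curve: GrowthCurve):
        if curve.times.size < 5:
            raise ValueError("need at least 5 points to fit a 3-parameter model")
        self.curve = curve
        self.y = curve.log_ratio

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, od0: float | None = None) -> "GompertzModel":
        return cls(GrowthCurve.from_dataframe(df, od0=od0))

    def _initial_values(self):
        t, y = self.curve.times, self.y
        A0 = float(np.max(y))
        slopes = np.diff(y) / np.diff(t)
        k = int(np.argmax(slopes))
        mu0 = float(max(slopes[k], 1e-3))
        t_star = 0.5 * (t[k] + t[k + 1])
        y_star = 0.5 * (y[k] + y[k + 1])
        lam0 = float(max(t_star - y_star / mu0, 0.0))
        return A0, mu0, lam0

    def fit(self) -> GompertzResults:
        """Bounded nonlinear least squares on y = ln(OD/OD0).

        Raises
        ------
        NoGrowthError
            If the curve never rises MIN_GROWTH_LOG_RATIO above baseline.
        """
        t, y = self.curve.times, self.y
        if float(np.max(y)) < MIN_GROWTH_LOG_RATIO:
            raise NoGrowthError(
                f"max ln(OD/OD0) = {np.max(y):.4f} < {MIN_GROWTH_LOG_RATIO}; "
                "no measurable growth"
            )
        x0 = np.array(self._initial_values())
        lower = [1e-6, 1e-6, 0.0]
        upper = [10.0 * max(x0[0], 0.1), 100.0 * x0[1], float(t[-1])]
        x0 = np.clip(x0, lower, upper)

        def resid(p):
            return gompertz(t, *p) - y

        sol = least_squares(resid, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14)
        A, mu, lam = map(float, sol.x)
        rss = float(np.sum(sol.fun**2))
        stderr = self._stderr(sol, rss, t.size)
        return GompertzResults(
            A=A,
            mu_max=mu,
            lam=lam,
            rss=rss,
            converged=bool(sol.success),
            stderr=stderr,
            n_obs=int(t.size),
            curve=self.curve,
        )

    @staticmethod
    def _stderr(sol, rss, n):
        dof = max(n - 3, 1)
        s2 = rss / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        return {"A": float(se[0]), "mu_max": float(se[1]), "lambda": float(se[2])}


def fit_gompertz(curve: GrowthCurve) -> GompertzResults:
    """Convenience wrapper: ``GompertzModel(curve).fit()``."""
    return GompertzModel(curve).fit()
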