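"""Method-agreement statistics for paired descriptor series.

Given paired values from this tool and a reference method (typically
quantum-chemistry iso-density surfaces), computes the standard error
battery — MSE, RMSE, MAE, per-pair relative errors and APE, MAPE —
together with Pearson's r, the OLS coefficient of determination R²,
Bland–Altman bias and 95% limits of agreement, plus Cochran sample-size
selection and bootstrap uncertainty for any metric.

Residuals are oriented ``method − reference`` throughout; relative errors
are residuals over the reference value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "PairedSeries",
    "AgreementMetrics",
    "Metric",
    "agreement",
    "cochran_sample_size",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired method/reference values of equal length n ≥ 2."""

    method_values: np.ndarray
    reference_values: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.method_values, dtype=float)
        r = np.asarray(self.reference_values, dtype=float)
        if m.ndim != 1 or r.ndim != 1 or m.shape != r.shape:
            raise ValueError("method and reference must be 1-D of equal length")
        if m.size < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(r))):
            raise ValueError("paired values must be finite")
        object.__setattr__(self, "method_values", m)
        object.__setattr__(self, "reference_values", r)

    @property
    def n(self) -> int:
        return int(self.method_values.size)

    @classmethod
    def from_sequences(
        cls, method: Sequence[float], reference: Sequence[float]
    ) -> "PairedSeries":
        return cls(np.asarray(method, float), np.asarray(reference, float))


@dataclass(frozen=True)
class AgreementMetrics:
    """The full agreement battery for one paired series."""

    mse: float
    rmse: float
    mae: float
    mape: float  # percent
    relative_errors: np.ndarray
    ape: np.ndarray  # percent
    pearson_r: float
    r_squared: float
    bland_mean_residual: float
    loa_low: float
    loa_high: float
    n: int


def agreement(pairs: PairedSeries) -> AgreementMetrics:
    """Compute every agreement metric for ``pairs``.

    MSE is the mean squared residual, RMSE its square root, MAE the mean
    absolute residual; relative error is residual/reference (so MAPE
    requires nonzero references), APE its absolute value in percent and
    MAPE the mean APE. R² is the coefficient of determination of the OLS
    regression of method on reference with intercept (equal to r² for
    simple regression). The Bland–Altman summary is the mean residual with
    ±1.96·SD limits of agreement.
    """
    m = pairs.method_values
    r = pairs.reference_values
    resid = m - r
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(resid)))
    zero = np.flatnonzero(r == 0.0)
    if zero.size:
        raise ZeroDivisionError(
            f"reference value is 0 at index {zero[0]}; relative error undefined"
        )
    rel = resid / r
    ape = np.abs(rel) * 100.0
    mape = float(np.mean(ape))
    if np.ptp(m) == 0.0 or np.ptp(r) == 0.0:
        # constant series: correlation undefined; perfect agreement ⇒ 1
        pearson = 1.0 if np.allclose(m, r) else float("nan")
        r2 = pearson**2 if pearson == pearson else float("nan")
    else:
        lr = _sps.linregress(r, m)
        pearson = float(lr.rvalue)
        r2 = float(lr.rvalue**2)
    bias = float(np.mean(resid))
    sd = float(np.std(resid, ddof=1))
    return AgreementMetrics(
        mse=mse,
        rmse=rmse,
        mae=mae,
        mape=mape,
        relative_errors=rel,
        ape=ape,
        pearson_r=pearson,
        r_squared=r2,
        bland_mean_residual=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=pairs.n,
    )


def cochran_sample_size(
    z: float, p_hat: float, epsilon: float, population_n: int | None = None
) -> tuple[float, float]:
    """Cochran sample size ``n = z²·p̂(1−p̂)/ε²`` and its finite-population
    correction ``n′ = n / (1 + n/N)``.

    Returns ``(n, n_prime)``; with no population size (infinite N),
    ``n_prime == n``.
    """
    if not (0.0 < p_hat < 1.0):
        raise ValueError("p_hat must lie in (0, 1)")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    n = z**2 * p_hat * (1.0 - p_hat) / epsilon**2
    if population_n is None:
        return n, n
    if population_n <= 0:
        raise ValueError("population_n must be positive")
    n_prime = n / (1.0 + n / population_n)
    return n, n_prime


class Metric(enum.Enum):
    """Metrics resolvable by :func:`bootstrap_ci`."""

    mse = "mse"
    rmse = "rmse"
    mae = "mae"
    mape = "mape"
    pearson_r = "pearson_r"
    r_squared = "r_squared"
    bland_mean_residual = "bland_mean_residual"


def _metric_value(pairs: PairedSeries, metric: Metric) -> float:
    return float(getattr(agreement(pairs), metric.value))


def bootstrap_ci(
    pairs: PairedSeries,
    metric: Metric | str,
    reps: int = 1000,
    seed: int = 0,
    percentile: bool = False,
) -> tuple[float, float] | tuple[float, float, tuple[float, float]]:
    """Bootstrap uncertainty for one agreement metric.

    Pairs are resampled with replacement ``reps`` times and the metric is
    recomputed per replicate; the reported ± is the replicate standard
    deviation. With ``percentile=True`` the 2.5/97.5 percentile interval is
    appended. Seeded and reproducible.
    """
    if isinstance(metric, str):
        metric = Metric(metric)
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    point = _metric_value(pairs, metric)
    n = pairs.n
    values = np.empty(reps)
    for b in range(reps):
        idx = rng.integers(0, n, size=n)
        values[b] = _metric_value(
            PairedSeries(pairs.method_values[idx], pairs.reference_values[idx]),
            metric,
        )
    half_width = float(np.std(values, ddof=1))
    if percentile:
        lo, hi = np.percentile(values, [2.5, 97.5])
        return point, half_width, (float(lo), float(hi))
    return point, half_width
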