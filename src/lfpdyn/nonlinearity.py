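"""Surrogate-data nonlinearity tests.

The null hypothesis is that a trace was produced by a stationary Gaussian
linear process. A discriminating statistic lambda is computed on the original
trace (lambda_0) and on each of n surrogates (lambda_i); the null is rejected
when lambda_0 is incompatible with the surrogate distribution, judged by

* the average score  gamma = |mean(lambda_i)/lambda_0 - 1|  (> 1 rejects),
* the coefficient-of-variation score
  gamma = |mean(lambda_i) - lambda_0| / std(lambda_i)  (> 1.96 rejects at
  the 95% level for approximately normal lambda_i), or
* rank ordering: lambda_0 strictly first or last among the pooled values
  (at significance level l this needs at least n = 1/l surrogates, e.g. 20
  for l = 0.05).

Two statistics are provided: time-reversal asymmetry (irreversibility is a
signature of nonlinearity) and the false-nearest-neighbor fraction
(determinism lowers the FNN fraction of the original below every surrogate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .embedding import fnn_fraction
from .surrogates import SurrogateSet
from .timeseries import TimeSeries

__all__ = [
    "min_surrogates",
    "time_reversal_asymmetry",
    "gamma_avg",
    "gamma_cv",
    "rank_test",
    "discriminate",
    "fnn_discrimination",
    "DiscriminationResult",
    "FnnDiscriminationResult",
    "GAMMA_CV_THRESHOLD",
]

#: two-sided 95% normal critical value used for the coefficient-of-variation score
GAMMA_CV_THRESHOLD = 1.96


def min_surrogates(significance: float = 0.05) -> int:
    """Minimum surrogate count n = 1/l for a rank test at level ``l``."""
    if not (0 < significance < 1):
        raise ValueError("significance must lie in (0, 1)")
    return math.ceil(1.0 / significance)


def time_reversal_asymmetry(series: TimeSeries | np.ndarray, delay: int = 1) -> float:
    """Cubed-over-squared increment ratio, a time-irreversibility statistic.

    ``<(x_i - x_{i-delay})^3> / <(x_i - x_{i-delay})^2>`` over all valid i.
    Zero for any series with time-symmetric increment statistics.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if delay < 1:
        raise ValueError("delay must be >= 1")
    if x.size <= delay:
        raise ValueError("series shorter than the delay")
    d = x[delay:] - x[:-delay]
    denom = float(np.mean(d**2))
    if denom == 0:
        raise ValueError("time-reversal statistic undefined for constant series")
    return float(np.mean(d**3) / denom)


def gamma_avg(lambda0: float, lambdas: Sequence[float]) -> float:
    """Average-method score ``|mean(lambda_i)/lambda_0 - 1|``."""
    if lambda0 == 0:
        raise ValueError("gamma_avg undefined for lambda0 = 0")
    return abs(float(np.mean(lambdas)) / lambda0 - 1.0)


def gamma_cv(lambda0: float, lambdas: Sequence[float]) -> float:
    """Coefficient-of-variation score ``|mean(lambda_i) - lambda_0| / std(lambda_i)``."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size < 2:
        raise ValueError("need at least 2 surrogate statistics")
    sd = float(np.std(lambdas, ddof=1))
    if sd == 0:
        raise ValueError("gamma_cv undefined for zero surrogate spread")
    return abs(float(np.mean(lambdas)) - lambda0) / sd


def rank_test(lambda0: float, lambdas: Sequence[float]) -> tuple[int, bool]:
    """Position of lambda_0 in the ascending pooled list and the verdict.

    Rejects only when lambda_0 is *strictly* first or last; a tie with a
    surrogate at the extreme does not reject. For reporting, a tied lambda_0
    is placed at the extreme position of its tie block.
    """
    lam = np.asarray(lambdas, dtype=float)
    n = lam.size
    below = int(np.sum(lam < lambda0))
    above = int(np.sum(lam > lambda0))
    ties = n - below - above
    if below == 0:
        rank = 1
    elif above == 0:
        rank = n + 1
    else:
        rank = below + 1
    reject = (below == 0 or above == 0) and ties == 0
    return rank, reject


@dataclass(frozen=True)
class DiscriminationResult:
    """Scalar-statistic surrogate test outcome for one trace."""

    lambda0: float
    lambdas: np.ndarray
    gamma_avg: float
    gamma_cv: float
    rank: int
    reject_cv: bool
    reject_rank: bool

    @property
    def n(self) -> int:
        return self.lambdas.size


def discriminate(
    surrogate_set: SurrogateSet,
    delay: int = 1,
    threshold: float = GAMMA_CV_THRESHOLD,
) -> DiscriminationResult:
    """Run the time-reversal-asymmetry surrogate test on one trace."""
    lam0 = time_reversal_asymmetry(surrogate_set.original, delay=delay)
    lams = np.array(
        [
            time_reversal_asymmetry(surrogate_set.surrogates[i], delay=delay)
            for i in range(surrogate_set.n)
        ]
    )
    g_cv = gamma_cv(lam0, lams)
    rank, reject_rank = rank_test(lam0, lams)
    try:
        g_avg = gamma_avg(lam0, lams)
    except ValueError:
        g_avg = float("nan")
    return DiscriminationResult(
        lambda0=lam0,
        lambdas=lams,
        gamma_avg=g_avg,
        gamma_cv=g_cv,
        rank=rank,
        reject_cv=bool(g_cv > threshold),
        reject_rank=reject_rank,
    )


@dataclass(frozen=True)
class FnnDiscriminationResult:
    """FNN-fraction surrogate test outcome for one trace."""

    dims: np.ndarray
    original_curve: np.ndarray
    surrogate_curves: np.ndarray  # (n_surrogates, n_dims)
    reject: bool

    @property
    def surrogate_min(self) -> np.ndarray:
        return self.surrogate_curves.min(axis=0)

    @property
    def surrogate_max(self) -> np.ndarray:
        return self.surrogate_curves.max(axis=0)


def fnn_discrimination(
    surrogate_set: SurrogateSet,
    lag: int,
    dims=range(1, 6),
    f_ratio: float = 10.0,
    theiler: int = 0,
    sigma_criterion: bool = True,
) -> FnnDiscriminationResult:
    """Surrogate test using the FNN fraction as discriminating statistic.

    Determinism unfolds: the original's FNN percentage should fall strictly
    below the minimum over all surrogates at every tested dimension for the
    null to be rejected.
    """
    def curve(values: np.ndarray) -> np.ndarray:
        ts = surrogate_set.original.with_values(values)
        return fnn_fraction(
            ts,
            lag=lag,
            dims=dims,
            f_ratio=f_ratio,
            theiler=theiler,
            sigma_criterion=sigma_criterion,
        ).fnn_fraction

    orig = curve(np.asarray(surrogate_set.original.values))
    surro = np.vstack(
        [curve(surrogate_set.surrogates[i]) for i in range(surrogate_set.n)]
    )
    reject = bool(np.all(orig < surro.min(axis=0)))
    return FnnDiscriminationResult(
        dims=np.asarray(list(dims), dtype=int),
        original_curve=orig,
        surrogate_curves=surro,
        reject=reject,
    )
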