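"""Delay-embedding parameter estimation and trajectory construction.

Reconstruction of phase-space dynamics from a single observable uses delay
vectors ``(x_i, x_{i+n}, ..., x_{i+(d-1)n})`` with lag time ``tau = n*dt``.
The lag is chosen from the first zero of the autocorrelation function (linear
independence of coordinates) and the first local minimum of the average
mutual information (general statistical independence); the embedding
dimension ``d_E`` comes from the false-nearest-neighbor (FNN) criterion with
a Theiler window excluding temporally correlated neighbor pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .timeseries import TimeSeries

__all__ = [
    "autocorrelation",
    "first_zero_lag",
    "average_mutual_information",
    "first_min_lag",
    "estimate_lag",
    "fnn_fraction",
    "embed",
    "LagEstimate",
    "FnnCurve",
    "EmbeddedTrajectory",
]


def autocorrelation(
    series: TimeSeries, max_lag: int, mode: str = "periodic"
) -> np.ndarray:
    """Normalized autocorrelation for lags ``0..max_lag``.

    ``periodic`` mode treats the series as circular (the TISEAN ``autocor -p``
    convention the trial protocol uses); ``linear`` uses the biased
    (1/N-normalized) estimator. The value at lag 0 is exactly 1.
    """
    x = np.asarray(series.values, dtype=float)
    n = x.size
    if not (0 < max_lag < n):
        raise ValueError("max_lag must lie in [1, N-1]")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("autocorrelation of a constant series is undefined")
    if mode == "periodic":
        f = np.fft.rfft(x)
        acf = np.fft.irfft(f * np.conj(f), n=n).real
        out = acf[: max_lag + 1] / acf[0]
    elif mode == "linear":
        full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
        out = full / denom
    else:
        raise ValueError("mode must be 'periodic' or 'linear'")
    out[0] = 1.0
    return out


def first_zero_lag(curve: np.ndarray) -> int:
    """Smallest lag with autocorrelation <= 0.

    Raises if the curve never crosses zero (advising a larger ``max_lag``).
    """
    curve = np.asarray(curve, dtype=float)
    # tolerance so an exact zero computed in floating point still counts
    idx = np.flatnonzero(curve <= 1e-12)
    if idx.size == 0:
        raise ValueError(
            "autocorrelation has no zero crossing within max_lag; "
            "recompute with a larger max_lag"
        )
    return int(idx[0])


def interpolated_zero_crossing(curve: np.ndarray) -> float:
    """Linearly interpolated (fractional) index of the first zero crossing."""
    k = first_zero_lag(curve)
    if k == 0 or curve[k] == 0:
        return float(k)
    c0, c1 = curve[k - 1], curve[k]
    return float(k - 1 + c0 / (c0 - c1))


def average_mutual_information(
    series: TimeSeries, max_lag: int, n_bins: int = 16
) -> np.ndarray:
    """AMI (nats) between ``x_t`` and ``x_{t+k}`` for lags ``0..max_lag``.

    Probabilities come from an equal-width 2-D histogram with ``n_bins`` bins
    per axis spanning the observed range of the series.
    """
    x = np.asarray(series.values, dtype=float)
    n = x.size
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if not (0 < max_lag < n):
        raise ValueError("max_lag must lie in [1, N-1]")
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("AMI of a constant series is undefined")
    # precompute bin index of every sample once; reuse for every lag
    bins = np.minimum(
        (np.floor((x - lo) / (hi - lo) * n_bins)).astype(np.int64), n_bins - 1
    )
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        a = bins[: n - k]
        b = bins[k:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).astype(float)
        joint /= joint.sum()
        p = joint.reshape(n_bins, n_bins)
        pi = p.sum(axis=1)
        qj = p.sum(axis=0)
        mask = p > 0
        out[k] = float(
            np.sum(p[mask] * np.log(p[mask] / (np.outer(pi, qj)[mask])))
        )
    return out


def first_min_lag(curve: np.ndarray) -> int:
    """Smallest lag k with curve(k) < curve(k-1) and curve(k) <= curve(k+1)."""
    curve = np.asarray(curve, dtype=float)
    if curve.size < 3:
        raise ValueError("curve must have at least 3 points")
    falling = curve[1:-1] < curve[:-2]
    rising = curve[1:-1] <= curve[2:]
    idx = np.flatnonzero(falling & rising)
    if idx.size == 0:
        raise ValueError("curve has no local minimum within max_lag")
    return int(idx[0] + 1)


@dataclass(frozen=True)
class LagEstimate:
    """Candidate lag times for one trace, from ACF and AMI."""

    acf_curve: np.ndarray
    acf_first_zero: Optional[int]
    ami_curve: np.ndarray
    ami_first_min: Optional[int]
    chosen_lag: int


def estimate_lag(
    series: TimeSeries,
    max_lag: int,
    n_bins: int = 16,
    acf_mode: str = "periodic",
) -> LagEstimate:
    """Estimate the embedding lag from ACF first zero and AMI first minimum.

    The chosen lag defaults to the AMI first minimum when one exists,
    falling back to the ACF first zero; both curves are always reported.
    """
    acf = autocorrelation(series, max_lag, mode=acf_mode)
    try:
        acf_zero = first_zero_lag(acf)
    except ValueError:
        acf_zero = None
    ami = average_mutual_information(series, max_lag, n_bins=n_bins)
    try:
        ami_min = first_min_lag(ami)
    except ValueError:
        ami_min = None
    if ami_min is not None:
        chosen = ami_min
    elif acf_zero is not None and acf_zero >= 1:
        chosen = acf_zero
    else:
        raise ValueError(
            "no usable lag: AMI has no local minimum and ACF no zero crossing"
        )
    return LagEstimate(
        acf_curve=acf,
        acf_first_zero=acf_zero,
        ami_curve=ami,
        ami_first_min=ami_min,
        chosen_lag=int(chosen),
    )


@dataclass(frozen=True)
class EmbeddedTrajectory:
    """Delay-vector trajectory reconstructed from one trace."""

    points: np.ndarray  # (n_points, dim)
    lag: int
    dim: int
    source_id: str = ""


def embed(series: TimeSeries, lag: int, dim: int, source_id: str = "") -> EmbeddedTrajectory:
    """Build delay vectors ``(x_k, x_{k+lag}, ..., x_{k+(dim-1)lag})``.

    The trajectory has ``N - (dim-1)*lag`` points; each vector spans a time
    window ``t_w = (dim-1)*lag*dt``.
    """
    if lag < 1 or dim < 1:
        raise ValueError("lag and dim must be positive")
    n = series.n
    m = n - (dim - 1) * lag
    if m < 1:
        raise ValueError("series too short for the requested embedding")
    x = series.values
    points = np.empty((m, dim))
    for j in range(dim):
        points[:, j] = x[j * lag : j * lag + m]
    return EmbeddedTrajectory(points=points, lag=int(lag), dim=int(dim), source_id=source_id)


@dataclass(frozen=True)
class FnnCurve:
    """Fraction of false nearest neighbors per candidate dimension."""

    dims: np.ndarray
    fnn_fraction: np.ndarray
    f_ratio: float
    theiler: int
    sigma_criterion_used: bool
    d_E: Optional[int]


def _admissible_neighbors(points: np.ndarray, theiler: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest neighbor of every point excluding temporal neighbors.

    Returns (neighbor index, neighbor distance) per point; points with no
    admissible neighbor get index -1. Ties broken toward the smallest index.
    """
    m = points.shape[0]
    tree = cKDTree(points)
    nn_idx = np.full(m, -1, dtype=np.int64)
    nn_dist = np.full(m, np.inf)
    pending = np.arange(m)
    k = min(m, 2 * theiler + 3)
    while pending.size:
        dist, idx = tree.query(points[pending], k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        ok = np.abs(idx - pending[:, None]) > theiler
        # ensure exact ties resolve to the smallest index: scipy returns ties
        # in index order for equal distances, so first admissible hit suffices
        has = ok.any(axis=1)
        first = np.argmax(ok, axis=1)
        rows = np.flatnonzero(has)
        nn_idx[pending[rows]] = idx[rows, first[rows]]
        nn_dist[pending[rows]] = dist[rows, first[rows]]
        pending = pending[~has]
        if k >= m:
            break
        k = min(m, 2 * k)
    return nn_idx, nn_dist


def fnn_fraction(
    series: TimeSeries,
    lag: int,
    dims=range(1, 6),
    f_ratio: float = 10.0,
    theiler: int = 0,
    sigma_criterion: bool = True,
    sigma_mult: float = 2.0,
    selection_threshold: float = 0.01,
    decimate: int = 1,
) -> FnnCurve:
    """False-nearest-neighbor fractions over candidate embedding dimensions.

    For each dimension ``d`` every point's nearest neighbor (Euclidean, with
    temporal separation > ``theiler`` samples) is re-examined in dimension
    ``d+1``: the pair is false when the relative distance increase
    ``sqrt((R_{d+1}^2 - R_d^2) / R_d^2)`` exceeds ``f_ratio``, or (when the
    size criterion is active) when ``R_{d+1}`` exceeds ``sigma_mult`` times
    the standard deviation of the series, i.e. the pair is stretched to the
    scale of the whole attractor. ``d_E`` is the smallest dimension whose
    false fraction drops below ``selection_threshold`` (None if none does).

    Pairs at numerically zero distance in dimension ``d`` (relative to the
    attractor size) are judged by the extra coordinate alone: still together
    in ``d+1`` keeps them true neighbors, genuine separation marks them false.
    """
    dims = np.asarray(list(dims), dtype=int)
    if dims.size == 0 or dims.min() < 1:
        raise ValueError("dims must be positive")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if f_ratio <= 0:
        raise ValueError("f_ratio must be positive")
    if decimate > 1:
        # speed option for long traces: keep every decimate-th sample and
        # scale the lag to preserve the time spanned by each delay vector
        if lag % decimate:
            raise ValueError("lag must be divisible by the decimation factor")
        series = TimeSeries(
            values=series.values[::decimate],
            dt=series.dt * decimate,
            t0=series.t0,
        )
        lag = lag // decimate
        theiler = max(0, theiler // decimate)
    d_max = int(dims.max())
    n = series.n
    if n - d_max * lag < 10:
        raise ValueError("series too short for the requested dimensions")
    x = series.values
    sigma = float(np.std(x))
    fractions = np.empty(dims.size)
    for di, d in enumerate(dims):
        m = n - d * lag  # points that exist in both d and d+1 dims
        pts = np.lib.stride_tricks.sliding_window_view(x, (d - 1) * lag + 1)[
            :m, :: lag
        ]
        nn_idx, nn_dist = _admissible_neighbors(pts, theiler)
        valid = nn_idx >= 0
        i = np.flatnonzero(valid)
        j = nn_idx[i]
        rd = nn_dist[i]
        extra = np.abs(x[i + d * lag] - x[j + d * lag])
        rd1 = np.sqrt(rd**2 + extra**2)
        # pairs at (numerically) zero distance in dim d — e.g. exactly
        # repeating periodic loops — cannot be judged by the distance ratio;
        # they are false only if the extra coordinate genuinely separates them
        tiny = rd <= 1e-10 * sigma
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(~tiny, extra / np.where(tiny, 1.0, rd), 0.0)
        false = (~tiny & (ratio > f_ratio)) | (tiny & (extra > 1e-10 * sigma))
        if sigma_criterion:
            false |= rd1 > sigma_mult * sigma
        fractions[di] = false.mean() if i.size else np.nan
    below = np.flatnonzero(fractions < selection_threshold)
    d_E = int(dims[below[0]]) if below.size else None
    return FnnCurve(
        dims=dims,
        fnn_fraction=fractions,
        f_ratio=float(f_ratio),
        theiler=int(theiler),
        sigma_criterion_used=bool(sigma_criterion),
        d_E=d_E,
    )
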