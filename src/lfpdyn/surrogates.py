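"""Surrogate time-series generation for nonlinearity testing.

Surrogates realize the null hypothesis of a linearly correlated, otherwise
random process. Three schemes are provided:

``ft``
    Phase-randomized Fourier-transform surrogates: the periodogram of the
    original is preserved exactly, the Fourier phases are drawn uniformly.
``aaft``
    Amplitude-adjusted FT surrogates: a rank-ordered remapping sandwiches a
    phase randomization, so the surrogate has exactly the original's value
    multiset and approximately its spectrum.
``iaaft``
    Iterated AAFT: alternate between imposing the original power spectrum and
    the original amplitude distribution until the rank ordering stabilizes,
    keeping the value multiset exact and the spectrum as close as the
    iteration allows.

All schemes enforce conjugate symmetry explicitly (DC phase 0; for even
length the Nyquist phase restricted to {0, pi}) so surrogates are exactly
real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries

__all__ = ["make_surrogates", "SurrogateSet", "surrogate_matrix"]

_METHODS = ("ft", "aaft", "iaaft")


def _random_phases(rng: np.random.Generator, n_sur: int, n: int) -> np.ndarray:
    """Phase factors for the rfft bins of a length-n real series."""
    n_bins = n // 2 + 1
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_sur, n_bins))
    factors = np.exp(1j * phases)
    factors[:, 0] = 1.0  # DC untouched
    if n % 2 == 0:  # Nyquist bin must stay real: flip sign at random
        factors[:, -1] = np.where(phases[:, -1] < np.pi, 1.0, -1.0)
    return factors


def _ft_surrogates(x: np.ndarray, n_sur: int, rng: np.random.Generator) -> np.ndarray:
    spectrum = np.fft.rfft(x)
    factors = _random_phases(rng, n_sur, x.size)
    new_spec = np.abs(spectrum)[None, :] * factors
    new_spec[:, 0] = spectrum[0]  # keep the mean (DC bin), sign included
    return np.fft.irfft(new_spec, n=x.size, axis=1)


def _rank_remap(target_sorted: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Give each row the value multiset of ``target_sorted``, keeping rank order."""
    out = np.empty_like(rows)
    order = np.argsort(rows, axis=1, kind="stable")
    np.put_along_axis(out, order, target_sorted[None, :], axis=1)
    return out


def _aaft_surrogates(x: np.ndarray, n_sur: int, rng: np.random.Generator) -> np.ndarray:
    n = x.size
    x_sorted = np.sort(x)
    # gaussianize by rank
    gauss = np.sort(rng.standard_normal(n))
    rank_x = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    y = gauss[rank_x]
    shuffled = _ft_surrogates(y, n_sur, rng)
    return _rank_remap(x_sorted, shuffled)


def _iaaft_surrogates(
    x: np.ndarray, n_sur: int, rng: np.random.Generator, max_iter: int
) -> np.ndarray:
    n = x.size
    x_sorted = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    current = _aaft_surrogates(x, n_sur, rng)
    prev_order = np.argsort(current, axis=1)
    active = np.arange(n_sur)
    for _ in range(max_iter):
        spec = np.fft.rfft(current[active], axis=1)
        mag = np.abs(spec)
        with np.errstate(divide="ignore", invalid="ignore"):
            phase = np.where(mag > 0, spec / mag, 1.0)
        filtered = np.fft.irfft(target_amp[None, :] * phase, n=n, axis=1)
        # rank-remapping filtered onto the original value multiset preserves
        # its ordering, so this argsort doubles as the convergence probe
        order = np.argsort(filtered, axis=1)
        remapped = np.empty_like(filtered)
        np.put_along_axis(remapped, order, x_sorted[None, :], axis=1)
        current[active] = remapped
        converged = np.all(order == prev_order[active], axis=1)
        prev_order[active] = order
        active = active[~converged]
        if active.size == 0:
            break
    return current


def surrogate_matrix(
    values: np.ndarray,
    n: int,
    method: str = "iaaft",
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
) -> np.ndarray:
    """Generate ``n`` surrogates of a raw sample array as an ``(n, N)`` matrix."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for surrogate generation (need >= 8)")
    if n < 1:
        raise ValueError("need at least one surrogate")
    if np.ptp(x) == 0:
        raise ValueError("surrogates of a constant series are undefined")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "ft":
        return _ft_surrogates(x, n, rng)
    if method == "aaft":
        return _aaft_surrogates(x, n, rng)
    return _iaaft_surrogates(x, n, rng, max_iter)


@dataclass(frozen=True)
class SurrogateSet:
    """An original trace together with its null-hypothesis surrogates."""

    original: TimeSeries
    surrogates: np.ndarray  # (n, N)
    method: str
    seed: int

    @property
    def n(self) -> int:
        return self.surrogates.shape[0]

    def surrogate_series(self, i: int) -> TimeSeries:
        return self.original.with_values(self.surrogates[i])


def make_surrogates(
    series: TimeSeries,
    n: int,
    method: str = "iaaft",
    seed: int = 0,
    max_iter: int = 100,
) -> SurrogateSet:
    """Generate ``n`` surrogates of ``series`` under the linear-process null."""
    mat = surrogate_matrix(series.values, n, method=method, seed=seed, max_iter=max_iter)
    return SurrogateSet(original=series, surrogates=mat, method=method, seed=int(seed))
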