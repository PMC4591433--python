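"""Phase-resetting correction by circular shifting.

A brief stimulus arriving at different phases of the ongoing rhythm imposes a
different permanent phase shift on every trial, so raw trials do not overlap
and naive trial averaging destroys phase and amplitude structure. The
correction used here circularly shifts each trial to maximize its Pearson
correlation with a reference trial; the achieved shift is a direct measurement
of the stimulus-induced phase resetting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .timeseries import TimeSeries, TrialEnsemble

__all__ = [
    "circular_shift",
    "best_shift",
    "align_ensemble",
    "rms_error",
    "AlignmentResult",
]


def circular_shift(series: TimeSeries, k: int) -> TimeSeries:
    """Circularly shift so that output sample ``i`` is input sample ``(i-k) mod N``."""
    return series.with_values(np.roll(series.values, int(k)))


def rms_error(a: TimeSeries, b: TimeSeries, normalized: bool = True) -> float:
    """Root-mean-square difference between two equal-length traces.

    With ``normalized=False`` the plain Euclidean norm of the difference is
    returned instead (no 1/N factor).
    """
    if a.n != b.n:
        raise ValueError("rms_error requires equal-length series")
    d = a.values - b.values
    ss = float(np.dot(d, d))
    return float(np.sqrt(ss / a.n)) if normalized else float(np.sqrt(ss))


def _wrap_shift(k: int, n: int) -> int:
    """Map a shift onto the signed interval (-N/2, N/2]."""
    k = int(k) % n
    if k > n // 2:  # for even n, +n/2 itself stays positive
        k -= n
    return k


def best_shift(trial: TimeSeries, reference: TimeSeries):
    """Exhaustively optimal circular alignment of ``trial`` onto ``reference``.

    Returns ``(k_star, corr)`` where ``k_star`` maximizes the Pearson
    correlation between the reference and the trial shifted by ``k`` over all
    N circular shifts. The search is performed spectrally (one FFT pair
    evaluates every shift) and is exactly equivalent to exhaustive search.
    Ties are broken by smallest ``|k|``, then by positive ``k``. The shift is
    reported in ``(-N/2, N/2]``.
    """
    if trial.n != reference.n:
        raise ValueError("best_shift requires equal-length series")
    n = trial.n
    x = trial.values - trial.values.mean()
    r = reference.values - reference.values.mean()
    sx = float(np.sqrt(np.dot(x, x)))
    sr = float(np.sqrt(np.dot(r, r)))
    if sx == 0 or sr == 0:
        raise ValueError("best_shift is undefined for constant input")
    # corr(k) proportional to sum_m x_m * r_{(m+k) mod N}
    cross = np.fft.irfft(np.conj(np.fft.rfft(x)) * np.fft.rfft(r), n=n)
    corr = cross / (sx * sr)
    best = np.max(corr)
    candidates = np.flatnonzero(corr >= best - 1e-12 * max(1.0, abs(best)))
    wrapped = np.array([_wrap_shift(k, n) for k in candidates])
    order = np.lexsort((wrapped < 0, np.abs(wrapped)))  # |k| asc, positive first
    k_star = int(wrapped[order[0]])
    return k_star, float(corr[candidates[order[0]]])


@dataclass(frozen=True)
class AlignmentResult:
    """Per-trial shifts and before/after quality metrics of one alignment."""

    reference_id: str
    table: pd.DataFrame  # trial_id, shift_samples, corr_before/after, rms_before/after

    def summary(self) -> pd.DataFrame:
        cols = ["corr_before", "corr_after", "rms_before", "rms_after"]
        return self.table[cols].agg(["mean", "std"])


def _dominant_period_samples(values: np.ndarray) -> Optional[int]:
    """Dominant period from the first peak of the circular autocorrelation."""
    x = values - values.mean()
    n = x.size
    f = np.fft.rfft(x)
    acf = np.fft.irfft(f * np.conj(f), n=n).real
    if acf[0] <= 0:
        return None
    acf = acf / acf[0]
    # first local max after the first zero crossing
    below = np.flatnonzero(acf[1 : n // 2] <= 0)
    if below.size == 0:
        return None
    start = below[0] + 1
    seg = acf[start : n // 2]
    if seg.size < 3:
        return None
    k = int(np.argmax(seg)) + start
    return k if k > 0 else None


def align_ensemble(
    ensemble: TrialEnsemble,
    reference: str = "first",
) -> tuple[TrialEnsemble, AlignmentResult]:
    """Circularly shift every trial to best match a reference trial.

    Parameters
    ----------
    ensemble : TrialEnsemble
        Equal-length steady-state trials (transient already removed).
    reference : str
        ``"first"``, ``"medoid"`` (trial minimizing summed rms distance to all
        others), or an explicit trial id.

    Returns the shifted ensemble and an :class:`AlignmentResult` whose table
    also carries ``shift_phase``: the shift converted to fractions of the
    dominant oscillation period (NaN when no dominant period is detectable).
    """
    ids = ensemble.trial_ids
    if reference == "first":
        ref_idx = 0
    elif reference == "medoid":
        arr = ensemble.as_array()
        d = np.sqrt(
            np.sum((arr[:, None, :] - arr[None, :, :]) ** 2, axis=-1)
        )
        ref_idx = int(np.argmin(d.sum(axis=1)))
    else:
        ref_idx = ensemble.index_of(reference)
    ref = ensemble.trials[ref_idx]

    period = _dominant_period_samples(ref.values)
    rows = []
    shifted = []
    for tid, trial in zip(ids, ensemble.trials):
        if tid == ids[ref_idx]:
            k, c_after = 0, 1.0
        else:
            k, c_after = best_shift(trial, ref)
        out = circular_shift(trial, k)
        c_before = float(np.corrcoef(trial.values, ref.values)[0, 1])
        rows.append(
            {
                "trial_id": tid,
                "shift_samples": k,
                "shift_phase": (k * 1.0 / period) if period else np.nan,
                "corr_before": c_before,
                "corr_after": float(c_after),
                "rms_before": rms_error(trial, ref),
                "rms_after": rms_error(out, ref),
            }
        )
        shifted.append(out)
    result = AlignmentResult(
        reference_id=ids[ref_idx], table=pd.DataFrame(rows)
    )
    return TrialEnsemble(trials=tuple(shifted), trial_ids=ids), result
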