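"""Core containers and trial I/O for uniformly sampled LFP traces.

A trial is stored on disk as a single-column ASCII text file: one sample per
line, blank lines ignored, lines starting with ``#`` treated as comments.
Amplitudes are dimensionless (arbitrary units) throughout; the only physical
metadata are the sampling interval ``dt`` (seconds) and the time ``t0`` of the
first sample relative to stimulus onset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "TrialEnsemble",
    "read_trial",
    "write_trial",
    "drop_transient",
    "zscore",
    "read_manifest",
    "write_manifest",
    "load_ensemble",
    "save_ensemble",
]


@dataclass(frozen=True)
class TimeSeries:
    """One uniformly sampled real-valued trace.

    Sample ``i`` has time ``t0 + i*dt`` (index origin 0).

    Parameters
    ----------
    values : array-like of float
        Sample amplitudes, arbitrary units. Length must be at least 2 and
        every sample finite.
    dt : float
        Sampling interval in seconds (strictly positive).
    t0 : float, optional
        Time of the first sample relative to stimulus onset, seconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if vals.size < 2:
            raise ValueError("TimeSeries must contain at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries values must all be finite")
        if not (self.dt > 0):
            raise ValueError("sampling interval dt must be positive")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total time span covered by the samples, ``n*dt`` seconds."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class TrialEnsemble:
    """Ordered collection of equal-length trials from repeated stimulation."""

    trials: tuple
    trial_ids: tuple
    dt: float = field(default=0.0)

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        if not trials:
            raise ValueError("ensemble must contain at least one trial")
        ids = tuple(str(i) for i in self.trial_ids) if self.trial_ids else tuple(
            f"trial_{k:03d}" for k in range(len(trials))
        )
        if len(ids) != len(trials):
            raise ValueError("trial_ids length must match number of trials")
        if len(set(ids)) != len(ids):
            raise ValueError("trial_ids must be unique")
        n0 = trials[0].n
        dt0 = trials[0].dt
        for t in trials:
            if t.n != n0:
                raise ValueError("all trials must share the same length")
            if t.dt != dt0:
                raise ValueError("all trials must share the same dt")
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "trial_ids", ids)
        object.__setattr__(self, "dt", dt0)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def n_samples(self) -> int:
        return self.trials[0].n

    def as_array(self) -> np.ndarray:
        """Stack the ensemble into an ``(n_trials, n_samples)`` array."""
        return np.stack([t.values for t in self.trials])

    def index_of(self, trial_id: str) -> int:
        try:
            return self.trial_ids.index(trial_id)
        except ValueError:
            raise KeyError(f"trial id {trial_id!r} not in ensemble") from None

    def map(self, func) -> "TrialEnsemble":
        """Apply ``func`` to every trial, keeping ids."""
        return TrialEnsemble(
            trials=tuple(func(t) for t in self.trials),
            trial_ids=self.trial_ids,
        )


class TrialParseError(ValueError):
    """Raised when a trial file contains a non-numeric line."""


def read_trial(path, dt: float, t0: float = 0.0) -> TimeSeries:
    """Read a single-column ASCII trial file.

    Blank lines and lines beginning with ``#`` are skipped. A non-numeric
    line raises :class:`TrialParseError` naming the offending line number.
    """
    values = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise TrialParseError(
                    f"{path}: non-numeric value {stripped!r} on line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path}: empty trial file")
    return TimeSeries(values=np.asarray(values), dt=dt, t0=t0)


def write_trial(series: TimeSeries, path) -> None:
    """Write one sample per line at full (17 significant digit) precision."""
    with open(path, "w") as fh:
        for v in series.values:
            fh.write(f"{v:.17g}\n")


def drop_transient(series: TimeSeries, t_cut: float) -> TimeSeries:
    """Return the suffix starting ``t_cut`` seconds after the first sample.

    ``t0`` of the result is the (absolute) time of the first retained
    sample. The
    stimulus-evoked transient (the emulated protocol uses the first
    ~0.5 s of each 2 s trial) is discarded this way before any analysis.
    """
    if not (0 <= t_cut):
        raise ValueError("t_cut must be non-negative")
    if t_cut >= series.duration:
        raise ValueError(
            f"t_cut={t_cut} is not inside the series duration ({series.duration})"
        )
    # t_cut is measured from the series' own start; t0 keeps absolute time.
    # ceil with a small tolerance so t_cut landing exactly on a sample keeps it
    idx = int(np.ceil(t_cut / series.dt - 1e-9))
    idx = max(idx, 0)
    if series.n - idx < 2:
        raise ValueError("fewer than 2 samples would remain after the cut")
    return TimeSeries(
        values=series.values[idx:],
        dt=series.dt,
        t0=series.t0 + idx * series.dt,
    )


def zscore(series: TimeSeries) -> TimeSeries:
    """Standardize to mean 0 and sample standard deviation 1 (ddof=1)."""
    sd = np.std(series.values, ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant series")
    return series.with_values((series.values - np.mean(series.values)) / sd)


def write_manifest(path, trial_ids: Sequence[str], paths: Sequence[str]) -> None:
    pd.DataFrame({"trial_id": list(trial_ids), "path": list(paths)}).to_csv(
        path, index=False
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"trial_id": str, "path": str})
    missing = {"trial_id", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_ensemble(manifest_path, dt: float, t0: float = 0.0) -> TrialEnsemble:
    """Load every trial listed in a manifest CSV (columns trial_id, path).

    Relative trial paths are resolved against the manifest's directory.
    """
    df = read_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(os.fspath(manifest_path)))
    trials, ids = [], []
    for _, row in df.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        trials.append(read_trial(p, dt=dt, t0=t0))
        ids.append(row["trial_id"])
    return TrialEnsemble(trials=tuple(trials), trial_ids=tuple(ids))


def save_ensemble(ensemble: TrialEnsemble, outdir, manifest_name: str = "manifest.csv") -> str:
    """Write each trial to ``<outdir>/<trial_id>.txt`` plus a manifest CSV."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for tid, trial in zip(ensemble.trial_ids, ensemble.trials):
        fname = f"{tid}.txt"
        write_trial(trial, os.path.join(outdir, fname))
        paths.append(fname)
    manifest = os.path.join(outdir, manifest_name)
    write_manifest(manifest, ensemble.trial_ids, paths)
    return manifest
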