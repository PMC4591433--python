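"""Synthetic LFP generator built on Morris-Lecar oscillators.

The experiment emulated here delivers a brief pulse to an ongoing neural
rhythm once per trial. Because the pulse arrives at a different phase of the
rhythm on every trial, it imposes a trial-dependent *permanent phase shift*
(phase resetting) on the post-stimulus activity. The generator provides:

* a Morris-Lecar (ML) membrane-potential simulator with optional brief
  current pulses delivered at a prescribed phase of the oscillation,
* the phase-resetting curve (PRC) of the oscillator, advance positive,
* LFP synthesis as a weighted sum of oscillator traces, and
* full experiment-shaped trial ensembles (waveform classes of differing
  amplitude, imposed circular phase shifts, observation noise, a stimulus
  transient) with a ground-truth record of every hidden variable.

ML dynamics (voltages mV, time ms, currents uA/cm^2, capacitance uF/cm^2):

    C dV/dt = I - gCa*m_inf(V)*(V - VCa) - gK*w*(V - VK) - gL*(V - VL)
    dw/dt   = phi * (w_inf(V) - w) * cosh((V - V3) / (2*V4))

with m_inf(V) = (1 + tanh((V-V1)/V2))/2 and w_inf(V) = (1 + tanh((V-V3)/V4))/2.
The default parameters are the widely used type-II set, which yields a robust
limit cycle with a period near 100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .timeseries import TimeSeries, TrialEnsemble

__all__ = [
    "MLParams",
    "StimulusSpec",
    "EnsembleSpec",
    "GroundTruth",
    "simulate_ml",
    "simulate_ml_realizations",
    "find_voltage_peaks",
    "unperturbed_period",
    "phase_resetting_curve",
    "synthesize_lfp",
    "generate_ensemble",
]


@dataclass(frozen=True)
class MLParams:
    """Morris-Lecar parameters (type-II defaults)."""

    C: float = 20.0
    gCa: float = 4.4
    gK: float = 8.0
    gL: float = 2.0
    VCa: float = 120.0
    VK: float = -84.0
    VL: float = -60.0
    V1: float = -1.2
    V2: float = 18.0
    V3: float = 2.0
    V4: float = 30.0
    phi: float = 0.04
    # 100 uA/cm^2 sits safely inside the mono-stable oscillatory range of the
    # type-II set; at lower bias the cycle coexists with a stable fixed point
    # and a brief pulse can annihilate the rhythm entirely.
    I_bias: float = 100.0
    noise_amp: float = 0.0  # half-width of uniform noise on I_bias, per step

    def __post_init__(self) -> None:
        if min(self.gCa, self.gK, self.gL) < 0:
            raise ValueError("conductances must be non-negative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.noise_amp < 0:
            raise ValueError("noise_amp must be non-negative")


@dataclass(frozen=True)
class StimulusSpec:
    """A brief rectangular current pulse delivered at a phase of the cycle.

    ``phase`` is the fraction of the cycle, in [0, 1), measured from the most
    recent membrane-potential peak, at which the pulse switches on.
    """

    amplitude: float = 40.0
    duration: float = 0.010  # seconds (10 ms pulse, the optical-pulse analog)
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if not (0 <= self.phase < 1):
            raise ValueError("stimulus phase must lie in [0, 1)")


def _integrate_ml(
    params: MLParams,
    n_out: int,
    dt_ms: float,
    substeps: int,
    rng: Optional[np.random.Generator],
    stim_window_ms: Optional[tuple[float, float]] = None,
    stim_amp: float = 0.0,
    V0: float = -30.0,
    w0: float = 0.1,
) -> np.ndarray:
    """Fixed-step RK4 integration of one trace, subsampled to ``dt_ms``.

    Noise on the bias current is redrawn once per internal step and held
    constant across the four RK4 stages, so the integration is a
    deterministic map of the drawn sequence.
    """
    import math

    h = dt_ms / substeps
    c, gca, gk, gl = params.C, params.gCa, params.gK, params.gL
    vca, vk, vl = params.VCa, params.VK, params.VL
    v1, v2, v3, v4, phi = params.V1, params.V2, params.V3, params.V4, params.phi
    tanh, cosh = math.tanh, math.cosh

    def rhs(V: float, w: float, I: float) -> tuple[float, float]:
        m_inf = 0.5 * (1.0 + tanh((V - v1) / v2))
        w_inf = 0.5 * (1.0 + tanh((V - v3) / v4))
        dV = (I - gca * m_inf * (V - vca) - gk * w * (V - vk) - gl * (V - vl)) / c
        dw = phi * (w_inf - w) * cosh((V - v3) / (2.0 * v4))
        return dV, dw

    noisy = params.noise_amp > 0 and rng is not None
    on, off = stim_window_ms if stim_window_ms is not None else (0.0, 0.0)
    V, w = float(V0), float(w0)
    out = np.empty(n_out)
    out[0] = V
    t = 0.0
    for i in range(1, n_out):
        for _ in range(substeps):
            I = params.I_bias
            if noisy:
                I += rng.uniform(-params.noise_amp, params.noise_amp)
            if stim_window_ms is not None and on <= t < off:
                I += stim_amp
            k1v, k1w = rhs(V, w, I)
            k2v, k2w = rhs(V + 0.5 * h * k1v, w + 0.5 * h * k1w, I)
            k3v, k3w = rhs(V + 0.5 * h * k2v, w + 0.5 * h * k2w, I)
            k4v, k4w = rhs(V + h * k3v, w + h * k3w, I)
            V += (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
            w += (h / 6.0) * (k1w + 2 * k2w + 2 * k3w + k4w)
            t += h
        out[i] = V
    return out


def _integrate_ml_batch(
    params: MLParams,
    n_out: int,
    dt_ms: float,
    substeps: int,
    rng: Optional[np.random.Generator],
    stim_onset_ms: Optional[np.ndarray] = None,
    stim_offset_ms: Optional[np.ndarray] = None,
    stim_amp: float = 0.0,
    V0: np.ndarray | float = -30.0,
    w0: np.ndarray | float = 0.1,
    batch: Optional[int] = None,
) -> np.ndarray:
    """Vectorized RK4 over a batch of traces (shared parameters).

    Batch elements may differ in initial conditions, noise realization and
    stimulus window; returns V with shape ``(batch, n_out)``.
    """
    if batch is None:
        batch = np.broadcast(np.asarray(V0), np.asarray(w0)).size
        if stim_onset_ms is not None:
            batch = max(batch, np.asarray(stim_onset_ms).size)
    h = dt_ms / substeps
    p = params
    V = np.broadcast_to(np.asarray(V0, dtype=float), (batch,)).copy()
    w = np.broadcast_to(np.asarray(w0, dtype=float), (batch,)).copy()
    if stim_onset_ms is not None:
        on = np.broadcast_to(np.asarray(stim_onset_ms, dtype=float), (batch,))
        off = np.broadcast_to(np.asarray(stim_offset_ms, dtype=float), (batch,))
    noisy = p.noise_amp > 0 and rng is not None

    def rhs(V, w, I):
        m_inf = 0.5 * (1.0 + np.tanh((V - p.V1) / p.V2))
        w_inf = 0.5 * (1.0 + np.tanh((V - p.V3) / p.V4))
        dV = (I - p.gCa * m_inf * (V - p.VCa) - p.gK * w * (V - p.VK) - p.gL * (V - p.VL)) / p.C
        dw = p.phi * (w_inf - w) * np.cosh((V - p.V3) / (2.0 * p.V4))
        return dV, dw

    out = np.empty((batch, n_out))
    out[:, 0] = V
    t = 0.0
    for i in range(1, n_out):
        for _ in range(substeps):
            I = np.full(batch, p.I_bias)
            if noisy:
                I += rng.uniform(-p.noise_amp, p.noise_amp, size=batch)
            if stim_onset_ms is not None:
                I += stim_amp * ((on <= t) & (t < off))
            k1v, k1w = rhs(V, w, I)
            k2v, k2w = rhs(V + 0.5 * h * k1v, w + 0.5 * h * k1w, I)
            k3v, k3w = rhs(V + 0.5 * h * k2v, w + 0.5 * h * k2w, I)
            k4v, k4w = rhs(V + h * k3v, w + h * k3w, I)
            V = V + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
            w = w + (h / 6.0) * (k1w + 2 * k2w + 2 * k3w + k4w)
            t += h
        out[:, i] = V
    return out


def find_voltage_peaks(values: np.ndarray, dt: float) -> np.ndarray:
    """Times (seconds, parabolic-interpolated) of membrane-potential peaks.

    Peaks are local maxima above the mid-range of the trace, separated by a
    refractory gap of 20% of the (first-pass) period estimate.
    """
    v = np.asarray(values, dtype=float)
    height = 0.5 * (v.max() + v.min())
    rough, _ = find_peaks(v, height=height)
    if rough.size >= 3:
        period = np.median(np.diff(rough))
        idx, _ = find_peaks(v, height=height, distance=max(1, int(0.2 * period)))
    else:
        idx = rough
    times = []
    for i in idx:
        if 0 < i < v.size - 1:
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            frac = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom != 0 else 0.0
        else:
            frac = 0.0
        times.append((i + frac) * dt)
    return np.asarray(times)


def simulate_ml(
    params: MLParams = MLParams(),
    duration: float = 1.0,
    dt: float = 1e-4,
    stimulus: Optional[StimulusSpec] = None,
    seed: int = 0,
    stim_cycle: int = 2,
    substeps: int = 10,
    V0: float = -30.0,
    w0: float = 0.1,
) -> TimeSeries:
    """Simulate a Morris-Lecar membrane-potential trace.

    With a stimulus, the pulse is switched on at ``stimulus.phase`` of the
    cycle that starts at the ``stim_cycle``-th detected peak (0-based; the
    default perturbs the third full cycle) of the corresponding noise-free
    unperturbed trace. The result is deterministic given ``seed``.

    Raises if fewer than 3 peaks are detected (``non-oscillatory parameters``).
    """
    n_out = int(round(duration / dt))
    if n_out < 2:
        raise ValueError("duration must cover at least 2 samples")
    dt_ms = dt * 1000.0
    rng = np.random.default_rng(seed) if params.noise_amp > 0 else None
    window = None
    if stimulus is not None:
        quiet = replace(params, noise_amp=0.0)
        ref = _integrate_ml(quiet, n_out, dt_ms, substeps, None, V0=V0, w0=w0)
        peaks_s = find_voltage_peaks(ref, dt)
        if peaks_s.size < stim_cycle + 2:
            raise ValueError("non-oscillatory parameters: too few peaks for stimulus placement")
        # the phase is measured within the cycle being perturbed
        cycle_ms = (peaks_s[stim_cycle + 1] - peaks_s[stim_cycle]) * 1000.0
        onset_ms = peaks_s[stim_cycle] * 1000.0 + stimulus.phase * cycle_ms
        window = (onset_ms, onset_ms + stimulus.duration * 1000.0)
    v = _integrate_ml(
        params,
        n_out,
        dt_ms,
        substeps,
        rng,
        stim_window_ms=window,
        stim_amp=stimulus.amplitude if stimulus is not None else 0.0,
        V0=V0,
        w0=w0,
    )
    if find_voltage_peaks(v, dt).size < 3:
        raise ValueError("non-oscillatory parameters")
    return TimeSeries(values=v, dt=dt, t0=0.0)


def simulate_ml_realizations(
    params: MLParams = MLParams(),
    n_traces: int = 50,
    duration: float = 2.0,
    dt: float = 5e-4,
    seed: int = 0,
    substeps: int = 10,
) -> np.ndarray:
    """Independent ML realizations differing in initial conditions (and noise).

    Initial voltages are drawn uniformly on [-60, 20] mV and gate values on
    [0.05, 0.4]; returns an ``(n_traces, n_samples)`` array of membrane
    potentials. With ``noise_amp = 0`` the realizations differ only in their
    transient approach to the limit cycle and in phase.
    """
    rng = np.random.default_rng(seed)
    n_out = int(round(duration / dt))
    V0 = rng.uniform(-60.0, 20.0, size=n_traces)
    w0 = rng.uniform(0.05, 0.4, size=n_traces)
    return _integrate_ml_batch(
        params, n_out, dt * 1000.0, substeps, rng if params.noise_amp > 0 else None,
        V0=V0, w0=w0, batch=n_traces,
    )


def unperturbed_period(
    params: MLParams, duration: float = 1.0, dt: float = 1e-4, substeps: int = 10
) -> tuple[float, np.ndarray]:
    """Intrinsic period (seconds) and peak times of the noise-free oscillator."""
    quiet = replace(params, noise_amp=0.0)
    ts = simulate_ml(quiet, duration=duration, dt=dt, substeps=substeps)
    peaks = find_voltage_peaks(ts.values, dt)
    if peaks.size < 4:
        raise ValueError("non-oscillatory parameters")
    # skip the first (transient) cycle when averaging
    return float(np.mean(np.diff(peaks[1:]))), peaks


def phase_resetting_curve(
    params: MLParams = MLParams(),
    stimulus: StimulusSpec = StimulusSpec(),
    n_phases: int = 100,
    duration: float = 1.0,
    dt: float = 1e-4,
    stim_cycle: int = 2,
    substeps: int = 10,
) -> pd.DataFrame:
    """PRC: resetting ``(P_i - P_perturbed) / P_i`` at equally spaced phases.

    ``P_perturbed`` is the length of the cycle containing the perturbation,
    measured between the peaks bracketing the pulse. Advance is positive,
    delay negative. Columns: ``phase``, ``resetting``.
    """
    quiet = replace(params, noise_amp=0.0)
    p_i, peaks = unperturbed_period(quiet, duration=duration, dt=dt, substeps=substeps)
    if peaks.size < stim_cycle + 2:
        raise ValueError("trace too short to perturb the requested cycle")
    phases = np.arange(n_phases) / n_phases
    n_out = int(round(duration / dt))
    # normalize by the very cycle being perturbed so a null stimulus gives 0
    p_cycle = peaks[stim_cycle + 1] - peaks[stim_cycle]
    onsets = (peaks[stim_cycle] + phases * p_cycle) * 1000.0
    traces = _integrate_ml_batch(
        quiet,
        n_out,
        dt * 1000.0,
        substeps,
        None,
        stim_onset_ms=onsets,
        stim_offset_ms=onsets + stimulus.duration * 1000.0,
        stim_amp=stimulus.amplitude,
    )
    resettings = np.empty(n_phases)
    for k in range(n_phases):
        pk = find_voltage_peaks(traces[k], dt)
        if pk.size < stim_cycle + 2:
            raise ValueError("perturbed trace lost its peaks")
        p_pert = pk[stim_cycle + 1] - pk[stim_cycle]
        resettings[k] = (p_cycle - p_pert) / p_cycle
    return pd.DataFrame({"phase": phases, "resetting": resettings})


def synthesize_lfp(traces: Sequence[TimeSeries], weights: Sequence[float]) -> TimeSeries:
    """Pointwise weighted sum of oscillator traces — the LFP model."""
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    if len(traces) != len(weights):
        raise ValueError("weights length must match number of traces")
    n = traces[0].n
    for t in traces:
        if t.n != n:
            raise ValueError("all traces must share the same length")
    arr = np.stack([t.values for t in traces])
    w = np.asarray(weights, dtype=float)
    return traces[0].with_values(w @ arr)


@dataclass(frozen=True)
class EnsembleSpec:
    """Shape of a synthetic stimulation experiment.

    Defaults mirror the emulated protocol: 100 trials of 2 s sampled at
    10 kHz, a 0.5 s stimulus transient, four high-amplitude waveform classes
    plus a low-amplitude minority class (peak-to-peak ratio 5.5 to the
    largest class) standing in for degraded/artifact trials, stimulus phases
    drawn uniformly so each trial carries a random permanent phase shift.
    """

    n_trials: int = 100
    trial_duration: float = 2.0
    dt: float = 1e-4
    transient: float = 0.5
    group_weights: tuple = (0.40, 0.20, 0.15, 0.15, 0.10)
    group_amplitudes: tuple = (1.0, 0.85, 0.70, 0.55, 1.0 / 5.5)
    phase_law: str | Callable = "uniform"
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if len(self.group_weights) != len(self.group_amplitudes):
            raise ValueError("group_weights and group_amplitudes length mismatch")
        if abs(sum(self.group_weights) - 1.0) > 1e-9:
            raise ValueError("group_weights must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.transient < self.trial_duration):
            raise ValueError("transient must lie in [0, trial_duration)")

    @classmethod
    def full_scale(cls, **overrides) -> "EnsembleSpec":
        """Full experiment scale: 100 x 2 s at 10 kHz."""
        return cls(**overrides)

    @classmethod
    def fast(cls, **overrides) -> "EnsembleSpec":
        """Desk-fast preset: coarser sampling, fewer trials."""
        defaults = dict(n_trials=30, dt=5e-4)
        defaults.update(overrides)
        return cls(**defaults)

    def to_file(self, path) -> None:
        import dataclasses as _dc
        import json as _json

        import yaml as _yaml

        payload = _dc.asdict(self)
        payload["group_weights"] = list(payload["group_weights"])
        payload["group_amplitudes"] = list(payload["group_amplitudes"])
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                _json.dump(payload, fh, indent=2)
            else:
                _yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "EnsembleSpec":
        import yaml as _yaml

        with open(path) as fh:
            payload = _yaml.safe_load(fh)
        payload["group_weights"] = tuple(payload["group_weights"])
        payload["group_amplitudes"] = tuple(payload["group_amplitudes"])
        return cls(**payload)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden variables of a generated ensemble, one row per trial."""

    table: pd.DataFrame  # trial_id, class_label, shift_samples, stim_phase, noise_seed

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["class_label"].to_numpy()

    @property
    def shifts(self) -> np.ndarray:
        return self.table["shift_samples"].to_numpy()


def _class_counts(weights: Sequence[float], n: int) -> np.ndarray:
    """Deterministic per-class counts: floor(w*n) plus largest remainders."""
    raw = np.asarray(weights) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _default_template(spec: EnsembleSpec, n_total: int) -> np.ndarray:
    """Steady ML-derived LFP waveform, mean 0 and peak-to-peak 1."""
    settle = 0.3  # seconds discarded while the oscillator reaches its cycle
    ts = simulate_ml(
        MLParams(),
        duration=settle + (n_total + 1) * spec.dt,
        dt=spec.dt,
    )
    v = ts.values[-n_total:]
    v = v - v.mean()
    return v / np.ptp(v)


def generate_ensemble(
    spec: EnsembleSpec, template: Optional[TimeSeries] = None
) -> tuple[TrialEnsemble, GroundTruth]:
    """Generate an experiment-shaped trial ensemble with known ground truth.

    Each trial is built from a shared base waveform (an ML-derived steady LFP
    by default, or the supplied ``template``): the steady segment is the base
    scaled by its class amplitude and circularly shifted by the number of
    samples implied by the trial's stimulus phase; a stimulus transient with
    a decaying high-amplitude envelope is prepended; i.i.d. Gaussian
    observation noise is added. Bit-reproducible for a fixed seed.

    ``phase_law`` may be ``"uniform"`` (stimulus phases uniform on [0, 1)),
    ``"zero"`` (no resetting), or a callable ``(rng, n_trials) -> phases``.
    """
    n_steady = int(round((spec.trial_duration - spec.transient) / spec.dt))
    n_trans = int(round(spec.transient / spec.dt))
    n_total = n_trans + n_steady
    if n_steady < 2:
        raise ValueError("steady segment must contain at least 2 samples")

    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    noise_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(spec.n_trials)]

    if template is not None:
        base = np.asarray(template.values, dtype=float)
        if base.size < n_total:
            raise ValueError("template shorter than transient + steady segment")
        base = base[:n_total].copy()
        base = base - base.mean()
        base = base / np.ptp(base)
    else:
        base = _default_template(spec, n_total)
    trans_base = base[:n_trans] if n_trans else np.empty(0)
    steady_base = base[n_trans:]

    # class labels: deterministic counts, randomly permuted order
    counts = _class_counts(spec.group_weights, spec.n_trials)
    labels = np.repeat(np.arange(len(counts)), counts)
    labels = labels[rng.permutation(spec.n_trials)]

    if callable(spec.phase_law):
        phases = np.asarray(spec.phase_law(rng, spec.n_trials), dtype=float)
    elif spec.phase_law == "uniform":
        phases = rng.uniform(0.0, 1.0, size=spec.n_trials)
    elif spec.phase_law == "zero":
        phases = np.zeros(spec.n_trials)
    else:
        raise ValueError(f"unknown phase_law {spec.phase_law!r}")
    shifts = (np.round(phases * n_steady).astype(int)) % n_steady

    if n_trans:
        t_tr = np.arange(n_trans) * spec.dt
        envelope = 1.0 + 2.0 * np.exp(-t_tr / max(spec.transient / 4.0, spec.dt))
    trials = []
    ids = []
    rows = []
    for i in range(spec.n_trials):
        amp = spec.group_amplitudes[labels[i]]
        steady = amp * np.roll(steady_base, shifts[i])
        if n_trans:
            trans = amp * envelope * trans_base
            values = np.concatenate([trans, steady])
        else:
            values = steady
        if spec.noise_sd > 0:
            noise_rng = np.random.default_rng(noise_seeds[i])
            values = values + noise_rng.normal(0.0, spec.noise_sd, size=n_total)
        tid = f"trial_{i:03d}"
        trials.append(TimeSeries(values=values, dt=spec.dt, t0=0.0))
        ids.append(tid)
        rows.append(
            {
                "trial_id": tid,
                "class_label": int(labels[i]),
                "shift_samples": int(shifts[i]),
                "stim_phase": float(phases[i]),
                "noise_seed": noise_seeds[i],
            }
        )
    ensemble = TrialEnsemble(trials=tuple(trials), trial_ids=tuple(ids))
    return ensemble, GroundTruth(table=pd.DataFrame(rows))
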