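# Methods

This note documents the models, estimators and numerical choices behind
`lfpdyn`, and what the package's validation studies do and do not show.

## Problem setting

A brief pulse (the optical-stimulation analog) perturbs an ongoing neural
rhythm once per trial. Because the pulse lands at a different phase of the
rhythm on each trial, it imposes a trial-dependent *permanent phase shift*
(phase resetting) on the post-stimulus activity. Trials therefore cannot be
averaged directly: without phase correction the average destroys the phase
and amplitude structure of the waveform. The analysis chain is

transient removal → phase-resetting correction (circular shifting) →
dendrogram grouping → nonlinearity testing aggregated over groups → lag and
embedding-dimension estimation → delay-embedded trajectory export.

Trials are uniformly sampled single-channel traces (default Δt = 10⁻⁴ s,
2 s per trial, the first 0.5 s treated as stimulus transient), stored as
single-column ASCII files with a manifest CSV. Amplitudes are arbitrary
units throughout; no filtering is applied in software.

## Synthetic ensemble generator

**Oscillator.** Morris–Lecar (ML) membrane dynamics,

    C dV/dt = I − g_Ca m∞(V)(V−V_Ca) − g_K w (V−V_K) − g_L (V−V_L)
    dw/dt  = φ (w∞(V) − w) cosh((V−V₃)/(2V₄)),

with m∞, w∞ the usual tanh activation curves and the widely used type-II
parameter set (C=20 µF/cm², g_Ca=4.4, g_K=8, g_L=2 mS/cm², V_Ca=120,
V_K=−84, V_L=−60 mV, V₁=−1.2, V₂=18, V₃=2, V₄=30 mV, φ=0.04 /ms).
The default bias current is **I = 100 µA/cm²**: at lower bias (e.g. 90)
this parameter set is bistable — a stable fixed point coexists with the
limit cycle — and a 10 ms pulse annihilates the rhythm at roughly one phase
in ten, which breaks the phase-resetting protocol. At I = 100 the system is
mono-stably oscillatory with a period near 85 ms, and the default pulse
(40 µA/cm² for 10 ms) delays the next peak when delivered at phase 0.3 of
the cycle and advances it at phase 0.5, the qualitative signature the
protocol relies on.

**Integration.** Fixed-step RK4 at one tenth of the output sampling
interval. Dynamical noise, when enabled, is uniform on ±`noise_amp`, added
to the bias current, redrawn once per internal step and held constant
across the four RK4 stages, so a run is a deterministic map of the drawn
sequence. A vectorized batch integrator runs many realizations (different
initial conditions, noise draws, or stimulus windows) simultaneously.

**Peaks and phase.** Peaks are local maxima above the mid-range of the
trace with a refractory gap of 20% of the period, refined by parabolic
interpolation. The stimulus phase is measured from the most recent peak;
the phase-resetting curve normalizes by the unperturbed length of the very
cycle being perturbed, so a zero-amplitude stimulus yields exactly zero
resetting, with advance positive and delay negative.

**Ensembles.** Each trial is built from a shared base waveform (a steady
ML-derived trace by default; any template can be supplied), normalized to
zero mean and unit peak-to-peak: the steady segment is the base scaled by
its class amplitude and circularly shifted by `round(phase · N)` samples
with the stimulus phase drawn per the phase law (uniform by default); a
transient with a decaying envelope (3→1 over the first quarter of the
transient window) is prepended; i.i.d. Gaussian observation noise is added.
Default study conditions mirror the emulated protocol: 100 trials × 2 s at
10 kHz, 0.5 s transient, five waveform classes with weights
(0.40, 0.20, 0.15, 0.15, 0.10) and amplitudes (1.0, 0.85, 0.70, 0.55,
1/5.5) — the minority low-amplitude class (peak-to-peak factor 5.5 below
the largest) plays the role of degraded/artifact trials — and observation
noise σ = 0.05 in units of the unit peak-to-peak template. A `fast` preset
(30 trials, Δt = 5·10⁻⁴ s) is used throughout the test suite. Everything
is bit-reproducible from the ensemble seed.

**What the generator does not emulate.** Real LFPs are broadband and
nonstationary; the generator's trials are a noisy, shifted, scaled copy of
one template per class, so between-trial waveform variability, electrode
drift, line noise and the pulse-train stimulation protocol are absent.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated model, not performance guarantees on animal recordings.

## Surrogate-data nonlinearity testing

Surrogates realize the null of a linearly correlated, otherwise random
process. `ft` surrogates randomize Fourier phases exactly preserving the
periodogram (DC kept, Nyquist phase restricted to {0, π}, conjugate
symmetry enforced, so surrogates are exactly real). `aaft` adds rank
remapping to preserve the value distribution; `iaaft` (default) iterates
spectrum- and amplitude-imposition until the rank ordering stabilizes (at
most 100 iterations), keeping the value multiset exact and the spectrum
close.

The time-reversal statistic is the cubed-over-squared increment ratio
⟨(xᵢ−xᵢ₋δ)³⟩ / ⟨(xᵢ−xᵢ₋δ)²⟩. The library default for the increment delay δ
is 1 sample; the calibration studies set δ per trace to the first zero of
its autocorrelation. This matters: for a slowly varying rhythm the
one-sample increments carry almost no waveform asymmetry and the test has
essentially no power, while a delay matched to the correlation timescale
recovers it. Scores: γ_avg = |λ̄/λ₀ − 1| (reject above 1), γ_cv =
|λ̄ − λ₀|/σ_λ with σ_λ the sample standard deviation (reject above 1.96 at
95%), and the rank test (reject only when λ₀ is strictly extreme; ties do
not reject). Group-level verdicts average per-trial γ_cv within dendrogram
groups against the same 1.96 threshold.

Calibration at study scale (also recomputed by `scripts/acceptance.py`):
type-I error on 200 Gaussian AR(2) realizations (x_t = 1.6x_{t−1} −
0.8x_{t−2} + ε_t, N = 4096, 100 IAAFT surrogates each) and power on 50
noise-free ML realizations (8 s at 0.5 ms sampling, random initial
conditions). The 8 s length is needed because the surrogate spread of the
time-reversal statistic for a nearly periodic signal does not shrink
quickly with N; at 2 s the γ margin is below threshold.

The FNN discriminant rejects when the original's FNN fraction lies strictly
below the minimum over all surrogates at every tested dimension; it is the
second line of evidence when the γ test is inconclusive.

## Alignment, grouping

`best_shift` evaluates the Pearson correlation of the reference with every
circular shift of a trial via one FFT cross-correlation, exactly equivalent
to exhaustive search; ties break toward the smallest |k|, then positive k;
shifts are reported in (−N/2, N/2] and, as a derived column, in fractions
of the dominant period (from the first autocorrelation peak). Trials are
not z-scored before alignment or clustering: amplitude differences carry
the class structure that the dendrogram is meant to find. Clustering is
agglomerative on Euclidean waveform distances (scipy linkage; average
linkage by default — the common monotone choice for waveform similarity;
single/complete/ward selectable), cut either at a distance or to a target
group count (default 5, the emulated protocol's operating point).

## Lag and embedding dimension

The autocorrelation supports periodic (circular, the protocol's convention)
and linear (biased) estimators; the lag candidates are its first zero
crossing (with a linearly interpolated fractional crossing as auxiliary
output) and the first local minimum of the AMI computed from an equal-width
16-bin 2-D histogram in nats. The chosen lag prefers the AMI minimum and
falls back to the autocorrelation zero.

A caveat measured during development and asserted honestly in the tests:
for a noise-free pure sine the binned AMI curve carries deterministic
binning-aliasing ripples, so its first *strict* local minimum sits at a few
samples rather than at the quarter period; the quarter-period minimum is a
broad basin that contains the curve's global minimum. The ripple artifact
persists for every bin count above 2 and for noisy sines up to N = 10⁵.
Module tests therefore assert the basin property for the sine; the strict
first-minimum rule is exercised on constructed curves.

FNN marks a neighbor pair false when √((R²_{d+1} − R²_d)/R²_d) > f
(default f = 10, inside the stable range 7–20) or when R_{d+1} > A·σ with
σ the series standard deviation and A = 2 (the attractor-size criterion;
the coefficient-of-variation form σ/x̄ is dimensionally inconsistent with
its own attractor-size rationale and is not used). Neighbors are nearest
Euclidean points with temporal separation beyond the Theiler window
(KD-tree search, verified against an all-pairs oracle); pairs at
numerically zero distance relative to the attractor size are judged by the
extra coordinate alone; points with no admissible neighbor are excluded.
d_E is the smallest dimension whose false fraction falls below 1%.

The Lorenz-63 validation ensemble (12 trials, 3.5 s steady segments at
0.5 ms sampling, observation noise σ = 0.001, no phase shifts) recovers
d_E = 3 for every f in [7, 20]. Two of its conditions are deliberate:
trials are longer than the stimulation-protocol default so the attractor is
densely sampled, and noise is low because FNN's known noise sensitivity at
small f is not the property under test. Phase shifts are disabled because a
circular shift of a non-periodic chaotic segment manufactures a waveform
seam that embeds as a spurious jump across the attractor and never unfolds;
circular resetting shifts are physically meaningful only for periodic
steady rhythms, and shift-recovery studies use the periodic ML template
(recovery is exact at zero noise and within ±2 samples at a variance SNR of
10).

## Pipeline

Stages run in dependency order (alignment before grouping before
averaging/embedding). Per-trial lags are estimated on each aligned steady
trial and per-group lags on the group-average waveform; group embeddings
use the group lag. All randomness derives from the single config seed;
re-running with the same config and inputs reproduces the report
bit-for-bit. Reports are a JSON master plus CSV tables; trajectories are
exported one point per row. Numeric warnings (no autocorrelation zero,
monotone AMI, FNN never below threshold — in which case d_E falls back to
the deepest dimension tried) are collected in the report rather than
raised.

## Known limitations

* The γ test has low power for short, strictly periodic records (see the
  8 s calibration choice above); the FNN discriminant compensates.
* The AMI first-minimum rule is fragile on noise-free periodic signals
  (binning ripples); the autocorrelation zero fallback and the reported
  full curves let users override the automatic choice.
* Sub-sample (interpolated) shift estimation and time warping are out of
  scope; shifts are integer samples.
* The dendrogram cut count/height is a user decision; no automatic model
  selection is attempted.
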