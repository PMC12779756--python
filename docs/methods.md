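# Methods

This note documents the models, estimators and numerical choices behind
`sacskit`, and what the synthetic-data generator does and does not emulate.

## Problem setting

Alternating current stimulation (ACS) delivered through on-skull electrodes
superimposes a sinusoidal electric field on cortical tissue. Its effects on
nearby neurons are read out from multielectrode recordings along three axes:

1. **spike timing** — do a neuron's spikes concentrate at a preferred phase
   of the stimulus (entrainment)?
2. **firing rate** — does the neuron fire more or less during stimulation?
3. **network state** — do LFP band power and low-frequency-phase to
   high-frequency-amplitude coupling (PAC) change after stimulation?

The stimulus also contaminates the recording with a large sinusoidal
artifact at the stimulation frequency and its harmonics, which must be
attenuated (spike band) or avoided (LFP analysed only outside stimulation),
and which — usefully — carries the information needed to estimate the local
electric field from its spatial gradient across the array.

## Units and conventions

Seconds, Hz, µV, mm, mV/mm; phases in radians in [0, 2π) internally
(degrees only in reports). One phase convention is used by both the
generator and the analyzer: *phase is the angle of the analytic signal*
(Hilbert transform) of the stimulation waveform. The commanded stimulus is
`sin(2πf(t − onset) + φ₀)`; since `sin x = cos(x − π/2)`, its analytic-signal
angle is `x − π/2`, and a spike at a positive peak of the waveform has
phase 0. `StimProtocol.phase()` evaluates this in closed form — identical,
away from record edges, to running `scipy.signal.hilbert` on the commanded
waveform, which the tests verify.

## Entrainment: PLV, PPC, √|PPC|

The phase-locking value `PLV = |mean(exp(iθ))|` is positively biased at low
spike counts (its expectation under uniform phases is ≈ √(π/4N), not 0).
The pairwise phase consistency

    PPC = mean over pairs j<k of cos(θ_j − θ_k)

is an unbiased estimator of PLV². It is computed in O(N) through the exact
identity `PPC = (|Σ exp(iθ)|² − N)/(N(N−1))`, which the tests hold to the
O(N²) double sum at 1e−12. The reported entrainment metric is `√|PPC|`,
with the absolute value taken before the square root. Consequence (kept,
documented, not "fixed"): a set of two antipodal phases has PLV = 0 but
√|PPC| = 1, because its single pair contributes cos(π) = −1.

## Inclusion and significance testing

- **Sparse-rate filter**: a neuron is analysed only if at most half of its
  10-s windows (60-s windows for the 20-minute paradigm) across baseline and
  stimulation have a firing rate below 0.25 Hz. The boundary is read
  strictly: a window at exactly 0.25 Hz is not sparse.
- **ΔFR permutation test**: firing rate in 100-ms bins over the pre and
  stimulation intervals; bins are pooled, permuted without replacement, and
  resplit into groups of the original sizes; two-sided via |Δ|, 10,000
  iterations by default, p computed with the add-one correction
  `p = (1 + #{|Δ*| ≥ |Δ|})/(1 + iters)` so a finite permutation count never
  yields p = 0. Significance at p ≤ 0.05. A bootstrap (resampling with
  replacement) is available behind a flag but is not the default.
- **Δ√|PPC| permutation test**: same scheme on the pooled spike phases.
  Fewer than two spikes in either period marks the neuron untestable.
- **Grubbs pruning**: per condition, effect sizes are cleaned by the
  two-sided Grubbs test at α = 0.05, applied iteratively (remove the most
  extreme point, retest, repeat); single-pass behaviour is available via
  `iterative=False`. A zero-variance sample is treated as outlier-free.

Measured operating characteristics (recomputed by `scripts/acceptance.py`):
both permutation tests and the Grubbs procedure hold their nominal 5% level
on simulated nulls, and the mean signed PPC over uniform-phase spike trains
is zero within Monte-Carlo error.

## Artifact comb filter

`y[t] = x[t] − Σ_k w_k x[t − kT]` with `T = rate/f_stim` samples and
uniform weights over `n_periods = 4` periods by default. Fractional periods
are realized by linear two-tap interpolation, and the closed-form frequency
response used in `harmonic_attenuation` includes that interpolation factor
so it matches the implemented filter exactly. The filter nulls DC, the
stimulation frequency and all harmonics; white noise passes with variance
inflated by exactly 1 + 1/k. The first `⌈n_periods·T⌉` samples have
incomplete history and are flagged as warm-up; they should be excluded from
spike windows rather than zero-padded. Because the response is periodic in
`f/f_stim`, notch widths scale with the stimulation frequency: at 140 Hz the
suppressed bands around harmonics carve contiguous chunks out of the lower
MUA band several times wider than at 40 Hz, which is the qualitative reason
high-frequency stimulation resists comb-based artifact removal. The
pipeline applies the filter to the MUA band before spike analysis.

## LFP band power

LFP is decimated to 1.2 kHz by polyphase resampling with its built-in
anti-alias filter. Band power uses non-overlapping 2-s periodogram windows
(rectangular taper by default; Hann by flag), per-bin mean PSD (µV²/Hz)
within each canonical band — δ 0.5–4, θ 4–8, α 8–12, β 12–30, low-γ 30–80,
high-γ 80–140 Hz, half-open edges `lo ≤ f < hi` — then log10 ("log power";
the base is configurable). Per-bin mean rather than band-integrated power
was chosen so that bands of different widths are comparable; the Parseval
relation is still recoverable (and tested) by multiplying back by bin count
and bin width.

## Phase–amplitude coupling

Phase and amplitude series come from a Morlet-style wavelet applied as a
Gaussian weight on the positive-frequency spectrum, with spectral width
`σ_f = max(width/2, f₀/7)` (seven wavelet cycles). The constant-Q term is
essential at high frequencies: an amplitude filter must pass the modulation
sidebands at `f₀ ± f_phase`, which a fixed few-Hz band at a 60–140 Hz
center would remove.

The Tort modulation index divides phase into 18 bins, normalizes the mean
amplitude per bin into a distribution P, and reports
`MI = D_KL(P‖uniform)/log 18 ∈ [0, 1]` (the log-18 normalization is
flag-switchable). An empty phase bin — possible only in very short
windows — flags the MI as undefined (NaN) rather than guessing.

**Surrogate significance.** The envelope A(t) is cut at 9 random points and
the 10 pieces permuted, leaving φ(t) untouched; the observed MI is
significant if it exceeds the 95th percentile of 200 surrogate MIs. Block
permutation was chosen as the default over whole-record circular shifts
after measuring both on the generator's null: circular-shift surrogates of
a 10-s window are strongly mutually correlated (the envelope's ~0.3 s
correlation time allows only a few dozen effectively independent shifts),
which makes the estimated 95th percentile noisy and inflates the empirical
false-positive rate to ~10%; random-cut block permutation preserves
short-range autocorrelation, yields nearly independent surrogates, and
holds the 5% level. Random (rather than equally spaced) cut points matter:
equal blocks can land at offsets commensurate with the low-frequency
period and silently retain coupling. Circular shift and full sample
permutation remain available via `method=`.

**Comodulograms** cover phases 1–29 Hz (0.5 Hz steps, 2 Hz widths) ×
amplitudes 30–140 Hz (1 Hz steps, 5 Hz widths) in 10-s windows — the
shortest affording robust MI estimation. Band-pair summaries average cells
whose centers fall in δ/θ/α/β (β capped at 29 Hz, the top of the phase
grid) × low-γ/high-γ; all cells are included in the means, with
significance counts reported separately. Per-cell surrogate masks are
opt-in (`n_surrogates > 0`) because they multiply run time by the surrogate
count.

**Order normalization** for group-level modelling is the rank-based
inverse-normal transform `Φ⁻¹((r − 0.5)/n)` with ties averaged (the
(r − 0.5)/n offset is one standard choice among near-equivalent variants).

## Electric-field estimation

Per amplitude condition: band-pass the recording around the stimulation
frequency (4th-order Butterworth, ±1 Hz, zero-phase forward-backward),
take the maximum |V| per stimulation cycle (cycle boundaries from the
protocol), and average over cycles per channel. On the 4×4 grid (0.5 mm
pitch), neighbouring-electrode differences along rows and columns divided
by the pitch give orthogonal field components; within each of the 3×3
cells bounded by four electrodes, the two parallel edge gradients are
averaged per axis and combined as √(Ex² + Ey²), in mV/mm. The assignment
of components to cell centers (rather than shared electrodes) is a design
choice recorded in output metadata; for any locally linear potential the
two coincide. Summaries are the median with a distribution-free CI after
Grubbs pruning. `fit_lognormal` (three-parameter MLE via
`scipy.stats.lognorm.fit`) and `ellipsoid_summary` (covariance
eigen-decomposition; radii = 1.96 × the std along each principal axis,
covering ~95% of a Gaussian spread — a summary of cloud extent, not a
geometric fit) operate on arbitrary field-sample vectors and point clouds.

## Synthetic-data generator

The generator produces the study conditions the analysis assumes, with
known ground truth; its defaults were chosen once as realistic values for
anesthetized rat cortex and are not tuned per experiment.

- **Trial structure**: 1 min baseline / 1 min stimulation / 1 min post for
  the parameter-exploration paradigm; 20/20/10 min for the long paradigm;
  a sham layout with no stimulus. Frequencies 5–140 Hz, amplitudes
  50–400 µA as protocol metadata.
- **Spiking**: per-neuron log-normal baseline rates (median 1 Hz, σ = 0.7
  in log space — medians only are constrained by typical recordings, so the
  distribution shape is a documented choice). During stimulation an
  entrained neuron follows an inhomogeneous Poisson process with von Mises
  intensity `r·exp(κ cos(φ(t) − μ))/I₀(κ)` — normalized so the
  time-averaged rate stays r — realized exactly by Lewis–Shedler thinning
  with bound `r·e^κ/I₀(κ)`. Excited/suppressed neurons scale their rate by
  a factor (defaults ×2 and ×0.5). The spike-phase distribution is then von
  Mises, so the empirical PLV converges to I₁(κ)/I₀(κ), which the tests
  check against numerical integration.
- **LFP**: Gaussian background with PSD ∝ 1/f² above a 0.3 Hz high-pass
  (the lower edge of the recorded LFP band; without the high-pass nearly
  all the variance of a 1/f² process sits in sub-0.1 Hz drift that real
  acquisition filters remove), std 15 µV, plus a 4 µV broadband sensor
  noise floor. With PAC requested, a channel adds a low-frequency rhythm
  (4 µV) whose phase performs a random walk (0.5 rad²/s — cortical rhythms
  hold phase for seconds, not minutes) and a narrowband noise carrier
  (Gaussian spectral band, σ = 4 Hz, 3 µV RMS) whose amplitude is
  `(1 + depth·cos φ_LF)/2`-modulated. A noise carrier rather than a pure
  tone matters: a tone's envelope leaks coherently into neighbouring
  wavelet cells and smears the comodulogram peak upward in frequency.
- **Artifact**: a sinusoid at the stimulation frequency whose per-channel
  amplitude is `V₀ + 1000·(g_x·x + g_y·y)` µV with (x, y) the electrode
  position in mm, so the injected planar gradient (g_x, g_y) in mV/mm is
  exactly what the field estimator should recover.
- **MUA** (optional): white noise with a 1-ms biphasic spike template added
  at each ground-truth spike time, plus the artifact — used to exercise the
  comb filter; spike *times* are always delivered directly, since spike
  sorting is upstream of this package.

What the generator does **not** emulate: spike waveform variability and
sorting errors, bursting and refractory structure, non-stationary anesthesia
depth, cross-channel correlation of the LFP background, harmonic content of
the artifact, and line noise. Passing tests therefore validate the
estimators under the stated statistical structure, not robustness to these
real-data complications.

## Problem sizes

Default test and calibration sizes balance Monte-Carlo resolution against a
single-CPU run: 500 null trials × 1,000 permutations for each permutation
test, 200 epochs × 200 surrogates for the MI false-positive rate, 10,000
samples for the Grubbs level and the PPC mean, 120 s of signal for
comodulogram localization, and 10⁵ samples for log-normal recovery. The
pipeline CLI runs full-length one-minute sessions; a `--scale` factor
shrinks segments proportionally for quick demonstrations.

## Known limitations

- The Δ√|PPC| permutation test assumes exchangeable spike phases between
  periods; serial dependence of phases within a period (e.g. bursting at
  the stimulus period) would inflate its level.
- The MI surrogate test's level was calibrated on the generator's null;
  envelopes with much longer correlation times than ~1 s would call for
  longer blocks.
- `√|PPC|` is reported unsigned; a decrease in |PPC| toward 0 and a change
  of locking mode (unimodal → antipodal) are not distinguished.
- Electric-field estimation assumes the artifact dominates the
  stimulation-frequency band; endogenous oscillations at exactly the
  stimulation frequency would bias cycle peaks.
- Mixed-effects modelling of group contrasts is out of scope: the package
  exports tidy per-observation tables for external mixed-model software
  rather than re-implementing those fits.
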