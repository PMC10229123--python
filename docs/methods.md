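# Methods

`oscmem` reimplements, as a tested library, the computational analyses used
to characterize prefrontal–hippocampal interactions around a rodent
object-location memory task: sleep architecture, NREM oscillation events and
their cross-region coupling, spectral connectivity, single-unit activity,
and an exploration-learning model of task behavior.  Every stage can be
exercised on synthetic data with known ground truth, so correctness claims
are backed by oracle comparisons and injection-recovery experiments rather
than by eyeballing real recordings.

## Data model and conventions

All intervals are half-open `[start_s, end_s)` in seconds from recording
start; hypnogram epochs are 1 s and 0-based.  LFP is in microvolts.  Every
random draw flows through an explicit `numpy.random.Generator`; no function
touches global RNG state, so a fixed seed reproduces outputs bitwise.

## Sleep architecture (`oscmem.sleep`)

The hypnogram (states WAKE/NREM/REM/INT) is run-length encoded.  Rules:

- **Bouts**: maximal same-state runs *strictly longer than* 4 s (the floor
  is configurable; shorter runs are retained as "sub-bouts" for time
  accounting when requested).
- **Microarousals**: WAKE runs shorter than 15 s flanked by sleep on both
  sides, flagged whatever their length relative to the bout floor.
- **Sleep periods**: stretches of sleep separated by WAKE events longer
  than 300 s; quiet wake below 300 s is absorbed; leading/trailing wake is
  trimmed.
- **NREM episodes**: consecutive NREM bouts bridged across microarousals
  and across sub-bout runs of any state (the scoring literature bridges
  brief arousals; bridging sub-4 s non-WAKE runs is this package's choice
  and is documented here because the rule is otherwise undefined for, say,
  a 2 s REM run splitting two NREM bouts).
- **NREM periods**: episodes extended through immediately following
  transitional (INT) bouts.
- **Sleep cycles**: a NREM episode followed by zero or more INT bouts and
  then a REM bout.

Summaries report per-state totals (which conserve the hypnogram length by
construction), total sleep time (TST = NREM + REM + INT), %TST per sleep
state (undefined — reported as missing, never zero — when TST = 0), and
bout statistics.

## Oscillation events (`oscmem.events`)

Raw 30 kHz LFP is low-pass filtered (3rd-order Butterworth, 500 Hz
cut-off) and decimated by 30 to 1 kHz.  All filtering in the package is
zero-phase (forward–backward), so detected event times carry no filter lag
— the direction of filtering is a deliberate choice documented here
because it is otherwise ambiguous.

NREM epochs are extracted and concatenated; an `EpochMap` provides the
bijective mapping between concatenated and original timestamps.  Events
whose extent crosses a concatenation boundary are discarded: their true
duration is unobservable.

**Ripples** (HPC, 100–300 Hz).  Detection statistic: the Hilbert envelope
of the band-filtered trace ("thresholding voltage peaks" admits either the
rectified trace or its envelope; the envelope is chosen because the same
analytic-signal machinery defines event amplitude).  Each analysis period
(pre-sleep, post-trial rests) contributes a candidate threshold of
5 × SD of its concatenated-NREM *filtered trace* (not the envelope); the
single study-day threshold is the mean of period thresholds plus a 5 µV
offset.  Events must keep the envelope at or above threshold for ≥ 30 ms;
start/end are then extended outward to the half-threshold crossings, and
the peak is the envelope maximum.

**Spindles (9–20 Hz) and delta waves (1–6 Hz)** (PFC; delta optionally
HPC) use the same envelope machinery with a z-scored threshold, mean +
z × SD of the concatenated-NREM envelope, z = 2 by default, with minimum
durations 0.4 s (spindle) and 0.15 s (delta) and maxima 3 s / 1.5 s.  The
study this emulates tuned the equivalent thresholds per animal by eye;
the defaults here were calibrated once on the synthetic fixture and are
exposed in `BandEventParams`.

**Event features.**  Amplitude = max |Hilbert envelope| of the
band-filtered segment (µV).  Mean frequency = power-weighted mean of the
segment periodogram (Hz).

**Slow-oscillation phase.**  The cortical signal is band-passed 0.5–4 Hz;
the analytic phase is mapped to [0°, 360°) with **0° at the filtered
signal's positive peak and 180° at the trough** (cosine convention).  The
anchor is stated explicitly because phase conventions differ across labs.

## Coupling sequences (`oscmem.coupling`)

Sequences are defined on peak-to-peak lags falling in fixed windows,
closed on both ends (the boundary convention is configurable): D–S
[100, 1300] ms, D–R [50, 400] ms, R–D [50, 250] ms, R–S [2, 1000] ms.
Pair counting enumerates *all* qualifying ordered pairs — one event may
participate in several.  R–D–S counts delta waves that are both the target
of an R–D pair and the source of a D–S pair; D–R–S counts ripples that are
the target of a D–R pair and the source of an R–S pair.  Ripple–spindle
co-occurrence requires the ripple inside the spindle or either event's
boundary inside the other, which for closed intervals reduces to interval
overlap; a spindle hosting several ripples is counted once, the ripples
individually.

Ripple coupling fractions partition ripples into mutually exclusive
categories with precedence **DR > RD > ripple-with-spindle > single**.
The precedence is this package's tie-break (the partition is otherwise
undefined when a ripple qualifies for several categories) and is
configurable in spirit: the category sets are exposed by the
implementation.

## Spectral connectivity (`oscmem.spectral`)

**Theta coherence**: Welch magnitude-squared coherence, 1 s Hann windows,
80% overlap, constant detrending per window, averaged over 5–12 Hz.  Bias
under independence is ≈ 1/#windows, hence the calibration check with
~300 windows.

**Ripple-triggered spectrograms**: ±1 s around each ripple peak, 100 ms
Hann window, 10 ms steps; frequencies are evaluated exactly on the
requested grid (100–300 Hz step 2 for HPC, 0.5–20 Hz step 0.5 for PFC) by
direct DFT of the windowed frames.  A zero-phase mains notch (50 Hz
default, configurable to 60 Hz) is applied first.  Ripples without full
window coverage are excluded.  For group comparisons, the 2000 ripples
closest in amplitude to the median amplitude are selected first.

**Pixel-based permutation test**: statistic = difference of group means
per time-frequency pixel; the null is the distribution of the maximum
(and minimum) pixel statistic over label permutations (500 by default),
i.e. the max-statistic family-wise correction; two-tailed flags at the
1 − α/2 / α/2 quantiles.

**Nonparametric spectral Granger causality.**  Trial segments (2.2 s
around each ripple peak, long enough for one 0.5 Hz cycle) are Hann
tapered; the trial-averaged cross-spectral matrix S(f) is factorized with
Wilson's algorithm into S = H Σ H\*, a minimum-phase transfer function and
noise covariance, and Geweke's frequency-resolved directed influence is

&nbsp;&nbsp;&nbsp;&nbsp;GC<sub>x→y</sub>(f) = ln [ S<sub>yy</sub> /
(S<sub>yy</sub> − (Σ<sub>xx</sub> − Σ<sub>xy</sub>²/Σ<sub>yy</sub>)
|H<sub>yx</sub>|²) ]

Numerical notes on the factorization (tolerance 1e-8, ≤ 100 iterations):
the negative-frequency half of the spectrum is the plain transpose of the
positive half (equal to its conjugate for a Hermitian spectral matrix);
the causal (“plus”) projection keeps lags 0…M/2−1 with the zero-lag
coefficient halved and upper-triangularized — the shared ±M/2 lag of the
even FFT grid is dropped, without which the iteration settles into a
limit cycle instead of converging.  Convergence is typically reached in
~25 iterations; non-convergence raises with the residual in the message.
Granger values are clipped at 0 (the measure is nonnegative; tiny negative
values arise only from floating point).  The time-frequency variant slides
a 500 ms Hann STFT window in 10 ms steps and factorizes per step;
`granger_randomized_trials` draws 400-ripple subsets 30 times to build
trial sets for between-group permutation testing.

Interpretation caveat: directed spectral measures between strongly
oscillating, bidirectionally connected structures can be inflated by
shared rhythms and field spread; direction estimates here are validated
on simulated unidirectional systems and should be read comparatively, not
as literal causal flow.

## Single units (`oscmem.units`)

**Waveform features** operate on the 82-sample mean waveform at 30 kHz
(40 samples before the spike timestamp, 41 after): trough-to-peak delay =
time from the global minimum to the subsequent maximum; spike width =
full width at half trough depth with linearly interpolated crossings.
The width definition follows the convention of the standard cell-typing
tooling; it is stated because "spike width" alone is ambiguous.

**Cell typing**: a 2-component Gaussian mixture (diagonal covariances,
k-means++ init, 10 restarts, fixed seed) on (delay, width); the component
larger on both axes is pyramidal; points beyond 2 per-cluster SDs of
their centroid on either axis are outliers.

**Firing rates** per state pool all epochs of that state across the day;
zero time in a state yields an undefined rate (`None`), never 0.
Quantile groups G1–G5 use the 20/40/60/80 percentiles of the *reference*
population only (upper limits inclusive); target values above the
reference maximum fall in G5.

**ON/OFF periods**: spike trains of ≥ 7 neurons (configurable) are merged
into one multi-unit train per NREM bout.  OFF = inter-spike gaps strictly
longer than 50 ms; ON candidates are the complementary spike runs, kept
when 50 ms ≤ duration ≤ 4000 ms and ≥ 10 spikes.

**Ripple PETH**: spike lags in ±1 s windows around ripple peaks, pooled
per neuron, binned at 10 ms (200 bins), z-normalized across all 200 bins
(not against a baseline segment — the whole-vector convention), averaged
over neurons, then smoothed twice with a 5-point moving average whose
window shrinks symmetrically at the edges (MATLAB `smooth` semantics).

**Ripple response**: rates in baseline [−200, −120), pre [−120, −40),
during [−40, +40), post [+40, +120) ms epochs around the peak.  The
modulation label comes from a paired bootstrap (1000 resamples over
ripples) of the during − baseline rate difference: z ≥ +2 → active,
z ≤ −2 → suppressed, else neutral.  Resampling ripples (not epochs
separately) keeps the statistic unit-normal under an unmodulated neuron —
bootstrapping the baseline alone would inflate |z| by √2 under the null.
The criterion is this package's declaration; the original analysis never
specified one.

## Behavior model (`oscmem.behavior`)

The Object Space Task places two identical objects in two of four corners
over five 5-minute training trials; conditions: *stable* (both corners
fixed), *overlapping* (one fixed, one moving), *random* (both moving).
Discrimination index DI = (novel − familiar)/(novel + familiar); zero
total exploration raises, it is never silently scored 0.

The exploration model keeps a per-corner association strength w ∈ [0, 1]
updated by a delta rule, w ← (1 − α)w + α·o (o = 1 if occupied), with
uncertainty U = w(1 − w) and a softmax over β·U of the two present
corners deciding the exploration split.  α ∈ [0, 1] is the learning rate
(high α = recency-driven, episodic-like; low α = slowly accumulated,
semantic-like memory); β is the inverse temperature whose sign separates
neophilic (β > 0) from neophobic (β < 0) expression.  **This concrete
instantiation is a declared stand-in**: the source study delegates its
equations to earlier work, so this package fixes a minimal model with the
stated qualitative contract (stable associations → low uncertainty;
α controls recency weighting; β controls strength and sign of memory
expression) and treats it as the reference model of the artifact.

Likelihood: exploration time is discretized into 1 s units and the split
is binomial with the softmax proportion, giving a proper likelihood from
durations alone.  Fitting is an exhaustive grid (101 × 101 over
α ∈ [0, 1], β ∈ [−10, 10]) followed by Nelder-Mead refinement —
deterministic, no local-optimum ambiguity.  The grid is vectorized over α
(the memory trajectory depends only on α and the design) and broadcast
over β, so a 45-subject recovery experiment runs in ~2 s.  Flat ridges
are real degeneracies of this model (α = 0 or β = 0 both give p = ½ under
some designs); ties are broken deterministically toward the smallest |β|,
then smallest α — the weakest memory expression consistent with the data.

## Synthetic data (`oscmem.synthetic`)

The generator emulates all four pipeline inputs:

- **Hypnogram**: a semi-Markov chain with exponential bout durations
  (defaults: WAKE 120 s, NREM 300 s, REM 90 s, INT 20 s — plausible for
  rat polysomnography); a state with mean 0 is never entered.
- **LFP**: white noise (SD 5 µV) plus 1/f-shaped background (SD 15 µV,
  exponent 1) obtained by spectral shaping; events are **Hann-tapered
  sinusoid bursts** — the simplest morphology whose envelope, duration
  and mean frequency are analytically known, so detector timing can be
  verified in closed form.  Ripples (default 60–100 ms, 120–250 Hz) go
  only on the HPC channel and spindles/delta only on PFC, and only inside
  NREM epochs, matching where the detectors look.  Optional couplings
  (e.g. every delta spawns a ripple at a fixed lag) are recorded as links
  in the ground truth.
- **Spike trains**: inhomogeneous Poisson by thinning, log-normal base
  rates, a von Mises gain on a slow-oscillation phase ramp (unit mean),
  and a multiplicative gain inside ±50 ms of ripple peaks; 82-sample
  biphasic waveform templates with class-dependent trough-to-peak delay
  and width.
- **Behavior**: sessions simulated from the model itself, 40 s total
  exploration per 5-minute trial (8 s per trial-minute, a typical rat
  exploration budget).
- **Event trains**: exact numbers of requested sequences, each in its own
  time slot with 6 s spacing so no cross-slot lag can enter any window;
  lags drawn uniformly inside the window.  A requested triplet implies
  its in-chain pairs (an R-D-S adds one R-D and one D-S); D-R-S lags are
  drawn from [360, 400] × [950, 1000] ms so the induced D→S lag exceeds
  the 1.3 s D-S window.  The generator recounts its own output with the
  sequence counter and raises on any mismatch; the implied expected
  counts ship in the ground truth.

What the generator does **not** emulate: biophysical LFP (volume
conduction, electrode drift, state-dependent spectra), bursty or
refractory spiking, ripple-frequency chirps, behavioral satiety.  Passing
tests therefore demonstrate algorithmic correctness under controlled
conditions, not performance on real recordings — thresholds that are
tuned per animal in practice remain tunable here for the same reason.

## Validation problem sizes

The validation experiments (mirrored in `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 100 random event trains up to 1000 events
per kind for the sequence-counting oracle; 100 random multi-unit trains
for the ON/OFF oracle; one 30-minute all-NREM recording at 20 ripples/min
for injection recovery, with amplitudes drawn at 3.5–5× the noise-derived
detection threshold (5 × band-noise SD + 5 µV) so the weakest event still
satisfies SNR ≥ 3 — event power itself inflates the realized in-situ
threshold by roughly √(1 + duty·A²/2σ²), which is why amplitudes are
anchored to the noise-only threshold; 45 synthetic subjects × 8 sessions
for parameter recovery; 20 seeds each for Granger direction and
permutation-test calibration (60 trials × 2 s at 250 Hz per seed); and
100 random inputs per conservation property.  These sizes keep the whole
validation under a few minutes on one CPU while leaving comfortable
statistical margins.

## Known limitations

- The exploration model is a declared minimal instantiation; fitted α/β
  are comparable within this package, not numerically interchangeable
  with fits from other implementations of the task model.
- Spindle/delta thresholds are z-scored envelope criteria; cycle-counting
  detectors would disagree on marginal events.
- The Granger implementation is bivariate; conditional (multivariate)
  Granger and phase-amplitude coupling are out of scope.
- Sequence windows, the closed-boundary convention, and the ripple
  coupling precedence are configurable conventions, not discoveries; on
  real data their choice materially affects counts near window edges.
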