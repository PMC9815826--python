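# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `sgcoflux`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Timing conventions

Timestamps are seconds from session start. Bins are left-closed, right-open.
Every sliding window is causal: the value at time t summarises data in
(t − W, t]. For discrete series sampled at step s this is the w = W/s samples
ending at t; for continuous data (spikes, LVP samples) it is the set of
rate/step blocks wholly contained in the window. Causality is property-tested:
perturbing inputs after t never changes an output at or before t.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the biophysics:

- **LVP**: a smooth asymmetric pulse per beat (fast upstroke peaking at 30% of
  the beat, slower decay), diastolic→systolic→diastolic, beat periods jittered
  multiplicatively (SD 3%). Heart rate 80 bpm, 110/10 mmHg, sampled at 1 kHz.
  Only the amplitude distribution and the phase structure matter downstream.
- **Cardiac phase** φ is defined from successive systolic peaks (located on
  the waveform itself with a prominence criterion), linear in time between
  peaks, φ = 0 at each peak.
- **Spiking** is an exact inhomogeneous-Poisson process (thinning) with

      λ_c(t) = r₀ · exp(κ_c(t)·cos φ(t)) / I₀(κ_c(t)) · burst_c(t)

  Baseline r₀ = 5 Hz per channel. The I₀ normaliser keeps the mean rate at r₀
  for any locking strength, so rate and specificity are controlled
  independently. κ_c(t) is a reflected Gaussian random walk (1 s steps, step
  SD `kappa_drift_sd`) on [κ̄ − r, κ̄ + r] with κ̄ = 1.5 and half-range
  r = `kappa_half_range`. The *range*, not only the step size, controls the
  session-scale variance of κ: a narrow range pins κ near κ̄ however long the
  session. Control preset: drift 0.05, range 0.25; HF preset: drift 0.2,
  range 1.5. This is what plants "more variable specificity" in HF.
- **Events**: a Poisson process of rate `event_rate_true` (control 0.005/s,
  HF 6× = 0.03/s) of fixed-length bursts (10 s); overlapping draws are
  discarded so intervals never overlap. Each event recruits a uniform subset
  of at least half the channels; recruited channels get their rate multiplied
  by `event_gain` = 4 and their locking boosted by `event_kappa_boost` = 2.5.
  The boost is what plants lower (more coherent) in-event entropy; it is
  large because the |A|-entropy is nearly flat in κ over [1, 2.5] (measured
  H ≈ 0.849 at κ = 1 vs 0.842 at κ = 2.5, but 0.807 at κ = 4), so a small
  boost would plant no measurable effect.
- **Voltage**: each spike is a biphasic template (1 ms sine period, the
  repolarisation lobe scaled 0.5 — the asymmetry matches extracellular
  waveforms and prevents systematic plus/minus ties in the detector), scaled
  by amp·(1 ± 20% uniform), summed onto white Gaussian noise. Default
  amp/noise SD = 8.

Desk scale: 16 channels, 1200 s default sessions (scripts) and 1800 s for the
event-rate cohort experiment, standing in for ~6 h recordings; event rates
are correspondingly higher than in real data so a session contains enough
events to analyse. Determinism: all draws derive from `numpy` SeedSequences
spawned from a single seed; identical configs give bit-identical cohorts.

What the generator does **not** model: electrode drift and the
post-insertion stabilisation period, ECG/respiration, non-Poisson spike-train
structure (refractoriness, bursts within channels), correlated noise across
channels, hemodynamic feedback from neural activity onto LVP. Passing tests
therefore establish that the pipeline recovers planted structure of the
assumed form, not that real SG recordings have that structure.

## Spike detection

Competitive adaptive-threshold detection per channel. Plus and minus barriers
start at the trace extremes; both are stepped toward zero by 2% of their
current value per adjustment; the first polarity to show ≥ 3 threshold
crossings (maximal runs beyond the barrier) wins, one spike per run at the
run's extremum; ±1 ms around each detection is masked to zero; both starting
barriers shrink by 0.8 and the competition repeats. Barriers never start
below a floor of 4 robust noise SDs (median(|x|)/0.6745; for a noiseless
trace, 10⁻⁶ of the peak), and detection halts when a round steps below the
floor without a winner — i.e. when nothing above the noise floor remains.
Ties (both polarities reaching the crossing count at the same step) go to
the side with the larger extremum magnitude, then to plus; this makes
detection equivariant under trace negation. Consequences, all tested:
within a polarity the winning barriers strictly decrease and earlier
detections have larger magnitudes; re-running detection on the masked
residual finds (almost) nothing; at amp/noise = 8, recall ≥ 0.95 and
precision ≥ 0.90 against ground truth at ±1 ms tolerance.

All thresholds are exposed in `DetectorParams`; defaults are scale-free in
noise units. The detector returns multi-unit trains; no sorting.

## Rates, coactivity, events

- Rate bin 0.1 s; sliding statistic (mean or sample SD, n−1) over a 10 s
  window, stepped at 1 s. The smoothing window is deliberately several-fold
  shorter than the 60 s correlation window: if the two are equal, each
  Pearson window of the smoothed series has ≈ 1 effective degree of freedom
  and chance cofluctuation swamps the signal (measured: with 60 s/60 s
  windows, out-of-event cofluctuation at C = 0.5 is ~80%, above the in-event
  level; with 10 s/60 s it is ~19% against ~70% in-event).
- Pearson windows with zero variance on either series are undefined (NaN)
  and excluded from cofluctuation denominators — silent zeros would bias the
  percentage.
- Cofluctuation uses signed R > C (coactivation, not anti-correlation).
- An event opens at an up-crossing (< T to ≥ T) and closes at the next
  down-crossing or at series end; a series already above T at its first
  defined sample opens no event (no up-crossing was observed). NaN samples
  do not change the crossing state. ER = events / defined duration.
  Note the event *count* is not monotone in T: raising T can split one long
  excursion into several. Total event *duration* is monotone.
- (C, T) selection: ER is computed on the grid C ∈ {0.50…0.95} × T ∈
  {10…90}%; a point is convergent when ER > 0 and the relative ER change to
  each in-grid 4-neighbour is ≤ tol; the largest connected convergent
  plateau wins, lowest C then lowest T within it; with no convergent point,
  the minimum-roughness point is returned flagged. tol defaults to 0.4: at
  desk-scale event counts (n ≈ 5–20 per session) the Poisson jitter between
  neighbouring grid cells is ~√(2/n) ≈ 30–45%, and a tighter tolerance
  rejects every true plateau while keeping degenerate 1–3-event plateaus
  whose neighbours are identical. For long recordings with hundreds of
  events a tighter tol is appropriate.
- Log-normal diagnostics: μ_FIT, σ_FIT are the ML estimates (mean/SD of the
  natural logs of the positive values; ≥ 100 required); the 68% band is
  exp(μ ± σ); `frac_outside` ≈ 0.317 for a true log-normal, larger under
  heavy tails.

## Specificity and entropy

LVP amplitude is discretised into B = 20 uniform bins between the 1st and
99th percentiles (outer bins absorb the tails). At each step (1 s) and
channel, p_spike is the normalised histogram of LVP values (nearest-sample
lookup — LVP varies slowly at 1 kHz) at the spikes in the causal window, and
p_rand the histogram of all LVP samples in the window; A = p_spike − p_rand.
Rows with no spikes are undefined. The window default is 15 s: long enough
for ~20 cardiac cycles and ~75 spikes at baseline rate, short enough to
resolve 10 s events — a 60 s window dilutes a burst 6:1 with surrounding
baseline and suppresses both the in-event entropy drop and the HF
variability contrast.

Entropy: q = |A| / Σ|A| (rows with Σ|A| = 0 get H = 1, the
vanishing-specificity limit), H = −Σ q ln q / ln B ∈ [0, 1] n.u., with
0·ln 0 ≡ 0. Entropy of p_spike itself is available behind a flag. Summaries
use the sample SD. The event partition joins entropy and event series on
nearest timestamps within half a step; a summary with an empty partition is
marked partial and excluded from model input.

## Statistics

- Scalar gate: Shapiro–Wilk per group at α = 0.05; both normal → pooled
  Student t (Welch behind a flag), else Wilcoxon rank-sum; a zero-variance
  group forces the rank-sum path, flagged. Cohen's d on the pooled SD is
  always reported. Under Normal and heavy-tailed nulls the gated pipeline's
  type-I error stays ≤ 0.065 at nominal 0.05, and its power at a planted
  standardised difference of 1.5 (n = 6 vs 11) matches the closed-form
  noncentral-t power within 3 points (both verified over 2000 replicates).
- Mixed models are fit by REML (`statsmodels` MixedLM) with a random animal
  intercept and variance components for channel (and, in the event model,
  for deciles of each channel's baseline entropy — a continuous variable
  cannot index a random intercept directly, so it is binned; using it as a
  fixed covariate is available behind a flag). Singular fits refit without
  the offending component, flagged.
- Inference uses between/within t reference distributions: animal-level
  coefficients (group) get df = n_animals − 2, within-animal coefficients
  the residual df. With z-based Wald p-values the 14-animal design is
  anti-conservative (≈10% rejections at nominal 5% under label permutation);
  with the t correction the permutation null is uniform and planted-offset
  CI coverage is ≈ 95% (verified over 500 replicates).
- d_RM (repeated-measures Cohen) pairs inside- vs outside-event values per
  (animal, channel, statistic); for the group entropy model, where no
  within-animal pairing exists, it pairs the two groups' channel-wise means
  across the shared channel labels. Degenerate pairings (zero-variance
  margin with non-zero mean difference) are an error; identical pairs give 0.
- Two-sided p < 0.05 is the significance convention; no multiplicity
  correction is applied.

## Channel screening and session handling

Channels are masked when their robust noise SD exceeds 5× the median
channel's or their spike count falls below 10 per session; a session with
fewer than two surviving channels is excluded with an explicit error.
Sessions with unusable LVP can still contribute event rates (the
event-rate and entropy analyses take different cohorts).

## Numerical notes

- Coactivity is computed from centred windows (two-pass within each window),
  matching the textbook Pearson formula to < 1e−12 on test instances.
- Specificity uses per-block histogram cumulative sums, exact in integer
  counts; zero-sum of A rows holds to < 1e−12.
- The detector's inner loop touches only samples above the barrier floor, so
  full-session detection is O(noise excursions + spikes), not O(samples),
  per barrier step.
- The SD rate statistic uses the numerically guarded one-pass form with a
  max(·, 0) clamp before the square root.

## Known limitations

- The convergent-threshold rule can still land on a degenerate small-count
  plateau for an occasional session (observed ~1 in 10 at desk scale),
  inflating between-animal ER variance; the ER surface and plateau mask are
  returned for audit.
- Detected event intervals lag the underlying bursts by up to the
  correlation window, so entropy partitioned by *detected* events dilutes
  the in-event contrast relative to partitioning by true burst times (~70%
  vs ~100% of channels showing the planted direction).
- Event counts are not monotone in T (splitting); only event duration is.
- d_RM for the group entropy model relies on channel labels being comparable
  across animals (same electrode geometry), which holds for the generator
  and for fixed linear arrays but not generally.
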