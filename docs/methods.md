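# Methods

## Signal model and detrending

A photometry session is a pair of uniformly sampled channels on a common
clock, digitized at 1017.3 Hz by default: the 465 nm signal channel and the
405 nm isosbestic control.  The synthetic generator and the analysis chain
share one forward model:

    F465(t) = B465(t) · (1 + c465·a(t) + s(t)) + ε465(t)
    F405(t) = B405(t) · (1 + c405·a(t))        + ε405(t)

* `B(t)` — double-exponential-plus-constant photobleaching baseline
  (defaults 10·e^(−t/120 s) + 20·e^(−t/1200 s) + 70 a.u., i.e. ~100 a.u.
  dropping ~30% over tens of minutes).  By default the 405 channel uses the
  same shape scaled by 0.6, the regime in which a straight-line fit of
  control onto signal is exact — both channels bleach through the same
  fluorophore, so proportional decay is the physically natural default.
* `a(t)` — shared artifact process (motion, fiber bending): unit-variance
  Gaussian noise smoothed to a −3 dB bandwidth of 0.5 Hz.  The draw is softly
  saturated at ±3.2 σ (tanh) so that 1 + c·a stays positive for couplings up
  to 0.3; only the extreme tail of the process is affected.  Couplings
  default to 0 and are set explicitly in artifact-rejection experiments.
* `s(t)` — sum of sensor transients: difference-of-exponentials kernels
  (τ_rise 0.1 s, τ_decay 1 s by default, approximating fast GCaMP kinetics),
  peak-normalized so the `amplitude` parameter *is* the peak fractional dF/F
  (default 0.05 = 5%).  The kernel peaks at τ_r·τ_d/(τ_d−τ_r)·ln(τ_d/τ_r)
  ≈ 0.256 s after the event.
* `ε(t)` — i.i.d. Gaussian measurement noise per channel.  The default is
  defined in terms of what the detrended trace sees: the *net* dF/F noise at
  the native rate is 1% of baseline (peri-event SNR ≈ 5 against the default
  5% transient).  Both channels contribute — the control channel's noise is
  amplified by the regression slope — so each channel carries
  0.01/√2 of its own baseline.
* Acquisition-chain emulation: a 6th-order 6 Hz low-pass is applied to both
  assembled channels, because the hardware band-limits everything it
  digitizes and the pipeline never sees white noise at the native rate.  It
  is applied zero-phase so injected event times stay exactly aligned with the
  ground truth; disable with `lowpass_hz=None` (the signal-model collapse
  identity — dF/F ≡ 100·s(t) with artifacts, noise and bleach off — is
  stated and tested in that configuration).

Detrending downsamples by non-overlapping block means (block =
round(fs/target); 100 Hz for peri-event work, 10 Hz for movement
correlation), stamps each block mean at its block center (so alignment
carries no half-block bias), fits F̂ = β₁·F405 + β₀ by ordinary least
squares, and computes dF/F(%) = 100·(F465 − F̂)/F̂.  "Per-trial" mode fits
one regression per event window, the paper-style treatment for peri-event
analysis; "whole-session" mode uses a single fit.  A zero-variance control
channel degrades the fit to predicting a constant: the *median* of the 465
segment (slope 0), with a logged warning.  The median rather than the mean is
deliberate — with sparse positive transients the median sits on the baseline,
while the mean would bias dF/F downward by the transient mass.

## Iterative baseline flattening

For session-long analyses (movement cross-correlation) residual slow drift is
removed by an iterative lower-envelope smoother: b₀ = signal,
b_{k+1} = centered 15 s moving average of min(signal, b_k), output =
signal − b₁₀₀.  Transients shorter than the window ride above the envelope
and survive (≥ 99% of a 5% peak in the validation runs); drift at scales
longer than the window is absorbed into the baseline.

Numerical choices: the window length is rounded to an odd sample count so the
average is centered; the moving average pads both ends by first-order
extrapolation from the terminal windows, which makes a linear ramp an exact
fixed point of the smoother (constant padding would bend the baseline
estimate at the trace edges).  The procedure is idempotent to within
0.05% RMS.

Known properties and limitations: (i) on *noisy* traces the min-envelope
recursion settles ≈ 2.3 σ below the local mean, leaving a positive offset of
about +0.23% at the pipeline's 10 Hz noise level — harmless for correlation
analyses (which z-score) but visible as a small positive baseline; the
flattening contract is therefore stated for drift + transients.  (ii) the
iterated 15 s average has an effective smoothing scale of roughly 45 s, so
oscillatory drift with substantial curvature below that scale is not fully
removed; photobleaching-type drift (decaying exponentials, linear ramps) is.

## Peri-event quantification

Rows of the trial matrix are the samples in [onset − pre, onset + post); the
sample at relative time 0 is the first sample at or after the onset.  Trials
whose window leaves the trace (or crosses undetrended gaps in per-trial
traces) are dropped with a warning.  Summaries:

* mean ± SEM (sd/√n, ddof 1) pointwise over trials;
* peak delta: per-trial max over a response window minus max over a disjoint
  earlier baseline window, both half-open in relative time; raw sample maxima,
  no smoothing or prominence criterion.  The per-animal summary is the mean
  of trial deltas (`peak_delta_of_mean` provides the delta-of-averaged-traces
  alternative).  The "2 s surrounding consumption" window is centered:
  [−1, +1) s around the scored consumption time.  Consumption times are an
  input column (scored from video), never auto-detected.
* AUC delta: trapezoidal area over [onset, onset + 3 s] minus
  [onset − 3 s, onset], in %·s.  Both windows span their nominal duration
  exactly (closed sample spans sharing the onset sample), so adding a
  constant to the trace cancels exactly in the delta.  Areas are signed —
  a dip below baseline subtracts.

## Movement, cross-correlation, locomotion

Body movement is the percentage of pixels whose intensity changes by more
than a threshold (default 10 on a 0–255 scale) between consecutive frames;
frame 0 is assigned 0.  Inactivity time totals maximal sub-threshold runs
lasting at least a minimum bout (defaults 0.05% pixels, 1 s); both defaults
are package choices, as tracking-software internals are proprietary, and are
configurable.

The cross-correlogram z-scores both series over the whole session and
normalizes each lag's sum by its overlap count, so lag 0 is the ordinary
Pearson correlation.  Sign convention: positive lag means the photometry
signal leads movement (r(ℓ) pairs dff(t) with movement(t+ℓ)).  Because video
and acquisition clocks are never exact multiples, `align_movement`
interpolates the movement trace onto the photometry grid before correlating;
without it the two 10 Hz streams drift apart by several samples over a
session.  The estimator is pinned to a brute-force per-lag oracle at 1e−10.

Locomotion: total distance is the sum of Euclidean step lengths of the x/y
track; time per zone counts samples inside half-open axis-aligned rectangles
(boundary points belong to the rectangle containing them under
[x0,x1)×[y0,y1)), divided by the frame rate.  Zones must not overlap.

## Optogenetic dose-response

Pulse-count titration: per condition, the mean over its 10 trials of the AUC
delta (3 s pre / 3 s post); a configuration error is raised if trials are
closer than the combined window.  Intensity titration: per trial the maximum
dF/F within 1 s after onset; per block the *median* of trial peaks (median
for the intensity titration, mean for the pulse-count titration, both
configurable — the two protocols are conventionally summarized differently
and we keep both defaults).  A 0 mW control block is scored from the 1 s
before onset, giving the noise floor of the same statistic.

## Statistics

t and df come from the closed forms (t = (x̄−μ₀)/(s/√n), df = n−1; paired =
one-sample on differences), p from the t distribution; zero variance or n < 2
raise rather than return NaN.  The mixed ANOVA is the classical
sums-of-squares decomposition for a balanced design with one
between-subjects factor (subjects nested in groups) and one within-subjects
factor: the between effect is tested against the subjects-within-groups mean
square, the within effect and interaction against the within-error mean
square.  Balance is enforced with an error listing the missing
(subject, level) cells; for balanced designs Type I/II/III sums of squares
coincide, so the distinction does not arise.  No sphericity
(Greenhouse–Geisser) correction is applied — a known limitation for designs
with more than two within levels.  Post-hocs are pooled-variance two-sample
t-tests of group pairs at each within level, Šídák-adjusted
(p' = 1 − (1−p)^m) with family size m = (#levels × #pairs).  Count data from
operant tasks can be transformed with log₁₀(x+1), which admits zero counts.
Calibration is verified by simulation: one-sample t type-I error at α = 0.05
within [0.04, 0.06] over 10,000 Gaussian-null replicates (n = 6), and all
three ANOVA F tests within [0.03, 0.07] over 1,000 replicates.

## Synthetic paradigms (study conditions)

* **Fear**: 6 trials; 30 s tone with the 0.5 mA foot shock in its last 2 s
  (shock onset 28 s after tone onset); quasi-random inter-onset intervals
  uniform on [0.5, 1.5]× a 180 s mean.  Transients are locked to shock
  onsets.  The movement trace (video rate, default 30 Hz) is a baseline plus
  gain × the transient drive delayed by the configured coupling lag, plus
  smoothed noise, clipped to [0, 100]%.
* **Reward**: 30 trials; 5 s tone then pellet delivery; consumption = delivery
  + positive jitter (exponential with 1 s mean by default; a degenerate law is
  available); transients locked to *consumption*, not delivery.  Omission
  trials drop the pellet and the transient; unpredicted trials drop the cue.
  Mean ITI 60 s, quasi-random as above.
* **Opto**: 2/5/10/20/40-pulse trains at 20 Hz in shuffled order, 10 trials
  per condition (50 total), fixed 45 s ITI; evoked amplitude =
  gain-per-pulse × pulse count (default 0.25% dF/F per pulse; optional
  saturation cap, off by default).
* **Behavior streams**: a bright square blob random-walks inside a 45×45 cm
  arena rendered to binary frames; the per-frame changed-pixel percentage is
  recorded as ground truth, and the matching position track drives the
  locomotion measures.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: hemodynamic or autofluorescence contamination,
sensor-kinetics nonlinearity and saturation, non-Gaussian artifact shapes
(cable tugs are often impulsive), lock-in demodulation hardware, tracking
noise, and inter-animal variability.  Bleach and noise magnitudes are package
defaults chosen to be representative, not measurements.

## Problem sizes used in validation

The acceptance script and the end-to-end tests run full-length sessions at
the native 1017.3 Hz (fear ≈ 15–20 min with the default 3 min mean ITI,
reward ≈ 30 min, opto ≈ 38 min), 10,000-sample cross-correlation oracle
comparisons, 10,000 t-test null replicates and 1,000 ANOVA null replicates —
sizes at which every stochastic check is stable across seeds.
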