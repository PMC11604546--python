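# Methods

## Scope

`photolock` analyzes behavior-locked neural recordings of the kind used
to study social behavior circuits: dual-wavelength fiber photometry of a
genetically encoded calcium indicator (GCaMP) recorded during repeated
social exposures, patch-clamp spike-rate series under bath-applied
neuropeptides (AVP, the oxytocin agonist TGOT), and contact-duration
tables from a social habituation/discrimination task. Because the
corresponding animal recordings are not packaged here, the library ships
a first-class synthetic-data generator whose outputs carry complete
ground truth; every processing stage is validated against that truth.

## Photometry processing model

A recording holds two demodulated channels on a uniform time base: the
calcium-dependent signal (465 nm excitation) and the isosbestic control
(405 nm), at which GCaMP fluorescence is calcium-independent. The
working model is

    F465(t) = B465(t) * (1 + a(t) + s(t)) + e1(t)
    F405(t) = B405(t) * (1 + g * a(t))    + e2(t)

with per-channel bleaching baselines `B`, shared motion artifacts `a`
(per-channel gain `g`), calcium transients `s` present only in the
signal channel, and independent noise. The chain in
`process_recording` is:

1. **Low-pass filter** (default 12 Hz, zero-phase 4th-order
   Butterworth). Zero phase so event latencies are not shifted; DC gain
   1. The stage is skipped (`cutoff_hz=None`) when the sampling rate
   puts the cutoff at or above Nyquist — e.g. the 20 Hz demo
   configuration.
2. **Loess smoothing** of each channel: local linear fits with tricube
   weights (`statsmodels` lowess). The span is expressed as a fraction
   of samples; the demo configuration uses 5 samples (0.25 s at 20 Hz),
   small enough to preserve the fast GCaMP rise (~0.1 s).
3. **Moving-minima detrending**. The slow-drift envelope is a
   morphological opening — a centered running minimum followed by a
   running maximum with the same window (default 60 s) — then
   loess-smoothed to remove staircase steps. The bare running minimum
   of a monotonically bleaching trace is biased low by the within-window
   drift (the minimum of a decaying curve sits at the window's trailing
   edge); the following maximum restores the envelope to the local floor
   while still ignoring any transient narrower than the window. Edges
   use point-reflection padding, which continues the local trend and
   avoids the half-window edge bias a clamped window produces over steep
   early bleaching. The envelope is estimated on an extra-smoothed copy
   of the channel (`minima_presmooth_s`, default 5 s) so it tracks the
   floor rather than noise minima; the subtraction still applies to the
   lightly smoothed signal. Subtracting the envelope removes drift
   additively, preserving transient amplitudes.
4. **Positive re-offset.** After detrending both channels hover near
   zero; each channel gets the mean of its own envelope added back so
   the ratio in step 6 has a positive, interpretable denominator.
5. **Isosbestic regression.** Ordinary least squares predicting the 465
   signal from the 405 control over the whole recording. The fitted
   control (`slope * F405 + intercept`) carries exactly the structure
   the two channels share — residual motion artifacts — in signal-channel
   units. Detrending precedes the fit so the regression captures
   artifact coupling rather than shared bleach.
6. **dF/F** = (signal − fitted control) / fitted control, per sample.
7. **Z-score**, either over the whole recording (default) or over an
   explicit baseline window. Transient detection uses "+3 SD from
   baseline", so the validation runs normalize on a known quiet interval
   at the start of the recording; the generator guarantees such an
   interval (`quiet_start_s`).

## Transient detection and quantification

A transient is a maximal excursion of the z-scored trace above the
threshold (default +3 SD), extended outward to the nearest
zero-crossings of z — the "base" of the spike, zero being the baseline
itself in z units. Bases that overlap or sit closer than `min_gap_s`
(default 0.5 s) merge. Transients narrower than `min_width_s` are
discarded; the demo configuration uses 1.0 s, about half the narrowest
credible GCaMP7s transient base (decay ~1 s, base ≥ 2 s), which rejects
noise excursions that reach 3 SD but cannot sustain a transient-like
base. AUC is the trapezoidal integral of max(z, 0) from base to base
(the whole spike above baseline; a supra-threshold-only variant is
exposed via `auc_mode="supra"`). Width at base is offset − onset.

Peri-event analysis extracts z segments in a [−pre, +post] window
(default 5 s each, a 10 s peri-event period) around labeled events,
dropping events whose window leaves the recording (zero-padding would
bias the SEM). The pre/post change is mean(post) − mean(pre) per event,
summarized by mean, SD and Cohen's d against zero. Trial-block
summaries assign each transient to the trial containing its peak
(half-open intervals; a peak exactly on a boundary belongs to the
earlier trial) and report per-block AUC totals, counts and width
distributions, with out-of-trial transients tallied separately.

## Spike-train responder classification

Rates are binned (default 60 s bins; stimulations last ~2 min with long
washes) and expressed as % of the pre-drug baseline mean. A cell is
*responding* when some run of at least `consecutive_bins` (default 2)
consecutive non-baseline bins deviates from 100% by at least
`change_threshold_pct` (default 10%; the boundary counts as responding,
"less than 10%" is insensitive); otherwise *insensitive*. The rule is
direction-agnostic — sustained excitation classifies like inhibition —
because persistently deviating cells are pooled as responders.

Significance of the post-stimulation change uses a two-sided Wilcoxon
signed-rank test pairing each epoch bin with the temporally closest
baseline bin. Pairing against observed baseline bins rather than the
fitted 100% expectation keeps the test calibrated: the baseline-mean
estimation error would otherwise shift every epoch bin coherently and
inflate the type-I rate well above nominal (we measured ~10% at
α = 0.05 for the naive version; the paired form sits at 4–5%).

Group comparisons of responder proportions use Fisher's exact test on
the 2×2 classification counts (per-cell basis; a rank test on binary
labels reduces to a proportion test, and exact rank methods do not
tolerate the massive ties) or an exact Mann-Whitney test on per-animal
insensitive fractions (per-animal basis).

## Behavior: habituation and discrimination

Contact-duration tables hold one row per subject × trial (five 5-min
trials: the same stimulus mouse four times, then a novel mouse).
Inclusion rules act on trial 1 only: subjects exploring < 15 s are
excluded (strictly; exactly 15 s is retained), then subjects outside
mean ± 2 SD of their own experimental group's trial-1 distribution are
excluded. The reference population for the SD band is the within-group
trial-1 distribution of subjects surviving the minimum-duration rule —
within-group so a genotype effect on sociability does not itself drive
exclusions, post-minimum so near-zero explorers do not drag the band
toward zero. The band is computed once (an a-priori criterion, not an
iterated trimming). Later-trial performance never excludes.

Per-subject metrics: habituation index = trial4/trial1 (decline toward
familiarity) and discrimination index = trial5 − trial4 in seconds
(novelty rebound). Group contrasts report mean ± SEM, a two-sided
Mann-Whitney test (exact at small n) and Cohen's d with the pooled SD,

    d = (m_a − m_b) / sqrt(((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies
on: single-exponential photobleaching per channel (default 20% lost,
τ = 600 s, independent time constants so the channels' drifts are not
trivially identical), brief biphasic motion artifacts (one sine cycle,
0.2 s) shared between channels with configurable gain, double-exponential
calcium transients (rise 0.1 s, decay 1 s — GCaMP7s-like) only in the
signal channel, additive Gaussian noise, trial-structured social
exposures (empty box, the same mouse repeatedly, a novel mouse) whose
contact bouts end in turn-away events that anchor event-locked
responses, drug-inhibition epochs in spike series, and
habituating/non-discriminating contact-duration patterns.

Transient amplitudes are specified in units of the additive noise SD;
with `noise_sd=0` the unit falls back to 1 a.u. so degenerate noiseless
configurations still carry signal. The transient waveform is truncated
where it falls below 5% of its peak, floor-subtracted and renormalized,
giving it compact support: a pure double exponential never returns to
zero, so "width at base" would have no exact ground truth. The recorded
`true_auc` integrates the waveform on a 16× refined grid (convergence
< 0.1% under further refinement). Two condition groups differ in
event-locked response size: condition B scales amplitude ×1.5 and decay
×1.6 relative to A, emulating a larger/longer-response contrast between
genotype-like groups.

Not emulated: hemodynamic or pH confounds, wavelength-dependent artifact
shapes, bout-structure autocorrelation beyond minimum spacing, spike
waveforms (rates are generated directly), and any video-derived
kinematics. Passing the validation suite therefore demonstrates the
algorithms recover the structure they assume, not that real recordings
satisfy those assumptions.

## Validation suite and problem sizes

`photolock.validation` regenerates data and measures recovery; the same
functions back `tests/test_acceptance.py` and
`scripts/acceptance.py`. Problem sizes were chosen so the whole suite
runs in about a minute on one core: 100 series of 10⁴ samples for the
exact running-minimum cross-check; 300 s at 50 Hz with 20%-of-baseline
artifacts for isosbestic rejection; 50 transients with 5–8 SD peaks in
600 s of unit noise at 20 Hz for detection (sensitivity, false
positives, AUC against the integration oracle); 10⁶ samples for the
Gaussian tail calibration; 40 injected + 16 control events for
peri-event recovery; 20 recordings per arm for the condition contrast;
1000 repeats for the signed-rank type-I rate.

Two validation statistics are medians by design. The AUC recovery error
is a median over transients (robust to the occasional excursion that
merges with a neighbor). The noiseless width check is a median because
an exactly-noise-free z floor is a near-flat residual whose sign is
constant over long stretches — an isolated base can extend through such
a flat gap, and under any nonzero noise bases instead extend through
random positive noise runs; typical-case agreement (0–1 samples across
seeds) is the meaningful fidelity statement.

## Numerical choices and degenerate inputs

- Half-open time intervals [start, stop); sample i at t₀ + i/rate.
- Z-scoring uses the population SD (ddof = 0); mean 0, SD 1 holds to
  1e-9 over the normalization window.
- OLS via the closed-form normal equations; a constant control channel
  raises a degenerate-fit error; non-positive dF/F denominators raise a
  domain error naming the first offending index.
- Loess anchors every `span/10` points with linear interpolation
  between (exact for locally linear signals, large speedup).
- The exact signed-rank/Mann-Whitney methods are used up to n = 25,
  normal approximation beyond.
- Determinism: one master seed, substreams spawned per component
  (transients, artifacts, per-channel noise, events); identical config
  and seed reproduce outputs bit-for-bit, and the pipeline writes no
  wall-clock information into any output file.

## Known limitations

- The isosbestic fit is a single global regression; slow gain drift
  between channels within a session is not modeled (no rolling fit).
- Overlapping transients are merged rather than deconvolved; AUC of
  closely spaced events is attributed to the merged interval.
- The envelope needs a transient-free stretch within every window; an
  unbroken plateau of activity longer than `minima_window_s` would be
  partially absorbed into the baseline.
- Behavioral exclusion uses the within-group SD band; with very small
  groups (< 3 subjects) the rule is skipped and logged rather than
  estimated from an unstable SD.
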