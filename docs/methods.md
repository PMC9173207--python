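# Methods

## Task and behavior model

The task generator emulates a self-paced, color-cued rule-switching
game.  Rule runs (consecutive same-rule trials) are i.i.d. draws from a
probability mass function over lengths 1..10; the default is the
empirical distribution of the deployed game (6.4, 10.6, 13.5, 14.8,
14.3, 12.6, 10.0, 7.3, 4.8, 5.7 %), giving a mean run length of 5.03
trials and a long-run switch rate of ~0.20.  The run process restarts
at each session boundary, and the first trial of a session is neither a
switch nor preceded by an error.  Stimulus congruency is i.i.d.
Bernoulli with default rate 0.47, matching the observed base rate
(~104 incongruent of ~221 trials).

Response time (ms) follows a linear mixed model

    RT = β₀ + β·x + b_patient + ε,   b ~ N(0, σ_b²), ε ~ N(0, σ_ε²)

with x = (switch, moving rule, incongruent, prior error, log₁₀ trial,
session) and default coefficients (+161, +176, +92, +151, +13, −29),
σ_b = 150 ms, σ_ε = 400 ms.  RTs are floored at 300 ms (Gaussian
residuals would otherwise produce non-physical values; the floor
affects < 1 % of draws).  The intercept is calibrated analytically so
the marginal mean RT is 1.36 s, using the expected predictor values
under the task model; with five 60-s sessions this yields ≈ 221
completed trials per patient.  Because responses pace the task, each
session keeps only trials that complete within its duration; the final
partial trial is dropped.

Correctness is drawn from a logistic model in the four binary trial
features.  Each coefficient is the logit difference between the two
marginal accuracy rates of its contrast (e.g. switch 72.3 % vs repeat
78.0 %), and the intercept is solved by exact enumeration over the
independent predictor distribution so the marginal accuracy is 77.6 %.
This reproduces the marginal contingencies; it does not model
higher-order interactions, which the reference data do not constrain.
The prior-error flag is recomputed sequentially from the drawn
outcomes, so post-error effects are internally consistent.

For parameter-recovery experiments the generator can also emit
fixed-size sessions (e.g. 5 × 44 trials) without the time cap: the cap
preferentially drops slow trials at session end and attenuates fitted
session effects by a few percent, which is a property of the paced
design rather than of the estimator under study.

## Signal model

Each channel is 1/f-amplitude Gaussian noise (default 15 µV RMS,
spectral exponent 1), independent across channels.  Event-locked
high-gamma bursts are narrowband sinusoids (center frequency within
70–110 Hz) with a smoothed-boxcar envelope: a boxcar over
[onset, onset + duration] post-cue convolved with a 25-ms-σ Gaussian.
A pure Gaussian envelope would make the injected window's onset
ill-defined for recovery checks; the smoothed boxcar keeps edges
gradual while the envelope equals half its peak exactly at the nominal
onset and offset.  Burst amplitude is scaled per trial by trial-type
multipliers (e.g. 1.5× on switch trials) and by multiplicative practice
trends in log₁₀ trial and session.  Default amplitudes (0.3–0.5 µV)
were set against the measured high-gamma noise floor of the background
process (~0.16 µV at 90 Hz for 15 µV RMS), producing vs-rest responses
of a few hundred percent at burst sites — the scale seen at strongly
responsive iEEG electrodes.

Interictal-spike artifacts are Gaussian-envelope transients of
lowpassed noise (default 80 µV, 50 ms, 6th-order Butterworth at 45 Hz,
Poisson rate 0.1 Hz per channel).  The lowpass matters: real
interictal discharges carry most energy below the high-gamma band, and
the artifact-rejection rule (below) can only mask 30–85 Hz bins, so a
spectrally realistic artifact is one the rule can actually catch.

The generator does **not** emulate volume conduction or a forward
model, correlated noise across neighboring contacts, line noise,
non-stationary background spectra, eye/muscle artifacts, or realistic
spike morphology.  Passing tests therefore demonstrate that the
analysis machinery recovers known effects under idealized but
statistically honest conditions (overlapping epochs, artifact
contamination, trial-feature correlations); they do not certify
performance on clinical recordings.

## Preprocessing

Channels excluded for seizure-onset zone, lesion, or artifact are
omitted from the common average and dropped.  CAR subtracts the mean of
included channels at every sample (idempotent; requires ≥ 2 included
channels).  Gameplay epochs span 2400 ms centered on each cue onset;
with a ~1.36-s inter-response interval, neighboring epochs overlap by
design.  Epochs are dropped (and counted) if their window leaves the
recording or crosses a session boundary — zero-padding would bias
wavelet amplitudes.  Reference epochs of the same length are sampled
from a per-patient rest recording, one per retained trial,
non-overlapping whenever the rest duration allows (uniform-spacing
construction), with overlap permitted and logged otherwise.

## Time–frequency analysis

Complex Morlet wavelets with 7 cycles at 5-Hz centers from 30 to
110 Hz; the modulus of the convolution is the band amplitude
(proportional to the square root of band power), sampled every 10 ms.
An alternative reading of the source method — spectral bandwidth f/7
rather than 7-cycle wavelets — was considered and not adopted.
Wavelets are discretely L2-normalized (unit energy), so white noise
yields flat mean amplitude across frequency bins and amplitudes are
comparable across frequencies.  With 2400-sample epochs the 10-ms grid
gives 240 bins at −1200..+1190 ms.  Bins within half the wavelet
support of an epoch edge are masked per frequency rather than
zero-padded.

Artifact rejection: per channel and frequency in 30–85 Hz, bins whose
amplitude z-score — computed across all time bins and epochs of that
patient — exceeds |2| are masked.  The mask applies to the offending
frequency rows only; the high-gamma (70–110 Hz) average at that time
bin is computed from surviving rows.  If the artifact band is
configured to cover the whole analysis range with a degenerate
threshold, everything is masked and the baseline computation raises.

Percent change per time bin is 100·(HGA − baseline)/baseline with the
baseline either (a) the scalar mean over all reference epochs, high-
gamma bins and times of that channel (vs-rest mode, used for the
overall response) or (b) the channel's gameplay-period mean (used for
trial-type contrasts, whose series average to zero over the gameplay
window by construction).  ROI series are unweighted means across
included channels per ROI, with channel counts reported.

## Statistics

*Permutation tests.*  One-sample: per 10-ms bin, a t statistic across
units (electrode sites within an ROI, each contributing its
trial-averaged vs-rest series — chosen as the unit of observation
because across-site mean ± CI is also the display convention); the null
flips each unit's sign as a whole, preserving temporal correlation.
Two-sample: pooled-variance t on per-trial ROI series between trial
types; the null shuffles trial labels.  Both default to 1000
permutations, two-sided α = 0.05, p = (b+1)/(m+1) including the
identity permutation (p is never 0), and Benjamini–Hochberg FDR across
the computed bins (the corrected bin count is configurable).
Statistics are NaN-aware: bins with fewer than two finite values per
group get t = 0 and p = 1, so fully masked edge bins can never appear
significant.  Significant windows are maximal runs of FDR-significant
bins; the reported peak is the maximum absolute effect within
significant bins, hence always inside a window.

*Mixed models.*  Random-intercept-per-patient linear mixed models
(statsmodels `MixedLM`, REML, L-BFGS then BFGS) for response time and
for trial-wise ROI high-gamma amplitude (summarized per trial as the
mean percent change over the 0–1200 ms post-cue window).  Trials with
missing congruency are dropped.  Wald t statistics are reported with
residual degrees of freedom (n − p); Satterthwaite/Kenward–Roger
corrections are delegated to the backend and not replicated.  A
singular fit (random-intercept variance at zero or non-finite standard
errors) falls back to OLS with a logged warning.  ROI-level p-values
are BH-FDR corrected across ROIs per predictor.

*Specificity.*  An ROI's high-gamma modulation is "trial-type
specific" for a contrast iff the permutation test yields a significant
window **and** the contrast's mixed-model predictor survives the
across-ROI FDR at 0.05.  The conjunction matters in practice: because
epochs overlap, short-RT trials catch more of the next trial's response
in their post-cue window, which can make RT-correlated predictors
(e.g. congruency) spuriously significant in the mixed model alone.

*Contingencies.*  Accuracy contrasts use Pearson chi-square on the 2×2
table, one df, no continuity correction — the convention that
reproduces the reference statistics (5.0, 119.4, 134.5, 121.6) from
their printed counts.

## Prediction

Among switch trials (configurable), an unpenalized logistic regression
predicts correctness from the trial's ROI high-gamma percent change
(summarized over the ROI's significant post-cue window, default
330–780 ms for the precuneus), task rule, congruency, and session.
Prior-error and trial-number predictors are excluded to avoid
circularity with post-error and practice effects.  Discrimination uses
5-fold stratified cross-validation (seeded; refolded with a new seed if
a training fold's outcome is constant): every trial is scored exactly
once out-of-fold, pooled scores give the ROC and AUC, and the AUC CI is
a stratified bootstrap (2000 resamples) of the pooled scores.
Coefficients and Wald CIs come from a full-data fit; odds ratios are
exponentiated coefficients.

## Problem sizes and reproducibility

All randomness flows from explicit seeds (NumPy `SeedSequence`
streams, one per patient and stage).  The test suite exercises the
full chain on a 3-patient, 2-ROI, 7-channel cohort (five 60-s sessions
per patient, ~640 trials total) for the injected-window recovery
check; permutation-validity checks use 100 simulated null datasets;
mixed-model and logistic recovery use 9 × ~220 trials and 1209 trials
respectively, matching the reference cohort's scale.
`scripts/acceptance.py` reports means over 30 (mixed-model) and 8
(logistic) simulation replicates to separate estimator behavior from
single-draw noise.

## File formats

Continuous signals are written as FIF (MNE's native format); events
and electrode tables as TSV in a BIDS-iEEG-flavored per-patient layout;
the generator configuration as YAML; reports as TSV/JSON plus a PNG
figure; each run emits a manifest (config snapshot, seeds, stage
counts, output hashes).

## Known limitations

- The signal model is phenomenological; no biophysics, no volume
  conduction, no spatial correlation structure.
- Amplitude effects enter multiplicatively on burst amplitude, but the
  measured percent change is nonlinear in burst-to-floor ratio, so
  configured multipliers do not translate 1:1 into percent-change
  differences.
- Mixed-model inference uses Wald statistics with residual df; exact
  small-sample df corrections are out of scope.
- The one-sample permutation treats electrode sites as exchangeable
  units; treating patients or trials as units would change the test's
  granularity and is not implemented.
- Overlapping epochs couple neighboring trials; this is inherent to
  the paced paradigm and is deliberately not "corrected".
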