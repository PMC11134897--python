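# Methods

`hrvreact` implements a heart-rate-variability (HRV) reactivity analysis for
early cardiotoxicity screening in patients starting cardiotoxic chemotherapy.
The clinical idea: beat-to-beat RR-interval series are recorded under three
physiological conditions — supine rest, active standing (orthostatic
challenge), and 0.1 Hz paced ("rhythmic") breathing — and the per-subject
change Δ of each HRV index between supine rest and each maneuver quantifies
autonomic reactivity.  Blunted reactivity before chemotherapy is evaluated as
a predictor of cardiotoxicity at a three-month follow-up, where
cardiotoxicity is defined from echocardiographic strain/ejection-fraction
criteria and troponin conversion.

## HRV indexes

All indexes are computed on a standardized **NN segment**: exactly L = 300
consecutive normal-to-normal (sinus-origin) intervals, covering roughly five
minutes at typical heart rates.

**Time domain.** mean NN (ms), mean HR = 60000 / mean NN (bpm), SDNN (sample
standard deviation of NN, N−1 denominator), pNN50 (% of successive
differences strictly greater than 50 ms).

**Frequency domain.** The tachogram (each NN value located at its closing
beat time) is linearly interpolated and resampled at 3 Hz; a one-sided Welch
periodogram (Hann window of 256 samples ≈ 85 s, 50% overlap, per-window
constant detrend, density scaling) estimates the PSD, whose integral over
frequency approximates the detrended sample variance.  Band powers are
trapezoidal integrals over LF = [0.04, 0.15) Hz and HF = [0.15, 0.4] Hz (the
0.15 Hz boundary belongs to HF).  Normalised units are
lf_nu = 100·LF/(LF+HF) by default (an alternative total-power denominator is
available), and log10(LF/HF) is emitted rather than the raw ratio.
Undefined ratios (zero denominators) are flagged as NaN, never ±inf.

**Poincaré.** With lag-1 pairs (NN_n, NN_{n+1}) rotated 45°,
SD1 = sample SD of (NN_{n+1} − NN_n)/√2 (dispersion perpendicular to the
identity line, short-term/vagal) and SD2 = sample SD of
(NN_{n+1} + NN_n)/√2 (along the identity line, long-term).  This rotation
*is* the ellipse-axis computation for axes fixed on the identity line; no
least-squares ellipse regression is performed.  Both SD2/SD1 and SD1/SD2 are
reported because both conventions circulate in the field.

## Preprocessing

Cleaning relabels intervals without correcting them (exclusion, not
interpolation): an interval is non-normal if (a) annotated ectopic/artifact
upstream, (b) it deviates by more than 20% from the running median of the
previous 11 normal intervals, or (c) it lies outside a physiological window
of 300–2000 ms.  The median buffer only ever receives accepted normals,
which makes cleaning idempotent.  Automated filtering stands in for visual
artifact editing; thresholds are configurable and exclusion counts are
reported per recording.

Segment selection takes, among all runs of 300 consecutive NN intervals
whose first interval starts at or after 180 s (discarding the transient
after a posture change), the run with minimal SDNN — "stable" operationalised
as minimum-variability — breaking ties toward the earliest window.
Contiguity is in the NN sequence, so excluded beats do not interrupt a run.

## Reactivity deltas and ROC analysis

Δ(index, maneuver) = value(maneuver) − value(supine).  With this sign an
index that rises during a maneuver gives a positive Δ, and blunted
reactivity appears as a smaller Δ; cut-offs therefore naturally print as
"≤ c" bounds.  The opposite convention is available as a configuration
switch.  A missing maneuver flags that maneuver's deltas NaN (pairwise, not
listwise, exclusion downstream).

The ROC curve sweeps every distinct score as a threshold with equal scores
grouped into a single step (diagonal tie segments); AUC is the trapezoidal
area, equal to tie-corrected pair counting.  The orientation (≥ or ≤) with
AUC ≥ 0.5 is retained and reported.  The optimal cut-off minimises the
Euclidean distance √((1−sens)² + (1−spec)²) from a curve point to the ideal
corner (0, 1), earliest threshold on ties.  Inference uses the Hanley–McNeil
standard error with a two-sided normal test of AUC = 0.5 (at AUC = 0.5 the
formula coincides with the null Mann–Whitney SD, so the test is calibrated
near the null); DeLong's covariance-based SE would be a drop-in replacement
but is not needed for single-curve inference here.  Perfect separation
collapses the SE to zero and is flagged as a boundary case.

## Cohort statistics

Continuous variables pass a normality gate — one-sample Kolmogorov–Smirnov
against a normal with estimated mean/SD; p < 0.05 triggers a log10
transform.  Using estimated parameters without the Lilliefors correction
makes the gate conservative (it under-rejects true normals); this mirrors
common practice in clinical toolchains and is kept deliberately.  A
triggered transform on non-positive data raises instead of silently
offsetting.  Comparisons use Student's t (pooled variance unpaired,
difference scores paired) and a one-way repeated-measures ANOVA from the
subject-blocked sum-of-squares decomposition with (k−1, (k−1)(n−1)) df and
no sphericity correction (documented limitation).  Categorical tables use
chi-squared without continuity correction when all expected counts are ≥ 5,
otherwise Fisher's exact test.  Pearson correlations are reported with
unadjusted p-values; no multiplicity correction is applied anywhere, and
output tables record how many tests were run implicitly through their shape.

Clinical rules: a significant LASr (left-atrial reservoir strain) reduction
is a follow-up value below the 35% normal threshold or a >10% relative
reduction; a baseline already below 35% requires the relative-reduction
branch.  The echocardiographic cardiotoxicity criterion defaults to
(follow-up LVEF3D < 53% with an absolute drop ≥ 10 points) OR (>10% relative
reduction of |GLS|, magnitude shrinking toward zero = function loss); the
troponin criterion is new follow-up positivity.  These thresholds are
explicit, configurable stand-ins for guideline-based criteria, not claims
about any particular study's settings.

## Synthetic cohort generator

Real recordings of this kind are not publicly deposited, so the package
ships a first-class generator that emulates the protocol's data structure.
The beat process is a modulated point process: the instantaneous interval

    m(t) = RR0·[1 + a_lf·sin(2π·0.1·t + φ) + a_hf·sin(2π·f_resp·t + ψ)] + ε

is evaluated at the current beat time and beats are emitted at cumulative
interval sums (interval-by-interval evaluation rather than full IPFM
integration — simpler, and adequate for band-power structure).  Defaults,
chosen once as the study conditions: 50 subjects, 46% in the cardiotoxicity
arm, 600 s per condition, RR0 = 850 ms (between-subject SD 60 ms),
a_lf = a_hf = 0.03 with lognormal per-subject multipliers (σ = 0.2),
spontaneous breathing at 0.25 Hz, white jitter SD 10 ms, per-beat ectopic
probability 0.003.  These place supine SDNN at ≈ 25–35 ms, inside the
physiological 20–60 ms range; the values are packaged conventions, not
estimates from any dataset.

Condition effects: standing shortens RR0 by 15% and scales a_lf ×1.5 /
a_hf ×0.5 (sympathetic shift); paced breathing moves the respiratory
component to 0.1 Hz, scales it ×2.0 and a_lf ×1.3, and phase-locks the two
components — paced breathing entrains the 0.1 Hz baroreflex oscillation, and
without that lock the two same-frequency components cancel at random phase
offsets, which would produce an implausibly variable breathing response.
Follow-up recordings shorten RR0 by 4% in every condition (the post-therapy
resting-HR shift).  In the cardiotoxicity arm all condition-induced
parameter changes are multiplied by λ (``lambda_reactivity``, default 0.3);
λ = 1 reproduces the control law exactly, which provides the null design
point.

Ectopics replace a beat by an early beat at 0.7× the local interval followed
by a compensatory pause that preserves the local beat-time sum; both
intervals are annotated.  The short–long signature deliberately inflates
SD1, so the effect of the cleaning stage is testable.

Echo panels are drawn per variable from normals at literature-scale means/SDs
(e.g. LVEF3D 63.5 ± 6.7%, GLS −23.9 ± 3.3%); follow-up values are baseline
plus a per-variable drift rather than an independent redraw — independent
draws at these SDs would yield ~30% spurious >10% GLS "reductions" in
controls.  No cross-variable covariance is modelled.  Cardiotoxicity-arm
subjects receive a criterion-sized LVEF/GLS shift with probability 0.8 and
troponin conversion with probability 0.7 (controls 0.02), which makes the
classification rules recover the generator's arm with sensitivity and
specificity above 0.9.

Randomness is counter-based: every (subject, timepoint, condition) recording
and every subject's parameter/clinical draw derives its own `SeedSequence`
substream from the master seed, so subject k is bit-identical regardless of
cohort size or of which conditions are generated, and all outputs are
reproducible under a fixed seed.

### What the generator does *not* emulate

Real tachograms are nonstationary (drifts, arousal, movement artifacts of
varying morphology), RR distributions are skewed, spectral peaks are broad
rather than line-like, echo variables are correlated, and visual artifact
editing is judgement-based.  Passing tests on synthetic cohorts therefore
demonstrate that the estimators, rules and inference machinery are correct
and calibrated under the stated generative model — not that the clinical
effect sizes or the published cut-offs generalise.

## Numerical choices and problem sizes

Sample SDs (N−1) everywhere; Poincaré coordinates are shifted by their first
element before the SD so constant series give exactly zero; band integrals
interpolate the PSD at band edges; ROC tie groups collapse to single curve
points; degenerate statistics (zero variance, single-class labels, empty
margins) raise typed errors or return flagged NaN, never silent infinities.
The verification suite uses 1000 random segments for estimator–oracle
equivalence, 200 random instances for ROC exactness, 2000–10000 null
replicates for calibration rates, and 200 replicate cohorts per arm of the
recovery study; the acceptance script uses 100 replicate cohorts per arm and
2000-replicate calibrations, sizes at which the Monte-Carlo error is well
below the decision margins being checked.

## Known limitations

* The repeated-measures ANOVA applies no sphericity correction.
* The normality gate inherits the estimated-parameter KS conservatism.
* Hanley–McNeil inference is asymptotic; very small samples or AUCs near the
  boundary produce degenerate (flagged) intervals.
* The generator's spectral content is two line components plus white jitter;
  broadband autonomic dynamics (1/f structure) are not modelled.
* Echo variables are drawn independently; multivariate strain structure is
  out of scope.
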