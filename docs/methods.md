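# Methods notes

This note records the modelling assumptions, numerical choices and open
design decisions behind `formscan`, and what validation on synthetic
data does and does not establish.

## The synthetic cohort generator (`formscan.synth`)

The generator's job is to reproduce the *statistical structure* of the
study design with a known ground truth, not the biophysics of MEG.

Per run it lays out `trials_per_run` triggers (default 300) in a
pseudo-randomised, exactly balanced condition sequence (lines/rhomboids
× nasal/temporal, 25% ± 1 trial each), 200 ms stimuli separated by a
uniform 600–800 ms inter-stimulus interval.  Events record *trigger*
time; the stimulus appears 17 ms later (projector delay), and the
pipeline must correct for this exactly as with real data.

Two evoked components are injected at the true stimulus onset:

* **Initial component**: cosine-phase Gabor, 35 Hz carrier, Gaussian
  envelope SD 6 ms, peaking at the subject's initial latency
  (population N(40, 6²) ms between subjects).  The high carrier makes
  it survive the 13–60 Hz filter while the 0.5–30 Hz filter largely
  removes it — the generator's realisation of the dual-filter logic.
  Its amplitude is form-dependent (line gain 1.0, rhomboid 0.7).
* **Main component (P100m analogue)**: cosine-phase Gabor, 10 Hz
  carrier, envelope SD 50 ms, peaking at the subject's main latency
  (N(100, 8²) ms), form-independent.  Component support is clamped to
  start no earlier than the stimulus itself.

Both components are projected through per-subject, unit-norm random
hemispheric topographies with a contralateral:ipsilateral source
drive of 3:1 (nasal/left-field stimuli drive the right hemisphere).
A per-subject lognormal amplitude factor (SD 0.5 log-units) produces
the realistic situation that weak-response subjects fail the initial
detection criterion while the P100m remains clear in everyone.

Background activity is stationary narrow-band Gaussian noise (alpha
8–12 Hz at 150 fT/channel, theta 4–8 Hz at 60 fT) plus 1/f noise
(150 fT).  Being stationary, it is incoherent with the jittered
stimulus train, so trial averaging reduces it as 1/sqrt(N) — the reason
the design jitters the ISI.  Blinks are Poisson events (4/min): a
400 ms half-sine of 1500 fT on the EOG channel with 2% random leakage
into MEG channels.

**Amplitude calibration.**  Units are nominal femtotesla but only the
ratios matter.  The defaults were chosen so that, after averaging a few
hundred trials: (i) the main response dominates the 0.5–30 Hz band by a
wide margin in every subject; (ii) the tight-band *remnant* of the main
wave inside the 15–70 ms search window stays below the 2-SD detection
threshold (a zero-phase 13–60 Hz filter inevitably smears some main-
response energy backwards — real analyses see the same artifact just
before the P100m and counter it with a forward-filter check, which this
package also implements); and (iii) the initial burst
sits 2–3× above threshold for a typical subject, so the weakest
subjects miss the criterion.  A physically faithful P100m would be
~10× larger than the initial component; pushing the ratio that far
makes its tight-band remnant swamp the initial burst at desk scale, so
the generator trades that ratio (≈ 2:1 here) for clean separability.
This is the generator's main departure from real data, and it means
passing recovery tests demonstrate correctness of the *analysis*, not
detectability of real 40 ms components at any given SNR.

What the generator does not emulate: realistic sensor geometry or lead
fields (random seeded topographies instead), eye movements other than
blinks, head movement, heartbeat artifacts, and non-stationary
background rhythms.

## Preprocessing

* Filters are 4th-order Butterworth bandpasses; `zero_phase` applies
  the design forwards and backwards (`sosfiltfilt`), `forward_only` a
  single causal pass.  The band edges (0.5–30, 13–60 Hz) are the
  analysis constants; the order/design is this package's choice.
* Filtering is applied to the continuous record *before* epoching, so
  epoch edges carry no filter transients; a test verifies the two
  orders agree on interior samples.
* Trigger-delay correction shifts onsets by `round(delay·fs/1000)`
  samples, nearest-sample, ties away from zero (17 ms at 1200 Hz →
  20 samples).
* Epochs are half-open [−500, 500) ms, 1200 samples at 1200 Hz, with
  t = 0 exactly on the corrected onset sample; the baseline is
  [−200, 0) ms.
* Blink rejection thresholds the raw-EOG peak-to-peak per epoch
  (default 100 fT-equivalent); the mask is computed on the *unfiltered*
  recording (a tight bandpass would remove the blink itself) and
  applied to the filtered epochs.  A manual mask stands in for the
  eye-tracker/visual inspection of the original workflow.

## Sensor statistics

* The absolute amplitude is max−min across a named occipital sensor set
  per bin; baseline mean/SD for the detection threshold are computed on
  the same filtered time-course over the [−200, 0) ms bins (ddof = 1).
* Peak-search windows (15–70, 70–160 ms) are *inclusive* of both
  sample-aligned endpoints, reproducing the printed 67-bin count for
  15–70 ms at 1200 Hz.
* Detection requires ≥ 4 consecutive supra-threshold bins.  When
  several disjoint runs qualify, the run containing the global
  in-window maximum is reported; if the global maximum sits in a
  too-short run, the qualifying run with the largest amplitude is used
  (a tie-break this package defines; the criterion itself is silent).
* Consecutive-bin t-tests are *paired* across subjects (the design is
  within-subject).  Null calibration (67 bins, n = 20, 1000 datasets)
  shows the family-wise error of the ≥4-bin rule is far below 0.05 and
  below the Bonferroni-corrected single-bin test, under independent
  noise; with strongly autocorrelated bins the rule is less
  conservative than this calibration suggests.
* The repeated-measures ANOVA (complete cases, statsmodels `AnovaRM`)
  yields F with df (1, n−1); the univariate variant (`ols` +
  `anova_lm`, type II) treats each accepted measurement as independent
  — an approximation forced by detection-pruned cells, at the cost of
  ignoring the within-subject correlation.  Post-hoc line-vs-rhomboid
  t-tests per quadrant are paired (RM) or pooled-variance independent
  (univariate) and reported uncorrected.
* The group-detection argument uses the exact binomial upper tail
  P(X ≥ k | n, p) by direct summation.  For k = 10, n = 20, p = 0.05
  this gives 1.13 × 10⁻⁸ (the package returns the exact sum).
* The P100m-amplitude vs initial-detection association is the
  point-biserial correlation, undefined (and reported as such) when all
  flags agree.

## The two-node DCM

The package substitutes a transparent damped second-order state space
for a full neural-mass ERP model; the architecture gating (which
connections and inputs exist per model 1–6) carries the scientific
content of the model comparison.

    ḧ_i = κ_i² ( Σ_j a_ij h_j(t−δ) − Σ_j b_ij h_j(t−δ_b) + c_i u(t) − h_i ) − 2 κ_i ḣ_i

with κ_i = 1/τ_i, u(t) a Gaussian bump (SD 4 ms) peaking at t_on =
20 ms ("input timing" is taken as the bump *peak*), forward delay δ =
4 ms, feedback delay δ_b = 8 ms.

**Feedback identifiability.**  On two nodes, purely linear coupling of
identical temporal character would make "forward both ways" (model 3)
and "forward + feedback both ways" (model 6) the same structure up to
reparametrisation.  Feedback connections are therefore given a
distinct kernel: negative sign (net suppressive, consistent with the
modulatory character of cortical feedback) and the slower delay δ_b.
Models 4–6 are then structurally distinct from 1–3 and model recovery
is well-posed; this asymmetry is a modelling choice, not an estimated
quantity.

**Inversion.**  Free parameters are the active couplings/inputs plus
both time constants, estimated in log-space with log-normal shrinkage
priors (means: a = b = 0.5, c = 1, τ = 8 ms; SD 0.5 log-units), by
damped Gauss–Newton on the variational-Laplace objective

    F = log p(y|θ̂) − ½(θ̂−μ₀)ᵀΣ₀⁻¹(θ̂−μ₀) + ½log|Σ_θ| − ½log|Σ₀|

with forward-difference state Jacobians, observation-noise precision
profiled at its ML value each iteration, step-halving on non-increase,
a 64-iteration budget and convergence at ΔF < 0.01.  Integration is
fixed-step RK4 at the data rate with linear interpolation of the
delayed states (delays exceed one sample).  The residual algebra is
carried in the rank-2 gain subspace, so cost is independent of channel
count.  Inversion is deterministic; "non-convergence" returns the best
F found, flagged.

**Gain vectors.**  Lead fields are out of scope.  `invert_dcm` takes an
explicit channels × 2 gain matrix: model-recovery studies pass the
generating gains; the end-to-end pipeline, which has no lead field for
its synthetic sources, uses the two leading left singular vectors of
the analysis window (`estimate_gains_svd`).  The SVD basis mixes the
true source patterns arbitrarily, which blurs architectural
distinctions; on such data the most flexible architecture (model 6)
tends to win, so the pipeline's own BMS table is a demonstration of
mechanics, while the controlled model-recovery study (data generated
from a known architecture, gains known) is the validation that the
evidence machinery discriminates architectures.

**Fixed-effects BMS** sums free energies over subjects and quadrants
per form — exact additivity is asserted in tests — and reports each
model relative to the worst (worst = 0).

## Problem sizes

Full-size runs (20 subjects × 6 runs × 300 trials ≈ 36 000 epochs,
~12 GB of continuous data) are unnecessary for validating the code
paths, so the test suite and acceptance script use reduced cohorts with
the trial *structure* unchanged: 20 subjects × 2 runs × 150 trials for
parameter recovery, 12 × 2 × 120 for the end-to-end acceptance run,
10 × 1 × 100 for the null-laterality check, 1000 null datasets for rule
calibration, and 20 replicate mini-cohorts (3 subjects × 2 quadrants ×
2 forms) for DCM model recovery.  Generator defaults remain the full
study design.  At the reduced trial counts the averaged-noise floor is
≈ 1.7× higher than at full size, which raises the detection threshold
and slightly lowers initial-response detection rates; latency recovery
accuracy is unaffected.

## Known limitations

* The initial:main amplitude ratio is compressed relative to real data
  (see calibration note above).
* Univariate ANOVA on detection-pruned cells ignores within-subject
  correlation; its interaction test can disagree with both post-hoc
  tests.
* The consecutive-bin rule's conservatism is only established under
  independent bin noise.
* The DCM is a signal-level abstraction: no synaptic physiology, no
  dipole geometry, two nodes only; free energies are comparable within
  this model family, not against SPM's.
* Model pairs remain practically hard to separate at low SNR when the
  feedback contribution is small; recovery is validated at effect sizes
  where the feedback kernel visibly shapes the waveform.
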