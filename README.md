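# formscan

Sensor-level MEG analysis of visual evoked fields elicited by simple and
complex forms, asking whether form complexity is mirrored by response
latency.  The pipeline separates two sequential event-related field
(ERF) components — a weak *initial response* ~40 ms after stimulus onset
and the *main response* (P100m) ~100 ms — compares their amplitudes and
latencies between stimulus forms (single lines vs rhomboids built from
the same lines) and visual hemifields (nasal vs temporal lower
quadrants), and asks, via dynamic causal modelling (DCM), whether the
earliest cortical response is better explained by sequential or
parallel input to striate (V1) and prestriate (V2/V3) cortex.

It is written for electrophysiologists who want a fully testable,
self-contained implementation of this analysis: because raw MEG of this
kind is rarely shareable, the package ships a synthetic-cohort
generator that reproduces the study design (1200 Hz sampling, occipital
MLO/MRO/MZO sensor groups, 4 conditions, 200 ms stimuli with 600–800 ms
jittered ISI, 300 trials/run, 17 ms trigger–projector delay, blink
artifacts, alpha/theta/1-f background) with a known ground truth, so
every stage can be validated by parameter recovery.

## Methods at a glance

**Dual-filter decomposition.**  Continuous data are bandpassed either
0.5–30 Hz (standard; isolates the P100m) or 13–60 Hz (tight; suppresses
the alpha/theta band and exposes the high-frequency initial component),
epoched −500…+500 ms around the delay-corrected stimulus onset and
baseline-corrected on −200…0 ms.

**Absolute amplitude.**  For a sensor set S and time bin t,

    A(t) = max_{c in S} B_c(t) − min_{c in S} B_c(t)        [fT]

**Sustained supra-threshold detection.**  A component is accepted only
if A(t) > mean + 2·SD of the baseline bins for ≥ 4 consecutive bins
(≥ 3.3 ms at 1200 Hz); its latency is the in-window argmax within the
qualifying run (search windows 15–70 ms and 70–160 ms; the 15–70 ms
window holds 67 bins of 0.833 ms).

**Consecutive-bin testing.**  Between-condition amplitude differences
use a paired t-test per bin at α = 0.05, accepting only runs of ≥ 4
consecutive significant bins of consistent sign — empirically more
conservative than Bonferroni under independent noise.

**Latency ANOVA.**  Quadrant × form two-way ANOVA: repeated-measures for
the main response (every subject contributes all cells), univariate for
the initial response (detection prunes cells unevenly).

**DCM.**  Six two-node architectures (sequential, anti-sequential,
multi-input; each with or without feedback) with damped second-order
node dynamics

    ḧ_i = κ_i² ( Σ_j a_ij h_j(t−δ) − Σ_j b_ij h_j(t−δ_b) + c_i u(t) − h_i ) − 2 κ_i ḣ_i

driven by a Gaussian input bump peaking 20 ms post-onset, fitted on the
0–52 ms sensor window by variational-Laplace free-energy maximisation,
with fixed-effects Bayesian model selection pooling log-evidence over
subjects and quadrants per form.

## Worked example

```python
from formscan.io_core import PipelineConfig, GeneratorParams
from formscan.report import run_pipeline

cfg = PipelineConfig()                       # the study's constants
cfg.generator = GeneratorParams(n_subjects=6, n_runs=1, trials_per_run=120)
rep = run_pipeline(cfg, seed=7, run_dcm=False)
print(rep.detection_table.to_string(index=False))
```

prints

```
response     form quadrant  n  n_subjects  latency_mean_ms  latency_sd_ms  binomial_tail_p
 initial     line    nasal  6           6             42.6            5.3     1.562500e-08
 initial     line temporal  6           6             42.6            5.3     1.562500e-08
 initial rhomboid    nasal  6           6             46.5            6.2     1.562500e-08
 initial rhomboid temporal  6           6             44.7            8.0     1.562500e-08
    main     line    nasal  6           6            100.8            9.9              NaN
    main     line temporal  6           6            101.0            7.1              NaN
    main rhomboid    nasal  6           6            100.4            8.9              NaN
    main rhomboid temporal  6           6            104.4           11.1              NaN
```

Initial and main latencies recover the generator's injected 40 ms and
100 ms components (per-subject latencies vary: SD 6 and 8 ms between
subjects); `n` counts subjects meeting the sustained supra-threshold
criterion, and `binomial_tail_p` is the exact binomial probability of
that many detections arising by chance at P = 0.05 per subject.  The
laterality table of the same report shows the contralateral-minus-
ipsilateral amplitude contrast (positive, p < 0.01 at the generator's
3:1 source laterality), and `rep.amp_windows` lists the consecutive-bin
windows where lines elicit stronger initial responses than rhomboids.

The same pipeline runs from a shell:

```
formscan run --config my.cfg --out results_dir --seed 7
formscan synth cohort --config my.cfg --out data_dir --seed 7
formscan io describe data_dir/sub00_run0.npz
```

Configs are flat `key = value` text files; unset keys take the study's
printed constants (17 ms delay, 13–60 Hz tight band, 15–70 ms window,
min_run 4, α 0.05, DCM window 0–52 ms, input at 20 ms, ...).

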