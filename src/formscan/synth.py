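"""Synthetic MEG cohorts matching the study design.

Each run is a continuous multi-sensor recording: 300 pseudo-randomised
stimulus presentations (lines / rhomboids in the nasal or temporal lower
quadrant, ~25% each), 200 ms stimuli with a 600-800 ms uniformly jittered
interstimulus interval, sampled at 1200 Hz.  Triggers are recorded 17 ms
*before* the true stimulus onset (projector delay), exactly as in the
acquisition the pipeline has to correct for.

Two evoked components are injected at the true onset:

* an *initial* component — a 35 Hz Gabor burst (Gaussian envelope,
  SD 6 ms) peaking ~40 ms after onset, amplitude modulated by form
  (lines > rhomboids) and lateralised 3:1 towards the hemisphere
  contralateral to the stimulated hemifield;
* a *main* component (P100m analogue) — a slow 10 Hz biphasic wave
  peaking ~100 ms after onset, form-independent by default.

Background activity is narrow-band alpha (10 Hz) and theta (6 Hz)
Gaussian noise plus 1/f noise, all stationary and therefore incoherent
with the jittered stimulus train.  Blinks are Poisson events: a 400 ms
half-sine on the EOG channel with small random leakage into MEG sensors.

The high-frequency carrier of the initial burst is what lets the tight
13-60 Hz filter isolate it, while the 0.5-30 Hz standard filter favours
the main wave — the generator realises the dual-filter logic the
analysis depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io_core import (
    CONDITIONS,
    ConditionCode,
    Event,
    GeneratorParams,
    Recording,
    ValidationError,
)

#: hemisphere contralateral to each stimulated quadrant
#: (nasal = lower-left field -> right hemisphere)
CONTRA_HEMI = {"nasal": "right", "temporal": "left"}

_SEGMENT_LEN_DEG = 1.5
_SEGMENT_WIDTH_DEG = 0.1


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry of one stimulus form in degrees of visual angle."""

    form: str
    segments: tuple  # of ((x0, y0), (x1, y1))
    polygons: tuple  # of vertex tuples; empty for the lines form
    quadrant: str = "nasal"


def stimulus_spec(form: str, quadrant: str = "nasal") -> StimulusSpec:
    """Return the 16-segment geometry of a form.

    ``line``: 16 disjoint 1.5 x 0.1 deg segments on a 4 x 4 grid.
    ``rhomboid``: four closed quadrilaterals built from the same 16
    segments (4 edges each, every edge 1.5 deg long).
    """
    if form == "line":
        segments = []
        for r in range(4):
            for c in range(4):
                x = 2.3 + c * 2.5
                y = -1.3 - r * 2.5
                segments.append(((x, y), (x + _SEGMENT_LEN_DEG, y)))
        return StimulusSpec(form, tuple(segments), (), quadrant)
    if form == "rhomboid":
        # rhombus with side 1.5 and acute angle 60 deg
        s = _SEGMENT_LEN_DEG
        dx, dy = s * np.cos(np.pi / 3), s * np.sin(np.pi / 3)
        polygons, segments = [], []
        for r in range(2):
            for c in range(2):
                x0 = 2.8 + c * 4.0
                y0 = -2.0 - r * 4.0
                verts = (
                    (x0, y0),
                    (x0 + s, y0),
                    (x0 + s + dx, y0 - dy),
                    (x0 + dx, y0 - dy),
                )
                polygons.append(verts)
                for i in range(4):
                    segments.append((verts[i], verts[(i + 1) % 4]))
        return StimulusSpec(form, tuple(segments), tuple(polygons), quadrant)
    raise ValidationError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# subject-level ground truth


@dataclass
class SubjectTruth:
    """Per-subject generative parameters recorded for recovery tests."""

    subject_id: int
    initial_latency_ms: float
    main_latency_ms: float
    amp_factor: float
    # topography per component per source hemisphere, over all channels
    topo: dict  # (component, hemi) -> np.ndarray (n_channels,)
    blink_leak_weights: np.ndarray


def _channel_table(params: GeneratorParams) -> list[tuple[str, str]]:
    chans = [(f"MLO{11 + i}", "MLO") for i in range(params.n_left_occ)]
    chans += [(f"MRO{11 + i}", "MRO") for i in range(params.n_right_occ)]
    chans += [(f"MZO{1 + i:02d}", "MZO") for i in range(params.n_midline_occ)]
    chans += [("EOG", "EOG")]
    return chans


def _make_topo(rng, channels, hemi: str) -> np.ndarray:
    """Unit-norm random topography concentrated on one hemisphere."""
    g = np.zeros(len(channels))
    for i, (_, grp) in enumerate(channels):
        if grp == ("MLO" if hemi == "left" else "MRO"):
            g[i] = rng.standard_normal()
        elif grp == "MZO":
            g[i] = 0.3 * rng.standard_normal()
    return g / np.linalg.norm(g)


def draw_subject_truth(params: GeneratorParams, subject_id: int,
                       seed: int) -> SubjectTruth:
    """Draw one subject's latent parameters (deterministic in seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, subject_id]))
    channels = _channel_table(params)
    topo = {}
    for comp in ("initial", "main"):
        for hemi in ("left", "right"):
            topo[(comp, hemi)] = _make_topo(rng, channels, hemi)
    leak = rng.standard_normal(len(channels)) * params.blink_leak
    leak[-1] = 0.0  # EOG gets the full blink, not the leakage
    return SubjectTruth(
        subject_id=subject_id,
        initial_latency_ms=float(
            rng.normal(params.initial_latency_ms, params.initial_latency_sd_ms)
        ),
        main_latency_ms=float(
            rng.normal(params.main_latency_ms, params.main_latency_sd_ms)
        ),
        amp_factor=float(
            np.exp(rng.normal(0.0, params.subject_amp_sd_log))
        ),
        topo=topo,
        blink_leak_weights=leak,
    )


# ---------------------------------------------------------------------------
# waveforms


def _gabor(t_ms: np.ndarray, carrier_hz: float, sd_ms: float) -> np.ndarray:
    """Cosine-phase Gabor: unit peak exactly at t=0."""
    return np.cos(2e-3 * np.pi * carrier_hz * t_ms) * np.exp(
        -(t_ms**2) / (2.0 * sd_ms**2)
    )


def _component_wave(params: GeneratorParams, component: str,
                    latency_ms: float) -> tuple[int, np.ndarray]:
    """Waveform sampled on the trigger-relative sample grid.

    Returns (first sample offset relative to the trigger, waveform).
    The peak sits at trigger + trigger_delay + latency, which is not in
    general sample-aligned; the fractional offset is identical for every
    trial of a subject, so one precomputed array serves the whole run.
    """
    if component == "initial":
        carrier, sd = params.initial_carrier_hz, params.initial_envelope_sd_ms
    else:
        carrier, sd = params.main_carrier_hz, params.main_envelope_sd_ms
    peak_ms = params.trigger_delay_ms + latency_ms
    dt_ms = 1000.0 / params.fs_hz
    half_ms = 4.0 * sd
    # evoked activity never precedes the stimulus itself (trigger + delay)
    k_onset = int(np.ceil(params.trigger_delay_ms / dt_ms))
    k0 = max(int(np.floor((peak_ms - half_ms) / dt_ms)), k_onset)
    k1 = int(np.ceil((peak_ms + half_ms) / dt_ms))
    t = np.arange(k0, k1 + 1) * dt_ms - peak_ms
    return k0, _gabor(t, carrier, sd)


def _pink_noise(rng, n_ch: int, n: int) -> np.ndarray:
    """1/f-power noise, unit SD per channel."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** -0.5
    out = np.fft.irfft(spec, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _narrowband_noise(rng, n_ch: int, n: int, fs: float, low: float,
                      high: float) -> np.ndarray:
    """Band-limited Gaussian noise, unit SD per channel."""
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


# ---------------------------------------------------------------------------
# run / cohort generation


def _event_sequence(params: GeneratorParams, rng) -> list[tuple[int, str]]:
    """Balanced pseudo-random condition sequence with jittered timing.

    Returns (trigger_sample, condition label) per trial.  Conditions are
    exactly balanced up to the remainder of trials_per_run / 4, so every
    count is within +-1 of 25%.
    """
    n = params.trials_per_run
    labels = list(CONDITIONS) * (n // 4)
    extra = rng.permutation(4)[: n % 4]
    labels += [CONDITIONS[i] for i in extra]
    labels = [labels[i] for i in rng.permutation(n)]

    fs = params.fs_hz
    t_ms = params.pad_ms
    out = []
    for lab in labels:
        out.append((int(round(t_ms * fs / 1000.0)), lab))
        isi = rng.uniform(params.isi_low_ms, params.isi_high_ms)
        t_ms += params.stim_duration_ms + isi
    return out


def generate_run(params: GeneratorParams, subject_id: int, run_id: int,
                 seed: int, truth: SubjectTruth | None = None) -> Recording:
    """Generate one continuous run for one subject.

    Fully deterministic in ``(params, subject_id, run_id, seed)``.  The
    subject's latent truth is drawn from ``(seed, subject_id)`` only, so
    all runs of a subject share latencies and topographies; pass
    ``truth`` explicitly to reuse a cohort-level draw.
    """
    params.validate()
    if truth is None:
        truth = draw_subject_truth(params, subject_id, seed)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, subject_id, run_id])
    )
    channels = _channel_table(params)
    n_ch = len(channels)
    fs = params.fs_hz

    seq = _event_sequence(params, rng)
    last_trigger = seq[-1][0]
    n_samples = last_trigger + int(round(
        (params.stim_duration_ms + params.pad_ms) * fs / 1000.0))
    data = np.zeros((n_ch, n_samples))

    # --- evoked components -------------------------------------------
    waves = {
        "initial": _component_wave(params, "initial",
                                   truth.initial_latency_ms),
        "main": _component_wave(params, "main", truth.main_latency_ms),
    }
    gains = {
        ("initial", "line"): params.gain_initial_line,
        ("initial", "rhomboid"): params.gain_initial_rhomboid,
        ("main", "line"): params.gain_main_line,
        ("main", "rhomboid"): params.gain_main_rhomboid,
    }
    amps = {"initial": params.amp_initial_ft, "main": params.amp_main_ft}
    lat = params.laterality_gain

    # precompute sensor patterns per (component, quadrant)
    pattern = {}
    for comp in ("initial", "main"):
        for quad in ("nasal", "temporal"):
            contra = CONTRA_HEMI[quad]
            ipsi = "left" if contra == "right" else "right"
            w_c = lat / (lat + 1.0) if lat > 0 else 0.5
            w_i = 1.0 / (lat + 1.0) if lat > 0 else 0.5
            pattern[(comp, quad)] = (
                w_c * truth.topo[(comp, contra)]
                + w_i * truth.topo[(comp, ipsi)]
            ) * 2.0  # keep overall scale ~unit-norm for lat=1

    for trig, lab in seq:
        form, quad = lab.split("_")
        for comp in ("initial", "main"):
            k0, wave = waves[comp]
            a, b = trig + k0, trig + k0 + len(wave)
            if a < 0 or b > n_samples:
                continue
            scale = amps[comp] * gains[(comp, form)] * truth.amp_factor
            data[:, a:b] += np.outer(pattern[(comp, quad)] * scale, wave)

    # --- background --------------------------------------------------
    meg = slice(0, n_ch - 1)
    if params.alpha_amp_ft > 0:
        data[meg] += params.alpha_amp_ft * _narrowband_noise(
            rng, n_ch - 1, n_samples, fs, 8.0, 12.0)
    if params.theta_amp_ft > 0:
        data[meg] += params.theta_amp_ft * _narrowband_noise(
            rng, n_ch - 1, n_samples, fs, 4.0, 8.0)
    if params.pink_amp_ft > 0:
        data[meg] += params.pink_amp_ft * _pink_noise(
            rng, n_ch - 1, n_samples)
    if params.eog_noise_ft > 0:
        data[-1] += params.eog_noise_ft * _pink_noise(rng, 1, n_samples)[0]

    # --- blinks ------------------------------------------------------
    if params.blink_rate_per_min > 0 and params.blink_amp_ft > 0:
        dur_min = n_samples / fs / 60.0
        n_blinks = rng.poisson(params.blink_rate_per_min * dur_min)
        blink_len = int(round(params.blink_duration_ms * fs / 1000.0))
        blink = np.sin(np.pi * np.arange(blink_len) / blink_len)
        for _ in range(n_blinks):
            s = rng.integers(0, max(1, n_samples - blink_len))
            seg = params.blink_amp_ft * blink
            data[-1, s:s + blink_len] += seg
            data[:, s:s + blink_len] += np.outer(
                truth.blink_leak_weights, seg)

    events = [
        Event(trig, ConditionCode(form=lab.split("_")[0],
                                  quadrant=lab.split("_")[1]), run_id)
        for trig, lab in seq
    ]
    meta = {
        "subject_id": subject_id,
        "run_id": run_id,
        "seed": seed,
        "trigger_delay_ms": params.trigger_delay_ms,
        "band": "raw",
    }
    return Recording(fs_hz=fs, channels=channels, data=data,
                     events=events, meta=meta).validate()


def cohort_truth_table(params: GeneratorParams, seed: int) -> pd.DataFrame:
    """True per-condition latencies/amplitudes, one row per subject x condition."""
    rows = []
    for s in range(params.n_subjects):
        tr = draw_subject_truth(params, s, seed)
        for cond in CONDITIONS:
            form, quad = cond.split("_")
            g_init = {"line": params.gain_initial_line,
                      "rhomboid": params.gain_initial_rhomboid}[form]
            g_main = {"line": params.gain_main_line,
                      "rhomboid": params.gain_main_rhomboid}[form]
            rows.append({
                "subject_id": s,
                "condition": cond,
                "form": form,
                "quadrant": quad,
                "initial_latency_ms": tr.initial_latency_ms,
                "main_latency_ms": tr.main_latency_ms,
                "initial_amp_ft": params.amp_initial_ft * g_init
                * tr.amp_factor,
                "main_amp_ft": params.amp_main_ft * g_main * tr.amp_factor,
            })
    return pd.DataFrame(rows)


def generate_cohort(params: GeneratorParams, seed: int,
                    out_dir=None):
    """Generate the full cohort.

    With ``out_dir`` set, recordings are written to disk one at a time
    (full-size cohorts do not fit in memory) and the paths are returned;
    otherwise the Recording objects themselves are returned.  In both
    cases the second element is the truth table.
    """
    from .io_core import write_recording

    params.validate()
    truth = cohort_truth_table(params, seed)
    out = {}
    for s in range(params.n_subjects):
        tr = draw_subject_truth(params, s, seed)
        for r in range(params.n_runs):
            rec = generate_run(params, s, r, seed, truth=tr)
            if out_dir is not None:
                path = write_recording(
                    rec, f"{out_dir}/sub{s:02d}_run{r}.npz")
                out[(s, r)] = path
            else:
                out[(s, r)] = rec
    return out, truth
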