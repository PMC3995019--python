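"""On-disk containers, configuration and validation shared by all stages.

A :class:`Recording` is a continuous multi-channel MEG time series in
femtotesla with an event table.  On disk it is a single ``.npz`` array
container plus plain-text sidecars (``<stem>.channels.tsv``,
``<stem>.events.tsv``, ``<stem>.meta.json``) so that channel and event
tables stay human-inspectable.

All times are milliseconds, all fields femtotesla.  Analysis windows are
half-open ``[start, end)`` except the printed peak-search windows
(15-70 ms, 70-160 ms), which are inclusive of both endpoints so that a
sample-aligned window reproduces the printed 67-bin count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

CHANNEL_GROUPS = ("MLO", "MRO", "MZO", "EOG", "OTHER")

FORMS = ("line", "rhomboid")
QUADRANTS = ("nasal", "temporal")

#: the four stimulus conditions, in canonical order
CONDITIONS = tuple(f"{f}_{q}" for f in FORMS for q in QUADRANTS)


class ValidationError(ValueError):
    """An in-memory container violates one of its invariants."""


class FormatError(ValueError):
    """An on-disk file does not match the documented container layout."""


@dataclass(frozen=True)
class ConditionCode:
    """Stimulus condition: either a (form, quadrant) pair or a task event."""

    form: Optional[str] = None
    quadrant: Optional[str] = None
    task: Optional[str] = None

    def __post_init__(self) -> None:
        stim = self.form is not None and self.quadrant is not None
        task = self.task is not None
        if stim == task or (self.form is None) != (self.quadrant is None):
            raise ValidationError(
                "ConditionCode needs exactly one of (form, quadrant) or task"
            )
        if stim:
            if self.form not in FORMS:
                raise ValidationError(f"unknown form {self.form!r}")
            if self.quadrant not in QUADRANTS:
                raise ValidationError(f"unknown quadrant {self.quadrant!r}")

    @property
    def label(self) -> str:
        if self.task is not None:
            return self.task
        return f"{self.form}_{self.quadrant}"


@dataclass(frozen=True)
class Event:
    """A trigger in the continuous recording (trigger time, not stimulus time)."""

    onset_sample: int
    code: ConditionCode
    run_id: int


@dataclass
class Recording:
    """Continuous multi-channel recording with channel metadata and events."""

    fs_hz: float
    channels: list[tuple[str, str]]  # (name, group)
    data: np.ndarray  # channels x samples, femtotesla
    events: list[Event] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    # -- invariants -----------------------------------------------------
    def validate(self) -> "Recording":
        if not self.fs_hz > 0:
            raise ValidationError(f"fs_hz must be > 0, got {self.fs_hz}")
        names = [n for n, _ in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate channel names: {dupes}")
        for n, g in self.channels:
            if g not in CHANNEL_GROUPS:
                raise ValidationError(f"channel {n!r} has unknown group {g!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels"
            )
        by_run: dict[int, int] = {}
        for ev in self.events:
            if not 0 <= ev.onset_sample < self.data.shape[1]:
                raise ValidationError(
                    f"event onset {ev.onset_sample} outside recording"
                )
            prev = by_run.get(ev.run_id)
            if prev is not None and ev.onset_sample <= prev:
                raise ValidationError(
                    f"event onsets not strictly increasing in run {ev.run_id} "
                    f"({ev.onset_sample} after {prev})"
                )
            by_run[ev.run_id] = ev.onset_sample
        return self

    # -- channel helpers ------------------------------------------------
    @property
    def channel_names(self) -> list[str]:
        return [n for n, _ in self.channels]

    def group_indices(self, *groups: str) -> np.ndarray:
        """Indices of all channels whose group is in ``groups``."""
        return np.array(
            [i for i, (_, g) in enumerate(self.channels) if g in groups],
            dtype=int,
        )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# on-disk container


def _npz_path(path) -> Path:
    p = Path(path)
    return p if p.suffix == ".npz" else p.with_suffix(p.suffix + ".npz")


def _sidecar(npz: Path, tag: str) -> Path:
    return npz.with_name(npz.name[: -len(".npz")] + tag)


def write_recording(rec: Recording, path) -> Path:
    """Write a Recording to ``path`` (.npz + plain-text sidecars).

    Round-trips exactly: data to full float64 precision, channel and
    event tables field-by-field.
    """
    rec.validate()
    npz = _npz_path(path)
    np.savez(npz, data=np.asarray(rec.data, dtype=np.float64),
             fs_hz=np.float64(rec.fs_hz))

    lines = ["name\tgroup"]
    lines += [f"{n}\t{g}" for n, g in rec.channels]
    _sidecar(npz, ".channels.tsv").write_text("\n".join(lines) + "\n")

    lines = ["onset_sample\tform\tquadrant\ttask\trun_id"]
    for ev in rec.events:
        c = ev.code
        lines.append(
            f"{ev.onset_sample}\t{c.form or '.'}\t{c.quadrant or '.'}"
            f"\t{c.task or '.'}\t{ev.run_id}"
        )
    _sidecar(npz, ".events.tsv").write_text("\n".join(lines) + "\n")
    _sidecar(npz, ".meta.json").write_text(json.dumps(rec.meta, indent=1))
    return npz


def read_recording(path) -> Recording:
    """Read a Recording written by :func:`write_recording` and validate it."""
    npz = _npz_path(path)
    if not npz.exists():
        raise FormatError(f"missing container file {npz}")
    with np.load(npz) as z:
        try:
            data = z["data"]
            fs = float(z["fs_hz"])
        except KeyError as e:
            raise FormatError(f"container missing array {e}") from None

    chan_file = _sidecar(npz, ".channels.tsv")
    if not chan_file.exists():
        raise FormatError(f"missing channel sidecar {chan_file}")
    channels = []
    rows = chan_file.read_text().rstrip("\n").split("\n")
    if rows[0] != "name\tgroup":
        raise FormatError(f"bad channel header {rows[0]!r}")
    for row in rows[1:]:
        parts = row.split("\t")
        if len(parts) != 2:
            raise FormatError(f"bad channel row {row!r}")
        channels.append((parts[0], parts[1]))

    ev_file = _sidecar(npz, ".events.tsv")
    if not ev_file.exists():
        raise FormatError(f"missing event sidecar {ev_file}")
    rows = ev_file.read_text().rstrip("\n").split("\n")
    if rows[0] != "onset_sample\tform\tquadrant\ttask\trun_id":
        raise FormatError(f"bad event header {rows[0]!r}")
    events = []
    for row in rows[1:]:
        if not row:
            continue
        parts = row.split("\t")
        if len(parts) != 5:
            raise FormatError(f"bad event row {row!r}")
        onset, form, quad, task, run = parts
        try:
            code = ConditionCode(
                form=None if form == "." else form,
                quadrant=None if quad == "." else quad,
                task=None if task == "." else task,
            )
            events.append(Event(int(onset), code, int(run)))
        except (ValidationError, ValueError) as e:
            raise FormatError(f"bad event row {row!r}: {e}") from None

    meta_file = _sidecar(npz, ".meta.json")
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}

    return Recording(fs_hz=fs, channels=channels, data=data,
                     events=events, meta=meta).validate()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorParams:
    """Synthetic-cohort parameters; defaults are the study design.

    Amplitudes are femtotesla at the sensor before topography
    normalisation; latencies/durations are milliseconds.
    """

    n_subjects: int = 20
    n_runs: int = 6
    trials_per_run: int = 300
    stim_duration_ms: float = 200.0
    isi_low_ms: float = 600.0
    isi_high_ms: float = 800.0
    trigger_delay_ms: float = 17.0
    fs_hz: float = 1200.0

    # initial (~40 ms) component: high-frequency Gabor burst
    initial_latency_ms: float = 40.0
    initial_latency_sd_ms: float = 6.0  # between subjects
    initial_carrier_hz: float = 35.0
    initial_envelope_sd_ms: float = 6.0
    amp_initial_ft: float = 150.0

    # main (~100 ms) component: slow biphasic wave
    main_latency_ms: float = 100.0
    main_latency_sd_ms: float = 8.0
    main_carrier_hz: float = 10.0
    main_envelope_sd_ms: float = 50.0
    amp_main_ft: float = 220.0

    # per-component x per-form gains
    gain_initial_line: float = 1.0
    gain_initial_rhomboid: float = 0.7
    gain_main_line: float = 1.0
    gain_main_rhomboid: float = 1.0

    # between-subject lognormal amplitude spread (log-units)
    subject_amp_sd_log: float = 0.5

    # contralateral : ipsilateral source drive
    laterality_gain: float = 3.0

    # background, per-channel SD in fT
    alpha_amp_ft: float = 150.0
    theta_amp_ft: float = 60.0
    pink_amp_ft: float = 150.0
    eog_noise_ft: float = 10.0

    # blinks
    blink_rate_per_min: float = 4.0
    blink_amp_ft: float = 1500.0
    blink_leak: float = 0.02
    blink_duration_ms: float = 400.0

    # layout (matches the analysed occipital sensor counts)
    n_left_occ: int = 18
    n_right_occ: int = 19
    n_midline_occ: int = 3

    pad_ms: float = 1000.0  # silence before first / after last trigger

    def validate(self) -> "GeneratorParams":
        gains = [self.gain_initial_line, self.gain_initial_rhomboid,
                 self.gain_main_line, self.gain_main_rhomboid,
                 self.laterality_gain, self.amp_initial_ft, self.amp_main_ft,
                 self.alpha_amp_ft, self.theta_amp_ft, self.pink_amp_ft,
                 self.blink_amp_ft]
        if any(g < 0 for g in gains):
            raise ValidationError("all gains/amplitudes must be >= 0")
        if self.isi_low_ms > self.isi_high_ms:
            raise ValidationError("isi_low_ms must be <= isi_high_ms")
        for name in ("initial_latency_ms", "main_latency_ms"):
            v = getattr(self, name)
            if not 0 <= v <= 500:
                raise ValidationError(f"{name}={v} outside the epoch window")
        if min(self.n_subjects, self.n_runs, self.trials_per_run) < 1:
            raise ValidationError("cohort dimensions must be >= 1")
        if not self.fs_hz > 0:
            raise ValidationError("fs_hz must be > 0")
        return self


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the study's printed constants."""

    rng_seed: int = 0

    trigger_delay_ms: float = 17.0
    band_standard_low_hz: float = 0.5
    band_standard_high_hz: float = 30.0
    band_tight_low_hz: float = 13.0
    band_tight_high_hz: float = 60.0
    filter_order: int = 4

    epoch_start_ms: float = -500.0
    epoch_end_ms: float = 500.0
    baseline_start_ms: float = -200.0
    baseline_end_ms: float = 0.0

    initial_window_start_ms: float = 15.0
    initial_window_end_ms: float = 70.0
    main_window_start_ms: float = 70.0
    main_window_end_ms: float = 160.0

    k_sd: float = 2.0
    min_run: int = 4
    alpha: float = 0.05
    eog_threshold_ft: float = 100.0

    dcm_window_start_ms: float = 0.0
    dcm_window_end_ms: float = 52.0
    dcm_input_onset_ms: float = 20.0
    dcm_input_sigma_ms: float = 4.0
    dcm_delta_ms: float = 4.0
    dcm_delta_fb_ms: float = 8.0
    dcm_prior_sd_log: float = 0.5
    dcm_max_iter: int = 64
    dcm_tol: float = 0.01

    generator: GeneratorParams = field(default_factory=GeneratorParams)

    def validate(self) -> "PipelineConfig":
        windows = [
            ("epoch", self.epoch_start_ms, self.epoch_end_ms),
            ("baseline", self.baseline_start_ms, self.baseline_end_ms),
            ("initial_window", self.initial_window_start_ms,
             self.initial_window_end_ms),
            ("main_window", self.main_window_start_ms, self.main_window_end_ms),
            ("dcm_window", self.dcm_window_start_ms, self.dcm_window_end_ms),
        ]
        for name, lo, hi in windows:
            if not lo < hi:
                raise ValidationError(f"{name}: start {lo} must be < end {hi}")
        for name, lo, hi in [
            ("band_standard", self.band_standard_low_hz,
             self.band_standard_high_hz),
            ("band_tight", self.band_tight_low_hz, self.band_tight_high_hz),
        ]:
            if not 0 < lo < hi:
                raise ValidationError(f"{name}: need 0 < low < high, "
                                      f"got {lo}, {hi}")
        if self.min_run < 1:
            raise ValidationError("min_run must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.k_sd < 0:
            raise ValidationError("k_sd must be >= 0")
        self.generator.validate()
        return self


_CFG_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)
               if f.name != "generator"}
_GEN_FIELDS = {f.name: f for f in dataclasses.fields(GeneratorParams)}


def _coerce(raw: str, typ, key: str):
    raw = raw.strip()
    try:
        if typ is int:
            return int(raw)
        if typ is float:
            return float(raw)
    except ValueError:
        raise FormatError(f"malformed value {raw!r} for key {key!r}") from None
    return raw


def load_config(path) -> PipelineConfig:
    """Load a flat ``key = value`` config file; unset keys take defaults.

    Generator keys live in the same flat namespace (e.g. ``n_subjects``,
    ``amp_initial_ft``) alongside analysis keys (``band_tight_low_hz``).
    """
    cfg = PipelineConfig()
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"line {lineno}: expected 'key = value', "
                              f"got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key in _CFG_FIELDS:
            setattr(cfg, key, _coerce(raw, _field_type(_CFG_FIELDS[key]), key))
        elif key in _GEN_FIELDS:
            setattr(cfg.generator, key,
                    _coerce(raw, _field_type(_GEN_FIELDS[key]), key))
        else:
            valid = sorted(set(_CFG_FIELDS) | set(_GEN_FIELDS))
            raise FormatError(
                f"unknown config key {key!r}; valid keys: {', '.join(valid)}"
            )
    return cfg.validate()


def _field_type(f: dataclasses.Field):
    # dataclass fields carry the annotation as a string under
    # `from __future__ import annotations`
    return {"int": int, "float": float, "str": str}.get(str(f.type), str)
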