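"""Continuous recordings -> per-condition evoked fields under two filters.

The pipeline order is: correct the 17 ms trigger/projector delay on the
event table, bandpass the *continuous* recording (so epoch edges carry no
filter transients), epoch into 1000 ms windows starting 500 ms before
stimulus onset, baseline-correct on the 200 ms pre-onset interval, reject
blink-contaminated epochs on the (raw) EOG peak-to-peak, and average per
condition.

Two filter regimes isolate the two evoked components: a standard
0.5-30 Hz bandpass for the main response (~100 ms) and a tight 13-60 Hz
bandpass for the initial response (~40 ms).  A forward-only (causal)
variant of either filter is available to rule out acausal filter
artifacts spreading backwards from the main response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_core import Recording, ValidationError


@dataclass
class EpochSet:
    """Condition-labelled stack of fixed-length trials."""

    data: np.ndarray             # epochs x channels x samples
    conditions: list[str]        # label per epoch
    times_ms: np.ndarray         # sample times relative to stimulus onset
    fs_hz: float
    channels: list[tuple[str, str]]
    rejected: np.ndarray = None  # bool per epoch
    reject_reason: list[str] = None
    band: str = "raw"
    n_dropped_edge: int = 0

    def __post_init__(self):
        if self.rejected is None:
            self.rejected = np.zeros(len(self.conditions), dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = [""] * len(self.conditions)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        for i, (n, _) in enumerate(self.channels):
            if n == name:
                return i
        raise ValidationError(f"no channel named {name!r}")


@dataclass
class Evoked:
    """Average ERF for one condition under one filter band."""

    condition: str
    band: str
    data: np.ndarray            # channels x samples
    times_ms: np.ndarray
    fs_hz: float
    channels: list[tuple[str, str]]
    n_epochs: int

    def group_indices(self, *groups: str) -> np.ndarray:
        return np.array(
            [i for i, (_, g) in enumerate(self.channels) if g in groups],
            dtype=int,
        )


def _round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (not banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def correct_trigger_delay(rec: Recording, delay_ms: float) -> Recording:
    """Shift every event onset by the projector delay (trigger precedes
    the stimulus), dropping events pushed past the end of the recording.

    The shift is ``round(delay_ms * fs / 1000)`` samples, nearest-sample,
    ties away from zero.  The number of dropped events is recorded in
    ``meta['n_events_dropped_delay']``.
    """
    if delay_ms < 0:
        raise ValidationError("delay_ms must be >= 0")
    shift = _round_half_away(delay_ms * rec.fs_hz / 1000.0)
    events, dropped = [], 0
    from dataclasses import replace

    for ev in rec.events:
        onset = ev.onset_sample + shift
        if onset >= rec.n_samples:
            dropped += 1
            continue
        events.append(replace(ev, onset_sample=onset))
    meta = dict(rec.meta)
    meta["n_events_dropped_delay"] = dropped
    meta["trigger_delay_corrected_ms"] = delay_ms
    return Recording(fs_hz=rec.fs_hz, channels=rec.channels, data=rec.data,
                     events=events, meta=meta).validate()


def bandpass_filter(rec: Recording, low_hz: float, high_hz: float,
                    mode: str = "zero_phase", order: int = 4) -> Recording:
    """Butterworth bandpass on the continuous data.

    ``zero_phase`` applies the design forwards and backwards
    (sosfiltfilt, no phase distortion); ``forward_only`` is a single
    causal pass, which cannot smear energy before an event.
    """
    nyq = rec.fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValidationError(
            f"band {low_hz}-{high_hz} Hz outside (0, {nyq}) Hz")
    if mode not in ("zero_phase", "forward_only"):
        raise ValidationError(f"unknown filter mode {mode!r}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=rec.fs_hz, output="sos")
    if mode == "zero_phase":
        data = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        data = signal.sosfilt(sos, rec.data, axis=1)
    meta = dict(rec.meta)
    meta["band"] = f"{low_hz}-{high_hz}Hz/{mode}"
    return Recording(fs_hz=rec.fs_hz, channels=rec.channels, data=data,
                     events=rec.events, meta=meta)


def epoch(rec: Recording, window_ms: tuple[float, float] = (-500.0, 500.0),
          ) -> EpochSet:
    """Slice one epoch per event, t=0 aligned to the (corrected) onset.

    The window is half-open ``[start, end)`` in ms; at 1200 Hz the
    default -500..+500 ms window is exactly 1200 samples with sample 600
    at t=0.  Events whose window would run off either edge are dropped
    and counted in ``n_dropped_edge``.
    """
    lo, hi = window_ms
    if not lo < hi:
        raise ValidationError("epoch window start must be < end")
    fs = rec.fs_hz
    k0 = _round_half_away(lo * fs / 1000.0)
    k1 = _round_half_away(hi * fs / 1000.0)
    rel = np.arange(k0, k1)
    epochs, labels, dropped = [], [], 0
    for ev in rec.events:
        a, b = ev.onset_sample + k0, ev.onset_sample + k1
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, a:b])
        labels.append(ev.code.label)
    if not epochs:
        raise ValidationError("no events could be epoched")
    return EpochSet(
        data=np.stack(epochs),
        conditions=labels,
        times_ms=rel * 1000.0 / fs,
        fs_hz=fs,
        channels=list(rec.channels),
        band=rec.meta.get("band", "raw"),
        n_dropped_edge=dropped,
    )


def baseline_correct(ep: EpochSet,
                     baseline_ms: tuple[float, float] = (-200.0, 0.0),
                     ) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``[start, end)`` ms."""
    lo, hi = baseline_ms
    mask = (ep.times_ms >= lo) & (ep.times_ms < hi)
    if not mask.any():
        raise ValidationError("baseline window contains no samples")
    dt = 1000.0 / ep.fs_hz
    if lo < ep.times_ms[0] - dt / 2 or hi > ep.times_ms[-1] + dt:
        raise ValidationError("baseline window outside epoch window")
    mean = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=ep.data - mean,
        conditions=list(ep.conditions),
        times_ms=ep.times_ms,
        fs_hz=ep.fs_hz,
        channels=ep.channels,
        rejected=ep.rejected.copy(),
        reject_reason=list(ep.reject_reason),
        band=ep.band,
        n_dropped_edge=ep.n_dropped_edge,
    )


def reject_artifacts(ep: EpochSet, eog_channel: str = "EOG",
                     threshold_ft: float = 100.0,
                     manual_mask: np.ndarray | None = None) -> EpochSet:
    """Flag blink-contaminated epochs.

    An epoch is rejected iff the EOG peak-to-peak within it exceeds
    ``threshold_ft``, or the manual mask marks it.  The mask stands in
    for the eye-tracker / visual inspection of the original workflow.
    """
    if threshold_ft <= 0:
        raise ValidationError("threshold_ft must be > 0")
    try:
        eog_idx = ep.channel_index(eog_channel)
    except ValidationError:
        eog_idx = None
    if eog_idx is None and manual_mask is None:
        raise ValidationError(
            f"no channel {eog_channel!r} and no manual mask given")
    rejected = ep.rejected.copy()
    reasons = list(ep.reject_reason)
    if eog_idx is not None:
        eog = ep.data[:, eog_idx, :]
        ptp = eog.max(axis=1) - eog.min(axis=1)
        for i in np.nonzero(ptp > threshold_ft)[0]:
            rejected[i] = True
            reasons[i] = (reasons[i] + ";eog").lstrip(";")
    if manual_mask is not None:
        manual_mask = np.asarray(manual_mask, dtype=bool)
        if manual_mask.shape != (ep.n_epochs,):
            raise ValidationError("manual mask length mismatch")
        for i in np.nonzero(manual_mask)[0]:
            rejected[i] = True
            reasons[i] = (reasons[i] + ";manual").lstrip(";")
    return EpochSet(
        data=ep.data, conditions=list(ep.conditions), times_ms=ep.times_ms,
        fs_hz=ep.fs_hz, channels=ep.channels, rejected=rejected,
        reject_reason=reasons, band=ep.band,
        n_dropped_edge=ep.n_dropped_edge,
    )


def average(ep: EpochSet, condition: str) -> Evoked:
    """Pointwise mean over the retained epochs of one condition."""
    sel = np.array(
        [c == condition and not r
         for c, r in zip(ep.conditions, ep.rejected)], dtype=bool)
    n = int(sel.sum())
    if n == 0:
        raise ValidationError(
            f"no retained epochs for condition {condition!r}")
    return Evoked(
        condition=condition,
        band=ep.band,
        data=ep.data[sel].mean(axis=0),
        times_ms=ep.times_ms,
        fs_hz=ep.fs_hz,
        channels=ep.channels,
        n_epochs=n,
    )


@dataclass
class EvokedAccumulator:
    """Streaming per-condition average so full runs never co-reside in RAM."""

    sums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    template: EpochSet = None

    def add(self, ep: EpochSet) -> None:
        if self.template is None:
            self.template = ep
        for cond in set(ep.conditions):
            sel = np.array(
                [c == cond and not r
                 for c, r in zip(ep.conditions, ep.rejected)], dtype=bool)
            if not sel.any():
                continue
            s = ep.data[sel].sum(axis=0)
            self.sums[cond] = self.sums.get(cond, 0.0) + s
            self.counts[cond] = self.counts.get(cond, 0) + int(sel.sum())

    def evoked(self, condition: str) -> Evoked:
        if condition not in self.counts:
            raise ValidationError(
                f"no retained epochs for condition {condition!r}")
        t = self.template
        return Evoked(
            condition=condition, band=t.band,
            data=self.sums[condition] / self.counts[condition],
            times_ms=t.times_ms, fs_hz=t.fs_hz, channels=t.channels,
            n_epochs=self.counts[condition],
        )
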