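import numpy as np
import pytest

from formscan.io_core import (
    ConditionCode,
    Event,
    GeneratorParams,
    Recording,
)


@pytest.fixture
def small_params():
    """A fast cohort: full trial structure, reduced counts."""
    return GeneratorParams(n_subjects=2, n_runs=1, trials_per_run=40)


@pytest.fixture
def noiseless_params():
    """Evoked components only: no background, no blinks."""
    return GeneratorParams(
        n_subjects=1, n_runs=1, trials_per_run=40,
        alpha_amp_ft=0.0, theta_amp_ft=0.0, pink_amp_ft=0.0,
        eog_noise_ft=0.0, blink_rate_per_min=0.0,
    )


def make_recording(n_ch=3, n_samp=1000, fs=1200.0, events=None, seed=0,
                   groups=None):
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = ["MLO", "MRO", "EOG"][:n_ch]
        groups += ["OTHER"] * (n_ch - len(groups))
    channels = [(f"CH{i:02d}", g) for i, g in enumerate(groups)]
    return Recording(
        fs_hz=fs,
        channels=channels,
        data=rng.standard_normal((n_ch, n_samp)),
        events=events or [],
        meta={"seed": seed},
    )


def stim_event(onset, form="line", quadrant="nasal", run_id=0):
    return Event(onset, ConditionCode(form=form, quadrant=quadrant), run_id)
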