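import numpy as np
import pytest

from bcgpulse.simulate import SubjectProfile, make_beat_times, render_bcg
from bcgpulse.preprocessing import bandpass, segment


@pytest.fixture
def clean_profile():
    """Noiseless, artifact-free, jitter-free 60 bpm subject."""
    return SubjectProfile(
        subject_id="clean",
        mean_hr_bpm=60.0,
        hr_wander_sd_bpm=0.0,
        ibi_jitter_sd_s=0.0,
        noise_sd=0.0,
        artifact_events_per_hour=0.0,
        seed=7,
    )


@pytest.fixture
def default_profile():
    """The default resting sleeper (55 bpm, default noise and artifacts)."""
    return SubjectProfile(subject_id="default", seed=11)


@pytest.fixture
def clean_windows(clean_profile):
    """Band-passed 8 s windows of a 2-minute noiseless render, with truth."""
    duration = 120.0
    truth = make_beat_times(clean_profile, duration)
    rec = render_bcg(truth, duration, clean_profile)
    ws = segment(bandpass(rec))
    return ws, truth
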