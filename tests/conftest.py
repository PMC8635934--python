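import numpy as np
import pytest

from gaitdtcwt import (PipelineConfig, generate_dataset, make_default_templates,
                       recordings_to_features)
from gaitdtcwt.filters import default_filters
from gaitdtcwt.segmentation import extract_windows
from gaitdtcwt.preprocessing import smooth_recording
from gaitdtcwt.synthetic import SubjectProfile, generate_recording


@pytest.fixture(scope="session")
def filters():
    return default_filters()


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_features(pipeline_config):
    """4 subjects x 13 states x 4 windows at default noise."""
    recordings, _ = generate_dataset(n_subjects=4, windows_per_state=4, seed=0)
    return recordings_to_features(recordings, pipeline_config)


@pytest.fixture(scope="session")
def default_features(pipeline_config):
    """The default study-scale cohort: 10 subjects x 13 states x 6 windows."""
    recordings, _ = generate_dataset(n_subjects=10, windows_per_state=6, seed=1)
    return recordings_to_features(recordings, pipeline_config)


@pytest.fixture(scope="session")
def gait_window():
    """One smoothed 46-frame synthetic level-walking swing window."""
    template = make_default_templates()["LW"]
    subject = SubjectProfile(subject_id="S01", seed=11)
    rec, toe_offs = generate_recording(template, subject, n_cycles=3, seed=3)
    windows = extract_windows(smooth_recording(rec), window_len=46)
    assert windows[0].start_frame == toe_offs[0]
    return windows[0]
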