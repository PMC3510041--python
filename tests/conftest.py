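import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from flyheart.synth import (
    BeatTrainParams,
    GeometryParams,
    render_cardiogram,
    render_video,
    simulate_beat_train,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def regular_truth():
    """A perfectly regular 150 ms beat train (20 beats)."""
    return simulate_beat_train(
        BeatTrainParams(mean_period_ms=150.0, cv_period=0.0, n_beats=20), seed=11
    )


@pytest.fixture
def arrhythmic_truth():
    """An arrhythmic (CV 0.2) 150 ms beat train (40 beats)."""
    return simulate_beat_train(
        BeatTrainParams(mean_period_ms=150.0, cv_period=0.2, n_beats=40), seed=12
    )


@pytest.fixture
def fast_geom():
    """Quantization-free test geometry: 200 fps, no noise."""
    return GeometryParams(frame_rate_hz=200.0)


@pytest.fixture
def paper_geom():
    """The recording geometry of the assay: 32 fps."""
    return GeometryParams(frame_rate_hz=32.0)


@pytest.fixture
def clean_stack(regular_truth, fast_geom):
    """Noiseless rendered video of the regular train."""
    return render_video(regular_truth, fast_geom, seed=13)


@pytest.fixture
def clean_cardiogram(regular_truth, fast_geom):
    cg, _ = render_cardiogram(regular_truth, fast_geom, seed=14)
    return cg
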