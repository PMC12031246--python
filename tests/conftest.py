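import numpy as np
import pytest

from dolphinet import (
    AnnotationEvent,
    AudioRecording,
    EventSpec,
    SceneConfig,
    VocalizationClass,
    WhistleContour,
    render_scene,
)

FS = 192_000


@pytest.fixture(scope="session")
def whistle_scene():
    """A 1 s scene with one 0.5 s whistle at +20 dB SNR, plus its labels."""
    config = SceneConfig(
        duration=1.0,
        seed=101,
        events=[
            EventSpec(
                VocalizationClass.WHISTLE, 0.25, 0.5, snr_db=20.0,
                contour=WhistleContour(8_000, 14_000),
            )
        ],
    )
    waveform, labels = render_scene(config)
    return config, waveform, labels


@pytest.fixture(scope="session")
def whistle_recording(whistle_scene):
    _, waveform, labels = whistle_scene
    return AudioRecording(waveform, FS, source_path="whistle-scene"), labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
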