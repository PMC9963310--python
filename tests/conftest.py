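import numpy as np
import pytest

from pprdetect import (
    GeneratorConfig,
    LabeledWindow,
    generate_recording,
)


@pytest.fixture(scope="session")
def short_recording():
    """A 30-second default-style recording with a few PPR events."""
    cfg = GeneratorConfig(duration_range=(30.0, 30.0), ppr_event_rate=3, seed=11)
    return generate_recording(cfg, recording_id="short")


def make_ppr_window(data, case="whole", window_id="w", channel_names=None):
    """Construct a PPR-labelled window around an arbitrary data array."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return LabeledWindow(
        data=data,
        label="PPR",
        ppr_case=case,
        provenance="real",
        recording_id="fixture",
        start_sample=0,
        window_id=window_id,
        channel_names=channel_names,
    )


@pytest.fixture
def ppr_window_factory():
    return make_ppr_window
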