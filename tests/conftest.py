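import numpy as np
import pytest

from ecgbeat import BeatAnnotation, ECGRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_channel_record(rng):
    """A small two-channel record with plausible mV amplitudes."""
    sig = rng.normal(0.0, 0.3, size=(1000, 2)).round(3)
    return ECGRecord(
        record_id="fix01", fs=360.0, signals=sig, channel_names=["MLII", "V5"]
    )


@pytest.fixture
def simple_annotations():
    return [
        BeatAnnotation(10, "N"),
        BeatAnnotation(400, "L"),
        BeatAnnotation(900, "A"),
    ]
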