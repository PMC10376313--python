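import logging

import numpy as np
import pytest

from stressbox.io_core import FeatureTable, SignalRecord


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    """Filter warnings from intentionally degenerate fixtures out of the log."""
    logging.getLogger("stressbox").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def sine_record(channel: str, freq_hz: float, fs: float, duration_s: float,
                amplitude: float = 1.0) -> SignalRecord:
    t = np.arange(0, duration_s, 1.0 / fs)
    return SignalRecord(channel, amplitude * np.sin(2 * np.pi * freq_hz * t), fs)


def four_point_table() -> FeatureTable:
    """Two tight 2-D pairs: exact K-means solution known by hand."""
    return FeatureTable(
        ["a", "b"], np.array([[0.0, 0.0], [0.1, 0.1], [0.9, 0.9], [1.0, 1.0]])
    )
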