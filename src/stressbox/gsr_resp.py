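"""Windowed GSR statistics and respiration-rate estimation.

GSR (skin conductance, microsiemens) is summarized in non-overlapping
30 s windows — per-window mean and standard deviation — plus an overall
mean/std over the whole record.  Trailing partial windows are dropped.

Respiration rate is the dominant periodogram frequency over
[0.05, 1.0] Hz converted to breaths/min; the estimate is only accepted
when the spectral peak stands clear of the noise floor (peak-to-median
ratio of at least 3), so pure noise raises an estimation error instead of
returning a spurious rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import EstimationError, InsufficientDataError, ValidationError
from .io_core import SignalRecord

RESP_BAND_HZ = (0.05, 1.0)
PEAK_TO_MEDIAN_MIN = 3.0


@dataclass
class GsrStats:
    window_means: np.ndarray  # microsiemens, one per full 30 s window
    window_stds: np.ndarray
    gsr_mean: float  # over the full record
    gsr_std: float


@dataclass
class RespFeatures:
    resp_rate: float  # breaths/min


def gsr_window_stats(gsr: SignalRecord, window_s: float = 30.0) -> GsrStats:
    """Per-window and overall GSR statistics (non-overlapping windows)."""
    if gsr.channel != "gsr":
        raise ValidationError("window statistics expect a GSR record")
    if gsr.duration < window_s:
        raise InsufficientDataError(
            f"record of {gsr.duration:.1f} s shorter than one {window_s:.0f} s window"
        )
    n_win = int(gsr.duration // window_s)
    win_len = int(round(window_s * gsr.sampling_rate))
    means, stds = [], []
    for i in range(n_win):
        chunk = gsr.samples[i * win_len : (i + 1) * win_len]
        means.append(float(np.mean(chunk)))
        stds.append(float(np.std(chunk)))
    return GsrStats(
        window_means=np.asarray(means),
        window_stds=np.asarray(stds),
        gsr_mean=float(np.mean(gsr.samples)),
        gsr_std=float(np.std(gsr.samples)),
    )


def respiration_rate(resp: SignalRecord) -> RespFeatures:
    """Dominant-frequency respiration rate in breaths/min.

    The periodogram is searched over the physiologic band; an estimate is
    rejected when the in-band peak is not at least 3x the in-band median
    density (no clear oscillation present).
    """
    if resp.channel != "resp":
        raise ValidationError("respiration-rate estimation expects a RESP record")
    if resp.duration < 30.0:
        raise InsufficientDataError("need at least 30 s of respiration signal")
    x = resp.samples - np.mean(resp.samples)
    # Welch averaging (30 s segments) tames the periodogram's variance so
    # the peak-to-median gate rejects broadband noise; zero padding keeps
    # the frequency resolution fine enough for +/-0.5 breaths/min
    nperseg = min(len(x), int(30 * resp.sampling_rate))
    nfft = int(2 ** np.ceil(np.log2(nperseg * 16)))
    freqs, pxx = sps.welch(x, fs=resp.sampling_rate, nperseg=nperseg, nfft=nfft)
    band = (freqs >= RESP_BAND_HZ[0]) & (freqs <= RESP_BAND_HZ[1])
    if not band.any():
        raise EstimationError("no frequencies in the respiration band")
    f_band, p_band = freqs[band], pxx[band]
    med = float(np.median(p_band))
    peak_idx = int(np.argmax(p_band))
    if med <= 0 or p_band[peak_idx] / med < PEAK_TO_MEDIAN_MIN:
        raise EstimationError(
            "no dominant respiratory oscillation above the noise floor"
        )
    return RespFeatures(resp_rate=float(f_band[peak_idx]) * 60.0)


def extract_gsr_resp_features(
    gsr: SignalRecord, resp: SignalRecord, window_s: float = 30.0
) -> dict[str, float]:
    """GSR/respiration features as feature-table columns."""
    stats = gsr_window_stats(gsr, window_s)
    rate = respiration_rate(resp)
    return {
        "GSR_mean": stats.gsr_mean,
        "GSR_std": stats.gsr_std,
        "RESP_rate": rate.resp_rate,
    }
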