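"""Signal conditioning for the three recording channels.

Four steps, mirroring how the study conditioned its raw streams:

* ECG: a 50 Hz power-line notch (second-order IIR, Q = 30, applied
  forward-backward so it is zero-phase), then wavelet smoothing with a
  ``db6`` decomposition of depth 10 and a universal soft threshold on the
  detail coefficients.
* GSR: an order-6 Butterworth low-pass at 0.5 Hz, forward-backward.
* Respiration: a Blackman-windowed FIR band-pass, nominally 0.5-35 Hz; at
  the 32 Hz respiration sampling rate the upper edge is clamped below the
  16 Hz Nyquist (15 Hz by default) because the nominal band is not
  realizable there.

All filters preserve signal length.  The notch, Butterworth and Blackman
filters are linear; wavelet smoothing is not (thresholding is a nonlinear
shrinkage) and is excluded from linearity guarantees.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy import signal as sps

from .errors import ParameterError
from .io_core import SignalRecord

logger = logging.getLogger(__name__)


def _nyquist(record: SignalRecord) -> float:
    return record.sampling_rate / 2.0


def notch_filter(record: SignalRecord, center: float = 50.0, q: float = 30.0) -> SignalRecord:
    """Zero-phase narrow-band notch at ``center`` Hz (power-line removal).

    Q = 30 keeps the stop band narrow so oscillations just above or below
    the notch frequency are essentially untouched.
    """
    if not 0 < center < _nyquist(record):
        raise ParameterError(
            f"notch center {center} Hz must lie in (0, {_nyquist(record)}) Hz"
        )
    b, a = sps.iirnotch(center, q, fs=record.sampling_rate)
    out = sps.filtfilt(b, a, record.samples)
    return record.replace_samples(out)


def wavelet_smooth(
    record: SignalRecord,
    wavelet: str = "db6",
    level: int = 10,
    threshold: str = "universal",
) -> SignalRecord:
    """Smooth by wavelet decomposition and detail-coefficient shrinkage.

    ``threshold='universal'`` soft-thresholds every detail band at
    sigma * sqrt(2 ln N) with sigma estimated from the finest band
    (median absolute deviation / 0.6745).  ``threshold='none'`` performs a
    plain decompose-reconstruct round trip (useful to verify the perfect
    reconstruction property).

    The decomposition depth is reduced (with a warning) when the record is
    too short to support the requested level.
    """
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ParameterError(f"unknown wavelet {wavelet!r}")
    if threshold not in ("universal", "none"):
        raise ParameterError(f"unknown threshold rule {threshold!r}")
    x = record.samples
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet).dec_len)
    if max_level < 1:
        raise ParameterError("signal too short for any wavelet decomposition")
    eff_level = min(level, max_level)
    if eff_level < level:
        logger.warning(
            "wavelet level reduced from %d to %d for %d-sample signal",
            level, eff_level, len(x),
        )
    coeffs = pywt.wavedec(x, wavelet, level=eff_level)
    if threshold == "universal":
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745 if finest.size else 0.0
        thr = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
        if thr > 0:
            coeffs = [coeffs[0]] + [
                pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]
            ]
    out = pywt.waverec(coeffs, wavelet)[: len(x)]
    return record.replace_samples(out)


def butter_lowpass(
    record: SignalRecord, order: int = 6, cutoff: float = 0.5
) -> SignalRecord:
    """Zero-phase Butterworth low-pass (tonic GSR extraction).

    Applied forward-backward, so the magnitude response is squared (no
    phase lag, effective order doubled).
    """
    if not 0 < cutoff < _nyquist(record):
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, {_nyquist(record)}) Hz"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=record.sampling_rate, output="sos")
    out = sps.sosfiltfilt(sos, record.samples)
    return record.replace_samples(out)


def blackman_bandpass(
    record: SignalRecord,
    low: float = 0.5,
    high: float = 35.0,
    numtaps: int | None = None,
) -> SignalRecord:
    """Blackman-windowed FIR band-pass (respiration conditioning).

    The upper edge is clamped 1 Hz below Nyquist when the nominal band
    exceeds what the sampling rate supports (for 32 Hz data this clamps a
    nominal 35 Hz edge to 15 Hz), with a warning.  DC is rejected.
    """
    nyq = _nyquist(record)
    high_eff = high
    if high >= nyq:
        high_eff = nyq - 1.0
        logger.warning(
            "band-pass upper edge %.3g Hz clamped to %.3g Hz (Nyquist %.3g Hz)",
            high, high_eff, nyq,
        )
    if not 0 < low < high_eff:
        raise ParameterError(
            f"band edges ({low}, {high_eff}) Hz invalid after clamping"
        )
    if numtaps is None:
        numtaps = int(4 * record.sampling_rate) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    taps = sps.firwin(
        numtaps,
        [low, high_eff],
        pass_zero=False,
        window="blackman",
        fs=record.sampling_rate,
    )
    padlen = min(len(record.samples) - 1, numtaps)
    out = sps.filtfilt(taps, [1.0], record.samples, padlen=padlen)
    return record.replace_samples(out)


def preprocess_signal(record: SignalRecord, config: dict | None = None) -> SignalRecord:
    """Apply the channel-appropriate conditioning chain."""
    from .io_core import DEFAULT_CONFIG

    cfg = dict(DEFAULT_CONFIG["preprocess"])
    if config:
        cfg.update(config)
    if record.channel == "ecg":
        out = notch_filter(record, cfg["notch_hz"], cfg["notch_q"])
        return wavelet_smooth(out, cfg["wavelet"], cfg["wavelet_level"])
    if record.channel == "gsr":
        return butter_lowpass(record, cfg["gsr_order"], cfg["gsr_cutoff_hz"])
    if record.channel == "resp":
        low, high = cfg["resp_band_hz"]
        return blackman_bandpass(record, low, high)
    raise ParameterError(f"no preprocessing chain for channel {record.channel!r}")
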