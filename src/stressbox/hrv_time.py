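"""R-peak detection and time-domain / nonlinear HRV features.

Given a conditioned ECG, `detect_r_peaks` locates QRS complexes with a
Pan-Tompkins-style energy detector (band-pass, differentiate, square,
moving-window integrate, adaptive threshold, 0.25 s refractory period) and
returns the R-peak times with their successive RR intervals.

From an RR series the module computes the classical time-domain features
(mean HR, SDNN, RMSSD, NN50, pNN50), the Poincare short/long axis
deviations SD1/SD2, and approximate entropy ApEn(m, r).

Conventions: SDNN uses the sample (n-1) standard deviation; SD1/SD2 use
population standard deviations of the 45-degree rotated Poincare
coordinates, which keeps the identity RMSSD = SD1 * sqrt(2) exact.  ApEn
defaults to m = 2, r = 0.2 * sd with self-matches included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DetectionError, InsufficientDataError, ValidationError
from .io_core import SignalRecord

logger = logging.getLogger(__name__)

#: Physiologic RR guard band (seconds): outside this, an interval is an artifact.
RR_MIN_S = 0.25
RR_MAX_S = 3.0


@dataclass
class RRSeries:
    """Detected R-peak times (s, strictly increasing) and RR intervals (s)."""

    peak_times: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if len(self.rr) != max(len(self.peak_times) - 1, 0):
            raise ValidationError("rr length must be len(peak_times) - 1")
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValidationError("peak times must be strictly increasing")
        if not np.allclose(self.rr, np.diff(self.peak_times), atol=1e-12):
            raise ValidationError("rr must equal successive peak-time differences")
        if len(self.rr) and np.any(self.rr <= 0):
            raise ValidationError("all RR intervals must be positive")

    @classmethod
    def from_peak_times(cls, peak_times) -> "RRSeries":
        peak_times = np.asarray(peak_times, dtype=float)
        return cls(peak_times, np.diff(peak_times))

    def __len__(self) -> int:
        return len(self.rr)


@dataclass
class TimeDomainFeatures:
    mean_hr: float  # beats/min
    sdnn: float  # s
    rmssd: float  # s
    nn50: int
    pnn50: float
    sd1: float = float("nan")  # s
    sd2: float = float("nan")  # s
    apen: float = float("nan")


def detect_r_peaks(ecg: SignalRecord, refractory_s: float = 0.25) -> RRSeries:
    """Locate R peaks in a (preprocessed) ECG.

    Energy-based detection with an adaptive threshold; detected peaks are
    refined to the local maximum of the input signal within +/-40 ms.
    Intervals violating the physiologic guard band are logged; peaks closer
    than the refractory period are already excluded by construction.
    """
    if ecg.channel != "ecg":
        raise ValidationError("R-peak detection requires an ECG record")
    fs = ecg.sampling_rate
    x = ecg.samples
    if len(x) < 10 * fs:
        raise InsufficientDataError("need at least 10 s of ECG")
    if np.ptp(x) == 0:
        raise DetectionError("no R peaks detectable in flat ecg signal")

    # band-pass 5-15 Hz isolates QRS energy
    sos = sps.butter(2, [5.0, min(15.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    energy = np.gradient(band) ** 2
    win = max(int(0.15 * fs), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    height = 0.2 * np.percentile(integ, 99)
    if height <= 0:
        raise DetectionError("no R peaks detectable in ecg signal")
    locs, _ = sps.find_peaks(integ, height=height, distance=max(int(refractory_s * fs), 1))
    if len(locs) < 2:
        raise DetectionError("fewer than two R peaks detected in ecg signal")

    # refine each peak to the local maximum of the input waveform; iterate so
    # peaks near record edges (where the filter transient biases the energy
    # estimate) still converge onto the true apex
    half = max(int(min(0.1, refractory_s / 2) * fs), 1)
    refined = []
    for loc in locs:
        cur = int(loc)
        for _ in range(10):
            lo, hi = max(cur - half, 0), min(cur + half + 1, len(x))
            nxt = lo + int(np.argmax(x[lo:hi]))
            if nxt == cur:
                break
            cur = nxt
        refined.append(cur)
    refined = np.unique(refined)

    # enforce the refractory period after refinement (keep the taller peak)
    kept: list[int] = []
    for idx in refined:
        if kept and (idx - kept[-1]) / fs < refractory_s:
            if x[idx] > x[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    times = np.asarray(kept, dtype=float) / fs
    rr = np.diff(times)
    bad = (rr < RR_MIN_S) | (rr > RR_MAX_S)
    if bad.any():
        logger.warning("%d RR interval(s) outside [%.2f, %.1f] s", bad.sum(), RR_MIN_S, RR_MAX_S)
    return RRSeries.from_peak_times(times)


def clean_rr(rr: np.ndarray) -> np.ndarray:
    """Drop RR intervals outside the physiologic guard band (no interpolation)."""
    rr = np.asarray(rr, dtype=float)
    mask = (rr >= RR_MIN_S) & (rr <= RR_MAX_S)
    if not mask.all():
        logger.warning("dropping %d non-physiologic RR interval(s)", (~mask).sum())
    return rr[mask]


def time_domain_features(rr: RRSeries | np.ndarray) -> TimeDomainFeatures:
    """Mean HR, SDNN, RMSSD, NN50 and pNN50 from an RR series.

    NN50 counts successive differences strictly greater than 50 ms;
    pNN50 = NN50 / (number of successive differences).
    """
    vals = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if len(vals) < 2:
        raise InsufficientDataError("need at least 2 RR intervals")
    diffs = np.diff(vals)
    # strictly greater than 50 ms; the tolerance keeps a difference that is
    # exactly 50 ms (up to float rounding of the subtraction) excluded
    nn50 = int(np.sum(np.abs(diffs) > 0.050 + 1e-9))
    return TimeDomainFeatures(
        mean_hr=60.0 / float(np.mean(vals)),
        sdnn=float(np.std(vals, ddof=1)),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        nn50=nn50,
        pnn50=nn50 / len(diffs),
    )


def poincare_sd1_sd2(rr: RRSeries | np.ndarray) -> tuple[float, float]:
    """Poincare SD1 (short axis) and SD2 (long axis) in seconds.

    Standard HRV-toolkit convention: SD1^2 = mean(drr^2) / 2 (the spread of
    the cloud (rr[i], rr[i+1]) perpendicular to the identity line), and
    SD2^2 = 2 var(rr) - SD1^2 (spread along it, clipped at zero).  With
    population variance for var(rr), the identities RMSSD = SD1 * sqrt(2)
    and SD1^2 + SD2^2 = 2 var(rr) hold exactly; the 45-degree
    rotated-coordinate standard deviations agree with these up to the
    (tiny) squared mean of the successive differences.
    """
    vals = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if len(vals) < 3:
        raise InsufficientDataError("need at least 3 RR intervals")
    diffs = np.diff(vals)
    sd1_sq = float(np.mean(diffs**2)) / 2.0
    sd2_sq = max(2.0 * float(np.var(vals)) - sd1_sq, 0.0)
    return float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))


def approximate_entropy(
    series, m: int = 2, r_factor: float = 0.2, r: float | None = None
) -> float:
    """ApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r), self-matches included.

    Phi^m(r) is the average log fraction of length-m templates within
    Chebyshev distance r of each template.  By default r = r_factor times
    the population standard deviation of the series; a zero-variance series
    gets an r floor of 1e-12 so constant input returns exactly 0.
    Pass ``r`` to fix the tolerance in absolute units instead.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < m + 2:
        raise InsufficientDataError(f"need at least m + 2 = {m + 2} points")
    if r is None:
        sd = float(np.std(x))
        r = r_factor * sd if sd > 0 else 1e-12

    def phi(mm: int) -> float:
        k = n - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)  # k x mm
        # pairwise Chebyshev distances between templates
        dist = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        c = np.sum(dist <= r, axis=1) / k
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def extract_time_features(rr: RRSeries) -> dict[str, float]:
    """All time-domain/nonlinear features as a name -> value mapping
    (names match the feature-table columns)."""
    vals = clean_rr(rr.rr)
    td = time_domain_features(vals)
    sd1, sd2 = poincare_sd1_sd2(vals)
    apen = approximate_entropy(vals)
    return {
        "MeanHR": td.mean_hr,
        "SDNN": td.sdnn,
        "RMSSD": td.rmssd,
        "NN50": float(td.nn50),
        "PNN50": td.pnn50,
        "SD1": sd1,
        "SD2": sd2,
        "ApEN": apen,
    }
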