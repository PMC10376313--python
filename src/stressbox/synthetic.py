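"""Synthetic physiological signals with known ground truth.

The study's recordings are private, so every downstream module is
exercised on generated data whose answers are known in closed form:

* RR series: rr_n = mean_rr + a_lf sin(2 pi f_lf t_n) + a_hf sin(2 pi
  f_hf t_n) + noise, with the modulation frequencies at the LF/HF band
  centers (0.1 and 0.25 Hz).  Two sinusoids rather than an AR process so
  the true band-power ratio is exactly a_lf^2 / a_hf^2.
* ECG: a Gaussian QRS bump (20 ms wide, unit amplitude) at each beat
  time over baseline noise, with optional 50 Hz interference to exercise
  the notch filter.
* GSR: a tonic level plus exponential-decay phasic events plus noise.
* Respiration: a sinusoid at rate/60 Hz plus slow drift and noise.
* Feature tables: labeled Gaussian clusters for classifier fixtures.

A four-phase "study profile" bundles per-phase parameter sets that move
the way the study's phases did: the two stressor phases (T2 roller
coaster, T3 Stroop task) get a faster heart rate, a high LF/HF ratio,
rapid breathing and elevated skin conductance; the baseline (T1) and
video-game recovery (T4) phases sit at relaxed values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .hrv_time import RRSeries
from .io_core import SignalRecord, write_signal

F_LF_HZ = 0.1  # LF band center
F_HF_HZ = 0.25  # HF band center


@dataclass
class RrModelParams:
    """Parameters of the two-sinusoid RR generator."""

    mean_rr: float = 0.8  # s
    a_lf: float = 0.05  # s, modulation amplitude at f_lf
    a_hf: float = 0.025  # s, modulation amplitude at f_hf
    f_lf: float = F_LF_HZ
    f_hf: float = F_HF_HZ
    noise_sd: float = 0.01  # s
    n_beats: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.003 <= self.f_lf < 0.15 and 0.15 <= self.f_hf < 0.4):
            raise ParameterError("modulation frequencies must sit in the LF/HF bands")
        if self.mean_rr - self.a_lf - self.a_hf - 4.0 * self.noise_sd <= 0.25:
            raise ParameterError(
                "parameters admit non-physiologic RR intervals (< 0.25 s)"
            )
        if self.n_beats < 2:
            raise ParameterError("need at least 2 beats")

    @property
    def true_lf_hf(self) -> float:
        """Ground-truth LF/HF band-power ratio, a_lf^2 / a_hf^2."""
        if self.a_hf == 0:
            return float("inf")
        return (self.a_lf / self.a_hf) ** 2


def synth_rr(params: RrModelParams) -> RRSeries:
    """Generate an RR series with sinusoidal LF/HF modulation."""
    rng = np.random.default_rng(params.seed)
    times = [0.0]
    rr = []
    for _ in range(params.n_beats - 1):
        t = times[-1]
        interval = (
            params.mean_rr
            + params.a_lf * np.sin(2 * np.pi * params.f_lf * t)
            + params.a_hf * np.sin(2 * np.pi * params.f_hf * t)
            + (params.noise_sd * rng.standard_normal() if params.noise_sd > 0 else 0.0)
        )
        interval = max(interval, 0.26)  # guard against rare noise excursions
        rr.append(interval)
        times.append(t + interval)
    return RRSeries(np.asarray(times), np.asarray(rr))


def synth_ecg(
    rr: RRSeries,
    fs: float = 250.0,
    qrs_width_s: float = 0.020,
    amplitude: float = 1.0,
    noise_sd: float = 0.02,
    mains_amplitude: float = 0.0,
    mains_hz: float = 50.0,
    seed: int = 0,
) -> SignalRecord:
    """Place a Gaussian QRS bump at every beat time over baseline noise.

    ``mains_amplitude`` adds a 50 Hz interference component so the notch
    filter has something to remove.  Beat times are ``rr.peak_times``.
    """
    rng = np.random.default_rng(seed)
    duration = rr.peak_times[-1] + 0.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    sigma = qrs_width_s / 2.0
    for beat in rr.peak_times:
        lo = max(int((beat - 5 * sigma) * fs), 0)
        hi = min(int((beat + 5 * sigma) * fs) + 1, n)
        x[lo:hi] += amplitude * np.exp(-((t[lo:hi] - beat) ** 2) / (2 * sigma**2))
    if mains_amplitude > 0:
        x += mains_amplitude * np.sin(2 * np.pi * mains_hz * t)
    return SignalRecord("ecg", x, fs)


def synth_gsr(
    duration: float,
    fs: float = 32.0,
    tonic: float = 3.0,
    scr_events: list[tuple[float, float, float]] | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SignalRecord:
    """Tonic skin-conductance level plus phasic exponential-decay pulses.

    ``scr_events`` is a list of (onset_s, amplitude_uS, decay_s) tuples.
    """
    if tonic < 0:
        raise ParameterError("tonic level must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.full(n, float(tonic))
    for onset, amp, decay in scr_events or []:
        mask = t >= onset
        x[mask] += amp * np.exp(-(t[mask] - onset) / decay)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return SignalRecord("gsr", x, fs)


def synth_resp(
    duration: float,
    fs: float = 32.0,
    rate: float = 12.0,
    amplitude: float = 1.0,
    drift_amplitude: float = 0.2,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SignalRecord:
    """Sinusoidal breathing at ``rate`` breaths/min plus drift and noise."""
    if rate <= 0:
        raise ParameterError("respiration rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * (rate / 60.0) * t)
    x += drift_amplitude * np.sin(2 * np.pi * 0.01 * t)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return SignalRecord("resp", x, fs)


def synth_feature_table(
    n_per_class: int,
    class_centers: np.ndarray,
    spread: float,
    scheme: str | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
):
    """Labeled Gaussian clusters over named features.

    The label scheme defaults to binary for two centers, five-class for up
    to five, and unlabeled-style "none" semantics otherwise.
    """
    from .io_core import FeatureTable

    centers = np.asarray(class_centers, dtype=float)
    if centers.ndim != 2:
        raise ParameterError("class_centers must be (n_classes, n_features)")
    if scheme is None:
        scheme = "binary" if len(centers) == 2 else (
            "five_class" if len(centers) <= 5 else "none"
        )
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for c, center in enumerate(centers):
        blocks.append(center + spread * rng.standard_normal((n_per_class, len(center))))
        labels.extend([c] * n_per_class)
    names = feature_names or [f"feat{j}" for j in range(centers.shape[1])]
    return FeatureTable(names, np.vstack(blocks), np.asarray(labels), scheme)


# --- four-phase study emulation -----------------------------------------

@dataclass
class PhaseParams:
    """Generator settings for one experiment phase of one subject."""

    rr: RrModelParams
    resp_rate: float  # breaths/min
    gsr_tonic: float  # microsiemens
    n_scr_events: int = 2
    scr_amplitude: float = 0.3


@dataclass
class PhaseProfile:
    """Per-phase parameter sets emulating the study's directional trends."""

    phases: dict[str, PhaseParams] = field(default_factory=dict)


def study_profile(duration_s: float = 150.0) -> PhaseProfile:
    """Default four-phase profile.

    T2/T3 (stressors): shorter mean RR (faster heart rate), LF-dominated
    modulation (true LF/HF well above 3), breathing above 25 breaths/min,
    elevated and more eventful skin conductance.  T1/T4 (baseline and
    recovery): HF-balanced modulation (LF/HF below 1), slow breathing,
    low skin conductance.
    """

    def beats(mean_rr: float) -> int:
        return int(duration_s / mean_rr) + 2

    phases = {
        "T1": PhaseParams(
            RrModelParams(0.85, 0.030, 0.032, noise_sd=0.010, n_beats=beats(0.85)),
            resp_rate=12.0, gsr_tonic=3.2, n_scr_events=1,
        ),
        "T2": PhaseParams(
            RrModelParams(0.70, 0.050, 0.018, noise_sd=0.015, n_beats=beats(0.70)),
            resp_rate=27.0, gsr_tonic=6.2, n_scr_events=4,
        ),
        "T3": PhaseParams(
            RrModelParams(0.73, 0.048, 0.019, noise_sd=0.015, n_beats=beats(0.73)),
            resp_rate=26.0, gsr_tonic=5.7, n_scr_events=4,
        ),
        "T4": PhaseParams(
            RrModelParams(0.86, 0.028, 0.034, noise_sd=0.010, n_beats=beats(0.86)),
            resp_rate=13.0, gsr_tonic=3.1, n_scr_events=1,
        ),
    }
    return PhaseProfile(phases=phases)


@dataclass
class SubjectRecording:
    """All generated signals and ground truth for one subject."""

    subject_id: str
    signals: dict[str, dict[str, SignalRecord]]  # phase -> channel -> record
    truth: dict[str, dict]  # phase -> ground-truth parameters


def _jitter_phase(params: PhaseParams, rng: np.random.Generator) -> PhaseParams:
    """Small multiplicative between-subject variation (3% on RR terms)."""
    f = lambda: 1.0 + 0.03 * rng.standard_normal()  # noqa: E731
    rr = replace(
        params.rr,
        mean_rr=params.rr.mean_rr * f(),
        a_lf=params.rr.a_lf * f(),
        a_hf=params.rr.a_hf * f(),
        seed=int(rng.integers(2**31 - 1)),
    )
    return PhaseParams(
        rr=rr,
        resp_rate=params.resp_rate + 0.3 * rng.standard_normal(),
        gsr_tonic=params.gsr_tonic * f(),
        n_scr_events=params.n_scr_events,
        scr_amplitude=params.scr_amplitude,
    )


def simulate_study(
    n_subjects: int = 13,
    seed: int = 0,
    duration_s: float = 150.0,
    profile: PhaseProfile | None = None,
) -> list[SubjectRecording]:
    """Generate per-subject, per-phase ECG/GSR/RESP recordings."""
    profile = profile or study_profile(duration_s)
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        signals: dict[str, dict[str, SignalRecord]] = {}
        truth: dict[str, dict] = {}
        for phase, base in profile.phases.items():
            params = _jitter_phase(base, rng)
            rr = synth_rr(params.rr)
            ecg = synth_ecg(
                rr, mains_amplitude=0.1, seed=int(rng.integers(2**31 - 1))
            )
            events = [
                (float(t), params.scr_amplitude, 5.0)
                for t in rng.uniform(5, duration_s - 10, params.n_scr_events)
            ]
            gsr = synth_gsr(
                duration_s,
                tonic=params.gsr_tonic,
                scr_events=events,
                seed=int(rng.integers(2**31 - 1)),
            )
            resp = synth_resp(
                duration_s, rate=params.resp_rate, seed=int(rng.integers(2**31 - 1))
            )
            for rec in (ecg, gsr, resp):
                rec.subject_id = subject_id
                rec.phase = phase
            signals[phase] = {"ecg": ecg, "gsr": gsr, "resp": resp}
            truth[phase] = {
                "mean_rr": params.rr.mean_rr,
                "true_lf_hf": params.rr.true_lf_hf,
                "resp_rate": params.resp_rate,
                "gsr_tonic": params.gsr_tonic,
                "beat_times": rr.peak_times.tolist(),
                "stressed": phase in ("T2", "T3"),
            }
        subjects.append(SubjectRecording(subject_id, signals, truth))
    return subjects


def write_study(subjects: list[SubjectRecording], outdir: str | Path) -> None:
    """Write per-subject, per-phase signal CSVs plus a ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for subj in subjects:
        manifest[subj.subject_id] = {
            phase: {k: v for k, v in info.items() if k != "beat_times"}
            for phase, info in subj.truth.items()
        }
        for phase, channels in subj.signals.items():
            for channel, rec in channels.items():
                write_signal(rec, outdir / f"{subj.subject_id}_{phase}_{channel}.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
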