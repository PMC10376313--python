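"""Core data model and plain-text I/O.

The toolkit moves data around in three containers:

* :class:`SignalRecord` — one channel of a timed physiological recording
  (ECG in arbitrary mV-like units at 250 Hz; GSR in microsiemens and
  respiration in arbitrary units, both at 32 Hz by default).
* :class:`FeatureTable` — a samples x named-features matrix with optional
  integer labels (binary stress, or five ordered stress levels 0-4).
* :class:`StudyLayout` — per-subject bookkeeping of usable experiment
  phases, used to derive how many recordings enter an analysis.

Signals live in headerless (or single-header-line) delimited text files;
feature tables are CSV with a header row and an optional ``label`` column;
fitted models serialize to a documented JSON layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    FormatError,
    ParameterError,
    ParseError,
    SchemaError,
    ValidationError,
)

CHANNELS = ("ecg", "gsr", "resp")
PHASES = ("T1", "T2", "T3", "T4")

#: Sampling rates of the study hardware: ECG at 250 Hz, GSR/RESP at 32 Hz.
DEFAULT_RATES = {"ecg": 250.0, "gsr": 32.0, "resp": 32.0}

LABEL_SCHEMES = ("binary", "five_class", "none")


@dataclass
class SignalRecord:
    """A single-channel, uniformly sampled physiological recording."""

    channel: str
    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.phase is not None and self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "SignalRecord":
        """Copy of this record with new sample values (rate/tags kept)."""
        return SignalRecord(
            channel=self.channel,
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            subject_id=self.subject_id,
            phase=self.phase,
        )


def _sniff_delimiter(line: str) -> Optional[str]:
    for delim in (",", "\t"):
        if delim in line:
            return delim
    return None  # whitespace


def _parse_numeric_rows(path: Path) -> np.ndarray:
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = []
    start = 0
    first = lines[0].split(delim) if delim else lines[0].split()
    try:
        [float(tok) for tok in first]
    except ValueError:
        start = 1  # single header line
    for ln in lines[start:]:
        toks = ln.split(delim) if delim else ln.split()
        try:
            row = [float(tok) for tok in toks]
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric row {ln!r}") from exc
        if any(not np.isfinite(v) for v in row):
            raise ParseError(f"{path}: non-finite value in row {ln!r}")
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: ragged rows")
    return np.asarray(rows, dtype=float)


def read_signal(
    path: str | Path,
    channel: str,
    sampling_rate: Optional[float] = None,
    subject_id: str = "",
    phase: Optional[str] = None,
) -> SignalRecord:
    """Read a signal from one- or two-column delimited text.

    Two-column files are interpreted as (time, value); the time column must
    advance with a uniform step consistent with ``sampling_rate`` to within
    a relative tolerance of 1e-6.
    """
    if sampling_rate is None:
        sampling_rate = DEFAULT_RATES[channel]
    data = _parse_numeric_rows(Path(path))
    if data.shape[1] == 1:
        values = data[:, 0]
    elif data.shape[1] == 2:
        t, values = data[:, 0], data[:, 1]
        dt = np.diff(t)
        expected = 1.0 / sampling_rate
        if dt.size and not np.allclose(dt, expected, rtol=1e-6, atol=1e-12):
            raise FormatError(
                f"{path}: time step inconsistent with rate {sampling_rate} Hz"
            )
    else:
        raise FormatError(f"{path}: expected 1 or 2 columns, got {data.shape[1]}")
    return SignalRecord(channel, values, sampling_rate, subject_id, phase)


def write_signal(record: SignalRecord, path: str | Path, times: bool = False) -> None:
    """Write a signal as delimited text (value-only, or time,value columns)."""
    path = Path(path)
    if times:
        arr = np.column_stack([record.times, record.samples])
    else:
        arr = record.samples[:, None]
    np.savetxt(path, arr, delimiter=",", fmt="%.17g")  # round-trips float64 exactly


@dataclass
class FeatureTable:
    """Samples x named features, with optional integer labels."""

    feature_names: list[str]
    values: np.ndarray
    labels: Optional[np.ndarray] = None
    label_scheme: str = "none"

    def __post_init__(self) -> None:
        self.feature_names = list(self.feature_names)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names must be unique")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError("column count does not match feature names")
        if self.label_scheme not in LABEL_SCHEMES:
            raise ValidationError(f"unknown label scheme {self.label_scheme!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise ValidationError("labels length must equal sample count")
            if self.label_scheme == "binary" and not np.isin(self.labels, [0, 1]).all():
                raise ValidationError("binary labels must be in {0,1}")
            if self.label_scheme == "five_class" and not np.isin(
                self.labels, range(5)
            ).all():
                raise ValidationError("five-class labels must be in {0..4}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            idx = self.feature_names.index(name)
        except ValueError as exc:
            raise SchemaError(f"no feature named {name!r}") from exc
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_scheme: str = "none") -> "FeatureTable":
        labels = None
        if "label" in df.columns:
            labels = df["label"].to_numpy()
            df = df.drop(columns=["label"])
            if label_scheme == "none":
                label_scheme = (
                    "binary" if set(np.unique(labels)) <= {0, 1} else "five_class"
                )
        return cls(list(df.columns), df.to_numpy(dtype=float), labels, label_scheme)


def read_feature_table(path: str | Path, label_scheme: str = "none") -> FeatureTable:
    """Read a feature table from CSV; a ``label`` column becomes labels."""
    df = pd.read_csv(path)
    drop = [c for c in df.columns if c != "label"]
    if df[drop].isna().any().any():
        raise ParseError(f"{path}: missing values in feature columns")
    return FeatureTable.from_frame(df, label_scheme)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


@dataclass
class SubjectLayout:
    """Usable-phase bookkeeping for one subject."""

    usable_phases: int
    signals_per_phase: int = 3

    def __post_init__(self) -> None:
        if self.usable_phases < 0 or self.signals_per_phase < 0:
            raise ValidationError("counts must be nonnegative")


@dataclass
class StudyLayout:
    """Per-subject usable phases, plus recordings excluded after the fact."""

    subjects: list[SubjectLayout] = field(default_factory=list)
    unusable_signals: int = 0

    def __post_init__(self) -> None:
        if self.unusable_signals < 0:
            raise ValidationError("unusable_signals must be nonnegative")


def count_usable_signals(layout: StudyLayout) -> int:
    """Total usable recordings: sum over subjects of phases x signals-per-phase,
    minus recordings dropped for technical reasons."""
    total = sum(s.usable_phases * s.signals_per_phase for s in layout.subjects)
    total -= layout.unusable_signals
    if total < 0:
        raise ValidationError("more unusable signals than recorded signals")
    return total


# --- model serialization -------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model (CART tree or K-means feature model) to JSON."""
    payload = model.to_dict()
    if "kind" not in payload:
        raise SchemaError("model payload must carry a 'kind' tag")
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind == "cart":
        from .cart import CartTree

        return CartTree.from_dict(payload)
    if kind == "kmeans_feature":
        from .kmeans_feature import KMeansFeatureModel

        return KMeansFeatureModel.from_dict(payload)
    raise SchemaError(f"unknown model kind {kind!r}")


# --- configuration -------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "preprocess": {
        "notch_hz": 50.0,
        "notch_q": 30.0,
        "wavelet": "db6",
        "wavelet_level": 10,
        "gsr_cutoff_hz": 0.5,
        "gsr_order": 6,
        "resp_band_hz": [0.5, 35.0],
    },
    "hrv": {
        "resample_rate_hz": 4.0,
        "ar_order": 10,
        "apen_m": 2,
        "apen_r_factor": 0.2,
    },
    "kmeans": {"k": None, "mapping": "centroid_mean", "n_init": 10},
    "cart": {"max_depth": 5, "min_samples_leaf": 1, "impurity": "paper"},
    "eval": {"folds": 5, "select_k_features": "all"},
    "synth": {"n_subjects": 13, "phase_duration_s": 150.0},
}


def load_config(path: Optional[str | Path] = None) -> dict:
    """Load a YAML config, overlaying its sections on the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: config must be a mapping of sections")
        for section, entries in user.items():
            if section not in cfg:
                raise ParameterError(f"unknown config section {section!r}")
            cfg[section].update(entries or {})
    return cfg
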