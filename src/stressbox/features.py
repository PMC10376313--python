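"""End-to-end feature extraction: three conditioned signals in, the
21-feature row out.

Feature names (one row of the feature table):
time domain / nonlinear — MeanHR, SDNN, RMSSD, NN50, PNN50, SD1, SD2,
ApEN; AR spectrum — VLF_AR, LF_AR, HF_AR, LFHF_AR, TP_AR; Lomb spectrum —
VLF_Lomb, LF_Lomb, HF_Lomb, LFHF_Lomb, TP_Lomb; other channels —
GSR_mean, GSR_std, RESP_rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gsr_resp import extract_gsr_resp_features
from .hrv_freq import extract_freq_features
from .hrv_time import detect_r_peaks, extract_time_features
from .io_core import FeatureTable, SignalRecord
from .preprocess import preprocess_signal

FEATURE_NAMES = [
    "MeanHR", "SDNN", "RMSSD", "NN50", "PNN50", "SD1", "SD2", "ApEN",
    "VLF_AR", "LF_AR", "HF_AR", "LFHF_AR", "TP_AR",
    "VLF_Lomb", "LF_Lomb", "HF_Lomb", "LFHF_Lomb", "TP_Lomb",
    "GSR_mean", "GSR_std", "RESP_rate",
]


def extract_features(
    ecg: SignalRecord,
    gsr: SignalRecord,
    resp: SignalRecord,
    preprocess: bool = True,
    config: dict | None = None,
) -> dict[str, float]:
    """Extract the full 21-feature set for one recording epoch."""
    if preprocess:
        pp = (config or {}).get("preprocess")
        ecg = preprocess_signal(ecg, pp)
        gsr = preprocess_signal(gsr, pp)
        resp = preprocess_signal(resp, pp)
    rr = detect_r_peaks(ecg)
    row: dict[str, float] = {}
    row.update(extract_time_features(rr))
    row.update(extract_freq_features(rr))
    row.update(extract_gsr_resp_features(gsr, resp))
    return {name: row[name] for name in FEATURE_NAMES}


def rows_to_table(rows: list[dict[str, float]], labels=None, label_scheme="none") -> FeatureTable:
    """Stack extracted feature rows into a FeatureTable."""
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    return FeatureTable(
        FEATURE_NAMES,
        df.to_numpy(dtype=float),
        None if labels is None else np.asarray(labels, dtype=int),
        label_scheme,
    )
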