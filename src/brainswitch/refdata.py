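"""Reference per-subject detection counts from the pilot clinical
evaluation of this detector (eight healthy participants, nine stroke
patients; raw EEG is not redistributable).

Only the raw inputs are stored — TP/FP counts, trial numbers, scored
rest minutes and the selected channel plans; every derived rate in a
report is recomputed by :mod:`brainswitch.metrics`.
"""

from __future__ import annotations

import pandas as pd

#: trials per session (every paradigm block design repeats 30 times)
N_TRIALS = 30
#: scored rest minutes per session type
REST_MINUTES = {"offline": 5.0, "online_healthy": 3.0, "online_stroke": 4.0}

# calibration-day offline simulation: subject, ERD band, ROI, non-ROIs, TP, FP
OFFLINE_HEALTHY = [
    ("S1", "17-21", "CP5", ("F7", "Cz", "P5"), 10, 3),
    ("S2", "20-25", "C3", ("C4", "P3", "P6"), 13, 8),
    ("S3", "9-12", "C3", ("F7", "P3", "P4"), 10, 4),
    ("S4", "17-22", "CP3", ("Cz", "T8", "O1"), 8, 3),
    ("S5", "24-28", "C3", ("T7", "P6", "O2"), 4, 1),
    ("S6", "10-14", "C3", ("F7", "T7", "Cz"), 8, 2),
    ("S7", "18-22", "C3", ("T10", "P6", "O2"), 4, 0),
    ("S8", "8-12", "C3", ("F7", "FC1", "P5"), 4, 2),
]
OFFLINE_STROKE = [
    ("P1", "8-10", "Cz", ("FC5", "CP5", "P5"), 8, 5),
    ("P2", "8-12", "C5", ("P3", "P4", "F7"), 9, 4),
    ("P3", "16-22", "FC5", ("F7", "FC6", "CP6"), 8, 1),
    ("P4", "10-12", "C3", ("FC5", "P5", "O2"), 6, 3),
    ("P5", "8-10", "Cz", ("F7", "T7", "P6"), 9, 3),
    ("P6", "19-22", "C5", ("F7", "F3", "CP6"), 4, 2),
    ("P7", "8-12", "CP6", ("FC4", "P5", "O1"), 4, 2),
    ("P8", "14-17", "CP5", ("F3", "FC5", "Cz"), 10, 2),
    ("P9", "17-23", "C2", ("FC5", "FC1", "P5"), 4, 1),
]

# online sessions: subject, session interval (days), TP, FP
ONLINE_HEALTHY = [
    ("S1", 40, 10, 4), ("S2", 29, 15, 7), ("S3", 22, 10, 3),
    ("S4", 23, 7, 1), ("S5", 18, 10, 0),
]
ONLINE_STROKE = [
    ("P1", 14, 14, 6), ("P2", 14, 9, 3), ("P3", 14, 10, 3),
    ("P4", 20, 6, 2), ("P5", 14, 8, 3), ("P6", 7, 8, 3),
    ("P7", 8, 12, 7), ("P8", 10, 15, 4), ("P9", 5, 12, 6),
]

# online FP rejection ablation: subject, TP, FP without non-ROI, FP with
REJECTION = [
    ("S1", 10, 13, 4), ("S2", 15, 15, 7), ("S3", 10, 10, 3),
    ("S4", 7, 3, 1), ("S5", 10, 2, 0),
    ("P1", 14, 14, 6), ("P2", 9, 20, 3), ("P3", 10, 17, 3),
    ("P4", 6, 18, 2), ("P5", 8, 16, 3), ("P6", 8, 18, 3),
    ("P7", 12, 28, 7), ("P8", 15, 20, 4), ("P9", 12, 23, 6),
]

# phase-1-only offline simulation (shape rules + non-ROI rejection,
# no template matching): subject, TP, FP
PHASE1_HEALTHY = [
    ("S1", 23, 20), ("S2", 24, 32), ("S3", 21, 18), ("S4", 21, 16),
    ("S5", 26, 28), ("S6", 24, 27), ("S7", 22, 20), ("S8", 22, 24),
]
PHASE1_STROKE = [
    ("P1", 22, 17), ("P2", 23, 31), ("P3", 25, 31), ("P4", 19, 22),
    ("P5", 24, 24), ("P6", 26, 25), ("P7", 21, 22), ("P8", 21, 23),
    ("P9", 20, 30),
]


def offline_counts(group: str) -> pd.DataFrame:
    rows = OFFLINE_HEALTHY if group == "healthy" else OFFLINE_STROKE
    return pd.DataFrame(rows, columns=["subject", "band", "roi", "nonroi",
                                       "tp", "fp"])


def online_counts(group: str) -> pd.DataFrame:
    rows = ONLINE_HEALTHY if group == "healthy" else ONLINE_STROKE
    return pd.DataFrame(rows, columns=["subject", "interval_days", "tp", "fp"])


def rejection_counts() -> pd.DataFrame:
    return pd.DataFrame(REJECTION, columns=["subject", "tp", "fp_pre",
                                            "fp_post"])


def phase1_counts(group: str) -> pd.DataFrame:
    rows = PHASE1_HEALTHY if group == "healthy" else PHASE1_STROKE
    return pd.DataFrame(rows, columns=["subject", "tp", "fp"])
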