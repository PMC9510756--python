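"""Detection-performance metrics for block-design BCI sessions.

All rates derive from the TP/FP counts of a session:

    sensitivity    = TP / n_trials * 100           (%)
    selectivity    = TP / (TP + FP) * 100          (%)
    FP rate        = FP / n_trials * 100           (%)
    FP per minute  = FP / scored rest minutes      (1/min)
    rejection rate = rejected / FP_without * 100   (%)

Display rounding is half-up to two decimals; full precision is kept
internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, as printed in session reports."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def sensitivity(tp: int, n_trials: int) -> float:
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0 <= tp <= n_trials:
        raise ValueError("tp must be within [0, n_trials]")
    return tp / n_trials * 100.0


def selectivity(tp: int, fp: int) -> float:
    if tp + fp <= 0:
        raise ValueError("selectivity undefined with zero detections")
    return tp / (tp + fp) * 100.0


def fp_rate(fp: int, n_trials: int) -> float:
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return fp / n_trials * 100.0


def fp_per_minute(fp: int, rest_minutes: float) -> float:
    if rest_minutes <= 0:
        raise ValueError("rest time must be positive")
    return fp / rest_minutes


def rejection_rate(rejected: int, fp_pre: int) -> float | None:
    """Rejected fraction of the FPs produced without non-ROI channels;
    ``None`` (not applicable) when there were none to reject."""
    if rejected < 0 or (fp_pre and rejected > fp_pre):
        raise ValueError("rejected must be within [0, fp_pre]")
    if fp_pre == 0:
        return None
    return rejected / fp_pre * 100.0


@dataclass
class SessionMetrics:
    sensitivity: float
    selectivity: float | None
    fp_rate: float
    fpm: float
    rejection_rate: float | None = None
    inputs: dict | None = None


def session_metrics(tp: int, fp: int, n_trials: int, rest_minutes: float,
                    fp_pre: int | None = None) -> SessionMetrics:
    rej = None
    if fp_pre is not None:
        rej = rejection_rate(fp_pre - fp, fp_pre)
    return SessionMetrics(
        sensitivity(tp, n_trials),
        selectivity(tp, fp) if tp + fp else None,
        fp_rate(fp, n_trials),
        fp_per_minute(fp, rest_minutes),
        rej,
        inputs={"tp": tp, "fp": fp, "n_trials": n_trials,
                "rest_minutes": rest_minutes, "fp_pre": fp_pre},
    )


def group_report(counts: pd.DataFrame, n_trials: int, rest_minutes: float,
                 units: str = "percent", count_agg: str = "mean",
                 ) -> pd.DataFrame:
    """Per-subject metric table with an Average row.

    ``counts`` needs columns ``subject``, ``tp``, ``fp``.  The Average
    row pools selectivity (sum TP / sum detections) and averages the
    per-subject FP rate, FPM and sensitivity; TP/FP aggregate by
    ``count_agg`` (``mean`` or ``sum``).  ``units="fraction"`` reports
    FP rate, selectivity and sensitivity as fractions instead of
    percentages.
    """
    if len(counts) < 1:
        raise ValueError("need at least one subject")
    scale = 0.01 if units == "fraction" else 1.0
    rows = []
    for r in counts.itertuples():
        rows.append({
            "subject": r.subject, "tp": r.tp, "fp": r.fp,
            "fpr": fp_rate(r.fp, n_trials) * scale,
            "fpm": fp_per_minute(r.fp, rest_minutes),
            "selectivity": (selectivity(r.tp, r.fp) * scale
                            if r.tp + r.fp else np.nan),
            "sensitivity": sensitivity(r.tp, n_trials) * scale,
        })
    df = pd.DataFrame(rows)
    tp_sum, fp_sum = int(counts.tp.sum()), int(counts.fp.sum())
    agg = {
        "subject": "Average",
        "tp": tp_sum if count_agg == "sum" else tp_sum / len(counts),
        "fp": fp_sum if count_agg == "sum" else fp_sum / len(counts),
        "fpr": df.fpr.mean(),
        "fpm": df.fpm.mean(),
        "selectivity": (selectivity(tp_sum, fp_sum) * scale
                        if tp_sum + fp_sum else np.nan),
        "sensitivity": df.sensitivity.mean(),
    }
    return pd.concat([df, pd.DataFrame([agg])], ignore_index=True)


def rejection_report(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-subject FP-rejection table with a pooled Average row.

    ``counts`` needs columns ``subject``, ``tp``, ``fp_pre``, ``fp_post``.
    """
    rows = []
    for r in counts.itertuples():
        rej = r.fp_pre - r.fp_post
        rows.append({"subject": r.subject, "tp": r.tp, "fp_pre": r.fp_pre,
                     "fp_post": r.fp_post, "rejected": rej,
                     "rejection_rate": rejection_rate(rej, r.fp_pre)})
    df = pd.DataFrame(rows)
    total_rej = int(df.rejected.sum())
    total_pre = int(df.fp_pre.sum())
    agg = {"subject": "Average", "tp": int(df.tp.sum()),
           "fp_pre": total_pre, "fp_post": int(df.fp_post.sum()),
           "rejected": total_rej,
           "rejection_rate": rejection_rate(total_rej, total_pre)}
    return pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
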