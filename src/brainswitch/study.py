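"""End-to-end synthetic study harness.

One "subject" is a full protocol run on generated data: four
calibration sessions (MI + the three contamination paradigms), the
screening pipeline (ROI, band, template, non-ROI combination search),
and an online session scored with and without the non-ROI channels.
Used by the validation suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import synth
from .classifier import ClassifierConfig
from .engine import ablation_rejection
from .screening import run_calibration
from .signal_io import standard_montage

PARADIGMS = ("MI", "AEP", "VEP_AO", "VEP_NM")


def evaluate_subject(seed: int, n_trials: int = 30,
                     design: str = "online_healthy",
                     cfg: ClassifierConfig | None = None) -> dict:
    """Calibrate and score one synthetic subject.

    Returns the channel plan, the with/without non-ROI session results
    and the derived figures (sensitivity, FP counts, rejection rate,
    whether the true MI source channel was recovered).
    """
    cfg = cfg or ClassifierConfig()
    montage = standard_montage(
        "stroke" if design == "online_stroke" else "healthy")
    recordings = {}
    for i, paradigm in enumerate(PARADIGMS):
        rec, sched, _ = synth.generate_session(
            "calibration", paradigm, seed=seed * 10 + i, n_trials=n_trials,
            montage=montage)
        recordings[paradigm] = (rec, sched)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plan, tpl, _ = run_calibration(recordings, montage, cfg)
    online_rec, online_sched, truth = synth.generate_session(
        design, seed=seed * 10 + 7, n_trials=n_trials, montage=montage)
    with_nr, without, rejection = ablation_rejection(
        online_rec, online_sched, plan, tpl, cfg)
    true_source = synth.DEFAULT_SPECS["MI"].channel
    return {
        "seed": seed,
        "plan": plan,
        "template": tpl,
        "roi_recovered": plan.roi == true_source,
        "with_nonroi": with_nr,
        "without_nonroi": without,
        "rejection_rate": rejection,
        "sensitivity": with_nr.tp / with_nr.n_trials * 100.0,
        "n_contamination_events": sum(
            1 for _, kind, _ in truth.events if kind != "MI_ERD"),
    }


def summarize_study(results: list[dict]) -> dict:
    """Pooled study figures across seeds."""
    tp = sum(r["with_nonroi"].tp for r in results)
    trials = sum(r["with_nonroi"].n_trials for r in results)
    fp_with = sum(r["with_nonroi"].fp for r in results)
    fp_without = sum(r["without_nonroi"].fp for r in results)
    rest_min = sum(r["with_nonroi"].scored_rest_minutes for r in results)
    return {
        "n_subjects": len(results),
        "roi_recovery_pct": 100.0 * np.mean(
            [r["roi_recovered"] for r in results]),
        "sensitivity_pct": 100.0 * tp / trials,
        "fp_rate_pct": 100.0 * fp_with / trials,
        "fp_per_minute": fp_with / rest_min,
        "fp_with_nonroi": fp_with,
        "fp_without_nonroi": fp_without,
        "rejection_rate_pct": (
            100.0 * (fp_without - fp_with) / fp_without if fp_without
            else None),
    }
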