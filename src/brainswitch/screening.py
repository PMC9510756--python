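"""Calibration-time channel screening.

The subject-specific ROI channel is the channel with the deepest mean
task-interval ERSP across five mu/beta screening bands (8-12, 12-16,
16-20, 20-24, 24-28 Hz).  The subject's ERD band is then read off the
ROI channel's ERSP map as the contiguous frequency run reaching at least
half the depth of its deepest bin.  Contamination-source candidates are
localized the same way on the sensory-stimulation paradigms (AEP and the
two VEP variants), and the final non-ROI set is the candidate subset
that rejects the most false positives in an offline simulation of the
full two-phase classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .classifier import ClassifierConfig, Template
from .signal_io import EpochSet, EventSchedule, Montage, Recording
from .spectral import ERSPMap, band_topography, ersp

SCREENING_BANDS = [(8.0, 12.0), (12.0, 16.0), (16.0, 20.0),
                   (20.0, 24.0), (24.0, 28.0)]
TASK_INTERVAL = (0.0, 2.0)


class NoERDError(RuntimeError):
    """No channel showed negative mean task-interval ERSP in any band."""


@dataclass
class ChannelPlan:
    roi: str
    band: tuple[float, float]
    nonroi: list[str]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.roi in self.nonroi:
            raise ValueError("ROI channel cannot be a non-ROI channel")


@dataclass
class CandidateSet:
    """Per-paradigm ranked contamination-source candidates (most negative
    mean band ERSP first)."""

    per_paradigm: dict[str, list[tuple[str, float]]]

    def pool(self, exclude: tuple[str, ...] = ()) -> list[str]:
        """Deduplicated candidate labels, interleaved by rank."""
        out: list[str] = []
        ranked = list(self.per_paradigm.values())
        depth = max((len(v) for v in ranked), default=0)
        for k in range(depth):
            for chans in ranked:
                if k < len(chans) and chans[k][0] not in out \
                        and chans[k][0] not in exclude:
                    out.append(chans[k][0])
        return out


def select_roi(mi_epochs: EpochSet, montage: Montage,
               task_interval: tuple[float, float] = TASK_INTERVAL,
               min_depth_db: float = -1.5,
               ) -> tuple[str, dict]:
    """Pick the ROI channel: global argmin of mean task-interval ERSP
    over the five screening bands.

    The minimum must reach ``min_depth_db`` to count as ERD — noise
    alone leaves shallow (> -1 dB) minima, and accepting those would
    select an arbitrary channel.  Returns the channel label and a report
    containing the full ERSP map (reused by :func:`select_band`) plus
    per-band topographies.
    """
    if mi_epochs.n_trials < 2:
        raise ValueError("ROI screening needs at least 2 trials")
    for lab in mi_epochs.channel_labels:
        montage.position(lab)   # raises if unresolvable
    emap = ersp(mi_epochs)
    best: tuple[float, str, tuple[float, float]] | None = None
    topos = {}
    for band in SCREENING_BANDS:
        topo = band_topography(emap, band, task_interval)
        topos[band] = topo
        lab = min(topo, key=lambda l: (topo[l], l))
        if best is None or topo[lab] < best[0]:
            best = (topo[lab], lab, band)
    if best is None or best[0] > min_depth_db:
        raise NoERDError("no ERD found: no channel reaches "
                         f"{min_depth_db} dB mean task-interval ERSP in any "
                         "screening band")
    depth, roi, band = best
    return roi, {"ersp": emap, "band_topographies": topos,
                 "deepest_band": band, "roi_depth_db": depth}


def select_band(ersp_map: ERSPMap, roi: str,
                task_interval: tuple[float, float] = TASK_INTERVAL,
                depth_fraction: float = 0.5,
                min_width_hz: float = 3.0,
                envelope: tuple[float, float] = (8.0, 28.0),
                ) -> tuple[tuple[float, float], dict]:
    """Subject-specific ERD band at the ROI channel.

    Takes the contiguous frequency run (1-Hz grid) around the deepest
    bin whose task-interval mean ERSP reaches ``depth_fraction`` of the
    global minimum, widened to at least ``min_width_hz``.  As a
    double-check, the band topography over the returned band
    is recomputed and a warning (plus a diagnostics flag) is raised if
    the ROI is no longer the minimum channel.
    """
    ci = ersp_map.channel_index(roi)
    f_sel = (ersp_map.freqs >= envelope[0]) & (ersp_map.freqs <= envelope[1])
    t_sel = (ersp_map.times >= task_interval[0]) & (ersp_map.times < task_interval[1])
    freqs = ersp_map.freqs[f_sel]
    vals = ersp_map.power[ci][f_sel][:, t_sel].mean(axis=1)
    imin = int(np.argmin(vals))
    if vals[imin] >= 0:
        raise NoERDError(f"ROI channel {roi!r} shows no ERD in the envelope")
    thr = depth_fraction * vals[imin]
    keep = vals <= thr
    lo = hi = imin
    while lo > 0 and keep[lo - 1]:
        lo -= 1
    while hi < len(vals) - 1 and keep[hi + 1]:
        hi += 1
    # widen a too-narrow run toward the deeper neighbour
    while freqs[hi] - freqs[lo] < min_width_hz and (lo > 0 or hi < len(vals) - 1):
        left = vals[lo - 1] if lo > 0 else np.inf
        right = vals[hi + 1] if hi < len(vals) - 1 else np.inf
        if left <= right:
            lo -= 1
        else:
            hi += 1
    band = (float(freqs[lo]), float(freqs[hi]))
    topo = band_topography(ersp_map, band, task_interval)
    verified = min(topo, key=lambda l: (topo[l], l)) == roi
    if not verified:
        warnings.warn(f"band double-check failed: {roi!r} is not the minimum "
                      f"of the {band} Hz topography", RuntimeWarning)
    return band, {"band_values": dict(zip(freqs, vals)), "verified": verified,
                  "threshold_db": float(thr)}


def find_candidates(contamination_epochs: dict[str, EpochSet],
                    band: tuple[float, float], top_k: int = 2,
                    task_interval: tuple[float, float] = TASK_INTERVAL,
                    ) -> CandidateSet:
    """Rank contamination-source candidates per paradigm.

    Channels are ranked by mean task-interval ERSP in the subject's ERD
    band (most negative first, ties by label); the ``top_k`` channels
    with negative values are retained.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for paradigm, epochs in contamination_epochs.items():
        if epochs.n_trials < 2:
            raise ValueError(f"paradigm {paradigm!r} needs at least 2 trials")
        topo = band_topography(ersp(epochs), band, task_interval)
        ranked = sorted(topo.items(), key=lambda kv: (kv[1], kv[0]))
        negative = [(l, float(v)) for l, v in ranked if v < 0][:top_k]
        if not negative:
            warnings.warn(f"paradigm {paradigm!r}: no channel shows negative "
                          "band ERSP; empty candidate list", RuntimeWarning)
        out[paradigm] = negative
    return CandidateSet(out)


def search_nonroi(mi_session: tuple[Recording, EventSchedule],
                  contamination_sessions: list[tuple[Recording, EventSchedule]],
                  roi: str, band: tuple[float, float],
                  candidates: CandidateSet, tpl: Template,
                  cfg: ClassifierConfig | None = None,
                  max_size: int = 3, refractory_s: float = 3.0,
                  ) -> tuple[list[str], dict]:
    """Exhaustive offline search for the best non-ROI combination.

    Every candidate subset of size 1..``max_size`` is simulated with the
    full two-phase classifier over the contamination-paradigm sessions;
    the subset rejecting the largest fraction of the baseline (no
    non-ROI) detections wins.  Ties break toward higher selectivity on
    the MI session, then the smaller subset, then label order.
    """
    from . import metrics
    from .engine import SessionEvaluator

    cfg = cfg or ClassifierConfig()
    pool = candidates.pool(exclude=(roi,))
    if not pool:
        raise ValueError("candidate set is empty")
    channels = [roi] + pool
    cont_evs = [SessionEvaluator(rec, sched, band, channels, cfg)
                for rec, sched in contamination_sessions]
    mi_ev = SessionEvaluator(mi_session[0], mi_session[1], band, channels, cfg)

    def spurious(nonroi: list[str]) -> int:
        # every detection in a contamination session is a false detection
        total = 0
        for ev in cont_evs:
            res = ev.evaluate(roi, nonroi, tpl, refractory_s=refractory_s)
            total += res.tp + res.fp
        return total

    def mi_selectivity(nonroi: list[str]) -> float:
        res = mi_ev.evaluate(roi, nonroi, tpl, refractory_s=refractory_s)
        return metrics.selectivity(res.tp, res.fp) if res.tp + res.fp else 0.0

    fp_baseline = spurious([])
    subsets = [list(c) for size in range(1, max_size + 1)
               for c in combinations(pool, size)]
    table = []
    best = None
    for sub in subsets:
        fp_s = spurious(sub)
        rejected = fp_baseline - fp_s
        rej_rate = metrics.rejection_rate(rejected, fp_baseline) \
            if fp_baseline else 0.0
        sel = mi_selectivity(sub)
        key = (rej_rate, sel, -len(sub), [pool.index(c) for c in sub])
        table.append({"subset": sub, "spurious": fp_s,
                      "rejection_rate": rej_rate, "mi_selectivity": sel})
        if best is None or key > best[0]:
            best = (key, sub)
    assert best is not None
    if fp_baseline == 0 or best[0][0] == 0:
        warnings.warn("no candidate subset rejects any false positives; "
                      "returning the highest-selectivity subset", RuntimeWarning)
        best = max(((mi_selectivity(s), -len(s), s) for s in subsets),
                   key=lambda t: (t[0], t[1]))
        chosen = best[2]
    else:
        chosen = best[1]
    return chosen, {"baseline_spurious": fp_baseline, "search": table}


def run_calibration(recordings: dict[str, tuple[Recording, EventSchedule]],
                    montage: Montage, cfg: ClassifierConfig | None = None,
                    top_k: int = 2, max_size: int = 3,
                    ) -> tuple[ChannelPlan, Template, dict]:
    """Full calibration pipeline from the four paradigm sessions.

    ``recordings`` maps paradigm labels (``MI``, ``AEP``, ``VEP_AO``,
    ``VEP_NM``) to (recording, schedule).  Returns the channel plan, the
    phase-2 template and a diagnostics dict.  The training template is
    extracted with the full candidate pool as non-ROI comparisons, since
    the final subset is itself chosen with this template.
    """
    from .classifier import extract_training
    from .signal_io import extract_epochs
    from .spectral import bandpass, resample

    cfg = cfg or ClassifierConfig()
    if "MI" not in recordings:
        raise ValueError("calibration needs an MI session")
    mi_rec, mi_sched = recordings["MI"]
    mi64 = resample(mi_rec, cfg.rate)
    mi_epochs = extract_epochs(mi64, mi_sched, None, (-4.0, 4.0))
    roi, report = select_roi(mi_epochs, montage)
    band, band_diag = select_band(report["ersp"], roi)
    cont = {p: rs for p, rs in recordings.items() if p != "MI"}
    cont_epochs = {p: extract_epochs(resample(rec, cfg.rate), sched, None,
                                     (-4.0, 4.0))
                   for p, (rec, sched) in cont.items()}
    candidates = find_candidates(cont_epochs, band, top_k=top_k)
    mi_filt = bandpass(mi64, band)
    ep_filt = extract_epochs(mi_filt, mi_sched, None, (-4.0, 4.0))
    pool = candidates.pool(exclude=(roi,))
    tpl = extract_training(ep_filt, roi, pool, cfg)
    nonroi, search_diag = search_nonroi(
        (mi_rec, mi_sched), list(cont.values()), roi, band, candidates, tpl,
        cfg, max_size=max_size)
    plan = ChannelPlan(roi, band, nonroi, diagnostics={
        "roi_depth_db": report["roi_depth_db"],
        "deepest_band": report["deepest_band"],
        "band": band_diag, "candidates": candidates.per_paradigm,
        "search": search_diag})
    return plan, tpl, plan.diagnostics
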