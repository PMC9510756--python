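"""Asynchronous session simulation.

A session recording is resampled to the working rate, band-filtered to
the subject's ERD band, and scanned with 3-s windows advancing one
sample at a time.  Each window position is pushed through the two-phase
classifier; a positive decision emits a detection stamped at the window
*end* (the most recent sample, matching the latency-minimizing design of
the hind-area trough) and starts a post-detection refractory during
which the detector is offline.

Scoring follows the block design: a detection ending inside a task
period is a true positive (at most one per task period), inside a rest
period a false positive, and inside a scheduled cool-down interval it is
recorded but ignored.

The online RP baseline for each window is the trailing mean band power
over the 2 s preceding the window start, frozen (carried forward) while
the start lies in a task or cool-down period so that feedback-evoked
activity cannot corrupt the reference.

All heavy per-window quantities (front/hind means, hind trough, template
correlations at every lag) are computed once per channel for every
window position, so re-evaluating the same session with a different
non-ROI subset or Pearson threshold — the inner loop of the non-ROI
combination search and of threshold recalibration — costs almost
nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

from .classifier import ClassifierConfig, Template
from .signal_io import EventSchedule, Recording
from .spectral import bandpass, moving_average_power, resample

STATE_REST, STATE_TASK, STATE_COOLDOWN = 0, 1, 2


@dataclass
class Detection:
    """One emitted detection; ``label`` is TP, FP or ignored_cooldown."""

    time: float
    label: str
    r: float = np.nan
    cc_max: float = np.nan
    cc_lat: float = np.nan

    def to_dict(self) -> dict:
        return {"time": round(self.time, 6), "label": self.label,
                "r": round(float(self.r), 9),
                "cc_max": round(float(self.cc_max), 9),
                "cc_lat": round(float(self.cc_lat), 6)}


@dataclass
class SessionResult:
    detections: list[Detection]
    n_trials: int
    tp: int
    fp: int
    n_ignored: int
    scored_rest_minutes: float
    n_positive_windows: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tp > self.n_trials:
            raise ValueError("more TPs than task periods")
        labels = [d.label for d in self.detections]
        counted = (labels.count("TP"), labels.count("FP"))
        if counted != (self.tp, self.fp):
            raise ValueError("counts inconsistent with detection labels")

    def to_json(self) -> str:
        """Stable serialization (used by the determinism guarantee)."""
        payload = {
            "n_trials": self.n_trials, "tp": self.tp, "fp": self.fp,
            "n_ignored": self.n_ignored,
            "scored_rest_minutes": round(self.scored_rest_minutes, 6),
            "detections": [d.to_dict() for d in self.detections],
            "meta": self.meta,
        }
        return json.dumps(payload, sort_keys=True)


class SessionEvaluator:
    """Per-channel feature bank for one recording + schedule + band.

    Build once, then call :meth:`evaluate` for any ROI / non-ROI subset /
    threshold combination.
    """

    def __init__(self, rec: Recording, sched: EventSchedule,
                 band: tuple[float, float], channels: list[str],
                 cfg: ClassifierConfig | None = None,
                 smooth_s: float = 0.25) -> None:
        self.cfg = cfg or ClassifierConfig()
        self.sched = sched
        rate = self.cfg.rate
        if sched.session_dur > rec.duration + 1e-9:
            raise ValueError("schedule extends past the recording")
        work = rec.pick(list(dict.fromkeys(channels)))
        if abs(work.rate - rate) > 1e-9:
            work = resample(work, rate)
        work = bandpass(work, band)
        self.band = band
        self.labels = list(work.channel_labels)
        self.power = moving_average_power(work.samples, rate, smooth_s)
        n = self.power.shape[1]
        nwin, L = self.cfg.n_window, self.cfg.n_lag
        nbase = int(round(2.0 * rate))
        s0, s1 = max(nbase, L), n - nwin - L
        if s1 < s0:
            raise ValueError("recording too short for a single window")
        self.starts = np.arange(s0, s1 + 1, self.cfg.n_step)
        start_states = sched.classify_times(self.starts / rate)
        self._rest_start = start_states == STATE_REST
        self.end_times = (self.starts + nwin) / rate
        self.end_states = sched.classify_times(self.end_times)
        self._nbase = nbase
        self._feat: dict[str, dict[str, np.ndarray]] = {}
        self._corr: dict[str, tuple[int, tuple]] = {}

    # -- per-channel caches -------------------------------------------------

    def _baseline(self, p: np.ndarray) -> np.ndarray:
        cs = np.concatenate(([0.0], np.cumsum(p)))
        raw = (cs[self.starts] - cs[self.starts - self._nbase]) / self._nbase
        # freeze outside rest: carry the last rest-time value forward
        idx = np.where(self._rest_start, np.arange(len(raw)), -1)
        idx = np.maximum.accumulate(idx)
        frozen = raw.copy()
        ok = idx >= 0
        frozen[ok] = raw[idx[ok]]
        return frozen

    def features(self, label: str) -> dict[str, np.ndarray]:
        """Phase-1 feature arrays over every window position."""
        if label in self._feat:
            return self._feat[label]
        cfg = self.cfg
        p = self.power[self.labels.index(label)]
        nwin, split = cfg.n_window, cfg.n_split
        nh = nwin - split
        cs = np.concatenate(([0.0], np.cumsum(p)))
        s = self.starts
        front_mean = (cs[s + split] - cs[s]) / split
        hind_mean = (cs[s + nwin] - cs[s + split]) / nh
        hind = sliding_window_view(p, nh)[s + split]
        argmin = hind.argmin(axis=1)
        hind_min = hind[np.arange(len(s)), argmin]
        B = self._baseline(p)
        to_rp = lambda v: (v - B) / B * 100.0
        peak = to_rp(hind_min)
        mean_fw = to_rp(front_mean)
        mean_hw = to_rp(hind_mean)
        t_ph = (split + argmin) / cfg.rate
        dt = t_ph - cfg.split_s
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(dt > 0, (peak - mean_fw) / np.maximum(dt, 1e-300),
                             np.copysign(np.inf, peak - mean_fw))
        slope = np.where((dt == 0) & (peak == mean_fw), 0.0, slope)
        feat = {"peak_hw": peak, "mean_fw": mean_fw, "mean_hw": mean_hw,
                "d_mean": mean_fw - mean_hw, "t_ph": t_ph,
                "theta": np.arctan(slope)}
        self._feat[label] = feat
        return feat

    def correlations(self, label: str, tpl: Template) -> tuple:
        """(r, cc_max, cc_lat) arrays over every window position."""
        key = self._corr.get(label)
        if key is not None and key[0] == id(tpl):
            return key[1]
        cfg = self.cfg
        p = self.power[self.labels.index(label)]
        t = np.asarray(tpl.values, dtype=float)
        n, L = cfg.n_window, cfg.n_lag
        dots = fftconvolve(p, t[::-1], mode="valid")        # dot at every offset
        cs = np.concatenate(([0.0], np.cumsum(p)))
        cs2 = np.concatenate(([0.0], np.cumsum(p * p)))
        wsum = cs[n:] - cs[:-n]
        wsq = cs2[n:] - cs2[:-n]
        mt = t.mean()
        denom_t = np.sqrt(max(((t - mt) ** 2).sum(), 0.0))
        varx = np.maximum(wsq - wsum ** 2 / n, 0.0)
        denom_x = np.sqrt(varx)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_off = (dots - wsum * mt) / (denom_x * denom_t)
        r_off[(denom_x < 1e-12) | ~np.isfinite(r_off)] = 0.0
        r0 = r_off[self.starts]
        lag_win = sliding_window_view(r_off, 2 * L + 1)[self.starts - L]
        lags = np.arange(-L, L + 1)
        order = np.argsort(np.abs(lags) * 1000 + lags, kind="stable")
        ordered = lag_win[:, order]
        best = ordered.argmax(axis=1)                        # smallest |lag| on ties
        cc_max = ordered[np.arange(len(best)), best]
        cc_lat = lags[order][best] / cfg.rate
        out = (r0, cc_max, cc_lat)
        self._corr[label] = (id(tpl), out)
        return out

    # -- decision -----------------------------------------------------------

    def positive_mask(self, roi: str, nonroi: list[str], tpl: Template,
                      r_threshold: float | None = None) -> np.ndarray:
        """Boolean mask of window positions passing both phases (before
        any cool-down/refractory bookkeeping)."""
        cfg = self.cfg
        thr = cfg.r_threshold if r_threshold is None else r_threshold
        f = self.features(roi)
        mask = (f["peak_hw"] < 0) & (f["theta"] < 0)
        if cfg.require_negative_mean_hw:
            mask &= f["mean_hw"] < 0
        for lab in nonroi:
            g = self.features(lab)
            mask &= ((f["peak_hw"] < g["peak_hw"])
                     & (f["mean_hw"] < g["mean_hw"])
                     & (f["d_mean"] > g["d_mean"])
                     & (f["theta"] < g["theta"]))
        r0, cc_max, cc_lat = self.correlations(roi, tpl)
        mask &= (r0 >= thr) & (np.abs(cc_lat) <= cfg.lag_tol_s + 1e-12)
        for lab in nonroi:
            rn, ccn, _ = self.correlations(lab, tpl)
            mask &= (r0 > rn) & (cc_max > ccn)
        return mask

    def evaluate(self, roi: str, nonroi: list[str], tpl: Template,
                 r_threshold: float | None = None,
                 refractory_s: float = 3.0) -> SessionResult:
        mask = self.positive_mask(roi, nonroi, tpl, r_threshold)
        r0, cc_max, cc_lat = self.correlations(roi, tpl)
        pos = np.flatnonzero(mask)
        detections: list[Detection] = []
        credited: set[int] = set()
        task_starts = np.array([a for a, _ in self.sched.task_intervals()])
        next_free = -np.inf
        tp = fp = ignored = 0
        for i in pos:
            t_end = self.end_times[i]
            if t_end < next_free:        # post-detection refractory: offline
                continue
            state = self.end_states[i]
            det = Detection(t_end, "", float(r0[i]), float(cc_max[i]),
                            float(cc_lat[i]))
            if state == STATE_COOLDOWN:
                det.label = "ignored_cooldown"
                ignored += 1
            elif state == STATE_TASK:
                k = int(np.searchsorted(task_starts, t_end, side="right") - 1)
                if k in credited:
                    det.label = "ignored_cooldown"
                    ignored += 1
                else:
                    credited.add(k)
                    det.label = "TP"
                    tp += 1
                next_free = t_end + refractory_s
            else:
                det.label = "FP"
                fp += 1
                next_free = t_end + refractory_s
            detections.append(det)
        thr = self.cfg.r_threshold if r_threshold is None else r_threshold
        return SessionResult(
            detections, self.sched.n_trials, tp, fp, ignored,
            self.sched.scored_rest_seconds() / 60.0,
            n_positive_windows=int(mask.sum()),
            meta={"roi": roi, "nonroi": list(nonroi),
                  "band": list(self.band), "r_threshold": thr,
                  "refractory_s": refractory_s})


def run_session(rec: Recording, sched: EventSchedule, plan, tpl: Template,
                cfg: ClassifierConfig | None = None,
                refractory_s: float = 3.0) -> SessionResult:
    """Simulate one asynchronous session under a channel plan.

    ``plan`` needs ``roi``, ``band`` and ``nonroi`` attributes (a
    :class:`brainswitch.screening.ChannelPlan`).
    """
    ev = SessionEvaluator(rec, sched, plan.band,
                          [plan.roi] + list(plan.nonroi), cfg)
    return ev.evaluate(plan.roi, list(plan.nonroi), tpl,
                       refractory_s=refractory_s)


def ablation_rejection(rec: Recording, sched: EventSchedule, plan,
                       tpl: Template, cfg: ClassifierConfig | None = None,
                       refractory_s: float = 3.0):
    """Simulate with and without the non-ROI channels.

    Returns ``(result_with, result_without, rejection_rate)`` where the
    rejection rate is ``(fp_without - fp_with) / fp_without * 100`` and
    ``None`` (not applicable) when the ablated run produced no FPs.
    """
    ev = SessionEvaluator(rec, sched, plan.band,
                          [plan.roi] + list(plan.nonroi), cfg)
    with_nr = ev.evaluate(plan.roi, list(plan.nonroi), tpl,
                          refractory_s=refractory_s)
    without = ev.evaluate(plan.roi, [], tpl, refractory_s=refractory_s)
    if without.fp == 0:
        return with_nr, without, None
    rate = (without.fp - with_nr.fp) / without.fp * 100.0
    return with_nr, without, rate
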