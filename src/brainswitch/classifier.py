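"""Two-phase ERD classifier.

Phase 1 screens each 3-s relative-potential (RP) window with hand-crafted
shape features: the window is split into a front ("rest-like") area and a
hind area; a promising motor-imagery ERD must carry its negative trough in
the hind area and, compared with every non-ROI channel, show the deeper
trough, the lower hind-area mean, the larger front-to-hind drop and the
steeper decline angle

    theta_ERD = atan( (Peak_HW - Mean_FW) / (t_PH - t_FW) )

with the numerator in RP percent and the denominator in seconds (no
rescaling: only cross-channel comparisons at identical window geometry are
made).

Phase 2 accepts a phase-1 window only when it resembles the subject's
averaged training ERD: the zero-lag Pearson correlation with the template
must reach a threshold, the cross-correlation peak must sit within a small
lag, and both the peak cross-correlation and the Pearson correlation on the
ROI must exceed those of every non-ROI channel.  Correlation features are
amplitude-scale invariant, so rejection relies purely on shape similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import atan

import numpy as np

from .signal_io import EpochSet
from .spectral import RPWindow, moving_average_power

# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass
class ClassifierConfig:
    """Window geometry and phase-2 thresholds.

    All durations in seconds at the working rate (64 Hz by default):
    3-s window split at 2 s into front [0, 2) and hind [2, 3) areas,
    nominal 20-ms sliding step, Pearson threshold ``r_threshold``
    (runtime-adjustable), cross-correlation lag search +-0.5 s with a
    +-0.25 s acceptance tolerance.
    """

    rate: float = 64.0
    window_s: float = 3.0
    split_s: float = 2.0
    step_s: float = 0.02
    r_threshold: float = 0.7
    lag_search_s: float = 0.5
    lag_tol_s: float = 0.25
    require_negative_mean_hw: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.split_s < self.window_s:
            raise ValueError("front/hind split must lie inside the window")
        if not 0 < self.lag_tol_s <= self.lag_search_s:
            raise ValueError("lag tolerance must be within the lag search range")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")

    @property
    def n_window(self) -> int:
        return int(round(self.window_s * self.rate))

    @property
    def n_split(self) -> int:
        return int(round(self.split_s * self.rate))

    @property
    def n_step(self) -> int:
        # 20 ms is incommensurate with 64 Hz; realized as >= 1 sample
        return max(1, int(round(self.step_s * self.rate)))

    @property
    def n_lag(self) -> int:
        return int(round(self.lag_search_s * self.rate))


@dataclass
class WindowFeatures:
    """Phase-1 shape features of one RP window (percent / seconds)."""

    peak_hw: float
    t_ph: float
    mean_fw: float
    mean_hw: float
    d_mean: float
    theta_erd: float
    t_fw: float


@dataclass
class CorrelationFeatures:
    """Phase-2 similarity features against the training template."""

    cc_max: float
    cc_lat: float
    r: float
    degenerate: bool = False


@dataclass
class Template:
    """Pointwise mean of the accepted training RP windows."""

    values: np.ndarray
    rate: float = 64.0
    n_windows: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_windows < 1:
            raise ValueError("template needs at least one training window")


# ---------------------------------------------------------------------------
# phase 1
# ---------------------------------------------------------------------------


def window_features(w: RPWindow | np.ndarray,
                    cfg: ClassifierConfig) -> WindowFeatures:
    """Shape features of one window: trough depth/time in the hind area,
    front/hind means, their difference and the decline angle."""
    x = w.values if isinstance(w, RPWindow) else np.asarray(w, dtype=float)
    if len(x) != cfg.n_window:
        raise ValueError(f"window length {len(x)} != configured {cfg.n_window}")
    split = cfg.n_split
    front, hind = x[:split], x[split:]
    k = int(np.argmin(hind))            # earliest sample on ties
    peak_hw = float(hind[k])
    t_ph = (split + k) / cfg.rate
    mean_fw = float(front.mean())
    mean_hw = float(hind.mean())
    t_fw = cfg.split_s
    dt = t_ph - t_fw
    slope = (peak_hw - mean_fw) / dt if dt > 0 else np.copysign(
        np.inf, peak_hw - mean_fw) if peak_hw != mean_fw else 0.0
    return WindowFeatures(peak_hw, t_ph, mean_fw, mean_hw,
                          mean_fw - mean_hw, atan(slope), t_fw)


def phase1_decision(f_roi: WindowFeatures,
                    f_nonroi: list[WindowFeatures],
                    cfg: ClassifierConfig | None = None) -> bool:
    """True iff the ROI window looks like MI ERD *and* out-desynchronizes
    every non-ROI window.

    An empty non-ROI list degrades to the ROI-only conditions (used by
    the rejection-ablation study).
    """
    require_mean = cfg.require_negative_mean_hw if cfg is not None else True
    split = cfg.split_s if cfg is not None else f_roi.t_fw
    window = cfg.window_s if cfg is not None else 3.0
    if not (f_roi.peak_hw < 0 and f_roi.theta_erd < 0):
        return False
    if not (split <= f_roi.t_ph < window):
        return False
    if require_mean and not f_roi.mean_hw < 0:
        return False
    for f in f_nonroi:
        if not (f_roi.peak_hw < f.peak_hw
                and f_roi.mean_hw < f.mean_hw
                and f_roi.d_mean > f.d_mean
                and f_roi.theta_erd < f.theta_erd):
            return False
    return True


# ---------------------------------------------------------------------------
# phase 2
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def correlation_features(w: RPWindow | np.ndarray, tpl: Template,
                         cfg: ClassifierConfig) -> CorrelationFeatures:
    """Normalized cross-correlation of a window against the template.

    ``w`` may be the bare 3-s window (lags evaluated on the truncated
    overlap) or an extended segment of length ``n_window + 2*n_lag``
    centered on the window, in which case each lag compares a fully
    populated shifted window — the mode the session engine uses.

    The zero lag is part of the search, so ``cc_max >= r`` always holds.
    On ties the smallest ``|lag|`` wins.  A zero-variance window or
    template yields ``cc_max = r = 0`` with ``degenerate=True``.
    """
    x = w.values if isinstance(w, RPWindow) else np.asarray(w, dtype=float)
    t = tpl.values
    n, L = cfg.n_window, cfg.n_lag
    if len(t) != n:
        raise ValueError("template length does not match the window config")
    extended = len(x) == n + 2 * L
    if not extended and len(x) != n:
        raise ValueError(f"window length {len(x)} is neither {n} nor {n + 2 * L}")
    centre = x[L:L + n] if extended else x
    if centre.std() == 0 or t.std() == 0:
        return CorrelationFeatures(0.0, 0.0, 0.0, degenerate=True)
    r = _pearson(centre, t)
    best, best_lag = -np.inf, 0
    for lag in sorted(range(-L, L + 1), key=lambda l: (abs(l), l)):
        if extended:
            cc = _pearson(x[L + lag:L + lag + n], t)
        elif lag >= 0:
            cc = _pearson(x[lag:], t[:n - lag]) if lag < n else 0.0
        else:
            cc = _pearson(x[:n + lag], t[-lag:])
        if cc > best:
            best, best_lag = cc, lag
    return CorrelationFeatures(float(best), best_lag / cfg.rate, r)


def phase2_decision(c_roi: CorrelationFeatures,
                    c_nonroi: list[CorrelationFeatures],
                    cfg: ClassifierConfig) -> bool:
    """True iff the ROI window matches the template (small lag, Pearson
    above threshold) and is more template-like than every non-ROI window."""
    if abs(c_roi.cc_lat) > cfg.lag_tol_s + 1e-12:
        return False
    if c_roi.r < cfg.r_threshold:
        return False
    for c in c_nonroi:
        if not (c_roi.cc_max > c.cc_max and c_roi.r > c.r):
            return False
    return True


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class NoTrainingWindowsError(RuntimeError):
    pass


def extract_training(mi_epochs: EpochSet, roi: str, nonroi: list[str],
                     cfg: ClassifierConfig,
                     trough_range: tuple[float, float] = (0.0, 2.0),
                     smooth_s: float = 0.25,
                     min_peak_pct: float = -20.0) -> Template:
    """Build the phase-2 template from band-filtered MI epochs.

    Slides 3-s windows over each -4..+4 s epoch (band power against the
    cue-locked -4..-2 s baseline), keeps windows that pass phase 1 with
    their hind-area trough inside ``(0, 2]`` s post-cue, retains at most
    the deepest-trough window per trial, and averages the kept ROI RP
    windows pointwise.

    ``min_peak_pct`` demands a genuine ERD exemplar: the trough must
    reach at least that much desynchronization (default -20 % of
    baseline), so sign-level noise dips never enter the template.
    """
    if abs(mi_epochs.rate - cfg.rate) > 1e-9:
        raise ValueError("epochs must be resampled to the classifier rate")
    rate = cfg.rate
    nwin, nstep = cfg.n_window, cfg.n_step
    ri = mi_epochs.channel_index(roi)
    nr_idx = [mi_epochs.channel_index(l) for l in nonroi]
    cue = mi_epochs.cue_index
    base_lo = cue - int(round(4 * rate))
    base_hi = cue - int(round(2 * rate))
    kept: list[np.ndarray] = []
    for trial in mi_epochs.epochs:
        p = moving_average_power(trial, rate, smooth_s)
        base = p[:, base_lo:base_hi].mean(axis=1)
        if np.any(base <= 0):
            continue
        rp = (p - base[:, None]) / base[:, None] * 100.0
        best_peak, best_win = np.inf, None
        for s in range(0, trial.shape[1] - nwin + 1, nstep):
            f_roi = window_features(rp[ri, s:s + nwin], cfg)
            if f_roi.peak_hw > min_peak_pct:
                continue
            trough_t = (s + f_roi.t_ph * rate - cue) / rate
            if not trough_range[0] < trough_t <= trough_range[1]:
                continue
            f_nr = [window_features(rp[j, s:s + nwin], cfg) for j in nr_idx]
            if not phase1_decision(f_roi, f_nr, cfg):
                continue
            if f_roi.peak_hw < best_peak:
                best_peak, best_win = f_roi.peak_hw, rp[ri, s:s + nwin].copy()
        if best_win is not None:
            kept.append(best_win)
    if not kept:
        raise NoTrainingWindowsError(
            "no training windows passed phase 1 with a 0-2 s post-cue trough; "
            "review the frequency band and ROI choice")
    return Template(np.mean(kept, axis=0), rate, len(kept),
                    meta={"n_trials": mi_epochs.n_trials, "roi": roi,
                          "nonroi": list(nonroi)})


def calibrate_threshold(rec, sched, plan, tpl: Template, cfg: ClassifierConfig,
                        sensitivity_floor: float = 20.0,
                        grid: np.ndarray | None = None) -> float:
    """Recalibrate the phase-2 Pearson threshold on a practice session.

    Grid-searches r_threshold in [0.3, 0.95] (step 0.05) and returns the
    value maximizing selectivity subject to sensitivity >= the floor;
    ties go to the larger (more conservative) threshold.  If no value
    meets the floor the prior threshold is kept, with a warning.
    """
    from . import metrics
    from .engine import SessionEvaluator

    if grid is None:
        grid = np.round(np.arange(0.30, 0.9501, 0.05), 2)
    ev = SessionEvaluator(rec, sched, plan.band,
                          [plan.roi] + list(plan.nonroi), cfg)
    best: tuple[float, float] | None = None
    for thr in grid:
        res = ev.evaluate(plan.roi, list(plan.nonroi), tpl, r_threshold=float(thr))
        sens = metrics.sensitivity(res.tp, res.n_trials)
        if sens < sensitivity_floor or res.tp + res.fp == 0:
            continue
        sel = metrics.selectivity(res.tp, res.fp)
        if best is None or sel >= best[0]:
            best = (sel, float(thr))
    if best is None:
        warnings.warn("no threshold met the sensitivity floor; keeping the "
                      "calibration-day threshold", RuntimeWarning)
        return cfg.r_threshold
    return best[1]
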