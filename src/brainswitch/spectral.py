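"""Spectral preprocessing: resampling, band-pass filtering, band-power
envelopes, the relative-potential (RP) transform and baseline-corrected
event-related spectral perturbation (ERSP).

The RP of a band-power series ``A`` against a baseline power ``R`` is

    RP = (A - R) / R * 100   [% of baseline]

so an amplitude halving of the underlying oscillation (power quartered)
reads as RP = -75 %.  ERSP maps are expressed in dB relative to the
pre-stimulus baseline; event-related desynchronization (ERD) shows up as
negative dB / negative RP.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .signal_io import EpochSet, Recording

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PowerSeries:
    """Smoothed band power over time for one channel (uV^2)."""

    values: np.ndarray
    rate: float
    band: tuple[float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("band power must be non-negative")


@dataclass
class RPWindow:
    """Relative potential (% of baseline) over one 3-s window."""

    values: np.ndarray
    rate: float
    channel: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RP window contains non-finite values")


@dataclass
class ERSPMap:
    """Baseline-corrected time-frequency map, ``power[channel, freq, time]``
    in dB relative to the pre-stimulus baseline."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    baseline: tuple[float, float] = (-4.0, -2.0)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in ERSP map") from None

    def to_frame(self):
        """Long-format TSV-ready table (channel, freq, time, dB)."""
        import pandas as pd

        ch, fr, ti = np.meshgrid(np.arange(len(self.channel_labels)),
                                 self.freqs, self.times, indexing="ij")
        return pd.DataFrame({
            "channel": np.asarray(self.channel_labels)[ch.ravel()],
            "freq_hz": fr.ravel(), "time_s": ti.ravel(),
            "ersp_db": self.power.ravel(),
        })


# ---------------------------------------------------------------------------
# resampling / filtering
# ---------------------------------------------------------------------------


def resample(rec: Recording, target_rate: float) -> Recording:
    """Polyphase resampling (anti-alias filtered on downsampling).

    Duration is preserved within one sample of the target rate.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.rate:
        return rec.copy()
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator,
                            axis=1)
    n_target = int(round(rec.n_samples * target_rate / rec.rate))
    out = out[:, :n_target]
    return Recording(out, target_rate, list(rec.channel_labels))


def bandpass(rec: Recording, band: tuple[float, float], order: int = 4) -> Recording:
    """Zero-phase band-pass (forward-backward 4th-order Butterworth).

    Zero phase protects the latency features of the classifier (the
    trough timing and the cross-correlation lag).
    """
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi:
        raise ValueError(f"invalid band ordering {band}")
    if f_hi >= rec.rate / 2:
        raise ValueError(f"band {band} reaches the Nyquist rate {rec.rate / 2}")
    sos = sps.butter(order, band, btype="bandpass", fs=rec.rate, output="sos")
    out = sps.sosfiltfilt(sos, rec.samples, axis=1)
    return Recording(out, rec.rate, list(rec.channel_labels))


# ---------------------------------------------------------------------------
# band power / relative potential
# ---------------------------------------------------------------------------


def moving_average_power(x: np.ndarray, rate: float,
                         smooth_s: float = 0.25) -> np.ndarray:
    """Square the signal and smooth with a centered moving average of
    ``smooth_s`` seconds (applied along the last axis)."""
    if smooth_s < 0:
        raise ValueError("smooth_s must be >= 0")
    p = np.asarray(x, dtype=float) ** 2
    size = max(1, int(round(smooth_s * rate)))
    if size > 1:
        p = uniform_filter1d(p, size=size, axis=-1, mode="nearest")
    return p


def band_power(rec_filtered: Recording, smooth_s: float = 0.25,
               band: tuple[float, float] = (0.0, 0.0)) -> list[PowerSeries]:
    """Per-channel smoothed band power of an already band-filtered recording."""
    p = moving_average_power(rec_filtered.samples, rec_filtered.rate, smooth_s)
    return [PowerSeries(p[i], rec_filtered.rate, band, label)
            for i, label in enumerate(rec_filtered.channel_labels)]


def relative_potential(power: PowerSeries | np.ndarray,
                       baseline_power: float) -> np.ndarray:
    """RP = (A - R) / R * 100, pointwise, in percent of baseline power."""
    if baseline_power <= 0:
        raise ValueError("baseline power must be positive")
    a = power.values if isinstance(power, PowerSeries) else np.asarray(power, float)
    return (a - baseline_power) / baseline_power * 100.0


# ---------------------------------------------------------------------------
# ERSP
# ---------------------------------------------------------------------------

def _stft_power(x: np.ndarray, rate: float, freqs: np.ndarray,
                win_s: float, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered short-time DFT power of ``x[..., time]``.

    Returns ``(power[..., freq, frame], frame_offsets)`` where frame
    offsets are the window-center sample indices.
    """
    n_win = int(round(win_s * rate))
    if x.shape[-1] < n_win:
        raise ValueError("segment shorter than the STFT window")
    taper = sps.windows.hann(n_win, sym=False)
    frames = sliding_window_view(x, n_win, axis=-1)[..., ::hop, :]
    spec = np.fft.rfft(frames * taper, axis=-1)
    fft_freqs = np.fft.rfftfreq(n_win, d=1.0 / rate)
    bins = np.array([int(np.argmin(np.abs(fft_freqs - f))) for f in freqs])
    power = np.abs(spec[..., bins]) ** 2
    # [..., frame, freq] -> [..., freq, frame]
    power = np.moveaxis(power, -1, -2)
    offsets = np.arange(frames.shape[-2]) * hop + n_win / 2.0
    return power, offsets


def ersp(epochs: EpochSet, freqs: np.ndarray | None = None,
         baseline: tuple[float, float] = (-4.0, -2.0),
         win_s: float = 1.0, overlap: float = 0.97) -> ERSPMap:
    """Trial-averaged, baseline-corrected spectral perturbation.

    Time-frequency power comes from a short-time DFT with Hann-tapered
    1-s windows (97 % overlap by default; at 64 Hz the frequency grid is
    an exact 1-Hz comb).  Per channel and frequency the trial-averaged
    power is divided by the geometric-mean power over the pre-stimulus
    ``baseline`` interval and expressed as ``10*log10``, so the
    baseline-interval mean of the map is 0 dB by construction.
    """
    if freqs is None:
        freqs = np.arange(4.0, 33.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    w0, w1 = epochs.window
    if baseline[0] < w0 or baseline[1] > w1:
        raise ValueError("baseline interval outside the epoch window")
    n_win = int(round(win_s * epochs.rate))
    hop = max(1, int(round((1.0 - overlap) * n_win)))
    power, offsets = _stft_power(epochs.epochs, epochs.rate, freqs, win_s, hop)
    mean_power = power.mean(axis=0)  # [channel, freq, frame]
    times = (offsets - epochs.cue_index) / epochs.rate
    in_base = (times >= baseline[0]) & (times < baseline[1])
    if not np.any(in_base):
        raise ValueError("no STFT frames fall inside the baseline interval")
    log_p = 10.0 * np.log10(np.maximum(mean_power, np.finfo(float).tiny))
    db = log_p - log_p[..., in_base].mean(axis=-1, keepdims=True)
    return ERSPMap(db, freqs, times, list(epochs.channel_labels),
                   (baseline[0], baseline[1]))


def band_topography(ersp_map: ERSPMap, band: tuple[float, float],
                    interval: tuple[float, float]) -> dict[str, float]:
    """Mean ERSP (dB) per channel over a frequency band x time interval.

    ``band`` is inclusive at both edges on the frequency grid; the time
    ``interval`` is half-open.
    """
    f_sel = (ersp_map.freqs >= band[0]) & (ersp_map.freqs <= band[1])
    t_sel = (ersp_map.times >= interval[0]) & (ersp_map.times < interval[1])
    if not np.any(f_sel) or not np.any(t_sel):
        raise ValueError(f"band {band} / interval {interval} select nothing")
    sub = ersp_map.power[:, f_sel][:, :, t_sel]
    means = sub.mean(axis=(1, 2))
    return {lab: float(v) for lab, v in zip(ersp_map.channel_labels, means)}
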