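"""EEG recordings, scalp montages, event schedules and epoch extraction.

Conventions used throughout the package:

* sample indexing is 0-based and all time intervals are half-open
  ``[start, end)``;
* the cue sample of an event at ``onset`` seconds is ``floor(onset * rate)``;
* sample values are microvolts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import floor
from pathlib import Path

import numpy as np
import pandas as pd

#: labels that mark a task cue in an event schedule
CUE_LABELS = ("MI", "AEP", "VEP_AO", "VEP_NM")


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel EEG sample matrix.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in samples/second.
    channel_labels : list of str
        Ordered 10-20 channel names, unique.
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [channels x time] array")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] == 0:
            raise ValueError("recording has zero channels")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length does not match samples")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel label collision")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / rate)."""
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def pick(self, labels: list[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        idx = [self.channel_index(l) for l in labels]
        return Recording(self.samples[idx].copy(), self.rate, list(labels))

    def copy(self) -> "Recording":
        return Recording(self.samples.copy(), self.rate, list(self.channel_labels))


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass
class Montage:
    """Channel label -> 2-D scalp coordinate (azimuthal projection).

    Coordinates are unitless with head radius 1; +y is the nasion
    (front), +x the right ear.
    """

    entries: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for label, (x, y) in self.entries.items():
            if x * x + y * y > 1.0 + 1e-9:
                raise ValueError(f"channel {label!r} lies outside the unit disc")

    def position(self, label: str) -> np.ndarray:
        try:
            return np.asarray(self.entries[label], dtype=float)
        except KeyError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def positions(self, labels: list[str]) -> np.ndarray:
        return np.array([self.position(l) for l in labels])

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance on the 2-D projection, in head radii."""
        return float(np.linalg.norm(self.position(a) - self.position(b)))

    def check_resolvable(self, rec: Recording) -> None:
        missing = [l for l in rec.channel_labels if l not in self.entries]
        if missing:
            raise KeyError(f"recording channels not in montage: {missing}")


def _ideal_1020_positions() -> dict[str, tuple[float, float]]:
    # Idealized 10-20 / 10-10 azimuthal-equidistant layout. Radius is
    # polar angle / 90 deg, so the nasion-inion-preauricular level sits
    # at r = 1 and the classic outer ring (Fp*, F7/8, T7/8, O*) at 0.8.
    # Azimuth is measured from the nasion, positive toward the right ear.
    pos: dict[str, tuple[float, float]] = {}

    def put(label: str, r: float, az_deg: float) -> None:
        a = np.deg2rad(az_deg)
        pos[label] = (float(round(r * np.sin(a), 6)),
                      float(round(r * np.cos(a), 6)))

    # midline
    for label, r, az in [("Fpz", 0.8, 0), ("AFz", 0.6, 0), ("Fz", 0.4, 0),
                         ("FCz", 0.2, 0), ("Cz", 0.0, 0), ("CPz", 0.2, 180),
                         ("Pz", 0.4, 180), ("POz", 0.6, 180), ("Oz", 0.8, 180)]:
        put(label, r, az)
    # rows interpolated linearly in (radius, azimuth) between the midline
    # electrode and the outer-ring electrode of the same row
    rows = {
        "Fp": (0.8, 18.0, 0.8, 18.0, ["Fp1"]),          # ring only
        "AF": (0.6, 0.0, 0.8, 36.0, ["AF3", "AF7"]),
        "F": (0.4, 0.0, 0.8, 54.0, ["F1", "F3", "F5", "F7"]),
        "FC": (0.2, 0.0, 0.8, 72.0, ["FC1", "FC3", "FC5", "FT7"]),
        "C": (0.0, 90.0, 0.8, 90.0, ["C1", "C3", "C5", "T7"]),
        "CP": (0.2, 180.0, 0.8, 108.0, ["CP1", "CP3", "CP5", "TP7"]),
        "P": (0.4, 180.0, 0.8, 126.0, ["P1", "P3", "P5", "P7"]),
        "PO": (0.6, 180.0, 0.8, 144.0, ["PO3", "PO7"]),
        "O": (0.8, 162.0, 0.8, 162.0, ["O1"]),          # ring only
    }
    mirror = {"1": "2", "3": "4", "5": "6", "7": "8"}
    for r0, az0, r1, az1, labels in rows.values():
        n = len(labels)
        for k, left in enumerate(labels, start=1):
            f = k / n
            r = r0 + (r1 - r0) * f
            az = az0 + (az1 - az0) * f
            put(left, r, -az)
            right = left[:-1] + mirror[left[-1]]
            right = right.replace("FT7", "FT8").replace("TP7", "TP8")
            put(right, r, az)
    put("T9", 1.0, -90.0)
    put("T10", 1.0, 90.0)
    return pos


#: 32-channel layouts densely covering the left motor cortex; the second
#: swaps the inferior temporal pair for left/medial parietal electrodes.
HEALTHY_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "FC5", "FC3", "FC1", "FC4", "FC6",
    "FT7", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "T8", "T9", "T10",
    "CP5", "CP3", "CP1", "CP4", "CP6", "P5", "P3", "P4", "P6", "O1", "O2",
]
STROKE_32 = [l for l in HEALTHY_32 if l not in ("T9", "T10")] + ["P1", "POz"]


def standard_montage(group: str = "healthy") -> Montage:
    """Built-in 10-20 montage for the two 32-channel cap layouts.

    ``group`` is ``"healthy"`` or ``"stroke"``; any other value returns
    the full 10-10 superset.
    """
    pos = _ideal_1020_positions()
    if group == "healthy":
        labels = HEALTHY_32
    elif group == "stroke":
        labels = STROKE_32
    else:
        return Montage(pos)
    return Montage({l: pos[l] for l in labels})


# ---------------------------------------------------------------------------
# Event schedule
# ---------------------------------------------------------------------------

@dataclass
class BlockParams:
    """Durations (seconds) of one block of the paradigm design."""

    task_dur: float
    rest_dur: float
    cooldown_pre: float = 0.0
    cooldown_post: float = 0.0

    def to_dict(self) -> dict:
        return {"task_dur": self.task_dur, "rest_dur": self.rest_dur,
                "cooldown_pre": self.cooldown_pre,
                "cooldown_post": self.cooldown_post}


@dataclass
class EventSchedule:
    """Ordered cue onsets with paradigm labels, plus the block design.

    Every event marks the start of a task period; the surrounding
    cool-down and rest intervals are derived from ``block``.
    """

    events: list[tuple[float, str]]
    block: BlockParams
    session_dur: float

    def __post_init__(self) -> None:
        onsets = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        span = self.block.task_dur + self.block.cooldown_post
        for a, b in zip(onsets, onsets[1:]):
            if b - self.block.cooldown_pre < a + span:
                raise ValueError("event intervals overlap")

    @property
    def n_trials(self) -> int:
        return sum(1 for _, lab in self.events if lab in CUE_LABELS)

    def cue_onsets(self, label: str | None = None) -> list[float]:
        return [t for t, lab in self.events
                if (lab == label if label is not None else lab in CUE_LABELS)]

    def task_intervals(self) -> list[tuple[float, float]]:
        d = self.block.task_dur
        return [(t, t + d) for t in self.cue_onsets()]

    def cooldown_intervals(self) -> list[tuple[float, float]]:
        pre, post, d = self.block.cooldown_pre, self.block.cooldown_post, self.block.task_dur
        out = []
        for t in self.cue_onsets():
            if pre > 0:
                out.append((t - pre, t))
            if post > 0:
                out.append((t + d, t + d + post))
        return out

    def rest_intervals(self) -> list[tuple[float, float]]:
        """Complement of task+cool-down within [0, session_dur)."""
        busy = sorted(self.task_intervals() + self.cooldown_intervals())
        out, cur = [], 0.0
        for a, b in busy:
            if a > cur:
                out.append((cur, min(a, self.session_dur)))
            cur = max(cur, b)
        if cur < self.session_dur:
            out.append((cur, self.session_dur))
        return out

    def scored_rest_seconds(self) -> float:
        return sum(b - a for a, b in self.rest_intervals())

    def classify_times(self, times: np.ndarray) -> np.ndarray:
        """0 = rest, 1 = task, 2 = cool-down, vectorized over ``times``."""
        times = np.asarray(times, dtype=float)
        out = np.zeros(times.shape, dtype=np.int8)
        for code, ivals in ((2, self.cooldown_intervals()), (1, self.task_intervals())):
            for a, b in ivals:
                out[(times >= a) & (times < b)] = code
        return out

    def shifted(self, delta: float) -> "EventSchedule":
        ev = [(t + delta, lab) for t, lab in self.events]
        return EventSchedule(ev, self.block, self.session_dur + delta)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Cue-aligned epochs, ``epochs[trial, channel, time]``."""

    epochs: np.ndarray
    rate: float
    channel_labels: list[str]
    window: tuple[float, float]
    cue_index: int = field(default=-1)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be [trials x channels x time]")
        if self.cue_index < 0:
            self.cue_index = int(round(-self.window[0] * self.rate))

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the cue."""
        n = self.epochs.shape[2]
        return (np.arange(n) - self.cue_index) / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None


def extract_epochs(rec: Recording, sched: EventSchedule,
                   label: str | None = None,
                   window: tuple[float, float] = (-4.0, 4.0)) -> EpochSet:
    """Cut cue-aligned epochs out of a continuous recording.

    ``window`` is (start, end) in seconds relative to each cue; the
    default -4..+4 s leaves a 2-s pre-stimulus baseline margin.  Epoch
    ``t = 0`` is aligned to ``floor(onset * rate)``.
    """
    w0, w1 = window
    n = int(round((w1 - w0) * rec.rate))
    if n <= 0:
        raise ValueError("empty epoch window")
    off = int(round(w0 * rec.rate))
    onsets = sched.cue_onsets(label)
    if not onsets:
        raise ValueError(f"no cues with label {label!r} in schedule")
    out = np.empty((len(onsets), rec.n_channels, n))
    for i, onset in enumerate(onsets):
        cue = floor(onset * rec.rate)
        a = cue + off
        if a < 0 or a + n > rec.n_samples:
            raise ValueError(
                f"epoch for trial {i} (cue at {onset} s) exceeds recording bounds")
        out[i] = rec.samples[:, a:a + n]
    return EpochSet(out, rec.rate, list(rec.channel_labels), (w0, w1),
                    cue_index=-off)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_recording(path: str | Path, rec: Recording,
                    sched: EventSchedule | None = None) -> None:
    """Write the internal container (NumPy ``.npz``): bit-exact samples,
    rate, labels and, optionally, the event schedule."""
    arrays = {
        "samples": rec.samples,
        "rate": np.array(rec.rate),
        "channel_labels": np.array(rec.channel_labels),
    }
    if sched is not None:
        arrays["event_onsets"] = np.array([t for t, _ in sched.events])
        arrays["event_labels"] = np.array([lab for _, lab in sched.events])
        meta = dict(sched.block.to_dict(), session_dur=sched.session_dur)
        arrays["schedule_meta"] = np.array(json.dumps(meta))
    np.savez(Path(path), **arrays)


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from the internal container or an EDF/BDF file.

    ``format`` is ``"container"``, ``"edf"`` or ``"bdf"``; inferred from
    the file suffix when omitted.  EDF/BDF are read through :mod:`mne`
    and converted to microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".npz": "container", ".edf": "edf", ".bdf": "bdf"}.get(
            path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format of {path.name!r}")
    if format == "container":
        try:
            with np.load(path, allow_pickle=False) as z:
                return Recording(z["samples"], float(z["rate"]),
                                 [str(l) for l in z["channel_labels"]])
        except Exception as exc:
            raise ValueError(f"unreadable container {path}: {exc}") from exc
    if format in ("edf", "bdf"):
        import mne
        reader = mne.io.read_raw_edf if format == "edf" else mne.io.read_raw_bdf
        try:
            raw = reader(path, preload=True, verbose="error")
        except Exception as exc:
            raise ValueError(f"unreadable {format.upper()} file {path}: {exc}") from exc
        return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                         list(raw.ch_names))
    raise ValueError(f"unknown format {format!r}")


def read_container_schedule(path: str | Path) -> EventSchedule | None:
    """Event schedule stored alongside a container recording, if any."""
    with np.load(Path(path), allow_pickle=False) as z:
        if "event_onsets" not in z:
            return None
        meta = json.loads(str(z["schedule_meta"]))
        events = [(float(t), str(lab))
                  for t, lab in zip(z["event_onsets"], z["event_labels"])]
        block = BlockParams(meta["task_dur"], meta["rest_dur"],
                            meta["cooldown_pre"], meta["cooldown_post"])
        return EventSchedule(events, block, meta["session_dur"])


def write_events(path: str | Path, sched: EventSchedule) -> None:
    """Events as TSV (onset_s, label) with block parameters in ``#`` headers."""
    with open(path, "w") as fh:
        for k, v in dict(sched.block.to_dict(),
                         session_dur=sched.session_dur).items():
            fh.write(f"# {k}={v}\n")
        fh.write("onset_s\tlabel\n")
        for t, lab in sched.events:
            fh.write(f"{float(t)!r}\t{lab}\n")


def read_events(path: str | Path) -> EventSchedule:
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            k, v = line[1:].strip().split("=")
            meta[k.strip()] = float(v)
        else:
            body.append(line)
    df = pd.read_csv(pd.io.common.StringIO("".join(body)), sep="\t")
    events = [(float(r.onset_s), str(r.label)) for r in df.itertuples()]
    block = BlockParams(meta["task_dur"], meta["rest_dur"],
                        meta.get("cooldown_pre", 0.0),
                        meta.get("cooldown_post", 0.0))
    dur = meta.get("session_dur", max(t for t, _ in events) + block.task_dur)
    return EventSchedule(events, block, dur)


def write_montage(path: str | Path, montage: Montage) -> None:
    with open(path, "w") as fh:
        fh.write("label\tx\ty\n")
        for label, (x, y) in montage.entries.items():
            fh.write(f"{label}\t{float(x)!r}\t{float(y)!r}\n")


def read_montage(path: str | Path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    return Montage({str(r.label): (float(r.x), float(r.y))
                    for r in df.itertuples()})
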