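"""Synthetic multichannel EEG with ground-truth ERD and contamination.

The generator embodies the radial-spread picture the detector is built
around: desynchronization ripples outward from its source electrode.
Every channel carries an intrinsic band-limited rhythm (a constant-
envelope, frequency-drifting oscillation, so band power is steady
between events) on top of per-channel pink (1/f) noise with a spatially
correlated common component.  An "event" at a source attenuates that
source's rhythm by ``erd_depth`` and every other channel's by
``erd_depth * exp(-d / spread_scale)`` with ``d`` the montage distance
(raised-cosine 0.25-s ramps against spectral splatter), so the source
electrode always shows the strongest desynchronization and nearby
electrodes a graded, shape-identical pseudo-ERD.  Motor-imagery events
radiate from a mu-band source over the motor cortex; visual/auditory
contamination events radiate from posterior/temporal alpha sources,
producing exactly the pseudo-MI ERD that the non-ROI channels are meant
to veto.

Free parameters the emulated experiment does not pin down (amplitude
ratios, noise level, leakage constant) are set once here; see the
package methods notes for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import (BlockParams, EventSchedule, Montage, Recording,
                        standard_montage)

# ---------------------------------------------------------------------------
# source specification and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SourceSpec:
    """One oscillatory scalp source and its event-locked attenuation."""

    channel: str
    band: tuple[float, float] = (9.0, 12.0)
    osc_amplitude: float = 12.0      # uV
    erd_depth: float = 0.5           # fractional envelope attenuation
    erd_latency: float = 0.5         # s after the cue
    erd_duration: float = 2.0        # s
    spread_scale: float = 0.4        # head radii

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.erd_duration <= 0:
            raise ValueError("erd_duration must be positive")


@dataclass
class SynthGroundTruth:
    """What was actually injected: per event (onset, type, source)."""

    events: list[tuple[float, str, str]]
    seed: int
    specs: dict[str, SourceSpec] = field(default_factory=dict)


#: default sources: MI mu rhythm over the left motor cortex, visual
#: alpha at the occipital electrodes, auditory alpha at the temporal one
DEFAULT_SPECS = {
    "MI": SourceSpec("C3", (10.0, 12.0), osc_amplitude=20.0, erd_depth=0.5),
    "VEP_AO": SourceSpec("O1", (10.0, 12.0), osc_amplitude=25.0, erd_depth=0.8),
    "VEP_NM": SourceSpec("O2", (10.0, 12.0), osc_amplitude=25.0, erd_depth=0.8),
    "AEP": SourceSpec("T7", (10.0, 12.0), osc_amplitude=25.0, erd_depth=0.8),
}

#: intrinsic background rhythm at channels that host no source
IDLE_BAND = (10.0, 12.0)
IDLE_AMPLITUDE = 10.0

#: block layouts in seconds: rest, cool-down before task, task,
#: cool-down after task.  Calibration: 14-s blocks (10 s scored rest,
#: 2 s task, 2 s unscored buffer) -> 30 blocks = 7 min with 5 scored
#: rest minutes.  Online healthy: 6 s rest -> 3 scored rest minutes;
#: online stroke: 4 s task / 8 s rest -> 4 scored rest minutes.
DESIGNS = {
    "calibration": {"rest": 10.0, "pre": 0.0, "task": 2.0, "post": 2.0},
    "online_healthy": {"rest": 6.0, "pre": 2.0, "task": 2.0, "post": 2.0},
    "online_stroke": {"rest": 8.0, "pre": 2.0, "task": 4.0, "post": 2.0},
}


def make_schedule(design: str, paradigm: str, n_trials: int = 30,
                  ) -> EventSchedule:
    """Block-design schedule: each block is rest, optional pre-task
    cool-down, cue + task, post-task cool-down."""
    d = DESIGNS[design]
    block_dur = d["rest"] + d["pre"] + d["task"] + d["post"]
    cue0 = d["rest"] + d["pre"]
    events = [(cue0 + k * block_dur, paradigm) for k in range(n_trials)]
    block = BlockParams(d["task"], d["rest"], d["pre"], d["post"])
    return EventSchedule(events, block, n_trials * block_dur)


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------


def _pink(rng: np.random.Generator, n: int, alpha: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-alpha / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_background(montage: Montage, duration: float, rate: float = 128.0,
                        seed: int = 0, noise_std: float = 8.0,
                        common_weight: float = 0.4,
                        alpha: float = 1.0) -> Recording:
    """Pink-noise background EEG on every montage channel.

    Each channel mixes an independent pink series with a shared pink
    component (weight ``common_weight``), normalized so each channel has
    ``noise_std`` uV RMS; reproducible from ``seed``.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    labels = list(montage.entries)
    common = _pink(rng, n, alpha)
    w = common_weight
    samples = np.empty((len(labels), n))
    for i in range(len(labels)):
        own = _pink(rng, n, alpha)
        samples[i] = noise_std * (np.sqrt(1 - w * w) * own + w * common)
    return Recording(samples, rate, labels)


def _envelope(n: int, rate: float, events: list[float], latency: float,
              duration: float, depth: float, ramp_s: float = 0.25,
              ) -> np.ndarray:
    """Multiplicative envelope: 1 at rest, 1-depth during events, with
    raised-cosine on/off ramps of ``ramp_s`` seconds."""
    t = np.arange(n) / rate
    env = np.ones(n)
    for onset in events:
        a, b = onset + latency, onset + latency + duration
        drop = np.zeros(n)
        core = (t >= a + ramp_s / 2) & (t < b - ramp_s / 2)
        drop[core] = 1.0
        for edge, sign in ((a, 1.0), (b, -1.0)):
            sel = (t >= edge - ramp_s / 2) & (t < edge + ramp_s / 2)
            phase = (t[sel] - (edge - ramp_s / 2)) / ramp_s
            ramp = 0.5 - 0.5 * np.cos(np.pi * phase)
            drop[sel] = np.maximum(drop[sel], ramp if sign > 0 else 1 - ramp)
        env = np.minimum(env, 1.0 - depth * drop)
    return env


def _fm_oscillation(rng: np.random.Generator, n: int, rate: float,
                    band: tuple[float, float], tau_s: float = 0.4,
                    ) -> np.ndarray:
    """Constant-envelope oscillation whose instantaneous frequency
    wanders inside ``band`` (Ornstein-Uhlenbeck drift, correlation time
    ``tau_s``).  Unit amplitude, so unit power is amplitude^2 / 2.

    A frequency-modulated rhythm keeps the band power steady between
    events — the attenuation envelope, not amplitude noise, carries the
    ERD — while still filling the band and decorrelating across trials.
    """
    f0 = 0.5 * (band[0] + band[1])
    sd = (band[1] - band[0]) / 6.0
    dt = 1.0 / rate
    a = np.exp(-dt / tau_s)
    from scipy.signal import lfilter

    innov = rng.standard_normal(n) * sd * np.sqrt(1 - a * a)
    innov[0] = rng.standard_normal() * sd
    dev = lfilter([1.0], [1.0, -a], innov)
    freq = np.clip(f0 + dev, band[0], band[1])
    phase = 2 * np.pi * np.cumsum(freq) * dt + rng.uniform(0, 2 * np.pi)
    return np.sin(phase)


def add_idle_rhythm(rec: Recording, channel: str,
                    band: tuple[float, float] = IDLE_BAND,
                    amplitude: float = IDLE_AMPLITUDE,
                    rng: np.random.Generator | None = None) -> Recording:
    """Add an intrinsic constant-envelope rhythm to one channel."""
    if rng is None:
        rng = np.random.default_rng(0)
    out = rec.copy()
    i = out.channel_index(channel)
    out.samples[i] += amplitude * _fm_oscillation(rng, out.n_samples,
                                                  out.rate, band)
    return out


def inject_source(rec: Recording, spec: SourceSpec, events: list[float],
                  montage: Montage,
                  rng: np.random.Generator | None = None) -> Recording:
    """Add an oscillatory source whose event-locked ERD spreads radially.

    A constant-envelope, frequency-drifting oscillation of amplitude
    ``osc_amplitude`` runs at ``spec.channel`` for the whole recording;
    during ``[onset+latency, onset+latency+duration)`` its envelope
    drops by ``erd_depth``.  The desynchronization ripples outward:
    every *other* channel is multiplied by the same event envelope with
    depth ``erd_depth * exp(-d / spread_scale)`` (``d`` the montage
    distance), attenuating whatever rhythm that channel already carries.
    The source channel therefore always shows the strongest
    desynchronization, and neighbours a graded pseudo-ERD of identical
    shape.
    """
    if spec.channel not in rec.channel_labels:
        raise KeyError(f"source channel {spec.channel!r} not in recording")
    for onset in events:
        if not 0 <= onset <= rec.duration:
            raise ValueError(f"event at {onset} s outside the recording")
    if rng is None:
        rng = np.random.default_rng(0)
    n, rate = rec.n_samples, rec.rate
    osc = spec.osc_amplitude * _fm_oscillation(rng, n, rate, spec.band)
    osc *= _envelope(n, rate, events, spec.erd_latency, spec.erd_duration,
                     spec.erd_depth)
    src_pos = montage.position(spec.channel)
    out = rec.samples.copy()
    for i, lab in enumerate(rec.channel_labels):
        if lab == spec.channel:
            out[i] += osc
            continue
        d = float(np.linalg.norm(montage.position(lab) - src_pos))
        local_depth = spec.erd_depth * np.exp(-d / spec.spread_scale)
        if local_depth > 1e-4 and events:
            out[i] *= _envelope(n, rate, events, spec.erd_latency,
                                spec.erd_duration, local_depth)
    return Recording(out, rate, list(rec.channel_labels))


def generate_session(design: str, paradigm: str = "MI",
                     specs: dict[str, SourceSpec] | None = None,
                     seed: int = 0, n_trials: int = 30, rate: float = 128.0,
                     montage: Montage | None = None,
                     contamination_rate: float = 0.6,
                     noise_std: float = 8.0,
                     idle_amplitude: float | None = None,
                     ) -> tuple[Recording, EventSchedule, SynthGroundTruth]:
    """One full block-design session with ground truth.

    ``design`` is ``calibration``, ``online_healthy`` or
    ``online_stroke``.  A calibration session places the ``paradigm``'s
    events on the task cues; online sessions place MI events on the task
    cues and, with probability ``contamination_rate`` per rest period, a
    contamination event (random type) inside the rest period.  Idle
    oscillations of all sources run throughout, every source-free
    channel carries a background rhythm, and each event's
    desynchronization spreads radially, so the ROI channel shows the
    graded pseudo-ERD the rejection hypothesis assumes.
    """
    specs = dict(DEFAULT_SPECS if specs is None else specs)
    online = design.startswith("online")
    cue_paradigm = "MI" if online else paradigm
    if cue_paradigm not in specs:
        raise ValueError(f"no source spec for scheduled events {cue_paradigm!r}")
    sched = make_schedule(design, cue_paradigm, n_trials)
    if montage is None:
        montage = standard_montage(
            "stroke" if design == "online_stroke" else "healthy")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB5]))
    noise = generate_background(montage, sched.session_dur, rate,
                                seed=int(rng.integers(2 ** 31)),
                                noise_std=noise_std)
    # oscillatory layer kept apart from the noise floor: event envelopes
    # modulate rhythms only, never the background
    rec = Recording(np.zeros_like(noise.samples), rate,
                    list(noise.channel_labels))
    truth_events: list[tuple[float, str, str]] = []
    events_by_type: dict[str, list[float]] = {name: [] for name in specs}
    cues = sched.cue_onsets()
    events_by_type[cue_paradigm].extend(cues)
    truth_events.extend((t, "MI_ERD" if cue_paradigm == "MI" else cue_paradigm,
                         specs[cue_paradigm].channel) for t in cues)
    if online:
        cont_types = [k for k in specs if k != "MI"]
        needed = max(specs[k].erd_latency + specs[k].erd_duration + 0.5
                     for k in cont_types)
        for a, b in sched.rest_intervals():
            if b - a < needed or rng.random() >= contamination_rate:
                continue
            kind = cont_types[int(rng.integers(len(cont_types)))]
            onset = float(rng.uniform(a, b - needed))
            events_by_type[kind].append(onset)
            truth_events.append((onset, kind, specs[kind].channel))
    source_channels = {spec.channel for spec in specs.values()}
    if idle_amplitude is None:
        idle_amplitude = IDLE_AMPLITUDE
    for lab in rec.channel_labels:
        if lab not in source_channels:
            rec = add_idle_rhythm(rec, lab, amplitude=idle_amplitude, rng=rng)
    # the MI source first, so contamination events modulate the ROI's mu
    order = sorted(specs, key=lambda k: k != "MI")
    for name in order:
        spec = specs[name]
        if spec.channel not in rec.channel_labels:
            raise ValueError(f"source channel {spec.channel!r} not in montage")
        rec = inject_source(rec, spec, events_by_type[name], montage, rng=rng)
    rec = Recording(noise.samples + rec.samples, rate,
                    list(noise.channel_labels))
    truth = SynthGroundTruth(sorted(truth_events), seed, specs)
    return rec, sched, truth


def write_ground_truth(path, truth: SynthGroundTruth) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={truth.seed}\n")
        fh.write("onset_s\ttype\tsource\n")
        for onset, kind, src in truth.events:
            fh.write(f"{onset!r}\t{kind}\t{src}\n")
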