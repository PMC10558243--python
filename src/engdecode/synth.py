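"""Synthetic multi-channel ENG session generation.

Emulates intraneural (TIME-style) recordings from the pudendal nerve across
three bladder states — ``baseline`` (empty bladder), ``full`` (filled bladder
before leakage) and ``micturition`` (urine leakage) — so that the whole
decoding pipeline can be developed and tested without animal data.

Each functional active site carries a homogeneous Poisson spike train with an
absolute refractory dead time, rendered as a biphasic extracellular waveform
on top of broadband Gaussian noise and optional 50 Hz line interference.
Nonfunctioning ("dead") channels, a routine failure mode of chronically
implanted intrafascicular electrodes, carry noise only. The three state
segments have equal durations so downstream classification sees balanced
classes by construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical class order used everywhere downstream (confusion matrices,
#: fold stratification, reports).
STATES = ("baseline", "full", "micturition")

__all__ = [
    "STATES",
    "SynthConfig",
    "SpikeTrain",
    "Session",
    "generate_spike_train",
    "spike_template",
    "render_channel",
    "generate_session",
    "save_session",
    "load_session",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters for one synthetic recording session.

    Units: rates in Hz (events/s per channel), amplitudes and noise in µV,
    durations in seconds. ``state_noise_sd`` optionally overrides the
    broadband noise level per state on functional channels, which allows
    constructing datasets whose classes differ only in signal variance;
    dead channels always use the state-independent ``noise_sd``.
    """

    n_channels: int = 32
    fs_neural: float = 24414.0
    fs_physio: float = 1526.0
    state_rates: dict = field(
        default_factory=lambda: {"baseline": 5.0, "full": 40.0, "micturition": 80.0}
    )
    state_amplitudes: dict = field(
        default_factory=lambda: {"baseline": 30.0, "full": 35.0, "micturition": 40.0}
    )
    state_noise_sd: dict | None = None
    noise_sd: float = 4.0
    line_noise_amp: float = 1.0
    line_noise_hz: float = 50.0
    n_dead_channels: int = 5
    segment_duration_s: float = 60.0
    refractory_s: float = 0.004
    with_physio: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        if not 0 <= self.n_dead_channels <= self.n_channels:
            raise ValueError("n_dead_channels must lie in [0, n_channels]")
        if self.fs_neural <= 0 or self.fs_physio <= 0:
            raise ValueError("sampling rates must be positive")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be > 0")
        if self.segment_duration_s <= 0:
            raise ValueError("segment_duration_s must be > 0")
        if self.noise_sd < 0 or self.line_noise_amp < 0:
            raise ValueError("noise amplitudes must be non-negative")
        for mapping, what in (
            (self.state_rates, "state_rates"),
            (self.state_amplitudes, "state_amplitudes"),
        ):
            if set(mapping) != set(STATES):
                raise ValueError(f"{what} must have exactly the keys {STATES}")
            if any(v < 0 for v in mapping.values()):
                raise ValueError(f"{what} values must be non-negative")
        if self.state_noise_sd is not None:
            if set(self.state_noise_sd) != set(STATES):
                raise ValueError(f"state_noise_sd must have exactly the keys {STATES}")
            if any(v < 0 for v in self.state_noise_sd.values()):
                raise ValueError("state_noise_sd values must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike event times (seconds) on one channel."""

    times: np.ndarray
    channel: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class Session:
    """A labeled multi-channel recording.

    ``signal`` is channels × samples (µV). ``intervals`` is an ordered list of
    half-open ``(start_sample, end_sample, state)`` spans on the sample axis.
    ``channel_status`` holds ``"functional"`` or ``"dead"`` per channel.
    ``physio`` optionally carries (pressure, volume) traces sampled at
    ``fs_physio``.
    """

    signal: np.ndarray
    fs: float
    intervals: list
    channel_status: list
    physio: np.ndarray | None = None
    fs_physio: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if len(self.channel_status) != self.signal.shape[0]:
            raise ValueError("channel_status length must equal channel count")
        n = self.signal.shape[1]
        prev_end = 0
        for start, end, state in self.intervals:
            if not (0 <= start < end <= n):
                raise ValueError("interval out of bounds")
            if start < prev_end:
                raise ValueError("intervals overlap")
            if state not in STATES:
                raise ValueError(f"unknown state label {state!r}")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def functional_channels(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_status) == "functional")

    def dead_channels(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_status) == "dead")

    def state_durations(self) -> dict:
        out: dict = {}
        for start, end, state in self.intervals:
            out[state] = out.get(state, 0) + (end - start)
        return out


def generate_spike_train(
    rate: float,
    duration: float,
    refractory: float = 0.004,
    seed: int | np.random.Generator = 0,
    channel: int | None = None,
) -> SpikeTrain:
    """Draw a homogeneous Poisson spike train with absolute dead time.

    Inter-event intervals are ``refractory + Exp(rate')`` with the exponential
    rate compensated for the dead time (``rate' = rate / (1 - rate *
    refractory)``), so ``rate`` is the achieved mean firing rate: the expected
    event count is ``rate * duration`` regardless of the refractory period.
    With ``refractory=0`` this is an exact homogeneous Poisson process. The
    first event is a plain exponential wait from t = 0.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    if rate == 0:
        return SpikeTrain(np.empty(0), channel)
    if rate * refractory >= 1.0:
        raise ValueError(
            f"rate {rate} Hz is unachievable with a {refractory} s refractory period"
        )
    rate = rate / (1.0 - rate * refractory)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # draw ISIs in blocks until we pass `duration`
    mean_isi = refractory + 1.0 / rate
    block = max(16, int(1.5 * duration / mean_isi) + 16)
    times = []
    t = 0.0
    first = True
    while t < duration:
        isis = rng.exponential(1.0 / rate, size=block)
        if not first:
            isis = isis + refractory
        else:
            isis[1:] += refractory
            first = False
        cum = t + np.cumsum(isis)
        keep = cum[cum < duration]
        times.append(keep)
        if cum.size and cum[-1] >= duration:
            break
        t = cum[-1] if cum.size else duration
    events = np.concatenate(times) if times else np.empty(0)
    return SpikeTrain(events, channel)


def spike_template(
    fs: float, amplitude: float = 1.0, width_s: float = 1.0e-3
) -> np.ndarray:
    """Biphasic extracellular spike waveform (difference of Gaussians).

    A broad positive lobe followed by a narrow dominant trough, ~1 ms wide.
    The lobe areas cancel (the wide lobe has half the height and twice the
    width of the trough), so the waveform has no net low-frequency content
    and its spectral energy concentrates in the 1–6 kHz band where the
    pipeline's band-pass lives. Normalised so the trough depth equals
    ``amplitude``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    n = max(int(round(width_s * fs)), 3)
    t = np.arange(n) / fs
    sigma_trough = 0.05 * width_s
    c1, c2 = 0.35 * width_s, 0.50 * width_s
    w = 0.5 * np.exp(-0.5 * ((t - c1) / (2 * sigma_trough)) ** 2) - np.exp(
        -0.5 * ((t - c2) / sigma_trough) ** 2
    )
    w *= amplitude / np.abs(w.min())
    return w


def render_channel(
    train: SpikeTrain,
    template: np.ndarray,
    n_samples: int,
    fs: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    line_noise_amp: float = 0.0,
    line_noise_hz: float = 50.0,
) -> np.ndarray:
    """Render a spike train into a continuous trace.

    Superposes one template instance per event (template start aligned to the
    event time) plus white Gaussian noise and optional sinusoidal line
    interference. Events whose template runs past the end of the trace are
    truncated at the boundary, not dropped; the truncation count is logged.
    """
    template = np.asarray(template, dtype=float)
    if template.size == 0:
        raise ValueError("template must be non-empty")
    if template.size >= n_samples:
        raise ValueError("template must be shorter than the rendered signal")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")

    x = np.zeros(n_samples)
    idx = np.round(train.times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n_samples)]
    n_truncated = 0
    for i in idx:
        end = i + template.size
        if end > n_samples:
            x[i:] += template[: n_samples - i]
            n_truncated += 1
        else:
            x[i:end] += template
    if n_truncated:
        logger.info("render_channel: %d event(s) truncated at trace end", n_truncated)

    if noise_sd > 0:
        rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        x += rng.normal(0.0, noise_sd, n_samples)
    if line_noise_amp > 0:
        t = np.arange(n_samples) / fs
        x += line_noise_amp * np.sin(2 * np.pi * line_noise_hz * t)
    return x


def _physio_traces(config: SynthConfig) -> np.ndarray:
    """Pressure (cmH2O) and volume (ml) traces over the three segments.

    Volume ramps monotonically from 0 to 150 ml during the filling segment and
    stays there; intravesical pressure sits near baseline, rises while the
    bladder fills, and peaks during micturition.
    """
    m = int(round(config.segment_duration_s * config.fs_physio))
    ramp = np.linspace(0.0, 1.0, m, endpoint=False)
    volume = np.concatenate([np.zeros(m), 150.0 * ramp, np.full(m, 150.0)])
    pressure = np.concatenate(
        [np.full(m, 5.0), 5.0 + 20.0 * ramp, 25.0 + 15.0 * np.sin(np.pi * ramp)]
    )
    return np.vstack([pressure, volume])


def generate_session(config: SynthConfig) -> Session:
    """Generate one synthetic session: baseline → full → micturition.

    The three state segments have identical sample counts. Dead channels are
    selected at random (seeded) and carry broadband noise only. All randomness
    derives from ``config.seed`` through a single SeedSequence, so identical
    configs yield bit-identical sessions.
    """
    fs = config.fs_neural
    n_seg = int(round(config.segment_duration_s * fs))
    n_total = 3 * n_seg
    ss = np.random.SeedSequence(config.seed)
    rng_dead, rng_noise, rng_trains = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    dead = np.sort(
        rng_dead.choice(config.n_channels, size=config.n_dead_channels, replace=False)
    )
    status = ["functional"] * config.n_channels
    for ch in dead:
        status[ch] = "dead"

    signal = np.zeros((config.n_channels, n_total), dtype=np.float32)
    intervals = [(k * n_seg, (k + 1) * n_seg, state) for k, state in enumerate(STATES)]

    # noise first: every channel, state-dependent sd on functional channels
    for ch in range(config.n_channels):
        for (start, end, state) in intervals:
            if status[ch] == "functional" and config.state_noise_sd is not None:
                sd = config.state_noise_sd[state]
            else:
                sd = config.noise_sd
            if sd > 0:
                signal[ch, start:end] += rng_noise.normal(
                    0.0, sd, end - start
                ).astype(np.float32)

    if config.line_noise_amp > 0:
        t = np.arange(n_total) / fs
        line = (config.line_noise_amp * np.sin(2 * np.pi * config.line_noise_hz * t)).astype(
            np.float32
        )
        signal += line[None, :]

    for ch in range(config.n_channels):
        if status[ch] == "dead":
            continue
        for (start, end, state) in intervals:
            rate = config.state_rates[state]
            if rate == 0:
                continue
            train = generate_spike_train(
                rate, config.segment_duration_s, config.refractory_s, rng_trains, ch
            )
            template = spike_template(fs, config.state_amplitudes[state])
            rendered = render_channel(train, template, end - start, fs)
            signal[ch, start:end] += rendered.astype(np.float32)

    physio = _physio_traces(config) if config.with_physio else None
    return Session(
        signal=signal,
        fs=fs,
        intervals=intervals,
        channel_status=status,
        physio=physio,
        fs_physio=config.fs_physio if config.with_physio else None,
        provenance={"generator": "engdecode.synth", "config": config.to_dict()},
    )


# ---------------------------------------------------------------------------
# Session I/O: directory with signal.npy + meta.json (+ physio.csv), or a
# single HDF5 file when the path ends in .h5/.hdf5.


def save_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=session.signal)
            f.attrs["fs"] = session.fs
            f.attrs["meta"] = json.dumps(_meta_dict(session), sort_keys=True)
            if session.physio is not None:
                f.create_dataset("physio", data=session.physio)
        return path
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "signal.npy", session.signal)
    (path / "meta.json").write_text(
        json.dumps(_meta_dict(session), indent=2, sort_keys=True)
    )
    if session.physio is not None:
        header = "pressure_cmH2O,volume_ml"
        np.savetxt(
            path / "physio.csv",
            session.physio.T,
            delimiter=",",
            header=header,
            comments="",
        )
    return path


def _meta_dict(session: Session) -> dict:
    return {
        "fs": session.fs,
        "fs_physio": session.fs_physio,
        "intervals": [[int(s), int(e), st] for s, e, st in session.intervals],
        "channel_status": list(session.channel_status),
        "provenance": session.provenance,
    }


def load_session(path: str | Path) -> Session:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            signal = f["signal"][()]
            physio = f["physio"][()] if "physio" in f else None
    else:
        meta = json.loads((path / "meta.json").read_text())
        signal = np.load(path / "signal.npy")
        physio_path = path / "physio.csv"
        physio = (
            np.loadtxt(physio_path, delimiter=",", skiprows=1).T
            if physio_path.exists()
            else None
        )
    return Session(
        signal=signal,
        fs=meta["fs"],
        intervals=[(s, e, st) for s, e, st in meta["intervals"]],
        channel_status=meta["channel_status"],
        physio=physio,
        fs_physio=meta.get("fs_physio"),
        provenance=meta.get("provenance", {}),
    )
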