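"""Band-pass filtering, undersampling and spike-detection QC.

Single-channel ENG traces are filtered with a fourth-order Butterworth
band-pass (1–6 kHz by default, where somatic-fiber spike energy is localised)
applied forward–backward for zero phase, then undersampled by plain decimation
(factor 2 by default, which keeps the post-decimation Nyquist above the upper
cutoff, so no extra anti-alias filter is needed).

Spike detection here is a quality-control / visualisation aid, not a feature
source: the decoding features are computed on the continuous filtered signal.
Threshold crossings of a robust noise estimate (MAD / 0.6745) are reduced to
local extrema and pruned with an absolute refractory period (4 ms default,
earlier event wins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import Session, SpikeTrain

__all__ = [
    "FilterSpec",
    "SpikeDetectSpec",
    "bandpass_filter",
    "undersample",
    "detect_spikes",
    "preprocess_session",
    "spike_trains_to_csv",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass parameters.

    ``order`` is the prototype low-pass order handed to the design routine
    (the realised band-pass has twice that many poles); this convention is
    recorded in ``order_convention``. ``zero_phase`` selects forward–backward
    application; the single-pass variant exists for streaming parity.
    """

    f_lo: float = 1000.0
    f_hi: float = 6000.0
    order: int = 4
    kind: str = "butterworth-bandpass"
    order_convention: str = "prototype"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.kind != "butterworth-bandpass":
            raise ValueError("only butterworth-bandpass is supported")

    def validate_against(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"f_hi={self.f_hi} Hz must be below the Nyquist frequency {fs / 2} Hz"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate_against(fs)
        return sps.butter(
            self.order, [self.f_lo, self.f_hi], btype="bandpass", fs=fs, output="sos"
        )


@dataclass(frozen=True)
class SpikeDetectSpec:
    """Threshold-crossing spike detection parameters.

    Threshold = ``threshold_multiplier`` × (median absolute deviation /
    0.6745), a robust estimate of the noise standard deviation. Extracellular
    somatic spikes are trough-dominant, hence the negative default polarity.
    """

    threshold_multiplier: float = 4.5
    refractory_s: float = 0.004
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be > 0")
        if self.polarity not in {"negative", "positive", "both"}:
            raise ValueError("polarity must be negative, positive or both")


def bandpass_filter(
    x: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Output has the same length as the input. Forward–backward application
    squares the magnitude response and cancels group delay, so window/label
    alignment is preserved.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    sos = spec.sos(fs)
    if x.shape[-1] == 0:
        return x.astype(float)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def undersample(x: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th sample starting at index 0 (plain decimation)."""
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    return np.asarray(x)[..., :: int(factor)]


def detect_spikes(
    x: np.ndarray, fs: float, spec: SpikeDetectSpec | None = None
) -> SpikeTrain:
    """Detect spikes on an already band-passed trace.

    Supra-threshold local extrema are accepted greedily left to right: any
    candidate within ``refractory_s`` of the last accepted event is discarded
    (the earlier event wins). Returns event times in seconds.
    """
    spec = spec or SpikeDetectSpec()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return SpikeTrain(np.empty(0))

    med = np.median(x)
    mad = np.median(np.abs(x - med))
    threshold = spec.threshold_multiplier * mad / 0.6745

    if spec.polarity == "negative":
        y = -x
    elif spec.polarity == "positive":
        y = x
    else:
        y = np.abs(x)
    peaks, _ = sps.find_peaks(y, height=threshold)

    refractory_n = spec.refractory_s * fs
    accepted = []
    last = -np.inf
    for p in peaks:
        if p - last >= refractory_n:
            accepted.append(p)
            last = p
    return SpikeTrain(np.asarray(accepted, dtype=float) / fs)


def preprocess_session(
    session: Session,
    filter_spec: FilterSpec | None = None,
    undersample_factor: int = 2,
) -> Session:
    """Filter every channel and decimate; rescale intervals and fs to match.

    Interval boundaries map to the retained sample grid (ceil division), so
    half-open state spans stay non-overlapping and in order.
    """
    filter_spec = filter_spec or FilterSpec()
    if int(undersample_factor) != undersample_factor or undersample_factor < 1:
        raise ValueError("undersample_factor must be an integer >= 1")
    f = int(undersample_factor)
    n_ch, n = session.signal.shape
    n_out = -(-n // f)
    out = np.empty((n_ch, n_out), dtype=np.float32)
    for ch in range(n_ch):  # channel-wise to bound peak memory on long sessions
        filt = bandpass_filter(session.signal[ch].astype(np.float64), session.fs, filter_spec)
        out[ch] = undersample(filt, f)
    intervals = [(-(-s // f), -(-e // f), st) for s, e, st in session.intervals]
    provenance = dict(session.provenance)
    provenance["preprocess"] = {
        "filter": {
            "f_lo": filter_spec.f_lo,
            "f_hi": filter_spec.f_hi,
            "order": filter_spec.order,
            "order_convention": filter_spec.order_convention,
            "zero_phase": filter_spec.zero_phase,
        },
        "undersample_factor": f,
    }
    return Session(
        signal=out,
        fs=session.fs / f,
        intervals=intervals,
        channel_status=list(session.channel_status),
        physio=session.physio,
        fs_physio=session.fs_physio,
        provenance=provenance,
    )


def spike_trains_to_csv(trains: list, path) -> None:
    """Export detected spike trains as a two-column CSV (time_s, channel)."""
    import csv

    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["time_s", "channel"])
        for train in trains:
            for t in train.times:
                writer.writerow([repr(float(t)), "" if train.channel is None else train.channel])
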