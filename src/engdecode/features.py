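"""Windowing, nine-feature extraction and feature-table assembly.

Each class interval of a session is split on the raw timeline into a training
and a held-out test portion (test:total ratio 1:10 by default) BEFORE any
windowing, so no raw sample ever appears on both sides. The training portion
is cut into fixed-length windows with 20% overlap (0.55 s / 0.11 s defaults);
the test portion is windowed without overlap.

Every window on every channel is summarised by nine classic myoelectric-style
features:

========  ======================================================
MEAN      arithmetic mean
VAR       population variance
SKEW      third standardised moment (0 for degenerate windows)
KUR       excess kurtosis, fourth standardised moment − 3
MAV       mean absolute value
WL        waveform length, Σ|x[i+1] − x[i]|
MAX       maximum sample
AMP       peak-to-peak amplitude, max − min
POW       mean squared sample
========  ======================================================

Per-channel feature blocks are concatenated channel-major into one row per
window (32 channels × 9 features = 288 columns). Standardisation is fit on
training data only and applied to the test table with the training mean/sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import STATES, Session

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("MEAN", "VAR", "SKEW", "KUR", "MAV", "WL", "MAX", "AMP", "POW")
N_FEATURES = len(FEATURE_NAMES)

__all__ = [
    "FEATURE_NAMES",
    "WindowSpec",
    "FeatureTable",
    "WindowFeatureExtractor",
    "split_train_test",
    "make_windows",
    "extract_features",
    "extract_feature_matrix",
    "assemble_table",
    "standardize",
    "shuffle_rows",
    "session_to_tables",
]


@dataclass(frozen=True)
class WindowSpec:
    """Framing parameters: window length and training overlap, in seconds.

    The test split is always windowed without overlap (``test_overlap_s`` is
    fixed at 0); the 0.11 s training overlap is 20% of the 0.55 s default
    length and exists only to enlarge the training set.
    """

    length_s: float = 0.55
    overlap_s: float = 0.11
    test_overlap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")
        if not 0 <= self.overlap_s < self.length_s:
            raise ValueError("need 0 <= overlap_s < length_s")
        if self.test_overlap_s != 0.0:
            raise ValueError("test windows are non-overlapping by contract")


@dataclass
class FeatureTable:
    """Windows × (channels × 9 features) matrix with aligned labels.

    ``window_ranges`` records each row's half-open raw-sample span on the
    session timeline (used for leakage audits); ``scaler`` holds the
    (mean, sd) fitted on training data once standardised. Rows are kept in
    time order within each class unless shuffled explicitly.
    """

    X: np.ndarray
    labels: np.ndarray
    column_names: list
    split_tag: str = "train"
    scaler: tuple | None = None
    window_ranges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match row count")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match column count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        unknown = set(np.unique(self.labels)) - set(STATES)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        if self.window_ranges is not None:
            self.window_ranges = np.asarray(self.window_ranges, dtype=int)
            if self.window_ranges.shape != (self.X.shape[0], 2):
                raise ValueError("window_ranges must be (n_rows, 2)")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df["label"] = self.labels
        if self.window_ranges is not None:
            df["start_sample"] = self.window_ranges[:, 0]
            df["end_sample"] = self.window_ranges[:, 1]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def scaler_to_json(self, path) -> None:
        """Serialise the fitted (mean, sd) scaler for reuse outside Python."""
        if self.scaler is None:
            raise ValueError("table has no fitted scaler")
        import json

        mean, sd = self.scaler
        payload = {
            "columns": list(self.column_names),
            "mean": [float(v) for v in mean],
            "sd": [float(v) for v in sd],
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path, split_tag: str = "train") -> "FeatureTable":
        df = pd.read_csv(path)
        ranges = None
        if {"start_sample", "end_sample"} <= set(df.columns):
            ranges = df[["start_sample", "end_sample"]].to_numpy()
            df = df.drop(columns=["start_sample", "end_sample"])
        labels = df.pop("label").to_numpy()
        return cls(
            X=df.to_numpy(),
            labels=labels,
            column_names=list(df.columns),
            split_tag=split_tag,
            window_ranges=ranges,
        )


def split_train_test(session: Session, test_fraction: float = 0.1):
    """Split every class interval on the raw timeline into train/test spans.

    The final ``test_fraction`` of each interval's duration becomes test data
    (the chronologically later part, mimicking prospective evaluation), the
    rest training data. Returns two lists of ``(start, end, state)`` spans.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    train_segments, test_segments = [], []
    for start, end, state in session.intervals:
        n = end - start
        n_test = int(round(n * test_fraction))
        if n_test < 1 or n - n_test < 1:
            raise ValueError(
                f"interval for class {state!r} is too short to split "
                f"({n} samples at test_fraction={test_fraction})"
            )
        boundary = end - n_test
        train_segments.append((start, boundary, state))
        test_segments.append((boundary, end, state))
    return train_segments, test_segments


def make_windows(x: np.ndarray, fs: float, length_s: float, overlap_s: float = 0.0):
    """Cut a trace into fixed-length windows with a fixed overlap.

    Returns ``(windows, starts)`` where ``windows`` is (n_windows, w) and
    ``starts`` the window start indices. With window w and overlap o samples
    the count is ``floor((L - w) / (w - o)) + 1``; the trailing remainder is
    discarded. A window longer than the trace yields zero windows (warned,
    not an error).
    """
    x = np.asarray(x)
    w = int(round(length_s * fs))
    o = int(round(overlap_s * fs))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if not 0 <= o < w:
        raise ValueError("need 0 <= overlap < window length")
    L = x.shape[-1]
    if w > L:
        logger.warning("window of %d samples longer than trace of %d; 0 windows", w, L)
        return np.empty((0, w), dtype=x.dtype), np.empty(0, dtype=int)
    step = w - o
    starts = np.arange(0, L - w + 1, step)
    windows = np.lib.stride_tricks.sliding_window_view(x, w)[starts]
    return np.ascontiguousarray(windows), starts


def extract_feature_matrix(windows: np.ndarray) -> np.ndarray:
    """Vectorised nine-feature extraction: (n_windows, w) → (n_windows, 9).

    Moments are population (biased) moments; KUR is excess kurtosis. Windows
    with (numerically) zero variance get SKEW = KUR = 0 so dead or saturated
    channels never inject non-finite values.
    """
    W = np.asarray(windows, dtype=np.float64)
    if W.ndim != 2:
        raise ValueError("windows must be 2-D (n_windows, w)")
    if W.shape[1] < 2:
        raise ValueError("windows must have at least 2 samples")
    mu = W.mean(axis=1)
    d = W - mu[:, None]
    var = np.mean(d * d, axis=1)
    power = np.mean(W * W, axis=1)
    # relative guard: a window whose variance is at rounding level is constant
    degenerate = var <= 1e-18 * np.maximum(power, 1e-300)
    safe_var = np.where(degenerate, 1.0, var)
    m3 = np.mean(d**3, axis=1)
    m4 = np.mean(d**4, axis=1)
    skew = np.where(degenerate, 0.0, m3 / safe_var**1.5)
    kur = np.where(degenerate, 0.0, m4 / safe_var**2 - 3.0)
    mav = np.mean(np.abs(W), axis=1)
    wl = np.sum(np.abs(np.diff(W, axis=1)), axis=1)
    mx = W.max(axis=1)
    amp = mx - W.min(axis=1)
    return np.column_stack([mu, var, skew, kur, mav, wl, mx, amp, power])


def extract_features(window: np.ndarray) -> np.ndarray:
    """Nine features of a single window, ordered as ``FEATURE_NAMES``."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be a 1-D vector with at least 2 samples")
    return extract_feature_matrix(window[None, :])[0]


class WindowFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer wrapping :func:`extract_feature_matrix`.

    Accepts ``(n_windows, n_samples)`` for single-channel input or
    ``(n_windows, n_channels, n_samples)`` for multi-channel windows, and
    returns the channel-major feature matrix compatible with sklearn
    pipelines and model selection.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[-1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.ndim == 2:
            return extract_feature_matrix(X)
        if X.ndim == 3:
            blocks = [extract_feature_matrix(X[:, ch, :]) for ch in range(X.shape[1])]
            return np.hstack(blocks)
        raise ValueError("expected 2-D or 3-D window array")

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


def column_name(channel: int, feature: str) -> str:
    return f"ch{channel:02d}_{feature}"


def assemble_table(
    per_channel_features: list,
    labels,
    channel_ids: list | None = None,
    split_tag: str = "train",
    window_ranges=None,
) -> FeatureTable:
    """Concatenate per-channel (n_windows × 9) blocks channel-major.

    Row i is the concatenation over channels of window i's nine features;
    column order is channel-major, feature-minor and recorded in the table's
    ``column_names``.
    """
    if not per_channel_features:
        raise ValueError("need at least one channel")
    counts = {np.asarray(f).shape[0] for f in per_channel_features}
    if len(counts) != 1:
        raise ValueError(f"window counts differ across channels: {sorted(counts)}")
    if channel_ids is None:
        channel_ids = list(range(len(per_channel_features)))
    X = np.hstack([np.asarray(f, dtype=float) for f in per_channel_features])
    names = [column_name(ch, feat) for ch in channel_ids for feat in FEATURE_NAMES]
    return FeatureTable(
        X=X,
        labels=np.asarray(labels),
        column_names=names,
        split_tag=split_tag,
        window_ranges=window_ranges,
    )


def standardize(train: FeatureTable, test: FeatureTable | None = None):
    """Fit a per-column (mean, sd) scaler on the training table and apply it.

    The sd is floored at 1e-12 so zero-variance columns (dead channels) map to
    zeros in train and finite values in test. Re-standardising an already
    scaled table, or fitting on a table not tagged as training data, violates
    the train-only-fitting contract and raises.
    """
    if train.scaler is not None:
        raise ValueError("table already standardized; refusing to re-fit")
    if train.split_tag != "train":
        raise ValueError(
            f"scaler must be fitted on training data, got split_tag={train.split_tag!r}"
        )
    mean = train.X.mean(axis=0)
    sd = np.maximum(train.X.std(axis=0), 1e-12)
    scaler = (mean, sd)
    train_out = replace(train, X=(train.X - mean) / sd, scaler=scaler)
    if test is None:
        return train_out
    if test.scaler is not None:
        raise ValueError("test table already standardized")
    if test.X.shape[1] != train.X.shape[1]:
        raise ValueError("train/test column mismatch")
    test_out = replace(test, X=(test.X - mean) / sd, scaler=scaler)
    return train_out, test_out


def shuffle_rows(table: FeatureTable, seed: int) -> FeatureTable:
    """Deterministically permute rows (labels and provenance stay aligned)."""
    perm = np.random.default_rng(seed).permutation(table.n_rows)
    return replace(
        table,
        X=table.X[perm],
        labels=table.labels[perm],
        window_ranges=None if table.window_ranges is None else table.window_ranges[perm],
    )


def _segments_to_table(
    session: Session, segments, length_s: float, overlap_s: float, split_tag: str
) -> FeatureTable:
    per_channel = [[] for _ in range(session.n_channels)]
    labels, ranges = [], []
    for start, end, state in segments:
        seg_windows = None
        for ch in range(session.n_channels):
            w, starts = make_windows(
                session.signal[ch, start:end], session.fs, length_s, overlap_s
            )
            if w.shape[0] == 0:
                raise ValueError(
                    f"class {state!r} segment too short for a {length_s} s window "
                    f"({end - start} samples at fs={session.fs})"
                )
            per_channel[ch].append(extract_feature_matrix(w))
            seg_windows = (starts, w.shape[1])
        starts, wlen = seg_windows
        labels.extend([state] * len(starts))
        ranges.extend((start + s, start + s + wlen) for s in starts)
    blocks = [np.vstack(fb) for fb in per_channel]
    return assemble_table(
        blocks,
        labels,
        split_tag=split_tag,
        window_ranges=np.asarray(ranges, dtype=int),
    )


def session_to_tables(
    session: Session,
    window_spec: WindowSpec | None = None,
    test_fraction: float = 0.1,
):
    """Full framing pipeline: split per class interval, window, featurise.

    Returns unstandardised ``(train_table, test_table)`` with rows in time
    order within each class, ready for nested cross-validation (which
    standardises and shuffles inside each fold).
    """
    spec = window_spec or WindowSpec()
    train_segments, test_segments = split_train_test(session, test_fraction)
    train = _segments_to_table(
        session, train_segments, spec.length_s, spec.overlap_s, "train"
    )
    test = _segments_to_table(
        session, test_segments, spec.length_s, spec.test_overlap_s, "test"
    )
    return train, test
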