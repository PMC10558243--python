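"""Window-length analysis: RF balanced accuracy across 20 window lengths.

Twenty window lengths, linearly spaced from 50 ms to 1 s inclusive (step
0.05 s), are each evaluated by cross-validated random-forest classification;
the training-side overlap is always 20% of the length under test, the test
side is windowed without overlap. Folds are contiguous spans of the raw
timeline cut per class interval, and the signal is re-windowed inside each
fold, so train and test windows never share raw samples at any length.

The trade-off rule formalises "highest BA at the smallest window": among the
usable lengths, pick the smallest one whose cross-session mean BA is within a
tolerance band (2 percentage points by default) of the best mean BA — shorter
windows mean lower decision latency for eventual real-time use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .decode import BladderStateDecoder, balanced_accuracy, confusion_matrix_3
from .features import _segments_to_table, standardize, shuffle_rows
from .synth import Session

logger = logging.getLogger(__name__)

__all__ = ["SweepResult", "window_sweep", "select_tradeoff", "sweep_lengths"]

DEFAULT_RF_PARAMS = {"n_estimators": 100, "max_depth": 20}


def sweep_lengths(
    n_lengths: int = 20, min_length_s: float = 0.05, max_length_s: float = 1.0
) -> np.ndarray:
    """Evaluated window lengths: linear spacing, endpoints inclusive."""
    return np.round(np.linspace(min_length_s, max_length_s, n_lengths), 10)


@dataclass
class SweepResult:
    """Per-length cross-validated BA and the selected trade-off length."""

    lengths_s: np.ndarray
    overlaps_s: np.ndarray
    per_session_ba: np.ndarray  # sessions x lengths, NaN where unusable
    usable: np.ndarray  # lengths, True where every session produced a score
    rf_params: dict
    n_folds: int
    seed: int
    tolerance_pp: float
    selected_length_s: float | None = None

    def __post_init__(self) -> None:
        self.lengths_s = np.asarray(self.lengths_s, dtype=float)
        if np.any(np.diff(self.lengths_s) <= 0):
            raise ValueError("lengths must be strictly increasing")

    @property
    def mean_ba(self) -> np.ndarray:
        """Cross-session mean BA per length (NaN where unusable)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.per_session_ba, axis=0)

    def to_dict(self) -> dict:
        return {
            "lengths_s": self.lengths_s.tolist(),
            "overlaps_s": self.overlaps_s.tolist(),
            "per_session_ba": [
                [None if np.isnan(v) else float(v) for v in row]
                for row in self.per_session_ba
            ],
            "mean_ba": [None if np.isnan(v) else float(v) for v in self.mean_ba],
            "usable": self.usable.astype(bool).tolist(),
            "rf_params": self.rf_params,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "tolerance_pp": self.tolerance_pp,
            "selected_length_s": self.selected_length_s,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        """Plot-ready long-format CSV: length_s, session, mean_ba."""
        import pandas as pd

        rows = [
            {"length_s": L, "session": s, "mean_ba": self.per_session_ba[s, i]}
            for s in range(self.per_session_ba.shape[0])
            for i, L in enumerate(self.lengths_s)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def _timeline_folds(session: Session, n_folds: int):
    """Cut every class interval into n_folds contiguous sub-spans.

    Yields per fold a pair (train_segments, test_segments) on the raw
    timeline: fold k's test spans are sub-span k of every class.
    """
    per_class = []
    for start, end, state in session.intervals:
        edges = np.linspace(start, end, n_folds + 1).astype(int)
        per_class.append([(edges[i], edges[i + 1], state) for i in range(n_folds)])
    for k in range(n_folds):
        test = [spans[k] for spans in per_class]
        train = [s for spans in per_class for i, s in enumerate(spans) if i != k]
        yield train, test


def _cv_ba(
    session: Session,
    length_s: float,
    overlap_s: float,
    rf_params: dict,
    n_folds: int,
    seeds: list,
) -> float:
    bas = []
    for k, (train_seg, test_seg) in enumerate(_timeline_folds(session, n_folds)):
        train = _segments_to_table(session, train_seg, length_s, overlap_s, "train")
        test = _segments_to_table(session, test_seg, length_s, 0.0, "test")
        train, test = standardize(train, test)
        train = shuffle_rows(train, seeds[k])
        est = BladderStateDecoder(
            model_kind="RF", random_state=seeds[k], **rf_params
        ).fit(train.X, train.labels)
        cm = confusion_matrix_3(test.labels, est.predict(test.X))
        bas.append(balanced_accuracy(cm))
    return float(np.mean(bas))


def window_sweep(
    sessions: list,
    rf_params: dict | None = None,
    seed: int = 0,
    n_lengths: int = 20,
    min_length_s: float = 0.05,
    max_length_s: float = 1.0,
    n_folds: int = 5,
    tolerance_pp: float = 2.0,
) -> SweepResult:
    """Evaluate cross-validated RF balanced accuracy at every window length.

    ``sessions`` must already be preprocessed (filtered, undersampled). One
    fixed RF configuration is used throughout (grid search per length is not
    part of this analysis); a length at which any fold of any session cannot
    produce at least one window per class is flagged unusable rather than
    aborting the sweep.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    if not sessions:
        raise ValueError("need at least one session")
    rf_params = dict(rf_params or DEFAULT_RF_PARAMS)
    extra = set(rf_params) - {"n_estimators", "max_depth"}
    if extra:
        raise ValueError(f"rf_params supports n_estimators/max_depth only, got {sorted(extra)}")

    lengths = sweep_lengths(n_lengths, min_length_s, max_length_s)
    overlaps = np.round(0.2 * lengths, 10)
    ss = np.random.SeedSequence(seed)
    length_seeds = ss.spawn(len(lengths))

    per_session = np.full((len(sessions), len(lengths)), np.nan)
    for i, (L, o) in enumerate(zip(lengths, overlaps)):
        fold_seeds = [
            int(s.generate_state(1)[0] % 2**31)
            for s in length_seeds[i].spawn(len(sessions) * n_folds)
        ]
        for s_idx, session in enumerate(sessions):
            seeds = fold_seeds[s_idx * n_folds : (s_idx + 1) * n_folds]
            try:
                per_session[s_idx, i] = _cv_ba(session, L, o, rf_params, n_folds, seeds)
            except ValueError as err:
                logger.warning("length %.3f s unusable on session %d: %s", L, s_idx, err)

    usable = ~np.any(np.isnan(per_session), axis=0)
    result = SweepResult(
        lengths_s=lengths,
        overlaps_s=overlaps,
        per_session_ba=per_session,
        usable=usable,
        rf_params=rf_params,
        n_folds=n_folds,
        seed=seed,
        tolerance_pp=tolerance_pp,
    )
    result.selected_length_s = select_tradeoff(result, tolerance_pp)
    return result


def select_tradeoff(result: SweepResult, tolerance_pp: float = 2.0) -> float:
    """Smallest usable length whose mean BA is within ``tolerance_pp`` of the best.

    Tolerance is in percentage points of balanced accuracy (BA itself is a
    proportion). With tolerance 0 this returns the first argmax length.
    """
    if tolerance_pp < 0:
        raise ValueError("tolerance_pp must be non-negative")
    mean = result.mean_ba
    usable = result.usable & ~np.isnan(mean)
    if not np.any(usable):
        raise ValueError("no usable window lengths in sweep result")
    best = np.nanmax(mean[usable])
    threshold = best - tolerance_pp / 100.0
    for L, ok, ba in zip(result.lengths_s, usable, mean):
        if ok and ba >= threshold - 1e-12:
            return float(L)
    raise AssertionError("unreachable: best length always satisfies its own band")
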