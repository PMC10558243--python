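"""Windowing, feature extraction, table assembly and standardisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import engdecode as ed
from engdecode.features import FEATURE_NAMES, column_name


def bruteforce_features(window):
    """Independent pure-Python oracle for the nine features."""
    xs = [float(v) for v in window]
    n = len(xs)
    mean = sum(xs) / n
    var = sum((x - mean) ** 2 for x in xs) / n
    if var > 0:
        skew = (sum((x - mean) ** 3 for x in xs) / n) / var**1.5
        kur = (sum((x - mean) ** 4 for x in xs) / n) / var**2 - 3.0
    else:
        skew = kur = 0.0
    mav = sum(abs(x) for x in xs) / n
    wl = sum(abs(b - a) for a, b in zip(xs, xs[1:]))
    mx = max(xs)
    amp = mx - min(xs)
    power = sum(x * x for x in xs) / n
    return [mean, var, skew, kur, mav, wl, mx, amp, power]


def bruteforce_window_count(L, w, o):
    """Slide a window by hand and count the fits."""
    count, start = 0, 0
    while start + w <= L:
        count += 1
        start += w - o
    return count


class TestMakeWindows:
    def test_counts_from_spec_examples(self):
        fs = 1.0
        w, _ = ed.make_windows(np.zeros(1000), fs, 100, 20)
        assert w.shape == (12, 100)
        w, _ = ed.make_windows(np.zeros(1000), fs, 100, 0)
        assert w.shape == (10, 100)

    def test_window_longer_than_trace_warns_not_raises(self, caplog):
        w, starts = ed.make_windows(np.zeros(50), 1.0, 100, 0)
        assert w.shape == (0, 100) and starts.size == 0

    def test_contents_are_contiguous_slices(self):
        x = np.arange(30.0)
        w, starts = ed.make_windows(x, 1.0, 10, 5)
        for win, s in zip(w, starts):
            assert np.array_equal(win, x[s : s + 10])

    @given(
        L=st.integers(2, 2000),
        w=st.integers(2, 2000),
        o=st.integers(0, 1999),
    )
    @settings(max_examples=200, deadline=None)
    def test_count_matches_bruteforce(self, L, w, o):
        w = min(w, L)
        o = min(o, w - 1)
        wins, _ = ed.make_windows(np.zeros(L), 1.0, w, o)
        assert wins.shape[0] == bruteforce_window_count(L, w, o)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            ed.make_windows(np.zeros(100), 1.0, 10, 10)


class TestExtractFeatures:
    def test_constant_window_degenerate_policy(self):
        out = ed.extract_features(np.full(50, 3.0))
        expected = dict(
            MEAN=3.0, VAR=0.0, SKEW=0.0, KUR=0.0, MAV=3.0, WL=0.0, MAX=3.0,
            AMP=0.0, POW=9.0,
        )
        for name, value in zip(FEATURE_NAMES, out):
            assert value == pytest.approx(expected[name], abs=1e-9), name

    def test_alternating_window_hand_arithmetic(self):
        out = dict(zip(FEATURE_NAMES, ed.extract_features(np.array([1.0, -1.0, 1.0, -1.0]))))
        assert out == pytest.approx(
            dict(MEAN=0, VAR=1, SKEW=0, KUR=-2, MAV=1, WL=6, MAX=1, AMP=2, POW=1)
        )

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 300)
            win = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 10), n)
            ours = ed.extract_features(win)
            ref = bruteforce_features(win)
            np.testing.assert_allclose(ours, ref, rtol=1e-9, atol=1e-12)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            ed.extract_features(np.array([1.0]))

    def test_matrix_and_single_agree(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(20, 64))
        M = ed.extract_feature_matrix(W)
        for i in range(20):
            np.testing.assert_allclose(M[i], ed.extract_features(W[i]), rtol=1e-12)


class TestWindowFeatureExtractor:
    def test_multichannel_transform_is_channel_major(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 3, 40))
        out = ed.WindowFeatureExtractor().fit_transform(X)
        assert out.shape == (5, 27)
        np.testing.assert_allclose(out[:, 9:18], ed.extract_feature_matrix(X[:, 1, :]))

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = ed.WindowFeatureExtractor()
        assert clone(est).get_params() == est.get_params()


class TestSplitTrainTest:
    def test_one_tenth_arithmetic(self):
        session = ed.Session(
            signal=np.zeros((1, 300)),
            fs=1.0,
            intervals=[(0, 100, "baseline"), (100, 200, "full"), (200, 300, "micturition")],
            channel_status=["functional"],
        )
        train, test = ed.split_train_test(session, 0.1)
        assert [(e - s) for s, e, _ in train] == [90, 90, 90]
        assert [(e - s) for s, e, _ in test] == [10, 10, 10]

    def test_sample_index_sets_disjoint_and_exhaustive(self, small_session):
        train, test = ed.split_train_test(small_session, 0.1)
        train_idx = set()
        test_idx = set()
        for s, e, _ in train:
            train_idx.update(range(s, e))
        for s, e, _ in test:
            test_idx.update(range(s, e))
        assert not (train_idx & test_idx)
        n = small_session.signal.shape[1]
        assert len(train_idx) + len(test_idx) == n

    def test_too_short_interval_names_class(self):
        session = ed.Session(
            signal=np.zeros((1, 12)),
            fs=1.0,
            intervals=[(0, 4, "baseline"), (4, 8, "full"), (8, 12, "micturition")],
            channel_status=["functional"],
        )
        with pytest.raises(ValueError, match="baseline"):
            ed.split_train_test(session, 0.05)


class TestAssembleTable:
    def test_32_channels_yield_288_columns(self):
        blocks = [np.zeros((4, 9)) for _ in range(32)]
        table = ed.assemble_table(blocks, ["baseline"] * 4)
        assert table.X.shape == (4, 288)
        assert table.column_names[0] == "ch00_MEAN"
        assert table.column_names[-1] == "ch31_POW"

    def test_single_channel_row_equals_feature_vector(self):
        win = np.random.default_rng(3).normal(size=60)
        table = ed.assemble_table([ed.extract_features(win)[None, :]], ["full"])
        np.testing.assert_allclose(table.X[0], ed.extract_features(win))

    def test_channel_permutation_permutes_blocks(self):
        rng = np.random.default_rng(4)
        blocks = [rng.normal(size=(3, 9)) for _ in range(4)]
        labels = ["baseline", "full", "micturition"]
        a = ed.assemble_table(blocks, labels, channel_ids=[0, 1, 2, 3])
        perm = [2, 0, 3, 1]
        b = ed.assemble_table([blocks[i] for i in perm], labels, channel_ids=perm)
        for new_pos, ch in enumerate(perm):
            np.testing.assert_array_equal(
                b.X[:, new_pos * 9 : (new_pos + 1) * 9],
                a.X[:, ch * 9 : (ch + 1) * 9],
            )
            assert b.column_names[new_pos * 9] == column_name(ch, "MEAN")

    def test_mismatched_window_counts_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ed.assemble_table([np.zeros((3, 9)), np.zeros((4, 9))], ["baseline"] * 3)


class TestStandardize:
    def _table(self, X, tag="train"):
        labels = np.resize(list(ed.STATES), X.shape[0])
        names = [f"ch00_{f}" for f in FEATURE_NAMES][: X.shape[1]]
        return ed.FeatureTable(X=X, labels=labels, column_names=names, split_tag=tag)

    def test_train_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(5)
        train = self._table(rng.normal(3.0, 2.0, size=(200, 5)))
        out = ed.standardize(train)
        assert np.all(np.abs(out.X.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(out.X.std(axis=0) - 1) < 1e-10)

    def test_zero_variance_column_maps_to_zero(self):
        X = np.column_stack([np.full(30, 7.0), np.random.default_rng(6).normal(size=30)])
        train = self._table(X)
        test = self._table(X + 1.0, tag="test")
        tr, te = ed.standardize(train, test)
        assert np.all(tr.X[:, 0] == 0)
        assert np.all(np.isfinite(te.X))

    def test_test_scaled_with_train_statistics(self):
        rng = np.random.default_rng(7)
        train = self._table(rng.normal(0.0, 1.0, size=(100, 3)))
        test = self._table(rng.normal(5.0, 2.0, size=(50, 3)), tag="test")
        _, te = ed.standardize(train, test)
        independent = (test.X - test.X.mean(0)) / test.X.std(0)
        assert not np.allclose(te.X, independent)
        assert te.X.mean() > 1.0  # shifted distribution stays shifted

    def test_refit_and_test_fitting_violations(self):
        rng = np.random.default_rng(8)
        train = self._table(rng.normal(size=(30, 2)))
        out = ed.standardize(train)
        with pytest.raises(ValueError, match="already standardized"):
            ed.standardize(out)
        test = self._table(rng.normal(size=(30, 2)), tag="test")
        with pytest.raises(ValueError, match="training data"):
            ed.standardize(test)


class TestShuffleRows:
    def test_permutation_preserves_pairs_and_counts(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 4))
        labels = np.resize(list(ed.STATES), 30)
        table = ed.FeatureTable(
            X=X, labels=labels, column_names=[f"ch00_{f}" for f in FEATURE_NAMES[:4]]
        )
        shuffled = ed.shuffle_rows(table, seed=3)
        assert shuffled.class_counts() == table.class_counts()
        orig = {(tuple(r), l) for r, l in zip(X, labels)}
        new = {(tuple(r), l) for r, l in zip(shuffled.X, shuffled.labels)}
        assert orig == new
        again = ed.shuffle_rows(table, seed=3)
        assert np.array_equal(shuffled.X, again.X)
        assert not np.array_equal(shuffled.X, table.X)


class TestSessionToTables:
    def test_balanced_test_windows_and_no_leakage(self, small_tables):
        train, test = small_tables
        counts = list(test.class_counts().values())
        assert max(counts) - min(counts) <= 1
        # raw-sample provenance of train and test windows must not intersect
        train_samples = set()
        for s, e in train.window_ranges:
            train_samples.update(range(s, e))
        for s, e in test.window_ranges:
            assert train_samples.isdisjoint(range(s, e))

    def test_column_count_and_labels(self, small_tables):
        train, test = small_tables
        assert train.X.shape[1] == 8 * 9
        assert set(np.unique(train.labels)) == set(ed.STATES)
        assert train.split_tag == "train" and test.split_tag == "test"

    def test_csv_roundtrip(self, small_tables, tmp_path):
        train, _ = small_tables
        train.to_csv(tmp_path / "t.csv")
        back = ed.FeatureTable.from_csv(tmp_path / "t.csv", "train")
        np.testing.assert_allclose(back.X, train.X, rtol=1e-12, atol=1e-12)
        assert list(back.labels) == list(train.labels)
        assert back.column_names == train.column_names
        assert np.array_equal(back.window_ranges, train.window_ranges)


def test_scaler_serializes_to_json(small_tables, tmp_path):
    import json

    train, _ = small_tables
    std = ed.standardize(train)
    std.scaler_to_json(tmp_path / "scaler.json")
    payload = json.loads((tmp_path / "scaler.json").read_text())
    assert payload["columns"] == train.column_names
    np.testing.assert_allclose(payload["mean"], train.X.mean(axis=0))
    with pytest.raises(ValueError, match="no fitted scaler"):
        train.scaler_to_json(tmp_path / "nope.json")
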