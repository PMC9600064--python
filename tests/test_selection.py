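import json

import numpy as np
import pytest

from tetrosleep import (
    EmptySelectionError,
    InvalidInputError,
    SelectionTrace,
    inca_select,
    minmax_normalize,
    nca_weights,
    positive_select,
    relieff_weights,
    threshold_select,
    tsrfinca,
)
from tetrosleep.nca import _objective


class TestMinMaxNormalize:
    def test_examples(self):
        col = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(col.ravel(), [0, 0.5, 1])
        const = minmax_normalize(np.full((3, 1), 5.0))
        np.testing.assert_array_equal(const.ravel(), [0, 0, 0])
        already = np.array([[0.0], [1.0]])
        np.testing.assert_array_equal(minmax_normalize(already), already)

    def test_range_bounds(self):
        rng = np.random.default_rng(0)
        X = minmax_normalize(rng.standard_normal((20, 7)) * 100)
        assert X.min() == 0.0 and X.max() == 1.0


class TestThresholdSelect:
    def test_removes_exactly_constant_columns(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 50))
        X[:, 7] = 3.3
        X[:, 30] = -1.0
        Xn = minmax_normalize(X)
        kept, idx = threshold_select(Xn)
        assert idx.size == 48
        assert 7 not in idx and 30 not in idx

    def test_all_constant_raises(self):
        with pytest.raises(EmptySelectionError):
            threshold_select(minmax_normalize(np.ones((5, 4))))


class TestReliefF:
    def test_constant_feature_weight_zero_and_ranking(self):
        # two-class toy: col 0 separates perfectly, col 1 constant, col 2 noise
        rng = np.random.default_rng(2)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        X = np.column_stack([y.astype(float), np.full(8, 0.5), rng.random(8)])
        w = relieff_weights(X, y, n_neighbors=3)
        assert w[1] == 0.0
        assert w[0] > w[2]
        assert w[0] > 0

    def test_duplicated_columns_equal_weights(self):
        rng = np.random.default_rng(3)
        X = rng.random((12, 2))
        X = np.column_stack([X, X[:, 0]])
        y = np.array([0, 1] * 6)
        w = relieff_weights(X, y)
        assert w[0] == pytest.approx(w[2])

    def test_singleton_class_rejected(self):
        with pytest.raises(InvalidInputError):
            relieff_weights(np.random.default_rng(0).random((3, 2)), [0, 0, 1])


class TestPositiveSelect:
    def test_strict_positivity(self):
        X = np.arange(12.0).reshape(4, 3)
        kept, idx = positive_select(X, [0.2, 0.0, -0.1])
        np.testing.assert_array_equal(idx, [0])
        _, idx_all = positive_select(X, [1, 1, 1])
        assert idx_all.size == 3
        with pytest.raises(EmptySelectionError):
            positive_select(X, [0.0, -1.0, 0.0])


class TestNCA:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        X = rng.random((12, 5)).astype(np.float32)
        y = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 0, 1, 2])
        same = ((y[:, None] == y[None, :]) & ~np.eye(12, dtype=bool)).astype(np.float32)
        w0 = rng.random(5) + 0.5
        _, g = _objective(w0, X, same, 1 / 12, 12)
        for r in range(5):
            e = np.zeros(5)
            e[r] = 1e-5
            fp, _ = _objective(w0 + e, X, same, 1 / 12, 12)
            fm, _ = _objective(w0 - e, X, same, 1 / 12, 12)
            assert g[r] == pytest.approx((fp - fm) / 2e-5, rel=0.05, abs=1e-4)

    def test_informative_features_outrank_noise(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1, 2], 15)
        X = rng.random((45, 10))
        X[:, 2] += y * 1.0  # planted signal
        X[:, 7] += y * 1.0
        w = nca_weights(minmax_normalize(X), y)
        relevance = w**2
        assert set(np.argsort(-relevance)[:2]) == {2, 7}


class TestINCA:
    def test_degenerate_single_k(self, small_features):
        X, y = small_features
        Xn = minmax_normalize(X)[:, :150]
        _, loss, k, idx, kmin, kmax = inca_select(Xn, y, kmin=100, kmax=100, folds=4)
        assert loss.shape == (1,) and k == 100 and idx.size == 100

    def test_clamping_and_errors(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 8)
        X = rng.random((16, 30))
        _, loss, k, idx, kmin, kmax = inca_select(X, y, kmin=100, kmax=1000, folds=4)
        assert kmin == kmax == 30 and idx.size == 30
        with pytest.raises(InvalidInputError):
            inca_select(X, y, kmin=100, kmax=1000, folds=4, clamp=False)

    def test_fast_kernel_path_equals_direct_svm(self):
        """The incremental precomputed-kernel loss must equal plain cubic-SVM CV."""
        from sklearn.model_selection import StratifiedKFold

        from tetrosleep.evaluate import cubic_svm
        from tetrosleep.selection import _cv_loss_curve

        rng = np.random.default_rng(7)
        y = np.repeat(np.arange(3), 10)
        X = rng.random((30, 40))
        X[:, :5] += y[:, None] * 0.4
        losses = _cv_loss_curve(X, y, 10, 20, 5, seed=3)
        for pos, k in enumerate(range(10, 21)):
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
            wrong = 0
            for train, test in skf.split(X, y):
                clf = cubic_svm()
                clf.fit(X[train][:, :k], y[train])
                wrong += int((clf.predict(X[test][:, :k]) != y[test]).sum())
            assert losses[pos] == pytest.approx(wrong / 30)


class TestTSRFINCA:
    def test_trace_nesting_and_persistence(self, small_features, tmp_path):
        X, y = small_features
        trace = tsrfinca(X, y, kmin=40, kmax=60, folds=4, seed=0)
        s1 = set(trace.kept_after_threshold.tolist())
        s2 = set(trace.kept_after_relieff.tolist())
        s3 = set(trace.final_indices.tolist())
        assert s3 <= s2 <= s1
        assert 40 <= trace.final_indices.size <= 60
        assert trace.loss_curve.shape == (21,)
        assert trace.loss_curve[trace.chosen_k - trace.kmin] == trace.loss_curve.min()

        trace.save(tmp_path / "trace.json")
        loaded = SelectionTrace.load(tmp_path / "trace.json")
        np.testing.assert_array_equal(loaded.final_indices, trace.final_indices)
        loaded.validate()

        trace.save_loss_curve_csv(tmp_path / "loss.csv")
        rows = (tmp_path / "loss.csv").read_text().splitlines()
        assert rows[0] == "k,loss" and len(rows) == 22

    def test_deterministic_given_seed(self, small_features, tmp_path):
        X, y = small_features
        for run in ("a", "b"):
            tsrfinca(X, y, kmin=40, kmax=45, folds=4, seed=9).save(tmp_path / f"{run}.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_selected_beats_random_subset(self, small_features):
        """The chosen subset should classify no worse than random same-size subsets."""
        from tetrosleep import cross_validate

        X, y = small_features
        trace = tsrfinca(X, y, kmin=40, kmax=50, folds=4, seed=0)
        Xn = minmax_normalize(X)
        chosen = cross_validate(Xn[:, trace.final_indices], y, folds=4, seed=0)
        wins = 0
        for s in range(5):
            rand_idx = np.random.default_rng(s).choice(
                trace.kept_after_threshold, size=trace.final_indices.size, replace=False
            )
            rand = cross_validate(Xn[:, rand_idx], y, folds=4, seed=0)
            wins += chosen.metrics["accuracy"] >= rand.metrics["accuracy"]
        assert wins >= 4

    def test_loss_curve_json_valid(self, small_features, tmp_path):
        X, y = small_features
        trace = tsrfinca(X, y, kmin=40, kmax=42, folds=4, seed=0)
        trace.save(tmp_path / "t.json")
        payload = json.loads((tmp_path / "t.json").read_text())
        assert payload["chosen_k"] == trace.chosen_k
        assert len(payload["loss_curve"]) == 3
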