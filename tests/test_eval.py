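import numpy as np
import pytest

from tetrosleep import (
    InvalidInputError,
    compare_classifiers,
    cross_validate,
    metrics_from_confusion,
)


def _separable_six_class(n_per_class=12, seed=0):
    """Six distinct constant signatures plus tiny noise: trivially separable."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(6):
        centers = np.zeros(8)
        centers[c] = 5.0
        X.append(centers + 0.01 * rng.standard_normal((n_per_class, 8)))
        y += [f"C{c}"] * n_per_class
    return np.vstack(X), np.array(y)


class TestMetrics:
    def test_identity_confusion(self):
        m = metrics_from_confusion(np.eye(6, dtype=int) * 10)
        assert all(m[name] == pytest.approx(100.0) for name in m)

    def test_two_class_hand_computed(self):
        m = metrics_from_confusion([[8, 2], [1, 9]])
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["sensitivity"] == pytest.approx(85.0)
        assert m["geometric_mean"] == pytest.approx(100 * np.sqrt(0.8 * 0.9))
        # precision: 8/9 and 9/11
        assert m["average_precision"] == pytest.approx(100 * (8 / 9 + 9 / 11) / 2)

    def test_degenerate_single_column(self):
        m = metrics_from_confusion([[5, 0], [5, 0]])
        assert m["accuracy"] == pytest.approx(50.0)
        assert m["geometric_mean"] == 0.0

    def test_bounds_and_amgm(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            C = rng.integers(0, 30, size=(4, 4))
            C += np.eye(4, dtype=int)  # ensure nonzero support
            m = metrics_from_confusion(C)
            assert all(0.0 <= v <= 100.0 for v in m.values())
            assert m["geometric_mean"] <= m["sensitivity"] + 1e-9

    def test_invalid(self):
        with pytest.raises(InvalidInputError):
            metrics_from_confusion([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(InvalidInputError):
            metrics_from_confusion([[0, 0], [0, 0]])


class TestCrossValidate:
    def test_separable_data_is_perfect(self):
        X, y = _separable_six_class()
        report = cross_validate(X, y, folds=10, seed=0)
        assert np.all(report.fold_accuracies == 100.0)
        assert report.metrics["accuracy"] == 100.0
        np.testing.assert_array_equal(report.confusion, np.eye(6, dtype=int) * 12)

    def test_conservation_and_accuracy_identity(self):
        X, y = _separable_six_class()
        rng = np.random.default_rng(0)
        X = X + rng.standard_normal(X.shape) * 3.0  # make it hard but well-formed
        report = cross_validate(X, y, folds=4, seed=1)
        assert report.confusion.sum() == len(y)
        assert report.metrics["accuracy"] == pytest.approx(
            100.0 * np.trace(report.confusion) / len(y)
        )
        # balanced data: mean fold accuracy tracks pooled accuracy
        assert abs(report.fold_accuracies.mean() - report.metrics["accuracy"]) < 1.0

    def test_shuffled_labels_near_chance(self):
        X, y = _separable_six_class(n_per_class=20)
        accs = []
        for s in range(10):
            ys = np.random.default_rng(s).permutation(y)
            accs.append(cross_validate(X, ys, folds=4, seed=s).metrics["accuracy"])
        assert abs(np.mean(accs) - 100 / 6) < 10.0

    def test_determinism(self):
        X, y = _separable_six_class()
        X = X + np.random.default_rng(3).standard_normal(X.shape)
        r1 = cross_validate(X, y, folds=5, seed=42)
        r2 = cross_validate(X, y, folds=5, seed=42)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        np.testing.assert_array_equal(r1.fold_accuracies, r2.fold_accuracies)

    def test_small_class_rejected(self):
        X, y = _separable_six_class(n_per_class=4)
        with pytest.raises(InvalidInputError):
            cross_validate(X, y, folds=10)

    def test_report_persistence(self, tmp_path):
        X, y = _separable_six_class()
        report = cross_validate(X, y, folds=4, seed=0)
        report.save(tmp_path / "r.json")
        report.save_fold_csv(tmp_path / "folds.csv")
        assert "accuracy" in (tmp_path / "r.json").read_text()
        assert (tmp_path / "folds.csv").read_text().startswith("fold,accuracy")
        assert "C0" in report.render_confusion()


class TestCompareClassifiers:
    def test_contract_on_separable_toy(self):
        X, y = _separable_six_class(n_per_class=10)
        table = compare_classifiers(X, y, folds=5, seed=0)
        assert len(table) == 8
        assert "CSVM" in set(table["classifier"])
        assert table.loc[table["classifier"] == "CSVM", "accuracy"].item() == 100.0
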