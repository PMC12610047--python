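"""Metrics and protocol invariants: confusion/macro-F1 correctness,
stratified splitting, LOSO leakage, the sweep grid, and metric
consistency, cross-checked against scikit-learn."""

import numpy as np
import pytest

from mmh_har.activities import ActivityClass, N_CLASSES
from mmh_har.balance import BalanceConfig
from mmh_har.evaluate import (
    EvalResult, accuracy, confusion, hyperparameter_sweep, loso, macro_f1,
    macro_precision, micro_f1, split_70_30, subject_increment, sweep_from_csv,
    sweep_to_csv,
)
from mmh_har.models import TrainConfig, build_bilstm
from mmh_har.preprocess import Segment, SegmentSet


def _segset(y, subjects=None) -> SegmentSet:
    rng = np.random.default_rng(0)
    subjects = subjects or ["S01"] * len(y)
    return SegmentSet([
        Segment(x=rng.standard_normal((10, 240)), y=ActivityClass(int(c)),
                subject_id=s)
        for c, s in zip(y, subjects)
    ])


class TestConfusion:
    def test_perfect_predictions_fill_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 5, 6, 0])
        cm = confusion(y, y)
        assert cm.sum() == 8
        assert np.diag(cm).sum() == 8

    def test_absent_class_zero_row(self):
        cm = confusion([0, 0], [1, 1])
        assert (cm[2:] == 0).all()
        assert cm[0, 1] == 2

    def test_item_order_invariance(self):
        rng = np.random.default_rng(1)
        yt = rng.integers(0, 7, 50)
        yp = rng.integers(0, 7, 50)
        perm = rng.permutation(50)
        assert (confusion(yt, yp) == confusion(yt[perm], yp[perm])).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestMacroF1:
    def test_perfect_diagonal_is_one(self):
        cm = np.diag([5, 3, 9, 2, 4, 6, 1])
        assert macro_f1(cm) == 1.0

    def test_hand_computed_two_class_case(self):
        # [[1,1],[0,2]]: class0 P=1, R=1/2, F1=2/3; class1 P=2/3, R=1,
        # F1=4/5; macro = (2/3 + 4/5)/2
        cm = np.array([[1, 1], [0, 2]])
        assert macro_f1(cm) == pytest.approx(0.7333, abs=1e-4)

    def test_balanced_random_predictions_near_one_seventh(self):
        rng = np.random.default_rng(123)
        n = 100_000
        y_true = np.repeat(np.arange(N_CLASSES), n // N_CLASSES)
        y_pred = rng.integers(0, N_CLASSES, y_true.size)
        assert macro_f1(confusion(y_true, y_pred)) == \
            pytest.approx(1 / N_CLASSES, abs=0.01)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            macro_f1(np.zeros((7, 7), dtype=int))

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        yt = rng.integers(0, 7, 500)
        yp = rng.integers(0, 7, 500)
        cm = confusion(yt, yp)
        assert macro_f1(cm) == pytest.approx(
            sklearn.f1_score(yt, yp, average="macro", zero_division=0),
            abs=1e-12,
        )
        assert accuracy(cm) == pytest.approx(
            sklearn.accuracy_score(yt, yp), abs=1e-12
        )
        assert macro_precision(cm) == pytest.approx(
            sklearn.precision_score(yt, yp, average="macro",
                                    zero_division=0), abs=1e-12,
        )

    def test_micro_f1_equals_accuracy(self):
        rng = np.random.default_rng(8)
        yt = rng.integers(0, 7, 300)
        yp = rng.integers(0, 7, 300)
        cm = confusion(yt, yp)
        assert micro_f1(cm) == pytest.approx(accuracy(cm), abs=1e-12)

    def test_eval_result_metrics_recomputable_from_cm(self):
        rng = np.random.default_rng(9)
        yt = rng.integers(0, 7, 200)
        yp = rng.integers(0, 7, 200)
        res = EvalResult.from_predictions(yt, yp)
        assert res.macro_f1 == macro_f1(res.cm)
        assert res.accuracy == accuracy(res.cm)
        assert res.macro_precision == macro_precision(res.cm)


class TestSplit7030:
    def test_fractions_and_disjointness(self):
        y = np.repeat(np.arange(7), 100)
        ss = _segset(y)
        train_set, test_set = split_70_30(ss, seed=1)
        assert len(train_set) + len(test_set) == 700
        assert abs(len(train_set) - 490) <= 7
        ids = lambda s: {id(seg) for seg in s.segments}
        assert not (ids(train_set) & ids(test_set))

    def test_per_class_train_fraction_bounded(self):
        y = np.repeat(np.arange(7), 100)
        train_set, _ = split_70_30(_segset(y), seed=2)
        for cls, count in train_set.class_counts.items():
            assert 65 <= count <= 75

    def test_deterministic_per_seed(self):
        y = np.repeat(np.arange(7), 10)
        a_train, _ = split_70_30(_segset(y), seed=3)
        b_train, _ = split_70_30(_segset(y), seed=3)
        for sa, sb in zip(a_train.segments, b_train.segments):
            assert (sa.x == sb.x).all()

    def test_singleton_class_stays_in_train(self):
        y = [0] * 10 + [1]
        train_set, test_set = split_70_30(_segset(y), seed=0)
        assert train_set.class_counts[ActivityClass.LF] == 1
        assert test_set.class_counts[ActivityClass.LF] == 0


class TestLosoProtocol:
    def _cohort_set(self, n_subjects=3, per_class=4):
        y, subs = [], []
        for s in range(n_subjects):
            for c in range(7):
                y.extend([c] * per_class)
                subs.extend([f"S{s:02d}"] * per_class)
        return _segset(y, subs)

    def test_one_fold_per_subject_no_leakage(self):
        ss = self._cohort_set(3)
        folds = loso(
            ss, lambda: build_bilstm(2),
            TrainConfig(max_epochs=1, batch_size=16, seed=0),
        )
        assert [sid for sid, _ in folds] == ["S00", "S01", "S02"]

    def test_two_subject_minimum(self):
        ss = self._cohort_set(1)
        with pytest.raises(ValueError):
            loso(ss, lambda: build_bilstm(2), TrainConfig(max_epochs=1))


class TestSubjectIncrement:
    def test_output_length_and_k1_runs(self):
        y, subs = [], []
        for s in range(2):
            for c in range(7):
                y.extend([c] * 6)
                subs.extend([f"S{s:02d}"] * 6)
        ss = _segset(y, subs)
        curve = subject_increment(
            ss, lambda: build_bilstm(2),
            TrainConfig(max_epochs=1, batch_size=16, seed=0), repeats=2,
        )
        assert len(curve) == 2
        assert curve[0]["n_subjects"] == 1
        assert all(0 <= r["mean_macro_f1"] <= 1 for r in curve)


class TestSweep:
    def test_grid_shape_and_csv_round_trip(self, tmp_path):
        y = np.repeat(np.arange(7), 8)
        ss = _segset(y)
        grid = hyperparameter_sweep(
            build_bilstm, [2, 3], [1, 2], ss,
            TrainConfig(max_epochs=1, batch_size=16, seed=0),
        )
        assert grid.shape == (2, 2)
        p = tmp_path / "grid.csv"
        sweep_to_csv(grid, [2, 3], [1, 2], p)
        loaded, hus, eps = sweep_from_csv(p)
        assert hus == [2, 3] and eps == [1, 2]
        assert np.allclose(loaded, grid, atol=1e-6)
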