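"""Split hygiene, SMOTE geometry, fold selection and the training loop."""

import numpy as np
import pytest

from sozdetect import (
    FoldResult,
    ModelSpec,
    SyntheticSpec,
    TrainConfig,
    cross_validate,
    gen_uci_like,
    select_best,
    smote,
    split_train_test,
)
from sozdetect.cnn import init_weights
from sozdetect.preprocess import binarize_labels, standardize_set
from sozdetect.training import train_one


@pytest.fixture(scope="module")
def table():
    return gen_uci_like(20, SyntheticSpec(seed=21))  # 100 rows


class TestSplit:
    def test_sizes_and_stratification(self, table):
        config = TrainConfig(seed=0)
        trainval, test = split_train_test(table, config)
        assert len(trainval) == 80 and len(test) == 20
        # binary ratio 1:4 preserved
        assert int(test.labels_binary.sum()) == 4
        assert int(trainval.labels_binary.sum()) == 16

    def test_disjoint_and_exhaustive(self, table):
        trainval, test = split_train_test(table, TrainConfig(seed=1))
        combined = np.vstack([trainval.windows, test.windows])
        assert combined.shape[0] == len(table)
        # row identity: every original row appears exactly once
        original = {row.tobytes() for row in table.windows}
        recovered = [row.tobytes() for row in combined]
        assert set(recovered) == original and len(recovered) == len(original)

    def test_seeded_determinism(self, table):
        a, _ = split_train_test(table, TrainConfig(seed=5))
        b, _ = split_train_test(table, TrainConfig(seed=5))
        np.testing.assert_array_equal(a.windows, b.windows)

    def test_single_class_rejected(self):
        ws = gen_uci_like(5, SyntheticSpec(seed=0))
        ws.labels5[:] = 2
        with pytest.raises(ValueError):
            split_train_test(ws, TrainConfig())


class TestSmote:
    def test_balances_counts(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((40, 6)), rng.standard_normal((10, 6)) + 5])
        y = np.array([0] * 40 + [1] * 10)
        X2, y2 = smote(X, y, seed=1)
        assert int((y2 == 0).sum()) == 40 and int((y2 == 1).sum()) == 40

    def test_synthetic_rows_are_convex_combinations(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.standard_normal((30, 5)), rng.standard_normal((8, 5)) + 3])
        y = np.array([0] * 30 + [1] * 8)
        X2, y2, parents = smote(X, y, k_neighbors=5, seed=2, return_parents=True)
        minority = X[y == 1]
        synth = X2[len(X):]
        for row, (i, j, lam) in zip(synth, parents):
            expected = minority[i] + lam * (minority[j] - minority[i])
            np.testing.assert_allclose(row, expected, atol=1e-12)
            assert 0.0 <= lam <= 1.0
            # lambda is recoverable componentwise wherever parent coords differ
            diff = minority[j] - minority[i]
            mask = np.abs(diff) > 1e-12
            lam_solved = (row[mask] - minority[i][mask]) / diff[mask]
            np.testing.assert_allclose(lam_solved, lam, atol=1e-9)

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 4))
        y = np.array([0, 1] * 10)
        X2, y2 = smote(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_tiny_minority_rejected(self):
        X = np.random.default_rng(1).standard_normal((10, 3))
        y = np.array([0] * 7 + [1] * 3)
        with pytest.raises(ValueError, match="k_neighbors"):
            smote(X, y, k_neighbors=5)


class TestSelectBest:
    def _fold(self, i, sens, acc=99.0):
        w = init_weights(ModelSpec(), seed=0)
        return FoldResult(fold_index=i, accuracy=acc, sensitivity=sens,
                          specificity=99.0, weights=w, epochs_run=10)

    def test_argmax_by_sensitivity(self):
        folds = [self._fold(0, 99.0), self._fold(1, 99.72), self._fold(2, 98.5)]
        assert select_best(folds).fold_index == 1

    def test_ties_break_on_accuracy_then_index(self):
        folds = [self._fold(0, 99.0, acc=98.0), self._fold(1, 99.0, acc=99.5),
                 self._fold(2, 99.0, acc=99.5)]
        assert select_best(folds).fold_index == 1
        equal = [self._fold(i, 99.0, acc=99.0) for i in range(3)]
        assert select_best(equal).fold_index == 0

    def test_single_and_empty(self):
        only = [self._fold(0, 97.0)]
        assert select_best(only) is only[0]
        with pytest.raises(ValueError):
            select_best([])


def _tiny_sets(n_per_class=12, seed=31):
    ws = gen_uci_like(n_per_class, SyntheticSpec(seed=seed))
    X = standardize_set(ws.windows)
    y = binarize_labels(ws.labels5)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    cut = int(0.8 * len(X))
    return (X[idx[:cut]], y[idx[:cut]]), (X[idx[cut:]], y[idx[cut:]])


class TestTrainOne:
    def test_loss_improves_and_respects_epoch_budget(self):
        train, val = _tiny_sets()
        config = TrainConfig(seed=2, max_epochs=25, patience=6, batch_size=32)
        weights, hist = train_one(ModelSpec(), train, val, config)
        assert hist["epochs_run"] <= config.max_epochs
        assert hist["train_loss"][hist["best_epoch"]] <= hist["train_loss"][0]

    def test_early_stopping_stops_before_budget(self):
        train, val = _tiny_sets(seed=32)
        config = TrainConfig(seed=2, max_epochs=200, patience=3, batch_size=32)
        _, hist = train_one(ModelSpec(), train, val, config)
        assert hist["epochs_run"] < config.max_epochs

    def test_seeded_determinism(self):
        train, val = _tiny_sets(seed=33)
        config = TrainConfig(seed=9, max_epochs=6, batch_size=32)
        _, h1 = train_one(ModelSpec(), train, val, config)
        _, h2 = train_one(ModelSpec(), train, val, config)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]


class TestCrossValidate:
    def test_folds_partition_the_set_and_exclude_test_rows(self):
        ws = gen_uci_like(15, SyntheticSpec(seed=41))  # 75 rows
        config = TrainConfig(seed=3, n_folds=3, max_epochs=3, batch_size=64)
        trainval, test = split_train_test(ws, config)
        results = cross_validate(trainval, config, ModelSpec())
        assert [r.fold_index for r in results] == [0, 1, 2]
        assert all(r.epochs_run <= 3 for r in results)
        # validation folds are disjoint and their union is the whole set
        all_val = np.concatenate([r.val_indices for r in results])
        assert len(all_val) == len(set(all_val.tolist())) == len(trainval)
        # no test row ever entered cross-validation
        test_rows = {row.tobytes() for row in test.windows}
        trainval_rows = {row.tobytes() for row in trainval.windows}
        assert not (test_rows & trainval_rows)
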