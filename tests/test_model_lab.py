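import numpy as np
import pytest

from orgprobe import model_lab as ml
from orgprobe.featurize import FeatureMatrix
from orgprobe.molecule_io import TaskTable

from oracles import oracle_metrics


def random_instance(rng, k):
    n = int(rng.integers(8, 31))
    classes = list(range(k))
    y_true = rng.integers(0, k, n)
    y_prob = rng.dirichlet(np.ones(k), size=n)
    y_pred = np.argmax(y_prob, axis=1)
    return y_true, y_pred, y_prob, classes


def test_metrics_match_bruteforce_oracle():
    """Accuracy/recall/precision/AUC agree with exhaustive-pair definitions
    to 1e-12 over random instances of 2-6 classes."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        k = int(rng.integers(2, 7))
        y_true, y_pred, y_prob, classes = random_instance(rng, k)
        averaging = "binary" if k == 2 else "weighted"
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = ml.compute_metrics(y_true, y_pred, y_prob, averaging, classes=classes)
        acc, auc, rec, prec = oracle_metrics(
            y_true, y_pred, y_prob, classes, averaging,
            positive=classes[-1] if averaging == "binary" else None,
        )
        assert m["acc"] == pytest.approx(acc, abs=1e-12)
        assert m["recall"] == pytest.approx(rec, abs=1e-12)
        assert m["precision"] == pytest.approx(prec, abs=1e-12)
        if np.isnan(auc):
            assert np.isnan(m["auc"])
        else:
            assert m["auc"] == pytest.approx(auc, abs=1e-12)


def test_metrics_perfect_prediction():
    y = np.array([0, 1, 2, 1, 0])
    prob = np.eye(3)[y]
    m = ml.compute_metrics(y, y, prob, "weighted", classes=[0, 1, 2])
    assert m["acc"] == m["auc"] == m["recall"] == m["precision"] == 1.0
    assert np.all(m["confusion"] == np.diag([2, 2, 1]))


def test_metrics_binary_auc_ranks():
    y = np.array([1, 1, 0, 0])
    prob = np.array([[0.1, 0.9], [0.2, 0.8], [0.7, 0.3], [0.9, 0.1]])
    m = ml.compute_metrics(y, (prob[:, 1] > 0.5).astype(int), prob, "binary", classes=[0, 1])
    assert m["auc"] == 1.0


def test_metrics_validates_probability_rows():
    with pytest.raises(ml.ModelLabError):
        ml.compute_metrics([0, 1], [0, 1], np.array([[0.5, 0.6], [0.5, 0.5]]), "binary")


def test_weighted_recall_equals_accuracy():
    """The support-weighted one-vs-rest recall is identically accuracy."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        y_true, y_pred, y_prob, classes = random_instance(rng, int(rng.integers(3, 7)))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = ml.compute_metrics(y_true, y_pred, y_prob, "weighted", classes=classes)
        assert m["recall"] == pytest.approx(m["acc"], abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 40)
    scores = rng.random(40)
    prob = np.column_stack([1 - scores, scores])
    m1 = ml.compute_metrics(y, (scores > 0.5).astype(int), prob, "binary", classes=[0, 1])
    warped = 1.0 / (1.0 + np.exp(-5 * (scores - 0.3)))
    prob2 = np.column_stack([1 - warped, warped])
    m2 = ml.compute_metrics(y, (scores > 0.5).astype(int), prob2, "binary", classes=[0, 1])
    assert m1["auc"] == pytest.approx(m2["auc"], abs=1e-12)


# ---------------------------------------------------------------------------
# splitting

def test_split_stratified_small():
    y = np.array(["a"] * 5 + ["b"] * 5)
    s = ml.split_dataset(y, seed=3)
    assert len(s.train_idx) == 8 and len(s.test_idx) == 2
    test_labels = sorted(y[s.test_idx])
    assert test_labels == ["a", "b"]
    s2 = ml.split_dataset(y, seed=3)
    np.testing.assert_array_equal(s.test_idx, s2.test_idx)


def test_split_stratified_imbalanced():
    y = np.array([0] * 90 + [1] * 10)
    s = ml.split_dataset(y, seed=0)
    assert len(s.test_idx) == 20
    assert np.sum(y[s.test_idx] == 0) == 18
    assert np.sum(y[s.test_idx] == 1) == 2
    assert set(s.train_idx) | set(s.test_idx) == set(range(100))
    assert not set(s.train_idx) & set(s.test_idx)


def test_split_tiny_class_stays_in_train():
    y = np.array([0] * 10 + [1])
    with pytest.warns(UserWarning, match="fewer than 2"):
        s = ml.split_dataset(y, seed=0)
    assert 10 in s.train_idx


def test_split_grouped_keeps_groups_together():
    y = np.array([0, 0, 1, 1, 0, 1, 0, 1, 0, 1])
    groups = np.array(["g1", "g1", "g2", "g2", "g3", "g3", "g4", "g4", "g5", "g5"])
    s = ml.split_dataset(y, seed=1, group_keys=groups)
    for g in np.unique(groups):
        sides = {i in set(s.test_idx) for i in np.flatnonzero(groups == g)}
        assert len(sides) == 1


# ---------------------------------------------------------------------------
# cross-validation

def blobs(rng, n=100, separation=12.0):
    X = np.vstack([
        rng.normal(0, 1, (n // 2, 2)),
        rng.normal(separation, 1, (n - n // 2, 2)),
    ])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return X, y


def test_cv_separable_blobs_perfect():
    rng = np.random.default_rng(4)
    X, y = blobs(rng)
    cv = ml.cross_validate(ml.ModelSpec("decision_tree", seed=0), X, y, folds=5, seed=0)
    assert cv["acc"][0] == 1.0
    assert cv["folds"] == 5
    assert all(len(f) == 20 for f in cv["fold_indices"])


def test_cv_shuffled_labels_chance_auc():
    """Permutation null: AUC near 0.5 on label-shuffled balanced data."""
    rng = np.random.default_rng(5)
    X = rng.random((400, 5))
    y = rng.permutation([0] * 200 + [1] * 200)
    cv = ml.cross_validate(ml.ModelSpec("logistic_regression", seed=0), X, y, folds=5, seed=0)
    assert 0.35 <= cv["auc"][0] <= 0.65


def test_cv_reduces_folds_for_small_class():
    rng = np.random.default_rng(6)
    X = rng.random((20, 3))
    y = np.array([0] * 17 + [1] * 3)
    with pytest.warns(UserWarning, match="reducing folds"):
        cv = ml.cross_validate(ml.ModelSpec("decision_tree", seed=0), X, y, folds=5, seed=0)
    assert cv["folds"] == 3


# ---------------------------------------------------------------------------
# models / grid

def test_all_algorithms_construct():
    for algo in ml.ALGORITHMS:
        assert ml._make_estimator(algo, seed=0, hyperparameters={}) is not None
    with pytest.raises(ml.ModelLabError):
        ml.ModelSpec("mystery_forest")


def test_predict_proba_rows_and_tiebreak():
    rng = np.random.default_rng(7)
    X, y = blobs(rng, n=60)
    model = ml.train_model(ml.ModelSpec("random_forest", seed=0), X, y)
    proba = model.predict_proba(X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    # deterministic lowest-index argmax on exact ties
    tied = np.array([[0.5, 0.5], [0.2, 0.8]])
    assert model.classes[np.argmax(tied, axis=1)].tolist() == [0, 1]
    with pytest.raises(ml.ModelLabError, match="width"):
        model.predict_proba(np.zeros((2, 5)))


def test_grid_compare_cells_and_best(small_tables):
    from orgprobe import featurize
    table = small_tables["B-MvsP"]
    fams = {
        "MACCS": featurize.featurize_records(table.records, "MACCS"),
        "ECFP4": featurize.featurize_records(table.records, "ECFP4", nbits=256),
    }
    specs = [ml.ModelSpec("lightgbm", seed=0), ml.ModelSpec("logistic_regression", seed=0)]
    rep = ml.grid_compare(table, fams, specs, seed=0, positive="mitochondria")
    assert len(rep.cells) == 4
    for c in rep.cells.values():
        assert c.error is None
        assert c.test["acc"] >= 0.8  # planted signal is separable
        assert 0.0 <= c.test["auc"] <= 1.0
    best = rep.best_cell()
    best_acc = max(c.test["acc"] for c in rep.cells.values())
    assert best.test["acc"] == best_acc
    df = rep.to_frame()
    assert len(df) == 4
    hm = rep.heatmap_frame()
    assert hm.shape == (2, 2)


def test_grid_single_cell_and_failure_isolation(small_tables):
    from orgprobe import featurize
    table = small_tables["B-MvsP"]
    fm = featurize.featurize_records(table.records, "MACCS")
    rep = ml.grid_compare(
        table, {"MACCS": fm},
        [ml.ModelSpec("lightgbm", seed=0),
         ml.ModelSpec("xgboost", hyperparameters={"max_depth": -3}, seed=0)],
        seed=0, positive="mitochondria",
    )
    assert len(rep.cells) == 2
    assert rep.cells[("MACCS", "lightgbm")].error is None
    assert rep.cells[("MACCS", "xgboost")].error is not None
    assert rep.best_cell().algorithm == "lightgbm"


def test_multiclass_grid_weighted_identity(small_tables):
    from orgprobe import featurize
    table = small_tables["M-PvsP"]
    fm = featurize.featurize_records(table.records, "MACCS")
    rep = ml.grid_compare(table, {"MACCS": fm}, [ml.ModelSpec("lightgbm", seed=0)], seed=0)
    cell = rep.cells[("MACCS", "lightgbm")]
    assert cell.error is None
    assert cell.test["recall"] == pytest.approx(cell.test["acc"], abs=1e-12)
    assert cell.cv["recall"][0] == pytest.approx(cell.cv["acc"][0], abs=1e-12)
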