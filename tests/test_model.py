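import numpy as np
import pandas as pd
import pytest

from pcirc import (
    ConfusionCounts,
    compute_metrics,
    confusion_from_labels,
    feature_combination_grid,
    load_bundle,
    predict,
    repeated_kfold_cv,
    roc_points,
    save_bundle,
    train_classifier,
)
from pcirc.model import ALGORITHMS, NEGATIVE_LABEL, POSITIVE_LABEL, make_classifier

from oracles import brute_metrics


def _blobs(rng, n=100, sep=4.0, d=6):
    """Two Gaussian classes separated by ``sep`` along every axis."""
    X = np.vstack([rng.normal(0, 1, (n // 2, d)), rng.normal(sep, 1, (n // 2, d))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(d)]), y


class TestComputeMetrics:
    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
        assert (rep.recall, rep.precision, rep.accuracy, rep.f1, rep.mcc) == (1, 1, 1, 1, 1)

    def test_hand_worked_table(self):
        rep = compute_metrics(ConfusionCounts(TP=8, TN=7, FP=2, FN=3))
        assert rep.recall == pytest.approx(8 / 11)
        assert rep.precision == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(2 * 0.8 * (8 / 11) / (0.8 + 8 / 11))
        assert rep.mcc == pytest.approx((8 * 7 - 2 * 3) / np.sqrt(10 * 11 * 9 * 10))

    def test_chance_symmetry(self):
        rep = compute_metrics(ConfusionCounts(TP=5, TN=5, FP=5, FN=5))
        assert rep.accuracy == 0.5
        assert rep.mcc == 0.0

    def test_zero_denominator_mcc_is_zero(self):
        rep = compute_metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=5))
        assert rep.mcc == 0.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + tn + fp + fn == 0:
                continue
            rep = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert rep.to_dict() | {"auc": None} == pytest.approx(
                brute_metrics(tp, tn, fp, fn) | {"auc": None}
            )

    def test_label_swap_preserves_accuracy_and_mcc(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 30, size=4))
            rep = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            swapped = compute_metrics(ConfusionCounts(TP=tn, TN=tp, FP=fn, FN=fp))
            assert swapped.accuracy == pytest.approx(rep.accuracy)
            assert swapped.mcc == pytest.approx(rep.mcc)
            assert swapped.recall == pytest.approx(tn / (tn + fp))


class TestTrainPredict:
    def test_separable_data_trains_to_perfect_accuracy(self, rng):
        X, y = _blobs(rng, n=200)
        bundle = train_classifier(X, y, "RF", seed=0)
        result = predict(bundle, X)
        pred = (result["label"] == POSITIVE_LABEL).astype(int).to_numpy()
        assert compute_metrics(confusion_from_labels(y, pred)).accuracy == 1.0
        assert result["score"].between(0, 1).all()

    def test_hyperparameters_recorded(self, rng):
        X, y = _blobs(rng)
        bundle = train_classifier(X, y, "RF", seed=0)
        assert bundle.hyperparameters == {"n_estimators": 100}
        assert bundle.model.n_estimators == 100
        assert make_classifier("KNN").n_neighbors == 7
        assert make_classifier("SVM").C == 10
        assert make_classifier("SVM").gamma == 0.001

    def test_same_seed_same_predictions(self, rng):
        X, y = _blobs(rng, sep=1.0)
        probe = X.iloc[:20]
        s1 = predict(train_classifier(X, y, "RF", seed=5), probe)["score"]
        s2 = predict(train_classifier(X, y, "RF", seed=5), probe)["score"]
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())

    def test_single_class_raises(self, rng):
        X, _ = _blobs(rng)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, np.zeros(len(X), dtype=int), "RF", 0)

    def test_nan_features_raise_with_column_name(self, rng):
        X, y = _blobs(rng)
        X.iloc[3, 2] = np.nan
        with pytest.raises(ValueError, match="f2"):
            train_classifier(X, y, "RF", 0)

    def test_string_labels_accepted(self, rng):
        X, y = _blobs(rng)
        labels = np.where(y == 1, "positive", "negative")
        bundle = train_classifier(X, labels, "RF", 0)
        assert set(predict(bundle, X)["label"]) <= {POSITIVE_LABEL, NEGATIVE_LABEL}

    def test_schema_mismatch_raises(self, rng):
        X, y = _blobs(rng)
        bundle = train_classifier(X, y, "RF", 0)
        renamed = X.rename(columns={"f0": "feat0"})
        with pytest.raises(ValueError, match="feat0"):
            predict(bundle, renamed)

    def test_prediction_invariant_to_row_order(self, rng):
        X, y = _blobs(rng, sep=1.5)
        bundle = train_classifier(X, y, "RF", 0)
        shuffled = X.sample(frac=1, random_state=1)
        straight = predict(bundle, X)["score"]
        reordered = predict(bundle, shuffled)["score"].reindex(straight.index)
        assert np.array_equal(straight.to_numpy(), reordered.to_numpy())


class TestBundleIO:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        X, y = _blobs(rng, sep=1.0)
        bundle = train_classifier(X, y, "RF", 0)
        path = tmp_path / "model.joblib"
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        assert loaded.feature_schema == bundle.feature_schema
        assert np.array_equal(
            predict(loaded, X)["score"].to_numpy(), predict(bundle, X)["score"].to_numpy()
        )

    def test_truncated_file_raises(self, rng, tmp_path):
        X, y = _blobs(rng)
        path = tmp_path / "model.joblib"
        save_bundle(train_classifier(X, y, "RF", 0), path)
        path.write_bytes(path.read_bytes()[:40])
        with pytest.raises(ValueError):
            load_bundle(path)

    def test_foreign_payload_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "other.joblib"
        joblib.dump({"something": "else"}, path)
        with pytest.raises(ValueError, match="bundle"):
            load_bundle(path)

    def test_full_schema_recorded(self, small_feature_table):
        ft = small_feature_table
        X = ft.drop(columns=["label"])
        bundle = train_classifier(X, ft["label"].to_numpy(), "RF", 0)
        assert len(bundle.feature_schema) == 341 + 2 + 200


class TestCrossValidation:
    def test_fold_table_shape(self, rng):
        X, y = _blobs(rng, n=60)
        _, table = repeated_kfold_cv(X, y, "RF", k=3, repeats=2, seed=0)
        assert len(table) == 6
        assert set(table["repeat"]) == {0, 1}

    def test_too_small_class_raises(self, rng):
        X, y = _blobs(rng, n=10)
        with pytest.raises(ValueError, match="stratify"):
            repeated_kfold_cv(X, y, "RF", k=10, repeats=1, seed=0)

    def test_reproducible(self, rng):
        X, y = _blobs(rng, n=60, sep=1.0)
        m1, t1 = repeated_kfold_cv(X, y, "RF", k=3, repeats=2, seed=4)
        m2, t2 = repeated_kfold_cv(X, y, "RF", k=3, repeats=2, seed=4)
        assert m1.to_dict() == m2.to_dict()
        pd.testing.assert_frame_equal(t1, t2)

    @pytest.mark.parametrize("algorithm", list(ALGORITHMS))
    def test_all_algorithms_run(self, rng, algorithm):
        X, y = _blobs(rng, n=60)
        mean, _ = repeated_kfold_cv(X, y, algorithm, k=3, repeats=1, seed=0)
        assert mean.accuracy > 0.9  # trivially separable


class TestFeatureGrid:
    def test_seven_combinations(self, small_feature_table):
        ft = small_feature_table
        grid = feature_combination_grid(
            ft.drop(columns=["label"]),
            ft["label"].to_numpy(),
            algorithms=("RF",),
            k=3,
            repeats=1,
            seed=0,
        )
        assert len(grid) == 7
        assert set(grid["n_blocks"]) == {1, 2, 3}
        assert grid["ACC"].between(0, 1).all()

    def test_missing_block_raises(self, rng):
        X, y = _blobs(rng)
        with pytest.raises(ValueError, match="kmer"):
            feature_combination_grid(X, y, blocks=("kmer",))


class TestRocPoints:
    def test_endpoints(self, rng):
        y = rng.integers(0, 2, size=50)
        scores = rng.random(50)
        pts = roc_points(y, scores)
        assert pts[0] == (0.0, 0.0)
        assert pts[-1] == (1.0, 1.0)
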