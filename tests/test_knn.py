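import numpy as np
import pytest

from pathsampler import (
    ValidationError,
    holdout_accuracy,
    loocv_accuracy,
    predict_nn,
)

from conftest import make_dataset, random_two_class
from oracles import holdout_accuracy_bruteforce, loocv_accuracy_bruteforce


def dataset_rows(ds, probes):
    """samples x features as plain lists, canonical order."""
    X = ds.matrix_for(probes)
    return [list(map(float, row)) for row in X], [ds.labels[s] for s in ds.sample_ids]


class TestPredictNn:
    def test_coincident_query_returns_its_class(self, tiny_dataset):
        q = tiny_dataset.values.loc[:, "s3"].to_numpy()
        assert predict_nn(tiny_dataset, tiny_dataset.probe_ids, q, k=1) == "control"

    def test_one_dimensional_geometry(self):
        ds = make_dataset([[0.0, 0.1, 10.0, 10.1]], ["g0"],
                          ["s1", "s2", "s3", "s4"],
                          ["A", "A", "B", "B"], case_label="A", control_label="B")
        assert predict_nn(ds, ["g0"], [2.0], k=1) == "A"
        assert predict_nn(ds, ["g0"], [8.0], k=1) == "B"

    def test_even_k_rejected(self, tiny_dataset):
        with pytest.raises(ValidationError, match="odd"):
            predict_nn(tiny_dataset, tiny_dataset.probe_ids, [1.0, 2.0, 3.0], k=2)

    def test_empty_probe_set_rejected(self, tiny_dataset):
        with pytest.raises(ValidationError, match="probe"):
            predict_nn(tiny_dataset, [], [], k=1)

    @pytest.mark.parametrize("k", [1, 3])
    def test_agrees_with_bruteforce_oracle(self, k):
        rng = np.random.default_rng(10)
        for _ in range(100):
            ds = random_two_class(rng, (4, 4), n_probes=int(rng.integers(1, 5)))
            rows, labels = dataset_rows(ds, ds.probe_ids)
            q = rng.normal(size=len(ds.probe_ids))
            from oracles import zscore_knn_predict
            expected = zscore_knn_predict(rows, labels, list(q), k)
            assert predict_nn(ds, ds.probe_ids, q, k=k) == expected


class TestLoocv:
    def test_separable_is_perfect(self, separable_dataset):
        ds, truth = separable_dataset
        res = loocv_accuracy(ds, truth.informative_probe_ids, k=1)
        assert res.accuracy_pct == 100.0 and res.n_misclassified == 0

    def test_hand_enumerated_zero_accuracy(self):
        """Every held-out point's nearest neighbor has the opposite label."""
        ds = make_dataset([[0.0, 2.0, 1.1, 3.0]], ["g0"],
                          ["s1", "s2", "s3", "s4"],
                          ["A", "A", "B", "B"], case_label="A", control_label="B")
        res = loocv_accuracy(ds, ["g0"], k=1)
        assert res.accuracy_pct == 0.0
        assert res.n_misclassified == 4

    @pytest.mark.parametrize("k", [1, 3])
    def test_oracle_equivalence_random_datasets(self, k):
        rng = np.random.default_rng(77)
        for _ in range(60):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            ds = random_two_class(rng, (n1, n2), n_probes=int(rng.integers(1, 6)))
            rows, labels = dataset_rows(ds, ds.probe_ids)
            expected = loocv_accuracy_bruteforce(rows, labels, k)
            got = loocv_accuracy(ds, ds.probe_ids, k=k)
            assert got.accuracy_pct == pytest.approx(expected)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        ds = random_two_class(rng, (5, 5), n_probes=4)
        base = loocv_accuracy(ds, ds.probe_ids, k=1).accuracy_pct
        perm = list(rng.permutation(ds.sample_ids))
        shuffled = ds.subset_samples(perm)
        assert loocv_accuracy(shuffled, ds.probe_ids, k=1).accuracy_pct == base

    def test_accuracy_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            ds = random_two_class(rng, (3, 4), n_probes=3)
            res = loocv_accuracy(ds, ds.probe_ids, k=1)
            assert res.accuracy_pct + 100.0 * res.n_misclassified / res.n_evaluated \
                == pytest.approx(100.0)

    def test_duplicated_sample_never_hurts_its_twin(self):
        """A duplicated same-label sample is its twin's zero-distance neighbor."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            ds = random_two_class(rng, (4, 4), n_probes=3)
            dup = ds.values.copy()
            dup["s_dup"] = dup["s0"]
            import pandas as pd
            labels = pd.concat([ds.labels, pd.Series({"s_dup": ds.labels["s0"]})])
            twin = make_dataset(dup.to_numpy(), ds.probe_ids, list(dup.columns),
                                list(labels))
            res = loocv_accuracy(twin, ds.probe_ids, k=1)
            assert res.per_sample_predictions["s0"] == ds.labels["s0"]

    def test_matches_sklearn_pipeline(self):
        """Independent cross-check: sklearn LOO + scaler + KNN."""
        from sklearn.model_selection import LeaveOneOut
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(123)
        for k in (1, 3):
            for _ in range(15):
                ds = random_two_class(rng, (5, 5), n_probes=3)
                X = ds.matrix_for(ds.probe_ids)
                y = np.array([ds.labels[s] for s in ds.sample_ids])
                correct = 0
                for train_idx, test_idx in LeaveOneOut().split(X):
                    scaler = StandardScaler().fit(X[train_idx])
                    clf = KNeighborsClassifier(n_neighbors=k).fit(
                        scaler.transform(X[train_idx]), y[train_idx])
                    correct += clf.predict(scaler.transform(X[test_idx]))[0] \
                        == y[test_idx][0]
                expected = 100.0 * correct / len(y)
                got = loocv_accuracy(ds, ds.probe_ids, k=k).accuracy_pct
                assert got == pytest.approx(expected)


class TestHoldout:
    def test_validation_duplicates_of_training_are_perfect(self):
        rng = np.random.default_rng(9)
        ds = random_two_class(rng, (4, 4), n_probes=3)
        train = ds.subset_samples(ds.sample_ids)
        # validation = exact copies of two training points, new ids
        import pandas as pd
        vals = ds.values[["s0", "s4"]].copy()
        vals.columns = ["v0", "v1"]
        validation = make_dataset(vals.to_numpy(), ds.probe_ids, ["v0", "v1"],
                                  [ds.labels["s0"], ds.labels["s4"]])
        res = holdout_accuracy(train, validation, ds.probe_ids, k=1)
        assert res.accuracy_pct == 100.0

    def test_empty_validation_rejected(self):
        rng = np.random.default_rng(9)
        ds = random_two_class(rng, (4, 4), n_probes=3)
        with pytest.raises(ValidationError):
            holdout_accuracy(ds, ds.subset_samples([]), ds.probe_ids, k=1)

    def test_overlapping_parts_rejected(self):
        rng = np.random.default_rng(9)
        ds = random_two_class(rng, (4, 4), n_probes=3)
        with pytest.raises(ValidationError, match="overlap"):
            holdout_accuracy(ds, ds.subset_samples(["s0"]), ds.probe_ids, k=1)

    @pytest.mark.parametrize("k", [1, 3])
    def test_agrees_with_bruteforce_on_random_splits(self, k):
        rng = np.random.default_rng(11)
        for _ in range(40):
            ds = random_two_class(rng, (5, 5), n_probes=int(rng.integers(1, 5)))
            samples = list(ds.sample_ids)
            val_ids = list(rng.choice(samples, size=3, replace=False))
            train_ids = [s for s in samples if s not in val_ids]
            train, val = ds.subset_samples(train_ids), ds.subset_samples(val_ids)
            if min((train.labels == c).sum()
                   for c in (train.case_label, train.control_label)) < 2:
                continue
            t_rows, t_labels = dataset_rows(train, ds.probe_ids)
            v_rows, v_labels = dataset_rows(val, ds.probe_ids)
            expected = holdout_accuracy_bruteforce(t_rows, t_labels, v_rows, v_labels, k)
            got = holdout_accuracy(train, val, ds.probe_ids, k=k)
            assert got.accuracy_pct == pytest.approx(expected)
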