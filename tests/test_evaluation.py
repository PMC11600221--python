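"""Heads, validation protocols, clustering and the accuracy t-test."""

import numpy as np
import pytest
from scipy import stats as sps

import gafsense as gs
from gafsense.errors import InvalidArgumentError, ProtocolError


def two_blob_set(n_per=10, d=5, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, d))
    b = rng.normal(gap, 1, size=(n_per, d))
    emb = np.vstack([a, b])
    labels = np.array(["a"] * n_per + ["b"] * n_per, dtype=object)
    return gs.FingerprintSet(emb, labels)


class TestHeads:
    def test_lda_separates_linear_clusters(self):
        fset = two_blob_set()
        clf = gs.train_head("LDA", fset)
        assert (clf.predict(fset.embeddings) == fset.labels).all()

    def test_knn_predicts_own_label_in_tight_clusters(self):
        fset = two_blob_set()
        clf = gs.train_head("KNN", fset)
        assert clf.predict(fset.embeddings[:1])[0] == "a"

    @pytest.mark.parametrize("name", ["RF", "ET", "XGB", "SVM"])
    def test_stochastic_heads_deterministic_under_seed(self, name):
        fset = two_blob_set(gap=2.0)
        p1 = gs.train_head(name, fset, seed=7).predict(fset.embeddings)
        p2 = gs.train_head(name, fset, seed=7).predict(fset.embeddings)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        fset = gs.FingerprintSet(np.zeros((4, 3)), np.array(["a"] * 4, dtype=object))
        with pytest.raises(InvalidArgumentError):
            gs.train_head("LDA", fset)

    def test_unknown_head_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gs.make_head("MLP")


class TestReportArithmetic:
    def test_mean_std_recomputable(self, wine_fingerprints):
        rep = gs.repeated_kfold_eval(wine_fingerprints, head="LDA", reps=8, seed=0)
        assert rep.mean_accuracy == pytest.approx(np.mean(rep.accuracies), abs=1e-12)
        assert rep.std_accuracy == pytest.approx(np.std(rep.accuracies, ddof=1), abs=1e-12)

    def test_confusion_rows_sum_to_test_counts(self, wine_fingerprints):
        reps = 6
        rep = gs.repeated_kfold_eval(wine_fingerprints, head="LDA", reps=reps, seed=0)
        # 80/20 stratified split of 10 per class -> 2 test instances per class per rep
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), 2 * reps)

    def test_one_error_of_40_is_97_5_percent(self):
        y_true = np.array(["c%d" % (i % 4) for i in range(40)])
        y_pred = y_true.copy()
        y_pred[0] = "c1" if y_true[0] != "c1" else "c2"
        assert gs.pooled_accuracy(y_true, y_pred) == pytest.approx(0.975)

    def test_six_errors_of_54_is_88_9_percent(self):
        y_true = np.array(["s%d" % (i % 5) for i in range(54)])
        y_pred = y_true.copy()
        for i in range(6):
            y_pred[i] = "s%d" % ((int(y_true[i][1]) + 1) % 5)
        assert round(100 * gs.pooled_accuracy(y_true, y_pred), 1) == 88.9

    def test_report_json_roundtrip(self, tmp_path, wine_fingerprints):
        import json

        rep = gs.repeated_kfold_eval(wine_fingerprints, head="LDA", reps=3, seed=0)
        path = rep.to_json(tmp_path / "report.json")
        data = json.loads(path.read_text())
        assert data["mean_accuracy"] == pytest.approx(rep.mean_accuracy)
        assert np.array(data["confusion"]).sum() == rep.confusion.sum()


class TestRepeatedKFold:
    def test_high_separation_wine_lda_above_95(self, wine_fingerprints):
        rep = gs.repeated_kfold_eval(
            wine_fingerprints, head="LDA", k_components=20, reps=20, seed=1
        )
        assert rep.mean_accuracy >= 0.95

    def test_class_below_five_instances_rejected(self):
        fset = two_blob_set(n_per=4)
        with pytest.raises(ProtocolError):
            gs.repeated_kfold_eval(fset, head="LDA", k_components=2, reps=2)

    def test_deterministic_given_seed(self, wine_fingerprints):
        a = gs.repeated_kfold_eval(wine_fingerprints, head="RF", reps=4, seed=3)
        b = gs.repeated_kfold_eval(wine_fingerprints, head="RF", reps=4, seed=3)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)


@pytest.fixture(scope="module")
def sugar_fingerprints():
    ds = gs.generate_task_dataset("sugar", gs.SimulationConfig(seed=1))
    return gs.featurize_dataset(ds)


class TestSugarProtocol:
    def test_pools_exactly_40_predictions(self, sugar_fingerprints):
        rep = gs.sugar_locov_eval(sugar_fingerprints, head="LDA", k_components=10)
        assert rep.n_pooled == 40
        assert rep.confusion.sum() == 40

    def test_high_separation_resolves_type_and_level(self, sugar_fingerprints):
        rep = gs.sugar_locov_eval(sugar_fingerprints, head="LDA", k_components=10)
        assert rep.pooled_accuracy >= 0.9

    def test_held_out_class_never_trains(self, monkeypatch, sugar_fingerprints):
        seen = []
        orig = gs.evaluation._fit_predict

        def spy(train, test, head, k, seed):
            seen.append((train.embeddings.copy(), test.embeddings.copy()))
            return orig(train, test, head, k, seed)

        monkeypatch.setattr(gs.evaluation, "_fit_predict", spy)
        gs.sugar_locov_eval(sugar_fingerprints, head="LDA", k_components=10)
        assert len(seen) == 4
        for train_emb, test_emb in seen:
            assert train_emb.shape[0] == 50 and test_emb.shape[0] == 10
            # no held-out row may appear among the training rows
            for row in test_emb:
                assert not (np.abs(train_emb - row).max(axis=1) < 1e-12).any()

    def test_missing_level_rejected(self, sugar_fingerprints):
        keep = np.array([not str(l).endswith("_5") for l in sugar_fingerprints.labels])
        with pytest.raises(ProtocolError):
            gs.sugar_locov_eval(sugar_fingerprints.subset(np.where(keep)[0]))


@pytest.fixture(scope="module")
def milk_fingerprints():
    ds = gs.generate_task_dataset("milk", gs.SimulationConfig(seed=1))
    return gs.featurize_dataset(ds)


class TestMilkProtocol:
    def test_pools_all_replicates(self, milk_fingerprints):
        rep = gs.milk_lopo_eval(milk_fingerprints, head="LDA", k_components=10)
        assert rep.n_pooled == 60  # 12 products x 5 replicates
        assert len(rep.accuracies) == 12
        assert rep.confusion.sum() == 60

    def test_source_recovered_from_sibling_products(self, milk_fingerprints):
        rep = gs.milk_lopo_eval(milk_fingerprints, head="LDA", k_components=10)
        assert rep.pooled_accuracy >= 0.8

    def test_single_product_source_rejected(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(15, 4))
        labels = np.array(["a"] * 10 + ["b"] * 5, dtype=object)
        pids = np.array(["a1"] * 5 + ["a2"] * 5 + ["b1"] * 5, dtype=object)
        fset = gs.FingerprintSet(emb, labels, pids)
        with pytest.raises(ProtocolError):
            gs.milk_lopo_eval(fset, head="LDA", k_components=2)

    def test_missing_product_ids_rejected(self, wine_fingerprints):
        fset = gs.FingerprintSet(wine_fingerprints.embeddings, wine_fingerprints.labels)
        with pytest.raises(ProtocolError):
            gs.milk_lopo_eval(fset)


class TestClustering:
    def test_well_separated_categories_cluster_perfectly(self):
        ds = gs.generate_task_dataset("clustering", gs.SimulationConfig(seed=1))
        fset = gs.featurize_dataset(ds)
        scores = gs.transform_pca(gs.fit_pca(fset, 5), fset)
        ari, assign = gs.cluster_and_score(scores, n_clusters=4)
        assert ari == pytest.approx(1.0)
        assert assign.shape == (len(ds),)

    def test_identical_partition_scores_one(self):
        from sklearn.metrics import adjusted_rand_score

        labels = np.array(["a", "a", "b", "b", "c", "c"])
        assert adjusted_rand_score(labels, labels) == 1.0

    def test_structureless_data_scores_near_zero(self):
        rng = np.random.default_rng(3)
        aris = []
        for _ in range(100):
            x = rng.normal(size=(60, 5))
            labels = rng.integers(0, 4, size=60)
            ari, _ = gs.cluster_and_score(x, labels, n_clusters=4)
            aris.append(ari)
        assert abs(np.mean(aris)) < 0.1

    def test_fewer_samples_than_clusters_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gs.cluster_and_score(np.zeros((3, 2)), ["a", "b", "c"], n_clusters=4)


class TestAccuracyTTest:
    def test_identical_distributions_give_p_one(self):
        a = [0.8, 0.8, 0.8]
        assert gs.compare_accuracy_distributions(a, list(a)) == 1.0

    def test_separated_distributions_significant(self, rng):
        a = rng.normal(0.60, 0.01, 50)
        b = rng.normal(0.90, 0.01, 50)
        p = gs.compare_accuracy_distributions(a, b)
        assert p < 1e-3
        # closed-form check of the pooled-variance t statistic
        na, nb = len(a), len(b)
        sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / na + 1 / nb))
        p_manual = 2 * sps.t.sf(abs(t), na + nb - 2)
        assert p == pytest.approx(p_manual, rel=1e-9)

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(0.7, 0.05, 20)
        b = rng.normal(0.75, 0.05, 20)
        assert gs.compare_accuracy_distributions(a, b) == pytest.approx(
            gs.compare_accuracy_distributions(b, a)
        )

    def test_short_vectors_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gs.compare_accuracy_distributions([0.5], [0.5, 0.6])


def test_chance_interval_brackets_uniform_guessing():
    lo, hi = gs.chance_interval(7, 700)
    assert lo < 1 / 7 < hi
    # interval tightens with more predictions
    lo2, hi2 = gs.chance_interval(7, 7000)
    assert (hi2 - lo2) < (hi - lo)
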