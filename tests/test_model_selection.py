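"""Fold grouping, hyperparameter sampling, classifiers, nested CV."""

import numpy as np
import pytest

import eegdistract as ed
from eegdistract.model_selection import KNN_DISTANCES
from conftest import make_white_epochset


class TestGroupStratifiedKFold:
    def test_trials_never_split_across_folds(self, effect_epochset):
        # 120 trials over 10 folds -> 12 trials per fold, label-balanced
        assign = ed.group_stratified_kfold(effect_epochset, 10, seed=0)
        folds = ed.epoch_folds(effect_epochset, assign)
        keys = effect_epochset.trial_keys()
        for k in set(keys):
            assert len(set(folds[keys == k])) == 1
        counts = np.bincount(list(assign.values()), minlength=10)
        assert np.all(counts == len(assign) // 10)
        # label balance inside each fold
        y = effect_epochset.labels_int()
        for f in range(10):
            frac = y[folds == f].mean()
            assert 0.4 <= frac <= 0.6

    def test_two_trials_two_folds(self):
        es = make_white_epochset(n_trials=2)
        assign = ed.group_stratified_kfold(es, 2, seed=0)
        assert sorted(assign.values()) == [0, 1]

    def test_epoch_order_does_not_change_trial_assignment(self):
        es = make_white_epochset(n_trials=10, seed=3)
        assign1 = ed.group_stratified_kfold(es, 5, seed=9)
        shuffled = ed.EpochSet([es.epochs[i] for i in
                                np.random.default_rng(0).permutation(len(es))])
        assign2 = ed.group_stratified_kfold(shuffled, 5, seed=9)
        assert assign1 == assign2

    def test_fewer_trials_than_folds(self):
        es = make_white_epochset(n_trials=4)
        with pytest.raises(ValueError, match="folds"):
            ed.group_stratified_kfold(es, 10)


class TestSampleHyperparameters:
    def test_domains_respected(self):
        for kind, n in [("knn", 200), ("svm", 200), ("ann", 100),
                        ("lda", 100), ("nb", 200)]:
            draws = ed.sample_hyperparameters(kind, n, seed=1)
            assert len(draws) == n
            for d in draws:
                if kind == "knn":
                    assert 1 <= d["n_neighbors"] <= 5
                    assert d["distance"] in KNN_DISTANCES
                    assert ("exponent" in d) == (d["distance"] == "minkowski")
                    if "exponent" in d:
                        assert 0.5 <= d["exponent"] <= 3.0
                elif kind == "svm":
                    assert 1e-3 <= d["box_constraint"] <= 1e3
                    assert ("polynomial_order" in d) == (
                        d["kernel"] == "polynomial")
                elif kind == "ann":
                    assert 25 <= d["hidden_neurons"] <= 200
                elif kind == "lda":
                    assert 0.0 <= d["gamma"] <= 1.0
                    assert 1e-6 <= d["delta"] <= 1e3
                else:
                    assert ("width" in d) == (d["distribution"] == "kernel")
                    if "width" in d:
                        assert 1e-4 <= d["width"] <= 1e14

    def test_log_uniform_median_near_one(self):
        draws = ed.sample_hyperparameters("svm", 1000, seed=2)
        med = np.median([d["box_constraint"] for d in draws])
        assert 1 / 3 <= med <= 3  # median of log-uniform on [1e-3, 1e3] is 1

    def test_deterministic_under_seed(self):
        assert ed.sample_hyperparameters("knn", 20, seed=5) == \
            ed.sample_hyperparameters("knn", 20, seed=5)

    def test_errors(self):
        with pytest.raises(ValueError):
            ed.sample_hyperparameters("tree", 5)
        with pytest.raises(ValueError):
            ed.sample_hyperparameters("knn", 0)


def _blobs(n=60, d=6, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = np.repeat([0, 1], n // 2)
    X[y == 1, 0] += sep
    return X, y


class TestTrainClassifier:
    def test_knn_memorizes_training_point(self):
        X, y = _blobs()
        m = ed.train_classifier("knn", {"n_neighbors": 1}, X, y)
        assert np.array_equal(m.predict(X), y)

    @pytest.mark.parametrize("kind,config", [
        ("knn", {"distance": "euclidean", "n_neighbors": 3}),
        ("svm", {"kernel": "linear", "box_constraint": 1.0}),
        ("ann", {"activation": "relu", "hidden_neurons": 25}),
        ("lda", {"discrim_type": "linear"}),
        ("nb", {"distribution": "normal"}),
    ])
    def test_separable_blobs_learned(self, kind, config):
        X, y = _blobs(sep=10.0)
        m = ed.train_classifier(kind, config, X, y, seed=0)
        assert np.mean(m.predict(X) == y) >= 0.95

    @pytest.mark.parametrize("distance", list(KNN_DISTANCES))
    def test_all_knn_distances_run(self, distance):
        X, y = _blobs(n=40)
        cfg = {"distance": distance, "n_neighbors": 3,
               "distance_weight": "inverse"}
        if distance == "minkowski":
            cfg["exponent"] = 1.5
        m = ed.train_classifier("knn", cfg, X, y)
        assert m.predict(X[:5]).shape == (5,)

    @pytest.mark.parametrize("dt", ["linear", "quadratic", "diagLinear",
                                    "diagQuadratic", "pseudoLinear",
                                    "pseudoQuadratic"])
    def test_all_discrim_types_separate_blobs(self, dt):
        X, y = _blobs(sep=8.0)
        m = ed.train_classifier("lda", {"discrim_type": dt, "gamma": 0.1}, X, y)
        assert np.mean(m.predict(X) == y) >= 0.95

    @pytest.mark.parametrize("kernel", ["normal", "box", "epanechnikov",
                                        "triangle"])
    def test_kernel_nb_variants(self, kernel):
        X, y = _blobs(sep=8.0)
        cfg = {"distribution": "kernel", "kernel": kernel, "width": 1.0}
        m = ed.train_classifier("nb", cfg, X, y)
        assert np.mean(m.predict(X) == y) >= 0.95

    def test_knn_tie_breaks_to_lowest_class(self):
        # four equidistant neighbours, 2 votes each class
        X = np.array([[0.0, 1], [0, -1], [1, 0], [-1, 0]])
        y = np.array([0, 0, 1, 1])
        m = ed.train_classifier(
            "knn", {"n_neighbors": 4, "distance": "euclidean"}, X, y)
        assert m.predict([[0.0, 0.0]])[0] == 0

    def test_errors(self):
        X, y = _blobs()
        with pytest.raises(ValueError, match="single-class"):
            ed.train_classifier("knn", {}, X, np.zeros_like(y))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ed.train_classifier("knn", {}, X, y)


class TestNestedCV:
    CVC = ed.NestedCVConfig(outer_folds=5, inner_folds=3, n_random_draws=4,
                            seed=12)

    def test_outer_folds_partition_epochs_exactly_once(self, effect_epochset):
        rep = ed.nested_cv(effect_epochset, ed.FeatureConfig(scheme="csp_only"),
                           "lda", self.CVC)
        assert np.all(rep.predictions >= 0)  # every epoch predicted once
        assert sum(f.n_test for f in rep.folds) == len(effect_epochset)

    def test_deterministic_under_seed(self, effect_epochset):
        fc = ed.FeatureConfig(scheme="csp_only")
        r1 = ed.nested_cv(effect_epochset, fc, "lda", self.CVC)
        r2 = ed.nested_cv(effect_epochset, fc, "lda", self.CVC)
        assert np.array_equal(r1.predictions, r2.predictions)
        assert r1.fold_accuracies.tolist() == r2.fold_accuracies.tolist()

    def test_strong_effect_recovered(self, effect_epochset):
        rep = ed.nested_cv(effect_epochset, ed.FeatureConfig(), "knn",
                           ed.NestedCVConfig(n_random_draws=8, seed=1))
        assert rep.mean_accuracy >= 0.9

    def test_null_data_at_chance_with_proper_pipeline(self, null_epochset):
        """Leakage guard: trial-grouped CV with per-partition CSP fitting
        must NOT inflate accuracy on label-free data, unlike fitting the
        CSP on all epochs before splitting."""
        rep = ed.nested_cv(null_epochset, ed.FeatureConfig(), "knn",
                           ed.NestedCVConfig(n_random_draws=5, seed=21))
        n_trials = len(set(null_epochset.trial_keys()))
        half_width = 1.96 * np.sqrt(0.25 / n_trials)
        assert abs(rep.mean_accuracy - 0.5) <= half_width

        # deliberately leaky contrast: CSP fit on ALL epochs (test included)
        bank = ed.design_filter_bank("proposed12", null_epochset.fs)
        cov = ed.band_covariances(null_epochset.data_array(), bank)
        y = null_epochset.labels_int()
        model = ed.fit_csp(cov, y)
        X = ed.csp_features(cov, model)
        assign = ed.group_stratified_kfold(null_epochset, 10, seed=21)
        folds = ed.epoch_folds(null_epochset, assign)
        leaky = []
        for f in range(10):
            tr, te = folds != f, folds == f
            m = ed.train_classifier("knn", {"n_neighbors": 3}, X[tr], y[tr])
            leaky.append(np.mean(m.predict(X[te]) == y[te]))
        assert np.mean(leaky) > rep.mean_accuracy

    def test_trial_label_permutation_reaches_chance(self, effect_epochset):
        permuted = ed.permute_trial_labels(effect_epochset, seed=8)
        rep = ed.nested_cv(permuted, ed.FeatureConfig(), "knn",
                           ed.NestedCVConfig(n_random_draws=5, seed=8))
        n_trials = len(set(permuted.trial_keys()))
        half_width = 1.96 * np.sqrt(0.25 / n_trials)
        assert abs(rep.mean_accuracy - 0.5) <= half_width

    def test_report_render_contains_folds(self, effect_epochset):
        rep = ed.nested_cv(effect_epochset, ed.FeatureConfig(scheme="csp_only"),
                           "lda", self.CVC)
        text = rep.render()
        assert "fold\taccuracy" in text
        assert f"{rep.folds[0].accuracy:.4f}" in text
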