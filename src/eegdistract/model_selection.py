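"""Classifiers, hyperparameter spaces, random search and trial-grouped
nested cross-validation.

Five classifier families are searchable: k-nearest neighbours, soft-margin
SVM, a single-hidden-layer neural network with weight decay, Gaussian
discriminant analysis, and naive Bayes.  Hyperparameters are drawn by
random search inside a nested cross-validation: the inner k-fold loop
(on the outer training set T_O) picks the configuration with the best
mean inner accuracy; a model with that configuration is then trained on
T_O as a whole and scored on the held-out outer fold E_O.  Averaging the
outer accuracies estimates generalization without letting the tuning see
the test data.

Two leakage guards are built in and non-negotiable:

* folds are assigned at the *trial* level, so the 1.5 s-overlapped epochs
  cut from one trial can never straddle the train/test boundary;
* all supervised feature fitting (CSP, feature standardization) happens
  inside each training partition only — CSP is part of the model and is
  refit for every partition.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.svm import SVC

from .classifiers import GaussianDiscriminant, KernelNaiveBayes
from .csp import band_covariances, csp_features, fit_csp
from .filterbank import design_filter_bank, make_band_scheme
from .signal_model import EpochSet
from .spectral import band_power_features, psd_estimate

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIERS",
    "FeatureConfig",
    "NestedCVConfig",
    "NestedCVReport",
    "group_stratified_kfold",
    "epoch_folds",
    "sample_hyperparameters",
    "train_classifier",
    "nested_cv",
    "permute_trial_labels",
]

CLASSIFIERS = ("knn", "svm", "ann", "lda", "nb")

KNN_DISTANCES = (
    "cityblock", "chebychev", "correlation", "cosine", "euclidean",
    "hamming", "jaccard", "mahalanobis", "minkowski", "seuclidean",
    "spearman",
)


@dataclass
class FeatureConfig:
    """Which features feed the classifier.

    kind='fbcsp' runs the filter bank + CSP chain (scheme 'csp_only'
    degenerates to broadband CSP, 8 features); kind='psd' uses absolute +
    relative Welch band powers.
    """

    kind: str = "fbcsp"
    scheme: str = "proposed12"
    filter_order: int = 8
    stopband_db: float = 30.0
    log_variance: bool = True
    psd_segment_s: float = 1.0
    psd_overlap: float = 0.5

    def __post_init__(self):
        if self.kind not in ("fbcsp", "psd"):
            raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class NestedCVConfig:
    """Nested cross-validation layout (outer l folds, inner k folds)."""

    outer_folds: int = 10
    inner_folds: int = 10
    n_random_draws: int = 50
    stratify_by_label: bool = True
    # None: z-score PSD features for scale-sensitive classifiers
    # (knn/svm/ann); never for FBCSP features, whose log normalized
    # variances already share a common scale by construction.
    standardize: bool | None = None
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")


@dataclass
class FoldResult:
    fold: int
    config: dict
    accuracy: float
    n_test: int


@dataclass
class NestedCVReport:
    """Per-outer-fold winners and accuracies plus pooled predictions."""

    subject_id: object
    classifier: str
    feature_config: FeatureConfig
    cv_config: NestedCVConfig
    folds: list
    predictions: np.ndarray  # per epoch, 0=attentive 1=distracted
    labels: np.ndarray
    n_features: int

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        # sample (n-1) standard deviation across outer folds
        return float(self.fold_accuracies.std(ddof=1))

    def render(self) -> str:
        fc, cv = self.feature_config, self.cv_config
        lines = [
            f"# nested CV report: subject={self.subject_id} "
            f"classifier={self.classifier}",
            f"# features={fc.kind}/{fc.scheme} n_features={self.n_features}",
            f"# outer={cv.outer_folds} inner={cv.inner_folds} "
            f"draws={cv.n_random_draws} seed={cv.seed} "
            f"standardize={cv.standardize}",
            "fold\taccuracy\tn_test\twinning_config",
        ]
        for f in self.folds:
            lines.append(f"{f.fold}\t{f.accuracy:.4f}\t{f.n_test}\t{f.config}")
        lines.append(
            f"# mean={100 * self.mean_accuracy:.1f}% "
            f"std={100 * self.std_accuracy:.1f}%"
        )
        return "\n".join(lines)


# --------------------------------------------------------------------------
# fold assignment

def group_stratified_kfold(epochset: EpochSet, n_folds: int, seed: int = 0):
    """Partition *trials* (never epochs) into label-balanced folds.

    Returns a dict mapping trial key -> fold index.  All epochs cut from
    one trial share its fold; within each class, shuffled trials are
    dealt round-robin so folds are balanced as evenly as integer counts
    allow.  Deterministic under ``seed``.
    """
    keys = epochset.trial_keys()
    y = epochset.labels_int()
    trial_label = {}
    trial_order = []
    for k, lab in zip(keys, y):
        if k not in trial_label:
            trial_label[k] = lab
            trial_order.append(k)
    if len(trial_order) < n_folds:
        raise ValueError(
            f"{len(trial_order)} trials cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    assignment = {}
    next_fold = 0
    for cls in (0, 1):
        # canonical (sorted) trial order: assignment is invariant to the
        # order epochs happen to arrive in
        trials = sorted(k for k in trial_order if trial_label[k] == cls)
        trials = [trials[i] for i in rng.permutation(len(trials))]
        for k in trials:
            assignment[k] = next_fold % n_folds
            next_fold += 1
    return assignment


def epoch_folds(epochset: EpochSet, assignment: dict) -> np.ndarray:
    """Map a trial-level fold assignment onto the epochs."""
    return np.array([assignment[k] for k in epochset.trial_keys()], dtype=int)


def permute_trial_labels(epochset: EpochSet, seed: int = 0) -> EpochSet:
    """Permute condition labels at the trial level (null-hypothesis data).

    Every epoch of a trial receives the trial's permuted label, so the
    grouping structure is preserved while the label-signal association is
    destroyed.
    """
    keys = epochset.trial_keys()
    y = epochset.labels()
    trial_order, trial_label = [], {}
    for k, lab in zip(keys, y):
        if k not in trial_label:
            trial_label[k] = lab
            trial_order.append(k)
    labels = [trial_label[k] for k in trial_order]
    rng = np.random.default_rng(seed)
    permuted = dict(zip(trial_order,
                        [labels[i] for i in rng.permutation(len(labels))]))
    new_epochs = []
    for e, k in zip(epochset.epochs, keys):
        e2 = copy.copy(e)
        e2.label = permuted[k]
        new_epochs.append(e2)
    return EpochSet(new_epochs)


# --------------------------------------------------------------------------
# hyperparameter sampling

def _loguniform(rng, lo, hi):
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def sample_hyperparameters(classifier: str, n_draws: int, seed: int = 0):
    """Draw random configurations from a classifier's search space.

    Log-scaled domains are sampled uniformly in log10, integer domains
    uniformly over the integers, categorical domains uniformly.
    Conditional parameters (polynomial order only with the polynomial
    kernel, Minkowski exponent only with the Minkowski distance, kernel
    width/shape only with the kernel distribution) appear only when
    active.
    """
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        if classifier == "knn":
            cfg = {
                "distance": str(rng.choice(KNN_DISTANCES)),
                "distance_weight": str(
                    rng.choice(["equal", "inverse", "squaredinverse"])
                ),
                "n_neighbors": int(rng.integers(1, 6)),
            }
            if cfg["distance"] == "minkowski":
                cfg["exponent"] = float(rng.uniform(0.5, 3.0))
        elif classifier == "svm":
            cfg = {
                "box_constraint": _loguniform(rng, 1e-3, 1e3),
                "kernel": str(rng.choice(["gaussian", "linear", "polynomial"])),
                "kernel_scale": _loguniform(rng, 1e-3, 1e3),
            }
            if cfg["kernel"] == "polynomial":
                cfg["polynomial_order"] = int(rng.integers(1, 5))
        elif classifier == "ann":
            cfg = {
                "activation": str(rng.choice(["relu", "sigmoid", "tanh"])),
                "hidden_neurons": int(rng.integers(25, 201)),
            }
        elif classifier == "lda":
            cfg = {
                "gamma": float(rng.uniform(0.0, 1.0)),
                "delta": _loguniform(rng, 1e-6, 1e3),
                "discrim_type": str(rng.choice([
                    "linear", "quadratic", "diagLinear", "diagQuadratic",
                    "pseudoLinear", "pseudoQuadratic",
                ])),
            }
        else:  # nb
            cfg = {"distribution": str(rng.choice(["normal", "kernel"]))}
            if cfg["distribution"] == "kernel":
                cfg["width"] = _loguniform(rng, 1e-4, 1e14)
                cfg["kernel"] = str(rng.choice(
                    ["normal", "box", "epanechnikov", "triangle"]
                ))
        draws.append(cfg)
    return draws


# --------------------------------------------------------------------------
# classifier construction

def _rank_rows(X):
    return stats.rankdata(X, axis=1)


def _make_knn(config: dict, X_train: np.ndarray):
    distance = config.get("distance", "euclidean")
    weights = {
        "equal": "uniform",
        "inverse": "distance",
        "squaredinverse": lambda d: 1.0 / (d**2 + 1e-12),
    }[config.get("distance_weight", "equal")]
    k = min(int(config.get("n_neighbors", 1)), len(X_train))
    kwargs = dict(n_neighbors=k, weights=weights, algorithm="brute")
    pre = None
    if distance == "spearman":
        # Spearman distance == correlation distance on per-row ranks
        pre = FunctionTransformer(_rank_rows)
        kwargs["metric"] = "correlation"
    elif distance == "chebychev":
        kwargs["metric"] = "chebyshev"
    elif distance == "minkowski":
        kwargs["metric"] = "minkowski"
        kwargs["p"] = float(config.get("exponent", 2.0))
    elif distance == "mahalanobis":
        cov = np.cov(X_train.T)
        cov += 1e-6 * np.trace(np.atleast_2d(cov)) / cov.shape[0] * np.eye(cov.shape[0])
        kwargs["metric"] = "mahalanobis"
        kwargs["metric_params"] = {"VI": np.linalg.pinv(cov)}
    elif distance == "seuclidean":
        kwargs["metric"] = "seuclidean"
        kwargs["metric_params"] = {"V": X_train.var(axis=0) + 1e-12}
    else:
        kwargs["metric"] = distance
    est = KNeighborsClassifier(**kwargs)
    if pre is not None:
        return Pipeline([("rank", pre), ("knn", est)])
    return est


def train_classifier(kind: str, config: dict, train_features, train_labels,
                     seed: int = 0):
    """Fit one classifier of the given family with the given configuration.

    Ties in k-NN voting break toward the lowest class index (attentive);
    equidistant neighbours are taken in training-set order.  The ANN is a
    single hidden layer trained with weight decay (L2 strength 1e-4) and
    early stopping on a 10% validation split; the SVM uses the soft-margin
    formulation with C = box_constraint.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    if kind == "knn":
        model = _make_knn(config, X)
    elif kind == "svm":
        kernel = {"gaussian": "rbf", "linear": "linear",
                  "polynomial": "poly"}[config.get("kernel", "gaussian")]
        ks = float(config.get("kernel_scale", 1.0))
        model = SVC(
            C=float(config.get("box_constraint", 1.0)),
            kernel=kernel,
            gamma=1.0 / ks**2,
            degree=int(config.get("polynomial_order", 3)),
            coef0=1.0 if kernel == "poly" else 0.0,
            max_iter=100_000,
        )
    elif kind == "ann":
        act = {"relu": "relu", "sigmoid": "logistic",
               "tanh": "tanh"}[config.get("activation", "relu")]
        # a 10% validation split is only informative with enough samples;
        # below that, train on a fixed epoch budget instead
        early = len(X) >= 200
        model = MLPClassifier(
            hidden_layer_sizes=(int(config.get("hidden_neurons", 100)),),
            activation=act,
            alpha=1e-4,  # weight decay
            max_iter=300,
            early_stopping=early,
            validation_fraction=0.1,
            n_iter_no_change=20,
            random_state=int(seed),
        )
    elif kind == "lda":
        model = GaussianDiscriminant(
            discrim_type=config.get("discrim_type", "linear"),
            gamma=float(config.get("gamma", 0.0)),
            delta=float(config.get("delta", 0.0)),
        )
    elif kind == "nb":
        model = KernelNaiveBayes(
            distribution=config.get("distribution", "normal"),
            width=config.get("width"),
            kernel=config.get("kernel", "normal"),
        )
    else:
        raise ValueError(f"unknown classifier {kind!r}")
    model.fit(X, y)
    return model


# --------------------------------------------------------------------------
# nested cross-validation

def _precompute(epochset: EpochSet, fc: FeatureConfig):
    """Label-independent per-epoch statistics computed once up front."""
    data = epochset.data_array()
    if fc.kind == "fbcsp":
        bank = design_filter_bank(
            make_band_scheme(fc.scheme), epochset.fs,
            order=fc.filter_order, stopband_db=fc.stopband_db,
        )
        cov = band_covariances(data, bank)
        return ("fbcsp", cov)
    feats = []
    for e in data:
        freqs, psd = psd_estimate(e, epochset.fs, fc.psd_segment_s,
                                  fc.psd_overlap)
        feats.append(band_power_features(freqs, psd, fc.scheme))
    return ("psd", np.asarray(feats))


def _fold_features(pre, fc: FeatureConfig, train_idx, eval_idx, y):
    """Features for one train/eval partition; CSP fit on train only."""
    kind, stat = pre
    if kind == "fbcsp":
        model = fit_csp(stat[train_idx], y[train_idx],
                        scheme_name=fc.scheme, log_variance=fc.log_variance)
        return csp_features(stat[train_idx], model), csp_features(
            stat[eval_idx], model)
    return stat[train_idx], stat[eval_idx]


def _maybe_standardize(Xtr, Xte, on: bool):
    if not on:
        return Xtr, Xte
    sc = StandardScaler().fit(Xtr)
    return sc.transform(Xtr), sc.transform(Xte)


def nested_cv(epochset: EpochSet, feature_config: FeatureConfig,
              classifier: str, cv_config: NestedCVConfig) -> NestedCVReport:
    """Trial-grouped nested cross-validation of one feature/classifier pair.

    The outer loop holds out 1/l of the trials per fold; the inner k-fold
    random search runs entirely inside the outer training set.  CSP and
    feature standardization are refit inside every training partition.
    """
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    y = epochset.labels_int()
    n = len(epochset)
    ss = np.random.SeedSequence(cv_config.seed)
    seeds = ss.generate_state(4 + cv_config.outer_folds) % (2**31)
    standardize = cv_config.standardize
    if standardize is None:
        standardize = (
            classifier in ("knn", "svm", "ann")
            and feature_config.kind == "psd"
        )

    pre = _precompute(epochset, feature_config)
    draws = sample_hyperparameters(
        classifier, cv_config.n_random_draws, seed=int(seeds[0])
    )
    outer_assign = group_stratified_kfold(
        epochset, cv_config.outer_folds, seed=int(seeds[1])
    )
    outer = epoch_folds(epochset, outer_assign)

    predictions = np.full(n, -1, dtype=int)
    fold_results = []
    for f in range(cv_config.outer_folds):
        test_idx = np.flatnonzero(outer == f)
        train_idx = np.flatnonzero(outer != f)
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"outer fold {f} contains a single class")

        inner_set = epochset[train_idx]
        inner_assign = group_stratified_kfold(
            inner_set, cv_config.inner_folds, seed=int(seeds[4 + f])
        )
        inner = epoch_folds(inner_set, inner_assign)

        # features per inner fold are draw-independent: compute once
        inner_parts = []
        for g in range(cv_config.inner_folds):
            it = train_idx[inner != g]
            iv = train_idx[inner == g]
            Xtr, Xte = _fold_features(pre, feature_config, it, iv, y)
            Xtr, Xte = _maybe_standardize(Xtr, Xte, standardize)
            inner_parts.append((Xtr, y[it], Xte, y[iv]))

        clf_seed = int(seeds[2])
        best_cfg, best_acc = None, -np.inf
        for cfg in draws:
            accs = []
            for Xtr, ytr, Xte, yte in inner_parts:
                model = train_classifier(classifier, cfg, Xtr, ytr,
                                         seed=clf_seed)
                accs.append(float(np.mean(model.predict(Xte) == yte)))
            mean_acc = float(np.mean(accs))
            if mean_acc > best_acc:
                best_cfg, best_acc = cfg, mean_acc

        Xtr, Xte = _fold_features(pre, feature_config, train_idx, test_idx, y)
        Xtr, Xte = _maybe_standardize(Xtr, Xte, standardize)
        model = train_classifier(classifier, best_cfg, Xtr, y[train_idx],
                                 seed=clf_seed)
        pred = model.predict(Xte)
        predictions[test_idx] = pred
        acc = float(np.mean(pred == y[test_idx]))
        fold_results.append(
            FoldResult(fold=f, config=best_cfg, accuracy=acc,
                       n_test=len(test_idx))
        )
        logger.info("outer fold %d: accuracy %.3f with %s", f, acc, best_cfg)

    subject_ids = set(epochset.subject_ids())
    n_feat = (pre[1].shape[1] if pre[0] == "psd"
              else epochset.n_channels * max(1, len(
                  make_band_scheme(feature_config.scheme).bands)))
    return NestedCVReport(
        subject_id=subject_ids.pop() if len(subject_ids) == 1 else "pooled",
        classifier=classifier,
        feature_config=feature_config,
        cv_config=cv_config,
        folds=fold_results,
        predictions=predictions,
        labels=y,
        n_features=n_feat,
    )
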