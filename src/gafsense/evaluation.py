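"""Classification heads, validation protocols, clustering and statistics.

Heads are lightweight classifiers trained on principal-component scores of
the image embeddings: Random Forest (50 trees), Linear Discriminant
Analysis, 3-nearest-neighbours, Support Vector Machine, Extra Trees and
gradient-boosted trees (XGBoost), all otherwise at library defaults. A
``random`` head (uniform guessing) is included as the chance baseline.

Protocols:

* ``repeated_kfold_eval`` — 50 repetitions of a stratified random 80/20
  train/test resampling; PCA refitted on each training split (no leakage).
* ``sugar_locov_eval`` — leave-one-class-out on the extreme concentration
  levels of each sugar, relabelling the middle level to the held-out side;
  predictions pooled over the four iterations.
* ``milk_lopo_eval`` — leave-one-product-out; the held-out product's protein
  source must remain represented by a sibling product in training.
* ``cluster_and_score`` — ward/Euclidean agglomerative clustering at a fixed
  cluster count, scored by the Adjusted Rand Index.
* ``compare_accuracy_distributions`` — two-sided two-sample t-test between
  accuracy distributions (e.g. with vs without augmentation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import adjusted_rand_score, confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC

from .errors import InvalidArgumentError, ProtocolError
from .features import FeatureExtractor, FingerprintSet, fit_pca
from .pipeline import featurize_dataset
from .simulate import TaskDataset

__all__ = [
    "HeadSpec",
    "EvaluationReport",
    "HEAD_NAMES",
    "make_head",
    "train_head",
    "pooled_accuracy",
    "chance_interval",
    "repeated_kfold_eval",
    "sugar_locov_eval",
    "milk_lopo_eval",
    "cluster_and_score",
    "compare_accuracy_distributions",
]

HEAD_NAMES = ("RF", "LDA", "KNN", "SVM", "ET", "XGB", "random")


@dataclass(frozen=True)
class HeadSpec:
    """A named classification head plus any fixed hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)


class _Head:
    """Wraps an sklearn-style estimator with label encoding and guards."""

    def __init__(self, base):
        self.base = base
        self._le = LabelEncoder()

    def fit(self, x, y):
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise InvalidArgumentError("training set must contain >= 2 classes")
        self.base.fit(np.asarray(x, dtype=float), self._le.fit_transform(y))
        return self

    def predict(self, x):
        return self._le.inverse_transform(self.base.predict(np.asarray(x, dtype=float)))


def make_head(spec: HeadSpec | str, seed: int = 0) -> _Head:
    """Instantiate a head by name; stochastic heads are seeded."""
    if isinstance(spec, str):
        spec = HeadSpec(spec)
    name = {"GBT": "XGB"}.get(spec.name, spec.name)
    hp = dict(spec.hyperparameters)
    if name == "RF":
        base = RandomForestClassifier(n_estimators=hp.pop("n_estimators", 50), random_state=seed, **hp)
    elif name == "LDA":
        base = LinearDiscriminantAnalysis(**hp)
    elif name == "KNN":
        base = KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 3), **hp)
    elif name == "SVM":
        base = SVC(random_state=seed, **hp)
    elif name == "ET":
        base = ExtraTreesClassifier(random_state=seed, **hp)
    elif name == "XGB":
        from xgboost import XGBClassifier

        base = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **hp)
    elif name == "random":
        base = DummyClassifier(strategy="uniform", random_state=seed)
    else:
        raise InvalidArgumentError(f"unknown head {spec.name!r}; choose from {HEAD_NAMES}")
    return _Head(base)


def train_head(spec: HeadSpec | str, scores: FingerprintSet, seed: int = 0) -> _Head:
    """Fit a head on principal-component scores."""
    return make_head(spec, seed).fit(scores.embeddings, scores.labels)


@dataclass
class EvaluationReport:
    """Outcome of one protocol run.

    ``accuracies`` holds one value per repetition/iteration; for pooled
    protocols ``pooled_accuracy`` over all held-out predictions is the
    headline number. Mean/std are always recomputed from the stored vector.
    """

    protocol: str
    accuracies: np.ndarray
    confusion: np.ndarray
    class_names: list
    seeds: list
    config: dict = field(default_factory=dict)
    pooled_accuracy: float | None = None
    n_pooled: int | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        acc = np.asarray(self.accuracies, dtype=float)
        return float(acc.std(ddof=1)) if acc.size > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "accuracies": list(map(float, self.accuracies)),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "n_pooled": self.n_pooled,
            "confusion": np.asarray(self.confusion).tolist(),
            "class_names": [str(c) for c in self.class_names],
            "seeds": list(map(int, self.seeds)),
            "config": self.config,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def pooled_accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions pooled over all held-out instances."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise InvalidArgumentError("prediction vectors must align and be non-empty")
    return float(np.mean(y_true == y_pred))


def chance_interval(n_classes: int, n_predictions: int, level: float = 0.95) -> tuple[float, float]:
    """95% binomial interval for the pooled accuracy of uniform guessing."""
    p = 1.0 / n_classes
    lo, hi = stats.binom.interval(level, n_predictions, p)
    return lo / n_predictions, hi / n_predictions


def _as_fingerprints(dataset, extractor, **encode_kw) -> FingerprintSet:
    if isinstance(dataset, FingerprintSet):
        return dataset
    if isinstance(dataset, TaskDataset):
        return featurize_dataset(dataset, extractor, **encode_kw)
    raise InvalidArgumentError("dataset must be a TaskDataset or FingerprintSet")


def _fit_predict(train: FingerprintSet, test: FingerprintSet, head, k_components, seed):
    """PCA on the training split only, then head fit/predict. No leakage."""
    k = min(k_components, train.n, train.embeddings.shape[1])
    if k < k_components:
        raise ProtocolError(
            f"k_components={k_components} exceeds training rank limit {k}"
        )
    model = fit_pca(train, k_components)
    # head seed decorrelated from the split seed so stochastic heads do not
    # share a random stream with the resampler
    head_seed = int(np.random.SeedSequence([int(seed), 0x6EAD]).generate_state(1)[0] % (2**31))
    clf = make_head(head, head_seed).fit(model.transform(train.embeddings), train.labels)
    return clf.predict(model.transform(test.embeddings))


def repeated_kfold_eval(
    dataset,
    extractor: FeatureExtractor | None = None,
    head: HeadSpec | str = "LDA",
    k_components: int = 20,
    reps: int = 50,
    seed: int = 0,
    **encode_kw,
) -> EvaluationReport:
    """Repeated stratified 80/20 random resampling validation.

    Each repetition draws a fresh stratified split, refits PCA on the
    training portion, trains the head and records test accuracy. Requires
    every class to have at least 5 instances (so each split keeps all
    classes on both sides).
    """
    fset = _as_fingerprints(dataset, extractor, **encode_kw)
    labels = fset.labels
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 5:
        raise ProtocolError("repeated 5-fold protocol needs >= 5 instances per class")
    accs, seeds = [], []
    conf = np.zeros((classes.size, classes.size), dtype=int)
    idx = np.arange(fset.n)
    for rep in range(reps):
        rep_seed = seed + rep
        tr, te = train_test_split(idx, test_size=0.2, stratify=labels, random_state=rep_seed)
        pred = _fit_predict(fset.subset(tr), fset.subset(te), head, k_components, rep_seed)
        accs.append(pooled_accuracy(labels[te], pred))
        conf += confusion_matrix(labels[te], pred, labels=classes)
        seeds.append(rep_seed)
    return EvaluationReport(
        protocol="repeated_kfold",
        accuracies=np.array(accs),
        confusion=conf,
        class_names=list(classes),
        seeds=seeds,
        config={"head": str(head), "k_components": k_components, "reps": reps, "seed": seed},
    )


_SUGAR_EXTREMES = {"2.5": "low", "10": "high"}


def _split_sugar_label(label: str) -> tuple[str, str]:
    sugar, _, level = str(label).rpartition("_")
    if not sugar:
        raise ProtocolError(f"label {label!r} is not of the form <sugar>_<level>")
    return sugar, level


def sugar_locov_eval(
    dataset,
    extractor: FeatureExtractor | None = None,
    head: HeadSpec | str = "LDA",
    k_components: int = 20,
    seed: int = 0,
    **encode_kw,
) -> EvaluationReport:
    """Leave-one-class-out over the extreme sugar concentration levels.

    Four iterations, one per (sugar, extreme level). All replicates of the
    held-out class are removed from training; the middle (5%) level is
    relabelled to the held-out side so the model still sees that region of
    concentration space. Predictions are pooled over all held-out instances
    and scored among {glucose,sucrose} x {low,high}.
    """
    fset = _as_fingerprints(dataset, extractor, **encode_kw)
    pairs = [_split_sugar_label(l) for l in fset.labels]
    sugars = sorted({s for s, _ in pairs})
    levels = sorted({lv for _, lv in pairs}, key=float)
    if len(levels) != 3:
        raise ProtocolError(f"sugar protocol expects 3 concentration levels, found {levels}")
    mid = levels[1]
    y_true_all, y_pred_all, accs, seeds = [], [], [], []
    class_names = sorted(f"{s}_{side}" for s in sugars for side in ("low", "high"))
    it = 0
    for sugar in sugars:
        for extreme, side in _SUGAR_EXTREMES.items():
            test_mask = np.array([s == sugar and lv == extreme for s, lv in pairs])
            if not test_mask.any():
                raise ProtocolError(f"missing class {sugar}_{extreme} in dataset")
            train_mask = ~test_mask
            train_labels = []
            for flag, (s, lv) in zip(train_mask, pairs):
                if not flag:
                    continue
                mapped = side if lv == mid else _SUGAR_EXTREMES.get(lv)
                if mapped is None:
                    raise ProtocolError(f"unexpected level {lv!r}")
                train_labels.append(f"{s}_{mapped}")
            train = FingerprintSet(
                fset.embeddings[train_mask], np.array(train_labels, dtype=object)
            )
            test = fset.subset(np.where(test_mask)[0])
            pred = _fit_predict(train, test, head, k_components, seed + it)
            truth = np.array([f"{sugar}_{side}"] * test.n, dtype=object)
            y_true_all.extend(truth)
            y_pred_all.extend(pred)
            accs.append(pooled_accuracy(truth, pred))
            seeds.append(seed + it)
            it += 1
    conf = confusion_matrix(y_true_all, y_pred_all, labels=class_names)
    return EvaluationReport(
        protocol="sugar_leave_one_class_out",
        accuracies=np.array(accs),
        confusion=conf,
        class_names=class_names,
        seeds=seeds,
        config={"head": str(head), "k_components": k_components, "seed": seed},
        pooled_accuracy=pooled_accuracy(y_true_all, y_pred_all),
        n_pooled=len(y_true_all),
    )


def milk_lopo_eval(
    dataset,
    extractor: FeatureExtractor | None = None,
    head: HeadSpec | str = "LDA",
    k_components: int = 20,
    seed: int = 0,
    **encode_kw,
) -> EvaluationReport:
    """Leave-one-product-out protein-source classification.

    One iteration per product: all its replicates are held out and the
    source is predicted among the training classes. Every source must own at
    least two products, otherwise the held-out product's class would vanish
    from training.
    """
    fset = _as_fingerprints(dataset, extractor, **encode_kw)
    if fset.product_ids is None or any(p is None for p in fset.product_ids):
        raise ProtocolError("leave-one-product-out requires product identifiers")
    products = np.asarray(fset.product_ids, dtype=object)
    labels = fset.labels
    for cls in np.unique(labels):
        if np.unique(products[labels == cls]).size < 2:
            raise ProtocolError(f"source class {cls!r} has a single product; protocol undefined")
    class_names = sorted(np.unique(labels))
    y_true_all, y_pred_all, accs, seeds = [], [], [], []
    for it, prod in enumerate(sorted(np.unique(products))):
        test_mask = products == prod
        train = fset.subset(np.where(~test_mask)[0])
        test = fset.subset(np.where(test_mask)[0])
        assert set(np.unique(test.labels)) <= set(np.unique(train.labels))
        pred = _fit_predict(train, test, head, k_components, seed + it)
        y_true_all.extend(test.labels)
        y_pred_all.extend(pred)
        accs.append(pooled_accuracy(test.labels, pred))
        seeds.append(seed + it)
    conf = confusion_matrix(y_true_all, y_pred_all, labels=class_names)
    return EvaluationReport(
        protocol="milk_leave_one_product_out",
        accuracies=np.array(accs),
        confusion=conf,
        class_names=class_names,
        seeds=seeds,
        config={"head": str(head), "k_components": k_components, "seed": seed},
        pooled_accuracy=pooled_accuracy(y_true_all, y_pred_all),
        n_pooled=len(y_true_all),
    )


def cluster_and_score(
    scores: FingerprintSet | np.ndarray,
    true_labels=None,
    n_clusters: int = 4,
) -> tuple[float, np.ndarray]:
    """Ward/Euclidean agglomerative clustering + Adjusted Rand Index.

    Returns (ARI against ``true_labels``, cluster assignments). ARI is 1
    when clusters reproduce the true grouping and near 0 for random labels.
    """
    if isinstance(scores, FingerprintSet):
        x = scores.embeddings
        if true_labels is None:
            true_labels = scores.labels
    else:
        x = np.asarray(scores, dtype=float)
    if true_labels is None:
        raise InvalidArgumentError("true labels required to score clustering")
    if x.shape[0] < n_clusters:
        raise InvalidArgumentError("need at least as many samples as clusters")
    assign = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(x)
    return float(adjusted_rand_score(np.asarray(true_labels, dtype=object), assign)), assign


def compare_accuracy_distributions(a, b) -> float:
    """Two-sided two-sample t-test p-value between accuracy distributions.

    Zero variance in both samples with equal means returns p = 1 by
    convention (scipy yields NaN there).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("need at least two accuracies per condition")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b).pvalue)
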