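"""Classification cases, cross-validation, classifier adapters and metrics.

The benchmark protocol groups the five Bonn sets (A, B healthy; C, D
interictal; E ictal) into 16 two-class problems — each contrasting some
combination of non-seizure sets against the seizure set E, plus the
AB-vs-CD contrast — and one three-class problem AB-CD-E.  Every problem
is evaluated by stratified 10-fold cross-validation: metrics are
computed on each held-out fold and the ten results averaged.

Four classical classifiers are wrapped behind one adapter contract:
linear-kernel support vector machine, k-nearest neighbours (k = 3,
Euclidean distance), Gaussian naive Bayes and a Gini decision tree.
Their internal optimisation/probability machinery is delegated to
scikit-learn; the adapter owns determinism, input validation and the
kNN tie-break (nearest-neighbour distance, then lowest class index).

Six confusion-matrix metrics are reported: accuracy, sensitivity,
specificity, PPV, NPV (all percentages) and the Matthews correlation
coefficient.  For the three-class problem the binary metrics are
one-vs-rest with the seizure group as the positive class, and accuracy
is the fraction of correctly classified patterns over all patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, FeatureTable

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassificationCase",
    "ClassifierSpec",
    "CVSpec",
    "ConfusionMatrix",
    "MetricsReport",
    "EvaluationResult",
    "build_cases",
    "make_case",
    "kfold_split",
    "fit_predict",
    "confusion_from_predictions",
    "compute_metrics",
    "run_case",
    "grid_evaluate",
    "best_per_case_classifier",
]

CLASSIFIER_KINDS = ("SVM", "KNN", "NB", "DT")

#: The canonical two-class case names, in published-table order.
_TWO_CLASS_NAMES = (
    "A-E", "B-E", "C-E", "D-E",
    "AB-E", "AC-E", "AD-E", "BC-E", "BD-E", "CD-E",
    "ABC-E", "ABD-E", "ACD-E", "BCD-E", "ABCD-E",
    "AB-CD",
)
_THREE_CLASS_NAME = "AB-CD-E"


@dataclass(frozen=True)
class ClassificationCase:
    """A named grouping of set labels into 2 or 3 classes.

    For two-class cases the last group is the designated positive class
    (the seizure side in every E-containing contrast).
    """

    name: str
    class_groups: Tuple[frozenset, ...]

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.class_groups)
        object.__setattr__(self, "class_groups", groups)
        if len(groups) not in (2, 3):
            raise ValueError(f"{self.name}: need 2 or 3 class groups")
        if any(not g for g in groups):
            raise ValueError(f"{self.name}: empty class group")
        seen: set = set()
        for g in groups:
            if seen & g:
                raise ValueError(f"{self.name}: class groups overlap")
            seen |= g
        # class index of a set label
        lookup = {}
        for idx, g in enumerate(groups):
            for lbl in g:
                lookup[lbl] = idx
        object.__setattr__(self, "_lookup", lookup)

    @property
    def n_classes(self) -> int:
        return len(self.class_groups)

    @property
    def positive_class(self) -> int:
        return self.n_classes - 1

    @property
    def set_labels(self) -> frozenset:
        return frozenset(self._lookup)

    def class_of(self, set_label: str) -> int:
        try:
            return self._lookup[set_label]
        except KeyError:
            raise KeyError(
                f"set label {set_label!r} not part of case {self.name}"
            ) from None


def make_case(name: str) -> ClassificationCase:
    """Build a case from a hyphenated name, e.g. ``"ABCD-E"`` or ``"AB-CD-E"``.

    Each hyphen-separated token is a group of single-character set labels.
    """
    groups = [frozenset(token) for token in name.split("-") if token]
    return ClassificationCase(name=name, class_groups=tuple(groups))


def build_cases(include_three_class: bool = True) -> List[ClassificationCase]:
    """The 16 canonical two-class problems, plus AB-CD-E when requested."""
    cases = [make_case(n) for n in _TWO_CLASS_NAMES]
    if include_three_class:
        cases.append(make_case(_THREE_CLASS_NAME))
    return cases


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation layout: fold count, stratification, shuffle seed."""

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"need at least 2 folds, got {self.n_folds}")


def kfold_split(labels: Sequence[int], spec: CVSpec) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(train, test) index pairs; test sets partition the index set.

    Stratified folds preserve each class's proportion to within one
    sample, which requires every class to have at least ``n_folds``
    members.
    """
    y = np.asarray(labels)
    n = y.size
    if n < spec.n_folds:
        raise ValueError(
            f"cannot split {n} samples into {spec.n_folds} folds"
        )
    if spec.stratified:
        classes, counts = np.unique(y, return_counts=True)
        small = classes[counts < spec.n_folds]
        if small.size:
            raise ValueError(
                f"classes {small.tolist()} have fewer than {spec.n_folds} "
                "members; stratified folding is impossible"
            )
        splitter = StratifiedKFold(
            n_splits=spec.n_folds, shuffle=True, random_state=spec.seed
        )
    else:
        splitter = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    return [
        (np.asarray(tr), np.asarray(te))
        for tr, te in splitter.split(np.zeros((n, 1)), y)
    ]


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four classifier kinds plus its hyperparameters.

    Defaults: SVM linear kernel with C = 1; kNN with k = 3 and Euclidean
    distance; Gaussian naive Bayes; decision tree with the Gini
    criterion and no depth limit.  ``seed`` fixes any stochastic
    component (tree feature-order tie-breaking).
    """

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; valid kinds: "
                f"{', '.join(CLASSIFIER_KINDS)}"
            )
        if self.kind == "KNN":
            k = self.hyperparameters.get("k", 3)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kNN k must be odd and >= 1, got {k}")


def _validate_xy(train_X, train_y, test_X):
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.ndim != 2 or test_X.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError(
            f"train has {train_X.shape[1]} feature columns but test has "
            f"{test_X.shape[1]}"
        )
    if not np.all(np.isfinite(train_X)) or not np.all(np.isfinite(test_X)):
        raise ValueError("non-finite feature value in input")
    return train_X, train_y, test_X


def _knn_predict(spec: ClassifierSpec, train_X, train_y, test_X) -> np.ndarray:
    """Majority vote over the k Euclidean nearest neighbours.

    Vote ties are broken by the distance of the nearest neighbour among
    the tied classes, then by the lowest class index.
    """
    k = spec.hyperparameters.get("k", 3)
    if k > train_X.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {train_X.shape[0]} training samples"
        )
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(train_X)
    dist, idx = nn.kneighbors(test_X)
    neigh_y = train_y[idx]  # (n_test, k)
    preds = np.empty(test_X.shape[0], dtype=train_y.dtype)
    for i in range(test_X.shape[0]):
        classes, votes = np.unique(neigh_y[i], return_counts=True)
        top = classes[votes == votes.max()]
        if top.size == 1:
            preds[i] = top[0]
            continue
        best_cls, best_dist = None, np.inf
        for cls in sorted(top):
            d = dist[i][neigh_y[i] == cls].min()
            if d < best_dist - 1e-12:
                best_cls, best_dist = cls, d
        preds[i] = best_cls
    return preds


def fit_predict(
    classifier: ClassifierSpec,
    train_X,
    train_y,
    test_X,
    n_classes: Optional[int] = None,
) -> np.ndarray:
    """Train the wrapped classifier and predict class indices for test rows.

    Deterministic given the spec's seed.  Raises when a class expected
    in the problem is absent from the training labels or any feature is
    non-finite.
    """
    train_X, train_y, test_X = _validate_xy(train_X, train_y, test_X)
    present = np.unique(train_y)
    if present.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if n_classes is not None and present.size != n_classes:
        missing = sorted(set(range(n_classes)) - set(present.tolist()))
        raise ValueError(f"classes {missing} missing from training data")

    hp = classifier.hyperparameters
    if classifier.kind == "KNN":
        return _knn_predict(classifier, train_X, train_y, test_X)
    if classifier.kind == "SVM":
        model = SVC(
            kernel=hp.get("kernel", "linear"),
            C=hp.get("C", 1.0),
            random_state=classifier.seed,
        )
    elif classifier.kind == "NB":
        model = GaussianNB()
    else:  # DT
        model = DecisionTreeClassifier(
            criterion=hp.get("criterion", "gini"),
            random_state=classifier.seed,
        )
    model.fit(train_X, train_y)
    return np.asarray(model.predict(test_X))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Full K x K count table (rows = truth, columns = prediction).

    Binary counts TP/FP/TN/FN are one-vs-rest for ``positive_class``;
    CCP (correctly classified patterns) is the trace and TPT the total.
    """

    table: np.ndarray
    positive_class: int = 1

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=int)
        object.__setattr__(self, "table", table)
        if table.ndim != 2 or table.shape[0] != table.shape[1]:
            raise ValueError("confusion table must be square")
        if (table < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if not (0 <= self.positive_class < table.shape[0]):
            raise ValueError(
                f"positive_class {self.positive_class} out of range for a "
                f"{table.shape[0]}-class table"
            )

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ConfusionMatrix":
        """Binary matrix from the four counts (positive class index 1)."""
        return cls(table=np.array([[tn, fp], [fn, tp]]), positive_class=1)

    def one_vs_rest(self, cls_index: int) -> Tuple[int, int, int, int]:
        """(TP, FP, TN, FN) treating ``cls_index`` as positive."""
        t = self.table
        tp = int(t[cls_index, cls_index])
        fn = int(t[cls_index].sum() - tp)
        fp = int(t[:, cls_index].sum() - tp)
        tn = int(t.sum() - tp - fn - fp)
        return tp, fp, tn, fn

    @property
    def TP(self) -> int:
        return self.one_vs_rest(self.positive_class)[0]

    @property
    def FP(self) -> int:
        return self.one_vs_rest(self.positive_class)[1]

    @property
    def TN(self) -> int:
        return self.one_vs_rest(self.positive_class)[2]

    @property
    def FN(self) -> int:
        return self.one_vs_rest(self.positive_class)[3]

    @property
    def CCP(self) -> int:
        return int(np.trace(self.table))

    @property
    def TPT(self) -> int:
        return int(self.table.sum())


def confusion_from_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    positive_class: int = 1,
    n_classes: Optional[int] = None,
) -> ConfusionMatrix:
    """Exact confusion counts from paired truth/prediction vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError(
            f"length mismatch: {y_true.size} truths vs {y_pred.size} predictions"
        )
    if y_true.size == 0:
        raise ValueError("need at least one prediction")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max(), positive_class)) + 1
    table = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(table=table, positive_class=positive_class)


@dataclass(frozen=True)
class MetricsReport:
    """The six confusion-matrix metrics.

    Percentages in [0, 100]; MCC in [-1, 1].  A 0/0 ratio is reported as
    NaN (printed ``NA``); an MCC whose denominator is zero is 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float

    _FIELDS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "mcc")

    @classmethod
    def mean(cls, reports: Sequence["MetricsReport"]) -> "MetricsReport":
        """Field-wise mean over folds; undefined (NaN) folds are skipped."""
        if not reports:
            raise ValueError("cannot average zero reports")
        values = {}
        for name in cls._FIELDS:
            col = np.asarray([getattr(r, name) for r in reports], dtype=float)
            finite = col[np.isfinite(col)]
            values[name] = float(finite.mean()) if finite.size else math.nan
        return cls(**values)


def _ratio_pct(num: int, den: int) -> float:
    return math.nan if den == 0 else 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV and MCC from a matrix.

    Accuracy is 100 * CCP / TPT (valid for 2- and 3-class tables); the
    other five are one-vs-rest for the matrix's positive class.
    """
    if cm.TPT == 0:
        raise ValueError("confusion matrix contains no patterns")
    tp, fp, tn, fn = cm.one_vs_rest(cm.positive_class)
    # exact integer product under one sqrt keeps MCC inside [-1, 1]
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom_sq == 0 else (tp * tn - fp * fn) / math.sqrt(denom_sq)
    mcc = min(1.0, max(-1.0, mcc))
    return MetricsReport(
        accuracy=100.0 * cm.CCP / cm.TPT,
        sensitivity=_ratio_pct(tp, tp + fn),
        specificity=_ratio_pct(tn, tn + fp),
        ppv=_ratio_pct(tp, tp + fp),
        npv=_ratio_pct(tn, tn + fn),
        mcc=mcc,
    )


@dataclass(frozen=True)
class EvaluationResult:
    """Cross-validated metrics for one (case, subband, feature, classifier)."""

    case_name: str
    subband: str
    feature: str
    classifier: str
    metrics: MetricsReport
    n_samples: int = 0


def run_case(
    case: ClassificationCase,
    table: FeatureTable,
    feature_selector: Union[str, Tuple[str, str]] = "all",
    classifier: Optional[ClassifierSpec] = None,
    cv: Optional[CVSpec] = None,
    pooled: bool = False,
) -> EvaluationResult:
    """Evaluate one classification case with k-fold cross-validation.

    ``feature_selector`` is a (subband, feature) pair for single-feature
    evaluation or ``"all"`` for the full feature matrix.  Metrics are
    computed per held-out fold and averaged unless ``pooled`` is set, in
    which case a single confusion matrix is accumulated over folds.
    """
    classifier = classifier or ClassifierSpec("SVM")
    cv = cv or CVSpec()
    missing = case.set_labels - set(table.set_labels)
    if missing:
        raise ValueError(
            f"case {case.name}: set labels {sorted(missing)} absent from the "
            "feature table"
        )
    cols = table.columns_for(feature_selector)
    if not cols:
        raise ValueError("empty feature selection")
    mask = table.frame["set_label"].isin(case.set_labels).to_numpy()
    sub = table.frame.loc[mask]
    X = sub[cols].to_numpy(dtype=float)
    y = np.asarray([case.class_of(lbl) for lbl in sub["set_label"]])

    folds = kfold_split(y, cv)
    per_fold = []
    pooled_table = np.zeros((case.n_classes, case.n_classes), dtype=int)
    for train_idx, test_idx in folds:
        preds = fit_predict(
            classifier, X[train_idx], y[train_idx], X[test_idx],
            n_classes=case.n_classes,
        )
        cm = confusion_from_predictions(
            y[test_idx], preds,
            positive_class=case.positive_class,
            n_classes=case.n_classes,
        )
        pooled_table += cm.table
        per_fold.append(compute_metrics(cm))
    if pooled:
        metrics = compute_metrics(
            ConfusionMatrix(table=pooled_table, positive_class=case.positive_class)
        )
    else:
        metrics = MetricsReport.mean(per_fold)
    if feature_selector == "all":
        subband, feature = "all", "all"
    else:
        subband, feature = feature_selector
    return EvaluationResult(
        case_name=case.name,
        subband=subband,
        feature=feature,
        classifier=classifier.kind,
        metrics=metrics,
        n_samples=int(y.size),
    )


def grid_evaluate(
    table: FeatureTable,
    cases: Sequence[ClassificationCase],
    classifiers: Sequence[ClassifierSpec],
    cv: Optional[CVSpec] = None,
    subbands: Optional[Sequence[str]] = None,
    features: Optional[Sequence[str]] = None,
) -> List[EvaluationResult]:
    """One EvaluationResult per (case x subband x feature x classifier).

    Single-feature evaluation is the default grid mode, mirroring the
    per-feature rows of the published tables; restrict ``subbands`` /
    ``features`` to shrink the grid.
    """
    if not cases or not classifiers:
        raise ValueError("need at least one case and one classifier")
    cv = cv or CVSpec()
    subbands = tuple(subbands) if subbands else table.subbands_used
    features = tuple(features) if features else FEATURE_NAMES
    results = []
    for case in cases:
        for sb in subbands:
            for ft in features:
                for clf in classifiers:
                    results.append(
                        run_case(case, table, (sb, ft), clf, cv)
                    )
    return results


def best_per_case_classifier(
    results: Sequence[EvaluationResult],
) -> Dict[Tuple[str, str], EvaluationResult]:
    """Highest-accuracy (subband, feature) per (case, classifier).

    Ties are broken by grid order: the first result encountered at the
    top accuracy wins (subband-major, features in canonical order).
    """
    best: Dict[Tuple[str, str], EvaluationResult] = {}
    for res in results:
        key = (res.case_name, res.classifier)
        cur = best.get(key)
        if cur is None or res.metrics.accuracy > cur.metrics.accuracy:
            best[key] = res
    return best
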