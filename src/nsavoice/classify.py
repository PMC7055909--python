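"""Voice-type classifiers, feature-subset ablation and evaluation metrics.

Five classifier families are evaluated on the seven-feature table: linear
discriminant (LD), a "medium" decision tree (up to 20 splits, Gini
criterion), a linear SVM with one-vs-one multiclass voting, weighted KNN
(k = 10, Euclidean, inverse-squared-distance weights), and a single-hidden-
layer neural network (100 units, cross-entropy loss, early stopping).
LD/DT/SVM/KNN are scored by stratified 5-fold cross-validation with
held-out predictions pooled across folds; the NN uses repeated random
stratified 70/15/15 train/validation/test splits (6 repeats) with the mean
test accuracy reported.

Feature subsets follow a leave-one-feature-out (LOFO) plan — the full set,
the seven 6-feature sets with one feature removed, the spectral set
{H1..H4, SE}, and the stability set {Jr, Sr}. Reports carry row-normalized
confusion matrices, overall and per-type accuracy, one-vs-rest TPR/FPR/AUC
per class, and per-set / per-classifier averages. Chi-square tests of
independence on (group x correct/incorrect) contingencies compare
classifiers on one subset or subsets within one classifier.

Features are z-score standardized inside each training fold (the distance-
and gradient-based classifiers are scale-sensitive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "EvalEntry",
    "EvaluationReport",
    "default_specs",
    "standard_subsets",
    "train_eval_cv",
    "train_eval_nn",
    "run_lofo",
    "per_type_metrics",
    "chi_square_compare",
]

CLASSIFIER_KINDS: tuple[str, ...] = ("LD", "DT", "SVM", "KNN", "NN")


def _inverse_squared_distance(d: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(d, 1e-12) ** 2


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its fixed hyperparameters and a seed."""

    kind: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def estimator(self) -> Pipeline:
        if self.kind == "LD":
            clf = LinearDiscriminantAnalysis()
        elif self.kind == "DT":
            # max_leaf_nodes = 21 caps the tree at 20 binary splits
            clf = DecisionTreeClassifier(
                criterion="gini", max_leaf_nodes=21, random_state=self.seed
            )
        elif self.kind == "SVM":
            # linear SVC trains one-vs-one and predicts by pairwise voting;
            # decision_function_shape only affects the exported scores
            clf = SVC(kernel="linear", decision_function_shape="ovr", random_state=self.seed)
        elif self.kind == "KNN":
            clf = KNeighborsClassifier(
                n_neighbors=10, metric="euclidean", weights=_inverse_squared_distance
            )
        else:  # NN
            clf = MLPClassifier(
                hidden_layer_sizes=(100,),
                early_stopping=True,
                validation_fraction=0.15 / 0.85,
                n_iter_no_change=25,
                learning_rate_init=0.005,
                max_iter=600,
                random_state=self.seed,
            )
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def default_specs(seed: int = 0, kinds: tuple[str, ...] = CLASSIFIER_KINDS) -> list[ClassifierSpec]:
    return [ClassifierSpec(kind=k, seed=seed) for k in kinds]


def standard_subsets(features: tuple[str, ...] = FEATURE_NAMES) -> dict[str, tuple[str, ...]]:
    """The ten evaluation subsets: full, seven LOFO sets, spectral, stability."""
    plan: dict[str, tuple[str, ...]] = {"full": tuple(features)}
    for f in features:
        plan[f"-{f}"] = tuple(x for x in features if x != f)
    plan["spectral"] = ("H1", "H2", "H3", "H4", "SE")
    plan["stability"] = ("Jr", "Sr")
    return plan


@dataclass
class EvalEntry:
    """Pooled held-out evaluation of one (subset, classifier) cell."""

    classifier: str
    subset: str
    classes: tuple[str, ...]
    confusion_counts: np.ndarray
    accuracy: float
    per_class_accuracy: dict[str, float]
    tpr: dict[str, float]
    fpr: dict[str, float]
    auc: dict[str, float]
    n_correct: int
    n_incorrect: int
    accuracy_per_repeat: list[float] = field(default_factory=list)

    @property
    def confusion_normalized(self) -> np.ndarray:
        counts = self.confusion_counts.astype(float)
        row_sums = counts.sum(axis=1, keepdims=True)
        return counts / np.where(row_sums == 0, 1.0, row_sums)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "subset": self.subset,
            "classes": list(self.classes),
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "auc": self.auc,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
        }


def per_type_metrics(
    confusion_counts: np.ndarray,
    classes: tuple[str, ...],
    y_true: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """One-vs-rest TPR, FPR and AUC per class.

    TPR/FPR come from the count matrix; AUC needs per-sample class scores
    (columns ordered like ``classes``) and is computed by the rank
    statistic, NaN when scores are absent.
    """
    cm = np.asarray(confusion_counts, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] != len(classes):
        raise ValueError("confusion matrix must be square and match classes")
    total = cm.sum()
    tpr: dict[str, float] = {}
    fpr: dict[str, float] = {}
    auc: dict[str, float] = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            raise ValueError(f"class {cls!r} has zero true instances; metrics undefined")
        tpr[cls] = float(tp / (tp + fn))
        fpr[cls] = float(fp / (fp + tn)) if fp + tn > 0 else float("nan")
        if scores is not None and y_true is not None:
            auc[cls] = float(roc_auc_score((np.asarray(y_true) == cls).astype(int), scores[:, i]))
        else:
            auc[cls] = float("nan")
    return tpr, fpr, auc


def _class_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)
        except AttributeError:
            pass
    return model.decision_function(X)


def _build_entry(
    classifier: str,
    subset: str,
    classes: tuple[str, ...],
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    accuracy: float | None = None,
    accuracy_per_repeat: list[float] | None = None,
) -> EvalEntry:
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    n_correct = int(np.trace(cm))
    n_total = int(cm.sum())
    tpr, fpr, auc = per_type_metrics(cm, classes, y_true=y_true, scores=scores)
    per_class = {c: tpr[c] for c in classes}  # per-type accuracy = class recall
    return EvalEntry(
        classifier=classifier,
        subset=subset,
        classes=classes,
        confusion_counts=cm,
        accuracy=float(accuracy if accuracy is not None else n_correct / n_total),
        per_class_accuracy=per_class,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        n_correct=n_correct,
        n_incorrect=n_total - n_correct,
        accuracy_per_repeat=accuracy_per_repeat or [],
    )


def _as_xy(features: pd.DataFrame, columns: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    if "label" not in features.columns:
        raise ValueError("feature table needs a 'label' column")
    return features.loc[:, list(columns)].to_numpy(float), features["label"].to_numpy()


def train_eval_cv(
    features: pd.DataFrame,
    spec: ClassifierSpec,
    folds: int = 5,
    columns: tuple[str, ...] = FEATURE_NAMES,
    subset_name: str = "full",
) -> EvalEntry:
    """Stratified k-fold cross-validation with metrics pooled over the
    held-out folds."""
    X, y = _as_xy(features, columns)
    classes = tuple(sorted(np.unique(y)))
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} samples < {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    y_pred = np.empty(len(y), dtype=object)
    scores = np.zeros((len(y), len(classes)))
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < len(classes):
            raise ValueError("a class is absent from a training fold")
        model = spec.estimator()
        model.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = model.predict(X[test_idx])
        scores[test_idx] = _class_scores(model, X[test_idx])
    return _build_entry(spec.kind, subset_name, classes, y, y_pred.astype(y.dtype), scores)


def train_eval_nn(
    features: pd.DataFrame,
    spec: ClassifierSpec,
    repeats: int = 6,
    test_frac: float = 0.15,
    columns: tuple[str, ...] = FEATURE_NAMES,
    subset_name: str = "full",
) -> EvalEntry:
    """Repeated random stratified 70/15/15 evaluation for the NN.

    Each repeat holds out ``test_frac`` for testing; the estimator's early
    stopping carves the validation share out of the remainder. The entry's
    ``accuracy`` is the mean test accuracy over repeats; confusion counts
    and TPR/FPR/AUC are pooled over all repeats' test sets.
    """
    if spec.kind != "NN":
        raise ValueError("train_eval_nn is for the NN classifier")
    X, y = _as_xy(features, columns)
    classes = tuple(sorted(np.unique(y)))
    counts = pd.Series(y).value_counts()
    if counts.min() < 20:
        raise ValueError("need at least 20 samples per class for the NN protocol")
    accs: list[float] = []
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    scores_all: list[np.ndarray] = []
    for r in range(repeats):
        rs = spec.seed + 1009 * r
        model = None
        for attempt, seed_r in enumerate((rs, rs + 7919)):
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=test_frac, stratify=y, random_state=seed_r
            )
            candidate = ClassifierSpec(kind="NN", seed=seed_r).estimator()
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    candidate.fit(Xtr, ytr)
                    model = candidate
                    break
                except ConvergenceWarning:
                    if attempt == 1:
                        raise RuntimeError(f"NN failed to converge on repeat {r}")
        pred = model.predict(Xte)
        accs.append(float(np.mean(pred == yte)))
        y_true_all.append(yte)
        y_pred_all.append(pred)
        scores_all.append(_class_scores(model, Xte))
    return _build_entry(
        "NN",
        subset_name,
        classes,
        np.concatenate(y_true_all),
        np.concatenate(y_pred_all),
        np.vstack(scores_all),
        accuracy=float(np.mean(accs)),
        accuracy_per_repeat=accs,
    )


@dataclass
class EvaluationReport:
    """Grid of evaluation entries over (subset, classifier) cells."""

    entries: dict[tuple[str, str], EvalEntry]
    subsets: dict[str, tuple[str, ...]]

    def entry(self, subset: str, classifier: str) -> EvalEntry:
        return self.entries[(subset, classifier)]

    @property
    def subset_names(self) -> list[str]:
        return list(self.subsets.keys())

    @property
    def classifier_names(self) -> list[str]:
        seen: list[str] = []
        for _, clf in self.entries:
            if clf not in seen:
                seen.append(clf)
        return seen

    def overall_accuracy_table(self) -> pd.DataFrame:
        """Subsets x classifiers overall accuracies, plus per-set mean/sd
        columns and per-classifier mean/sd rows."""
        table = pd.DataFrame(
            {
                clf: [self.entries[(s, clf)].accuracy for s in self.subset_names]
                for clf in self.classifier_names
            },
            index=self.subset_names,
        )
        table["set_mean"] = table.mean(axis=1)
        table["set_sd"] = table.iloc[:, :-1].std(axis=1, ddof=1)
        core = table.iloc[:, : len(self.classifier_names)]
        table.loc["classifier_mean"] = list(core.mean(axis=0)) + [np.nan, np.nan]
        table.loc["classifier_sd"] = list(core.std(axis=0, ddof=1)) + [np.nan, np.nan]
        return table

    def per_type_accuracy_table(self, voice_type: str) -> pd.DataFrame:
        table = pd.DataFrame(
            {
                clf: [
                    self.entries[(s, clf)].per_class_accuracy[voice_type]
                    for s in self.subset_names
                ]
                for clf in self.classifier_names
            },
            index=self.subset_names,
        )
        table["set_mean"] = table.mean(axis=1)
        return table

    def to_dict(self) -> dict:
        return {
            "subsets": {k: list(v) for k, v in self.subsets.items()},
            "entries": {f"{s}|{c}": e.to_dict() for (s, c), e in self.entries.items()},
            "overall_accuracy": self.overall_accuracy_table().to_dict(),
        }


def run_lofo(
    features: pd.DataFrame,
    specs: list[ClassifierSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    subsets: dict[str, tuple[str, ...]] | None = None,
    nn_repeats: int = 6,
) -> EvaluationReport:
    """Evaluate every classifier on every feature subset.

    Defaults to the five standard classifiers and the ten standard subsets
    (full, seven LOFO, spectral, stability).
    """
    specs = specs if specs is not None else default_specs(seed=seed)
    subsets = subsets if subsets is not None else standard_subsets(
        tuple(c for c in FEATURE_NAMES if c in features.columns)
    )
    for name, cols in subsets.items():
        if name.startswith("-") and len(cols) != len(subsets.get("full", cols)) - 1:
            raise ValueError(f"LOFO subset {name} must drop exactly one feature")
    entries: dict[tuple[str, str], EvalEntry] = {}
    for sname, cols in subsets.items():
        for spec in specs:
            if spec.kind == "NN":
                entry = train_eval_nn(
                    features, spec, repeats=nn_repeats, columns=cols, subset_name=sname
                )
            else:
                entry = train_eval_cv(
                    features, spec, folds=folds, columns=cols, subset_name=sname
                )
            entries[(sname, spec.kind)] = entry
    return EvaluationReport(entries=entries, subsets=subsets)


def chi_square_compare(
    report: EvaluationReport,
    axis: str = "classifiers",
    subset: str = "full",
    classifier: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Chi-square test of independence on correct/incorrect counts.

    ``axis="classifiers"`` compares the classifiers on one subset;
    ``axis="subsets"`` compares the subsets within one classifier.
    """
    if axis == "classifiers":
        cells = [report.entries[(subset, c)] for c in report.classifier_names]
    elif axis == "subsets":
        if classifier is None:
            raise ValueError("classifier required for axis='subsets'")
        cells = [report.entries[(s, classifier)] for s in report.subset_names]
    else:
        raise ValueError("axis must be 'classifiers' or 'subsets'")
    table = np.array([[c.n_correct, c.n_incorrect] for c in cells], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # a constant outcome column: no association measurable
        return {
            "statistic": 0.0,
            "p_value": 1.0,
            "dof": len(cells) - 1,
            "alpha": alpha,
            "significant": False,
            "low_expected_count": False,
        }
    stat, p, dof, expected = chi2_contingency(table)
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "dof": int(dof),
        "alpha": alpha,
        "significant": bool(p < alpha),
        "low_expected_count": bool((expected < 1).any()),
    }
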