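"""PCA compression, SVM classifiers, and evaluation frameworks.

Three frameworks are supported:

* ``fused`` — classifier trained across patients on per-patient normalized
  relative signatures (rss);
* ``inter_patient`` — trained across patients on raw signatures (ss);
* ``intra_patient`` — trained and evaluated within a single patient.

Signatures are compressed to the top-k (default 5) principal-component
scores before SVM training.  Pairwise AUC uses the rank (Mann-Whitney)
statistic; 3-way AUC is the unweighted macro mean of one-vs-rest AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "FRAMEWORKS",
    "PcaModel",
    "ClassifierBundle",
    "EvalReport",
    "ClassificationError",
    "InsufficientRankError",
    "fit_pca",
    "train_classifier",
    "auc_rank",
    "roc_points",
    "evaluate_roc_auc",
    "cross_validate",
    "confusion_metrics",
]

FRAMEWORKS = ("fused", "inter_patient", "intra_patient")


class ClassificationError(ValueError):
    """Classifier contract violation."""


class InsufficientRankError(ClassificationError):
    """Data rank below the requested number of components."""

    def __init__(self, rank: int, k: int):
        self.rank = rank
        self.k = k
        super().__init__(f"data rank {rank} < requested k={k} components")


@dataclass
class PcaModel:
    """Centered PCA with deterministic component signs.

    ``components`` holds the top-k orthonormal loading rows;
    ``explained_variance_ratio`` the matching k fractions.  The full ratio
    vector over all components is kept for variance-capture summaries.
    """

    mean_vector: np.ndarray
    components: np.ndarray  # (k, n_features)
    explained_variance_ratio: np.ndarray  # (k,)
    full_variance_ratio: np.ndarray  # all components
    k: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_vector) @ self.components.T


def fit_pca(X: np.ndarray, k: int = 5) -> PcaModel:
    """Fit centered PCA and keep the top-``k`` components.

    Component signs are fixed by making each component's largest-magnitude
    loading positive.  Raises :class:`InsufficientRankError` when the
    centered data matrix has rank below ``k``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ClassificationError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ClassificationError("X must be finite")
    if X.shape[0] < k + 1:
        raise ClassificationError(f"need at least {k + 1} rows to fit {k} components")
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < k:
        raise InsufficientRankError(rank, k)
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    comps = pca.components_[:k].copy()
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PcaModel(
        mean_vector=pca.mean_.copy(),
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_[:k].copy(),
        full_variance_ratio=pca.explained_variance_ratio_.copy(),
        k=k,
    )


@dataclass
class ClassifierBundle:
    pca: PcaModel
    svm: SVC
    classes: tuple[str, ...]
    framework: str
    training_manifest: dict = field(default_factory=dict)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous decision scores (1-D for binary, (n, n_classes) OVR)."""
        return self.svm.decision_function(self.pca.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.pca.transform(X))


def train_classifier(
    X: np.ndarray,
    y: Sequence[str],
    framework: str = "fused",
    patient_ids: Optional[Sequence[str]] = None,
    pca_k: int = 5,
    svm_params: Optional[dict] = None,
) -> ClassifierBundle:
    """Fit PCA on the training rows only, then an SVM on the top-k scores."""
    if framework not in FRAMEWORKS:
        raise ClassificationError(f"unknown framework {framework!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ClassificationError("X and y length mismatch")
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ClassificationError("training data must contain at least two classes")
    pca = fit_pca(X, k=pca_k)
    params = {"kernel": "rbf", "C": 1.0, "gamma": "scale", "class_weight": "balanced"}
    params.update(svm_params or {})
    svm = SVC(decision_function_shape="ovr", **params)
    svm.fit(pca.transform(X), y)
    manifest: dict = {"n_rows": int(X.shape[0]), "classes": list(classes)}
    if patient_ids is not None:
        pids = np.asarray(patient_ids)
        manifest["patients"] = sorted(set(pids))
        manifest["sector_counts"] = {
            p: int((pids == p).sum()) for p in manifest["patients"]
        }
    return ClassifierBundle(
        pca=pca, svm=svm, classes=classes, framework=framework,
        training_manifest=manifest,
    )


def auc_rank(scores: np.ndarray, y: Sequence, positive) -> float:
    """AUC via the rank (Mann-Whitney) statistic; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassificationError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, y: Sequence, positive) -> list[tuple[float, float]]:
    """(fpr, tpr) points swept over all score thresholds, high to low."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y) == positive
    order = np.argsort(-scores, kind="mergesort")
    y = y[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # keep one point per distinct threshold
    keep = np.r_[np.diff(s) != 0, True]
    n_pos, n_neg = max(tp[-1], 1), max(fp[-1], 1)
    pts = [(0.0, 0.0)]
    pts += [(fp[i] / n_neg, tp[i] / n_pos) for i in np.nonzero(keep)[0]]
    return pts


@dataclass
class EvalReport:
    task: str
    framework: str
    auc: Optional[float] = None
    auc_per_class: dict = field(default_factory=dict)
    roc: list = field(default_factory=list)
    accuracy_mean: Optional[float] = None
    accuracy_sd: Optional[float] = None
    sensitivity_mean: Optional[float] = None
    sensitivity_sd: Optional[float] = None
    specificity_mean: Optional[float] = None
    specificity_sd: Optional[float] = None
    fold_aucs: list = field(default_factory=list)
    per_patient_accuracy: dict = field(default_factory=dict)
    pooled_accuracy: Optional[float] = None
    n_folds: int = 0
    skipped_folds: int = 0

    def to_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, np.floating):
                value = float(value)
            out[key] = value
        return out


def evaluate_roc_auc(
    bundle: ClassifierBundle,
    X: np.ndarray,
    y: Sequence[str],
    positive: Optional[str] = None,
    with_roc: bool = True,
) -> EvalReport:
    """AUC (and ROC points) of a trained bundle on held-out rows.

    Binary tasks use the decision function directly; multiclass tasks report
    the unweighted macro mean of one-vs-rest AUCs.
    """
    y = np.asarray(y)
    present = set(y)
    missing = set(bundle.classes) - present
    if missing:
        raise ClassificationError(f"test set missing classes {sorted(missing)}")
    scores = bundle.scores(X)
    if len(bundle.classes) == 2:
        positive = positive or bundle.classes[1]
        s = scores if positive == bundle.classes[1] else -scores
        report = EvalReport(task=f"binary:{positive}", framework=bundle.framework)
        report.auc = auc_rank(s, y, positive)
        if with_roc:
            report.roc = roc_points(s, y, positive)
        return report
    report = EvalReport(task="multiclass-macro-ovr", framework=bundle.framework)
    per_class = {}
    for i, cls in enumerate(bundle.classes):
        per_class[cls] = auc_rank(scores[:, i], y == cls, True)
    report.auc_per_class = per_class
    report.auc = float(np.mean(list(per_class.values())))
    return report


def confusion_metrics(
    y_true: Sequence, y_pred: Sequence, positive
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) for a designated positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ClassificationError("empty input")
    if y_true.shape != y_pred.shape:
        raise ClassificationError("length mismatch")
    tp = int(((y_true == positive) & (y_pred == positive)).sum())
    fn = int(((y_true == positive) & (y_pred != positive)).sum())
    tn = int(((y_true != positive) & (y_pred != positive)).sum())
    fp = int(((y_true != positive) & (y_pred == positive)).sum())
    acc = (tp + tn) / y_true.size
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    patient_ids: Sequence[str],
    mode: str = "kfold",
    k: int = 10,
    framework: str = "fused",
    positive: Optional[str] = None,
    pca_k: int = 5,
    svm_params: Optional[dict] = None,
    seed: int = 0,
    group_kfold: bool = False,
) -> EvalReport:
    """K-fold or leave-one-patient-out evaluation with per-fold refitting.

    PCA and SVM are refit inside every training split (no leakage).  K-fold
    is stratified at sector level by default; ``group_kfold=True`` keeps
    each patient within a single fold.  LOPO holds out all sectors of one
    patient per fold and additionally reports pooled accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pids = np.asarray(patient_ids)
    classes = sorted(set(y))
    if positive is None:
        positive = classes[-1]
    report = EvalReport(task=f"cv:{mode}", framework=framework)

    if mode == "kfold":
        if X.shape[0] < k:
            raise ClassificationError(f"need >= {k} rows for {k}-fold CV")
        if group_kfold:
            rng = np.random.default_rng(seed)
            unique = np.array(sorted(set(pids)))
            rng.shuffle(unique)
            assignment = {p: i % k for i, p in enumerate(unique)}
            folds = [
                (np.nonzero(~np.isin(pids, [p for p, f in assignment.items() if f == i]))[0],
                 np.nonzero(np.isin(pids, [p for p, f in assignment.items() if f == i]))[0])
                for i in range(k)
            ]
        else:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = list(skf.split(X, y))
    elif mode == "lopo":
        unique = sorted(set(pids))
        if len(unique) < 3:
            raise ClassificationError("LOPO needs at least 3 patients")
        folds = [
            (np.nonzero(pids != p)[0], np.nonzero(pids == p)[0]) for p in unique
        ]
    else:
        raise ClassificationError(f"unknown CV mode {mode!r}")

    accs, sens, specs = [], [], []
    pooled_true, pooled_pred = [], []
    for fold_i, (tr, te) in enumerate(folds):
        if len(te) == 0 or len(set(y[tr])) < 2:
            warnings.warn(f"fold {fold_i}: degenerate split skipped")
            report.skipped_folds += 1
            continue
        bundle = train_classifier(
            X[tr], y[tr], framework=framework, patient_ids=pids[tr],
            pca_k=pca_k, svm_params=svm_params,
        )
        pred = bundle.predict(X[te])
        acc, se, sp = confusion_metrics(y[te], pred, positive)
        accs.append(acc)
        if np.isfinite(se):
            sens.append(se)
        if np.isfinite(sp):
            specs.append(sp)
        pooled_true.extend(y[te])
        pooled_pred.extend(pred)
        if len(set(y[te])) == len(bundle.classes):
            frag = evaluate_roc_auc(bundle, X[te], y[te], positive, with_roc=False)
            report.fold_aucs.append(frag.auc)
        else:
            report.skipped_folds += 0  # AUC undefined for this fold; metrics kept
        if mode == "lopo":
            report.per_patient_accuracy[str(pids[te][0])] = acc
        report.n_folds += 1

    if report.n_folds < 2:
        raise ClassificationError("fewer than 2 usable folds")
    report.accuracy_mean = float(np.mean(accs))
    report.accuracy_sd = float(np.std(accs, ddof=1))
    if sens:
        report.sensitivity_mean = float(np.mean(sens))
        report.sensitivity_sd = float(np.std(sens, ddof=1)) if len(sens) > 1 else 0.0
    if specs:
        report.specificity_mean = float(np.mean(specs))
        report.specificity_sd = float(np.std(specs, ddof=1)) if len(specs) > 1 else 0.0
    if report.fold_aucs:
        report.auc = float(np.mean(report.fold_aucs))
    report.pooled_accuracy = float(
        np.mean(np.asarray(pooled_true) == np.asarray(pooled_pred))
    )
    return report
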