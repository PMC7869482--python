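"""Cross-validated classification and micro-averaged multiclass metrics.

Evaluation mirrors the study design: stratified 5-fold cross validation of an
L2-regularized logistic regression on the (possibly gene-filtered) expression
matrix, reporting accuracy, micro-F1, micro one-vs-rest FPR, micro-averaged
ROC-AUC and the multiclass Matthews correlation coefficient as fold means with
standard deviations.

Leakage handling: data-driven selectors (MI, mRMR, ReliefF, or a custom
callable) are refit inside each training fold; fixed gene lists (Hallmark
unions, precomputed mutation-derived effective-gene sets) are applied
identically to every fold. A ``leak_free=False`` escape hatch fits data-driven
selectors once on the whole matrix, reproducing whole-dataset selection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
from scipy.stats import rankdata

from . import baseline_selectors as bs
from .effective_genes import SelectedGeneSet
from .expression_io import ExpressionMatrix, filter_matrix

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "micro_f", "roc_auc", "micro_fpr", "mcc")


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    fold_of_sample: dict[str, int]
    k: int
    seed: int

    def test_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of_sample.items() if f == fold]


def stratified_folds(labels: dict[str, str], k: int, seed: int) -> FoldAssignment:
    """Deterministic stratified k-fold partition; per-class fold counts differ
    by at most one."""
    from sklearn.model_selection import StratifiedKFold

    samples = sorted(labels)
    y = np.array([labels[s] for s in samples])
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(
            f"classes smaller than k={k}: {', '.join(map(str, small))}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(samples)), y)):
        for i in test_idx:
            assignment[samples[i]] = fold
    return FoldAssignment(fold_of_sample=assignment, k=k, seed=seed)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LRSettings:
    """Logistic-regression configuration: L2 penalty with inverse strength C,
    multinomial objective, deterministic given the seed."""

    C: float = 1.0
    max_iter: int = 5000
    seed: int = 0
    log_transform: bool = False  # optional log2(1+x) before fitting


def fit_predict_lr(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    settings: LRSettings = LRSettings(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit LR on the training split and score the test split.

    Returns (predicted labels, per-class probability matrix, class order).
    """
    from sklearn.linear_model import LogisticRegression

    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if not (np.isfinite(X_train).all() and np.isfinite(X_test).all()):
        raise ValueError("non-finite values in X")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain >= 2 classes")
    if settings.log_transform:
        X_train = np.log2(1.0 + X_train)
        X_test = np.log2(1.0 + X_test)
    model = LogisticRegression(  # default penalty is L2
        C=settings.C,
        max_iter=settings.max_iter,
        random_state=settings.seed,
    )
    model.fit(X_train, y_train)
    proba = model.predict_proba(X_test)
    pred = model.classes_[np.argmax(proba, axis=1)]
    return pred, proba, model.classes_


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("confusion matrix must be square over `labels`")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, labels: list[str]) -> ConfusionMatrix:
    from sklearn.metrics import confusion_matrix

    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    observed = set(y_true) | set(y_pred)
    missing = observed - set(labels)
    if missing:
        raise ValueError(f"labels do not cover observed classes: {missing}")
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return ConfusionMatrix(labels=list(labels), counts=cm)


def _ovr_counts(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    counts = cm.counts.astype(float)
    total = counts.sum()
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn
    return tp, fp, fn, tn


def micro_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, micro-averaged F1 and micro one-vs-rest FPR.

    For single-label multiclass data micro-F1 equals accuracy (aggregate
    FP == FN), which the evaluation reports exploit.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = _ovr_counts(cm)
    accuracy = tp.sum() / cm.total
    precision = tp.sum() / max(tp.sum() + fp.sum(), 1e-300)
    recall = tp.sum() / max(tp.sum() + fn.sum(), 1e-300)
    micro_f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    micro_fpr = fp.sum() / max(fp.sum() + tn.sum(), 1e-300)
    return {
        "accuracy": float(accuracy),
        "micro_f": float(micro_f),
        "micro_fpr": float(micro_fpr),
    }


def mcc_multiclass(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient from the confusion matrix:

        (c·s − Σ_k p_k t_k) / sqrt((s² − Σ p_k²)(s² − Σ t_k²))

    with c the correct count, s the total, and t_k / p_k the true / predicted
    counts of class k. Reduces to the binary MCC for 2x2; a degenerate
    denominator (a single observed or predicted class) yields 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    s = counts.sum()
    c = np.trace(counts)
    t = counts.sum(axis=1)
    p = counts.sum(axis=0)
    num = c * s - (p * t).sum()
    den = np.sqrt((s**2 - (p**2).sum()) * (s**2 - (t**2).sum()))
    if den == 0:
        warnings.warn("degenerate MCC denominator (single class); returning 0")
        return 0.0
    return float(num / den)


def micro_roc_auc(
    y_true, class_scores: np.ndarray, labels: list[str]
) -> float:
    """Micro-averaged ROC-AUC: all (sample, class) one-vs-rest pairs are
    flattened into one binary ranking problem and scored by the rank-sum
    (Mann-Whitney) formulation with midrank tie handling."""
    y_true = np.asarray(y_true)
    scores = np.asarray(class_scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    if scores.shape != (len(y_true), len(labels)):
        raise ValueError("class_scores must be (n_samples, n_classes)")
    label_index = {lab: j for j, lab in enumerate(labels)}
    onehot = np.zeros_like(scores, dtype=bool)
    for i, lab in enumerate(y_true):
        onehot[i, label_index[lab]] = True
    flat_y = onehot.ravel()
    flat_s = scores.ravel()
    n_pos, n_neg = int(flat_y.sum()), int((~flat_y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("flattened one-vs-rest labels contain a single class")
    ranks = rankdata(flat_s)  # midranks for ties
    return float(
        (ranks[flat_y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class SelectorSpec:
    """What to select before classifying.

    method: 'all' (no selection), 'mi_topk' / 'mrmr' / 'relieff'
    (data-driven, refit per training fold), 'fixed' (a constant gene set),
    or 'custom' (params['fn'](X_frame, y) -> gene list; for testing).
    """

    method: str = "all"
    k: int | None = None
    genes: SelectedGeneSet | set[str] | None = None
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def is_data_driven(self) -> bool:
        return self.method in {"mi_topk", "mrmr", "relieff", "custom"}

    def describe(self) -> str:
        if self.method == "all":
            return "all"
        if self.method == "fixed":
            n = len(self.genes.gene_ids if isinstance(self.genes, SelectedGeneSet)
                    else self.genes)
            name = self.params.get("name", "fixed")
            return f"{name}:{n}"
        return f"{self.method}:{self.k}"


def _run_selector(spec: SelectorSpec, X: ExpressionMatrix, y: np.ndarray) -> list[str]:
    if spec.method == "mi_topk":
        ranking = bs.mutual_info_rank(X.values, y, X.gene_ids, **spec.params)
    elif spec.method == "mrmr":
        return bs.mrmr_select(X.values, y, X.gene_ids, k=spec.k, **spec.params).top_genes(spec.k)
    elif spec.method == "relieff":
        ranking = bs.relieff_weights(X.values, y, X.gene_ids, **spec.params)
    elif spec.method == "custom":
        return list(spec.params["fn"](X, y))
    else:
        raise ValueError(f"unknown data-driven selector: {spec.method}")
    return ranking.top_genes(spec.k)


@dataclass
class EvaluationReport:
    per_fold: dict[str, list[float]]
    config: dict[str, Any]

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_fold[metric]))

    def std(self, metric: str) -> float:
        return float(np.std(self.per_fold[metric]))

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {"mean": self.mean(m), "std": self.std(m)} for m in self.per_fold
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": self.config,
            "per_fold": self.per_fold,
            "summary": self.summary(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def table_row(self) -> str:
        """Selector, feature count, then each metric as 'mean ±std' in percent."""
        cells = [
            str(self.config.get("selector", "?")),
            str(self.config.get("n_features", "?")),
        ]
        for m in METRICS:
            cells.append(f"{100 * self.mean(m):.2f} ±{100 * self.std(m):.2f}")
        return "\t".join(cells)


TABLE_HEADER = "selector\tfeature_count\taccuracy\tf_score\troc_auc\tfpr\tmcc"


def cross_validate(
    X: ExpressionMatrix,
    labels: dict[str, str],
    selector: SelectorSpec | None = None,
    k: int = 5,
    seed: int = 0,
    lr_settings: LRSettings | None = None,
    leak_free: bool = True,
) -> EvaluationReport:
    """Stratified k-fold CV of gene selection + logistic regression.

    Data-driven selectors see only the training portion of each fold unless
    ``leak_free=False``; fixed gene lists are applied to every fold unchanged.
    """
    selector = selector or SelectorSpec()
    lr_settings = lr_settings or LRSettings(seed=seed)
    missing = [s for s in X.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"unlabeled samples: {', '.join(missing)}")

    folds = stratified_folds({s: labels[s] for s in X.sample_ids}, k=k, seed=seed)
    sample_pos = {s: i for i, s in enumerate(X.sample_ids)}
    y_all = np.array([labels[s] for s in X.sample_ids])
    class_order = sorted(set(y_all))

    X_work = X
    if selector.method == "fixed":
        X_work = filter_matrix(X, selector.genes)
    whole_data_genes: list[str] | None = None
    if selector.is_data_driven and not leak_free:
        whole_data_genes = _run_selector(selector, X, y_all)

    per_fold: dict[str, list[float]] = {m: [] for m in METRICS}
    n_features_used: list[int] = []
    for fold in range(k):
        test_samples = folds.test_samples(fold)
        test_idx = np.array([sample_pos[s] for s in test_samples])
        train_mask = np.ones(len(X.sample_ids), dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)

        X_fold = X_work
        if selector.is_data_driven:
            if whole_data_genes is not None:
                genes = whole_data_genes
            else:
                X_train_view = ExpressionMatrix(
                    sample_ids=[X.sample_ids[i] for i in train_idx],
                    gene_ids=list(X.gene_ids),
                    values=X.values[train_idx],
                )
                genes = _run_selector(selector, X_train_view, y_all[train_idx])
            X_fold = filter_matrix(X, set(genes))
        n_features_used.append(len(X_fold.gene_ids))

        pred, proba, classes = fit_predict_lr(
            X_fold.values[train_idx], y_all[train_idx],
            X_fold.values[test_idx], lr_settings,
        )
        y_test = y_all[test_idx]
        cm = confusion(y_test, pred, labels=class_order)
        m = micro_metrics(cm)
        # align probability columns with class_order (absent classes score 0)
        aligned = np.zeros((len(test_idx), len(class_order)))
        for j, lab in enumerate(classes):
            aligned[:, class_order.index(lab)] = proba[:, j]
        per_fold["accuracy"].append(m["accuracy"])
        per_fold["micro_f"].append(m["micro_f"])
        per_fold["micro_fpr"].append(m["micro_fpr"])
        per_fold["roc_auc"].append(micro_roc_auc(y_test, aligned, class_order))
        per_fold["mcc"].append(mcc_multiclass(cm))

    config = {
        "selector": selector.describe(),
        "n_features": int(np.round(np.mean(n_features_used))),
        "n_features_per_fold": n_features_used,
        "k_folds": k,
        "seed": seed,
        "leak_free": leak_free,
        "lr": {
            "C": lr_settings.C,
            "max_iter": lr_settings.max_iter,
            "seed": lr_settings.seed,
            "log_transform": lr_settings.log_transform,
        },
    }
    return EvaluationReport(per_fold=per_fold, config=config)
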