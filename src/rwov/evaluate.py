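"""Classifier training and evaluation for class-imbalanced text features.

Implements the full comparison harness: per-class F1 and Mann-Whitney AUC,
stratified percentile-bootstrap confidence intervals, stratified 3-fold
cross-validation with shared splits across methods, and the DeLong test for
the difference between two correlated AUCs. Separate binary models are
trained per class (positive-vs-rest for each receptor state), reflecting that
users may care about either class under imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "f1_score",
    "auc",
    "delong_compare",
    "bootstrap_ci",
    "ClassifierConfig",
    "ClassMetrics",
    "EvalReport",
    "cross_validate",
    "compare_methods",
]


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall from confusion counts.

    Returns 0 when tp = 0 (including the fully degenerate tp=fp=fn=0 case).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError(
            "both classes must be present (labels must contain 0s and 1s)"
        )
    return y


def auc(scores, labels) -> float:
    """Probability a random positive is scored above a random negative.

    Mann-Whitney estimate; ties count 1/2. Raises on single-class input.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _placements(scores, y):
    """Per-observation placement values (V10 for positives, V01 for negatives)."""
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    # fraction of negatives below each positive, ties at 1/2
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(neg)
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / len(pos)
    return v10, v01


def delong_compare(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong p-value for the difference of two correlated AUCs.

    Both score vectors must refer to the same observations (paired design).
    The covariance of the paired AUC difference is estimated from placement
    values; the z-statistic is referred to the standard normal. Degenerate
    variance yields p = 1 with a warning.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores_a, scores_b and labels must align")
    v10 = np.vstack([_placements(a, y)[0], _placements(b, y)[0]])
    v01 = np.vstack([_placements(a, y)[1], _placements(b, y)[1]])
    aucs = v10.mean(axis=1)
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    contrast = np.array([1.0, -1.0])
    var = contrast @ s10 @ contrast / m + contrast @ s01 @ contrast / n
    diff = aucs[0] - aucs[1]
    if var <= 0 or not np.isfinite(var) or var < 1e-24:
        if diff != 0:
            warnings.warn(
                "degenerate DeLong variance with nonzero AUC difference",
                stacklevel=2,
            )
        else:
            warnings.warn("degenerate DeLong variance; returning p = 1", stacklevel=2)
        return 1.0
    z = diff / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def _f1_from_scores(scores, y, threshold: float) -> float:
    pred = np.asarray(scores) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return f1_score(tp, fp, fn)


def bootstrap_ci(
    metric: str,
    scores,
    labels,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    threshold: float = 0.5,
):
    """Stratified percentile bootstrap interval for F1 or AUC.

    Positives and negatives are resampled separately (so every resample keeps
    both classes); the interval is the (alpha/2, 1-alpha/2) percentile pair of
    the B resampled statistics. Seeded and deterministic.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    metric = metric.lower()
    if metric not in {"f1", "auc"}:
        raise ValueError("metric must be 'f1' or 'auc'")
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    stats = np.empty(B)
    for b in range(B):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        if metric == "auc":
            stats[b] = auc(s[idx], y[idx])
        else:
            stats[b] = _f1_from_scores(s[idx], y[idx], threshold)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ClassifierConfig:
    """The two benchmark classifiers.

    ``nn``: multilayer perceptron with three ReLU hidden layers of 50, 50 and
    100 units and a logistic (sigmoid) output, L2 penalty ``l2_lambda``.
    ``svm``: RBF-kernel SVM with inverse-class-frequency weighting; its AUC
    scores come from the decision function (F1 threshold 0 there, 0.5 on the
    NN probability scale).
    """

    kind: str = "nn"
    nn_hidden: tuple = (50, 50, 100)
    l2_lambda: float = 1e-2
    nn_solver: str = "lbfgs"  # full-batch quasi-Newton suits small dense designs
    svm_class_weighting: bool = True
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"nn", "svm"}:
            raise ValueError("kind must be 'nn' or 'svm'")

    @property
    def threshold(self) -> float:
        return 0.5 if self.kind == "nn" else 0.0

    def build(self):
        if self.kind == "nn":
            return MLPClassifier(
                hidden_layer_sizes=tuple(self.nn_hidden),
                activation="relu",
                solver=self.nn_solver,
                alpha=self.l2_lambda,
                max_iter=self.max_iter,
                random_state=self.seed,
            )
        return SVC(
            kernel="rbf",
            class_weight="balanced" if self.svm_class_weighting else None,
            random_state=self.seed,
        )


def _score(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class ClassMetrics:
    f1: float
    auc: float
    f1_ci: tuple
    auc_ci: tuple


@dataclass
class EvalReport:
    """Cross-validated per-class metrics with CIs and shared fold assignments."""

    per_class: dict
    folds: np.ndarray
    scores: dict = field(default_factory=dict)  # class label -> out-of-fold scores
    comparisons: dict = field(default_factory=dict)  # (name_a, name_b) -> p


def make_folds(labels, n_folds: int = 3, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (sizes differ by <=1 within each class)."""
    y = np.asarray(labels)
    folds = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = f
    return folds


def cross_validate(
    features,
    labels,
    config: ClassifierConfig = ClassifierConfig(),
    n_folds: int = 3,
    seed: int = 0,
    folds=None,
    ci_bootstrap: int = 2000,
) -> EvalReport:
    """Stratified k-fold evaluation, one binary model per class.

    Fold assignments are fixed by ``seed`` (or passed in via ``folds``) so
    that several feature sets can be scored on identical train/test splits.
    Reported F1/AUC are the averages of per-fold values; the bootstrap CIs are
    computed on the pooled out-of-fold scores.
    """
    X = np.asarray(features, dtype=float)
    y_raw = np.asarray(labels)
    if len(X) != len(y_raw):
        raise ValueError("features and labels must align")
    classes = sorted(np.unique(y_raw).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    folds = make_folds(y_raw, n_folds, seed) if folds is None else np.asarray(folds)
    for f in range(int(folds.max()) + 1):
        present = set(np.unique(y_raw[folds != f]))
        if present != set(classes):
            raise ValueError("a class is absent from a training fold")

    per_class: dict = {}
    oof: dict = {}
    for c in classes:
        y = (y_raw == c).astype(int)
        scores = np.empty(len(y))
        fold_f1, fold_auc = [], []
        for f in sorted(set(folds.tolist())):
            train, test = folds != f, folds == f
            model = config.build()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence chatter
                model.fit(X[train], y[train])
            s = _score(model, X[test])
            scores[test] = s
            fold_f1.append(_f1_from_scores(s, y[test], config.threshold))
            fold_auc.append(auc(s, y[test]))
        per_class[c] = ClassMetrics(
            f1=float(np.mean(fold_f1)),
            auc=float(np.mean(fold_auc)),
            f1_ci=bootstrap_ci(
                "f1", scores, y, B=ci_bootstrap, seed=seed, threshold=config.threshold
            ),
            auc_ci=bootstrap_ci("auc", scores, y, B=ci_bootstrap, seed=seed),
        )
        oof[c] = scores
    return EvalReport(per_class=per_class, folds=folds, scores=oof)


def compare_methods(
    feature_sets: dict,
    labels,
    config: ClassifierConfig = ClassifierConfig(),
    n_folds: int = 3,
    seed: int = 0,
    ci_bootstrap: int = 2000,
):
    """Evaluate several feature matrices on identical splits; DeLong-compare AUCs.

    Returns ``(reports, comparisons)`` where ``reports`` maps method name to
    its :class:`EvalReport` and ``comparisons`` maps
    ``(name_a, name_b, class)`` to the two-sided DeLong p-value for the AUC
    difference of the pooled out-of-fold scores.
    """
    y_raw = np.asarray(labels)
    folds = make_folds(y_raw, n_folds, seed)
    reports = {
        name: cross_validate(
            X, y_raw, config, n_folds, seed, folds=folds, ci_bootstrap=ci_bootstrap
        )
        for name, X in feature_sets.items()
    }
    comparisons: dict = {}
    names = list(feature_sets)
    classes = sorted(np.unique(y_raw).tolist())
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for c in classes:
                y = (y_raw == c).astype(int)
                comparisons[(a, b, c)] = delong_compare(
                    reports[a].scores[c], reports[b].scores[c], y
                )
    for rep in reports.values():
        rep.comparisons = comparisons
    return reports, comparisons
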