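"""PCA exploration and the PLS-DA classification workflow.

The discrimination of the three dissection tissue types from wide spectral
matrices (many more m/z bins than samples) uses partial least squares
discriminant analysis: class labels are one-hot encoded and a PLS2 latent
decomposition of the centred/scaled spectra against the centred indicator
matrix is fitted; the predicted class is the argmax of the continuous class
scores.  Model evaluation follows a repeated-split protocol — stratified
80/20 train/test splits, component count chosen by 2-fold cross-validation
on the training part only, 50 repeats with averaged accuracy / precision /
recall / F1 — and feature refinement keeps m/z bins whose variable
importance in projection (VIP) has both mean and median above 1 across the
repeats.  ROC/AUC of a refined model is computed from its continuous test
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SKPCA
from sklearn.model_selection import StratifiedKFold, train_test_split


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    feature_names: list[str] | None = None


@dataclass
class PLSDAModel:
    """A fitted PLS-DA model (PLS2 regression onto one-hot class indicators)."""

    n_components: int
    class_order: list
    x_weights: np.ndarray
    x_loadings: np.ndarray
    x_scores: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    _pls: PLSRegression = field(repr=False, default=None)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous per-class scores (columns follow class_order)."""
        return self._pls.predict(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.asarray(self.class_order)[np.argmax(scores, axis=1)]


@dataclass
class EvaluationSummary:
    per_repeat: pd.DataFrame  # accuracy, precision, recall, f1, n_components
    n_repeats: int
    split_fraction: float
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_repeat["accuracy"].mean())

    def means(self) -> dict:
        return self.per_repeat[["accuracy", "precision", "recall", "f1"]].mean().to_dict()


@dataclass
class VIPProfile:
    per_repeat: np.ndarray  # repeats x features
    feature_names: list[str] | None = None

    @property
    def mean(self) -> np.ndarray:
        return self.per_repeat.mean(axis=0)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.per_repeat, axis=0)

    @property
    def selected(self) -> np.ndarray:
        return (self.mean > 1.0) & (self.median > 1.0)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_class: object = None


def _as_matrix(table) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    return np.asarray(table, dtype=float), None


def _standardize(X: np.ndarray, center: bool, scale: bool) -> np.ndarray:
    Xs = X.copy()
    if center:
        Xs -= Xs.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # zero-variance columns: unit scale, zero weight
        Xs /= sd
    return Xs


def pca(table, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA of the mean-centred (and unit-scaled) data matrix.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making results deterministic across platforms.
    """
    X, names = _as_matrix(table)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    Xs = _standardize(X, center, scale)
    model = _SKPCA(svd_solver="full").fit(Xs)
    loadings = model.components_.T  # variables x components
    scores = model.transform(Xs)
    for a in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return PCAResult(scores, loadings, model.explained_variance_ratio_, names)


def fit_plsda(X, labels, n_components: int) -> PLSDAModel:
    """Fit a PLS-DA model of centred/scaled X against one-hot class labels."""
    X, _ = _as_matrix(X)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    cap = min(X.shape[0] - 1, X.shape[1])
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} exceeds the data rank bound; capped at {cap}",
            stacklevel=2,
        )
        n_components = cap
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    Y = np.array([[1.0 if lab == c else 0.0 for c in classes] for lab in labels])
    pls = PLSRegression(n_components=n_components, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns about y residual rank
        pls.fit(X, Y)
    return PLSDAModel(
        n_components=n_components,
        class_order=classes,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        x_scores=pls.x_scores_,
        y_loadings=pls.y_loadings_,
        coefficients=pls.coef_.T,
        _pls=pls,
    )


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection for every feature.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), with
    SSY_a the Y-variance explained by latent component a.  The mean of
    VIP^2 over features is exactly 1 for any fitted model.
    """
    W = model.x_weights
    T = model.x_scores
    Q = model.y_loadings
    p = W.shape[0]
    ssy = (Q**2).sum(axis=0) * (T**2).sum(axis=0)
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())


def select_n_components(
    X,
    labels,
    max_components: int = 10,
    n_folds: int = 2,
    seed: int = 0,
) -> int:
    """Choose the PLS component count by stratified k-fold cross-validation.

    Returns the smallest count attaining the minimum misclassification
    error over k = 1..max_components (ties favour the simpler model).
    Samples of classes with fewer members than folds stay in every training
    fold (flagged with a warning).
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    X, _ = _as_matrix(X)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < n_folds]
    always_train = np.isin(labels, small)
    if small.size:
        warnings.warn(
            f"classes {small.tolist()} have fewer than {n_folds} members; "
            "kept in every training fold",
            stacklevel=2,
        )
    idx_cv = np.flatnonzero(~always_train)
    idx_fixed = np.flatnonzero(always_train)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cap = min(max_components, X.shape[0] - X.shape[0] // n_folds - 1, X.shape[1])
    cap = max(cap, 1)
    errors = np.zeros(cap)
    for tr, te in skf.split(idx_cv, labels[idx_cv]):
        train_idx = np.concatenate([idx_cv[tr], idx_fixed]).astype(int)
        test_idx = idx_cv[te]
        if len(set(labels[train_idx])) < 2:
            continue
        for k in range(1, cap + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_plsda(X[train_idx], labels[train_idx], k)
            pred = model.predict(X[test_idx])
            errors[k - 1] += np.sum(pred != labels[test_idx])
    return int(np.argmin(errors)) + 1  # argmin takes the first (smallest k) minimum


def confusion_matrix(truth, pred, class_order) -> np.ndarray:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    k = len(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    out = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        out[index[t], index[p]] += 1
    return out


def classification_metrics(confusion: np.ndarray) -> dict:
    """Accuracy and macro-averaged precision/recall/F1 from a confusion matrix.

    Rows are truth, columns prediction.  A class never predicted (or never
    present) contributes 0 to the corresponding macro average.
    """
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(confusion)
    pred_tot = confusion.sum(axis=0)
    true_tot = confusion.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return {
        "accuracy": float(tp.sum() / total),
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }


def repeated_evaluation(
    X,
    labels,
    n_repeats: int = 50,
    train_fraction: float = 0.8,
    seed: int = 0,
    max_components: int = 10,
    feature_mask: np.ndarray | None = None,
) -> tuple[EvaluationSummary, VIPProfile]:
    """Repeated stratified 80/20 evaluation of the PLS-DA workflow.

    Each repeat draws a fresh stratified split (per-repeat seeds are fixed
    offsets from the master seed), chooses the component count by 2-fold CV
    on the training part only, fits, and records test metrics and the
    model's VIP profile.  ``feature_mask`` restricts the evaluation to a
    subset of columns (used for the VIP-refined second model).
    """
    X, names = _as_matrix(X)
    labels = np.asarray(labels)
    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        X = X[:, feature_mask]
        if names is not None:
            names = [n for n, keep in zip(names, feature_mask) if keep]
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < 2]
    if too_small.size:
        raise ValueError(
            f"stratified splitting impossible: class(es) {too_small.tolist()} "
            "have fewer than 2 samples"
        )
    rows, vips = [], []
    for rep in range(n_repeats):
        rep_seed = seed + rep  # fixed-offset derived seeds
        tr, te = train_test_split(
            np.arange(len(labels)),
            train_size=train_fraction,
            stratify=labels,
            random_state=rep_seed,
        )
        k = select_n_components(X[tr], labels[tr], max_components, n_folds=2, seed=rep_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsda(X[tr], labels[tr], k)
        pred = model.predict(X[te])
        metrics = classification_metrics(confusion_matrix(labels[te], pred, model.class_order))
        metrics["n_components"] = k
        metrics["repeat"] = rep
        rows.append(metrics)
        vips.append(vip_scores(model))
    summary = EvaluationSummary(
        per_repeat=pd.DataFrame(rows),
        n_repeats=n_repeats,
        split_fraction=train_fraction,
        seed=seed,
    )
    return summary, VIPProfile(np.vstack(vips), names)


def refine_by_vip(vip_profile: VIPProfile) -> np.ndarray:
    """Features whose VIP mean AND median exceed 1 across repeats (strict).

    Raises if nothing qualifies — with VIPs hugging 1 everywhere there is no
    informative subset and the threshold (or the model) needs review.
    """
    selected = vip_profile.selected
    if not selected.any():
        raise ValueError(
            "no feature has VIP mean and median above 1; "
            "review the VIP threshold or the model"
        )
    return selected


def roc_auc(scores, truth) -> ROCCurve:
    """ROC curve and trapezoid AUC from continuous scores and binary truth.

    The threshold sweep runs over the unique score values; the AUC equals
    the Mann-Whitney rank statistic P(score_pos > score_neg) + 0.5 *
    P(ties).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = truth[order]
    tps = np.cumsum(t_sorted)
    fps = np.cumsum(~t_sorted)
    # collapse runs of equal scores: keep the last index of each run
    last_of_run = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[last_of_run] / n_pos]
    fpr = np.r_[0.0, fps[last_of_run] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, auc)
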