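"""Group classification and clinical-scale prediction from dynamics metrics.

Two predictive analyses:

* **Linear-SVM classification** of group membership under stratified k-fold
  cross-validation. Features are the per-region metric values; within every
  training fold, features showing a significant covariate-adjusted group
  difference (uncorrected p < alpha) are selected, standardized on training
  statistics, and a linear-kernel SVM (box constraint C in (0, 1]) is fit.
  Held-out decision values are pooled for accuracy / sensitivity /
  specificity, the ROC curve and its AUC. Selection strictly inside each
  fold avoids label leakage; a leaky pre-CV selection mode exists behind an
  explicit flag for comparison only.

* **Improved connectome-based predictive modeling (CPM)** of a clinical
  scale under leave-one-subject-out cross-validation. On each fold's n−1
  training subjects every node-metric feature is Spearman-correlated with
  the scale; features significantly positively and negatively correlated
  (two-tailed p < alpha) form two sets, each z-scored by training mean/SD
  and summed per subject, and a multiple linear regression of the scale on
  {positive sum, negative sum} predicts the held-out subject. Predictive
  power is the Spearman correlation between held-out predictions and true
  scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .stats import METRICS, Cohort, batch_adjusted_t

logger = logging.getLogger("conndyn")


# ---------------------------------------------------------------------------
# feature assembly

def cohort_feature_matrix(cohort: Cohort, mask: np.ndarray | None = None) -> tuple[np.ndarray, list[str]]:
    """Stack the three regional metric matrices into subjects × features.

    Columns are named ``metric:region_id``. Columns containing non-finite
    values (degenerate-synchronizability sentinels) are dropped with a
    logged count so downstream models never see sentinels.
    """
    blocks, names = [], []
    for m in METRICS:
        M = cohort.metrics[m]
        blocks.append(M if mask is None else M[mask])
        names.extend(f"{m}:{r}" for r in cohort.region_ids)
    X = np.hstack(blocks)
    ok = np.isfinite(X).all(axis=0)
    if not ok.all():
        logger.info("dropping %d feature columns with non-finite values", int((~ok).sum()))
    return X[:, ok], [n for n, k in zip(names, ok) if k]


# ---------------------------------------------------------------------------
# feature selection

def select_features(
    X: np.ndarray,
    group01: np.ndarray,
    age: np.ndarray,
    sex01: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Mask of features with adjusted group-difference p < alpha (uncorrected).

    Falls back to all features with a warning when nothing is selected, so
    the classifier always has input.
    """
    _, p = batch_adjusted_t(X, group01, age, sex01)
    mask = p < alpha
    if not mask.any():
        logger.warning("feature selection empty at alpha=%g; falling back to all features", alpha)
        return np.ones(X.shape[1], dtype=bool)
    return mask


# ---------------------------------------------------------------------------
# classification

@dataclass
class ClassificationResult:
    contrast: str
    k: int
    pooled_accuracy: float
    mean_fold_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    fold_accuracies: list[float]
    roc_points: pd.DataFrame = field(repr=False)  # fpr, tpr
    confusion: dict[str, int] = field(default_factory=dict)
    decision_values: np.ndarray = field(default=None, repr=False)
    y_true01: np.ndarray = field(default=None, repr=False)


def svm_classify(
    X: np.ndarray,
    y01: np.ndarray,
    k: int = 10,
    C: float = 1.0,
    alpha: float = 0.05,
    age: np.ndarray | None = None,
    sex01: np.ndarray | None = None,
    seed: int = 0,
    select: bool = True,
    leaky_preselect: bool = False,
    contrast: str = "",
) -> ClassificationResult:
    """Stratified k-fold linear-SVM classification with in-fold selection.

    ``y01`` codes the positive class (the patient group of a contrast) as 1.
    ``leaky_preselect`` reproduces selection on the full data before CV —
    for demonstration of the leakage bias only, never for reported results.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=int)
    n = len(y01)
    if not 0.0 < C <= 1.0:
        raise ValueError("box constraint C must lie in (0, 1]")
    counts = np.bincount(y01, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs at least k={k} subjects, have {counts.tolist()}")
    age = np.zeros(n) if age is None else np.asarray(age, dtype=float)
    sex01 = np.zeros(n) if sex01 is None else np.asarray(sex01, dtype=float)

    global_mask = None
    if select and leaky_preselect:
        logger.warning("leaky pre-CV feature selection enabled; results are optimistically biased")
        global_mask = select_features(X, y01, age, sex01, alpha)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    decision = np.empty(n)
    y_pred = np.empty(n, dtype=int)
    fold_acc = []
    for train, test in skf.split(X, y01):
        if len(np.unique(y01[train])) < 2:
            raise ValueError("single-class training fold")
        if select:
            mask = global_mask if global_mask is not None else select_features(
                X[train], y01[train], age[train], sex01[train], alpha
            )
        else:
            mask = np.ones(X.shape[1], dtype=bool)
        mu = X[train][:, mask].mean(axis=0)
        sd = X[train][:, mask].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[train][:, mask] - mu) / sd
        Xte = (X[test][:, mask] - mu) / sd
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr, y01[train])
        decision[test] = clf.decision_function(Xte)
        y_pred[test] = clf.predict(Xte)
        fold_acc.append(float(np.mean(y_pred[test] == y01[test])))

    tp = int(np.sum((y_pred == 1) & (y01 == 1)))
    tn = int(np.sum((y_pred == 0) & (y01 == 0)))
    fp = int(np.sum((y_pred == 1) & (y01 == 0)))
    fn = int(np.sum((y_pred == 0) & (y01 == 1)))
    fpr, tpr, _ = roc_curve(y01, decision)
    auc = float(np.trapezoid(tpr, fpr))
    return ClassificationResult(
        contrast=contrast,
        k=k,
        pooled_accuracy=(tp + tn) / n,
        mean_fold_accuracy=float(np.mean(fold_acc)),
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        auc=auc,
        fold_accuracies=fold_acc,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        decision_values=decision,
        y_true01=y01,
    )


def classify_cohort(
    cohort: Cohort,
    contrast: str,
    k: int = 10,
    C: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
    leaky_preselect: bool = False,
) -> ClassificationResult:
    """Classify the two groups of a contrast from all regional metrics."""
    a, b = contrast.split("-")
    mask = cohort.group_mask(a) | cohort.group_mask(b)
    sub = cohort.subjects.loc[mask]
    X, _ = cohort_feature_matrix(cohort, mask)
    y01 = (sub["group"] == a).to_numpy(dtype=int)
    return svm_classify(
        X,
        y01,
        k=k,
        C=C,
        alpha=alpha,
        age=sub["age"].to_numpy(dtype=float),
        sex01=(sub["sex"] == "M").to_numpy(dtype=float),
        seed=seed,
        leaky_preselect=leaky_preselect,
        contrast=contrast,
    )


# ---------------------------------------------------------------------------
# improved CPM

@dataclass
class PredictionResult:
    scale: str
    y_true: np.ndarray
    y_pred: np.ndarray
    rho: float
    p: float
    positive_masks: list[np.ndarray] = field(repr=False, default_factory=list)
    negative_masks: list[np.ndarray] = field(repr=False, default_factory=list)


def _spearman_by_column(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-tailed t-approximation p of each column with y."""
    n = len(y)
    RX = sps.rankdata(X, axis=0)
    ry = sps.rankdata(y)
    RX = RX - RX.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(RX**2, axis=0) * np.sum(ry**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (RX.T @ ry) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    return r, p


def cpm_fit_predict(X: np.ndarray, y: np.ndarray, alpha: float = 0.05, scale: str = "") -> PredictionResult:
    """Improved CPM with leave-one-subject-out cross-validation.

    See the module docstring for the per-fold procedure. When both the
    positive and the negative feature set are empty in a fold, the held-out
    prediction falls back to the training-mean scale with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 subjects, have {n}")
    y_pred = np.empty(n)
    pos_masks, neg_masks = [], []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, ytr = X[tr], y[tr]
        r, p = _spearman_by_column(Xtr, ytr)
        pos = (r > 0) & (p < alpha)
        neg = (r < 0) & (p < alpha)
        pos_masks.append(pos)
        neg_masks.append(neg)
        preds_tr, preds_te = [], []
        for mask in (pos, neg):
            if not mask.any():
                continue
            mu = Xtr[:, mask].mean(axis=0)
            sd = Xtr[:, mask].std(axis=0)
            sd[sd == 0] = 1.0
            preds_tr.append(((Xtr[:, mask] - mu) / sd).sum(axis=1))
            preds_te.append(((X[i, mask] - mu) / sd).sum())
        if not preds_tr:
            logger.warning("fold %d: both CPM feature sets empty; predicting training mean", i)
            y_pred[i] = ytr.mean()
            continue
        D = np.column_stack([np.ones(n - 1), *preds_tr])
        beta = np.linalg.lstsq(D, ytr, rcond=None)[0]
        y_pred[i] = float(np.dot(np.concatenate([[1.0], preds_te]), beta))
    rho, pval = sps.spearmanr(y_pred, y)
    return PredictionResult(
        scale=scale,
        y_true=y,
        y_pred=y_pred,
        rho=float(rho),
        p=float(pval),
        positive_masks=pos_masks,
        negative_masks=neg_masks,
    )


def cpm_cohort(cohort: Cohort, group: str, scale: str, alpha: float = 0.05) -> PredictionResult:
    """Predict one clinical scale within one group from all regional metrics."""
    mask = cohort.group_mask(group)
    sub = cohort.subjects.loc[mask]
    y = sub[scale].to_numpy(dtype=float)
    have = np.isfinite(y)
    n_missing = int((~have).sum())
    if n_missing:
        logger.info("%s/%s: dropping %d subjects with missing scale", group, scale, n_missing)
    X, _ = cohort_feature_matrix(cohort, mask)
    return cpm_fit_predict(X[have], y[have], alpha=alpha, scale=scale)
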