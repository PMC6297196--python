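"""Minimal-panel classifier construction for amyloid status.

The workflow: (1) residualize each protein on the covariates (GLM
adjustment); (2) rank features by their order of entry into an L1-regularized
logistic path as the penalty relaxes (LASSO ranking); (3) sweep panel sizes
n = 1..K, training a linear-kernel SVM on the top-n features under repeated
stratified k-fold cross-validation; (4) pick the minimal panel size whose
mean cross-validated AUC is optimal; (5) report operating metrics (AUC,
sensitivity, specificity, PPV, NPV) at the Youden-J threshold over pooled
cross-validated decision values.

Feature ranking is recomputed inside every training fold by default: ranking
once on all data leaks label information into the held-out folds and inflates
the AUC estimate (with pure-noise features, fold-internal ranking keeps the
cross-validated AUC at chance). ``rank_once=True`` reproduces the optimistic
variant for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .assoc import _binarize

logger = logging.getLogger(__name__)


@dataclass
class AdjustedMatrix:
    """Features x samples of covariate-residualized values."""

    values: pd.DataFrame
    covariates: tuple[str, ...] = ()


def glm_adjust(matrix: pd.DataFrame, covariates: pd.DataFrame | None = None
               ) -> AdjustedMatrix:
    """Replace each feature by its least-squares residuals on the covariates.

    ``matrix`` is features x samples; ``covariates`` a numeric block aligned
    on samples. An intercept is always included, so with no covariates the
    features are mean-centered. Samples with a missing covariate are dropped;
    residuals are orthogonal to every covariate column.
    """
    samples = matrix.columns
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((len(samples), 1))
        used: tuple[str, ...] = ()
    else:
        covariates = covariates.reindex(samples).astype(float)
        keep = covariates.notna().all(axis=1)
        if not keep.all():
            logger.info("glm_adjust: dropping %d sample(s) with missing covariates",
                        int((~keep).sum()))
            samples = samples[keep.to_numpy()]
            covariates = covariates.loc[samples]
        X = np.column_stack([np.ones(len(samples)), covariates.to_numpy()])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient covariate design: "
                             f"{list(covariates.columns)}")
        used = tuple(covariates.columns)
    Y = matrix[samples].to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    values = pd.DataFrame(resid.T, index=matrix.index, columns=samples)
    return AdjustedMatrix(values=values, covariates=used)


def _standardize(train: np.ndarray, test: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    if test is None:
        return (train - mu) / sd
    return (train - mu) / sd, (test - mu) / sd


def lasso_rank(matrix: pd.DataFrame, labels: pd.Series, n_penalties: int = 30,
               c_min: float = 1e-3, c_max: float = 1e3) -> list:
    """Order features by first entry into the L1 logistic path.

    The regularization path is traversed from strong to weak penalty
    (increasing C on a geometric grid); a feature's rank is the first grid
    point at which its coefficient becomes nonzero, ties broken by
    coefficient magnitude at entry then by index order. Features that never
    enter are appended in index order. Features are standardized internally.
    """
    y = _binarize(labels.reindex(matrix.columns)).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = matrix.to_numpy(dtype=float).T
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features are constant")
    X = _standardize(X)
    features = list(matrix.index)
    order: list = []
    entered: set = set()
    for C in np.geomspace(c_min, c_max, n_penalties):
        clf = LogisticRegression(l1_ratio=1, C=C, solver="liblinear",
                                 max_iter=2000, tol=1e-6, random_state=0)
        clf.fit(X, y)
        coef = clf.coef_.ravel()
        new = [j for j in np.argsort(-np.abs(coef)) if coef[j] != 0 and j not in entered]
        for j in new:
            entered.add(j)
            order.append(features[j])
        if len(entered) == len(features):
            break
    order.extend(f for j, f in enumerate(features) if f not in order)
    return order


@dataclass
class PanelCurve:
    """Mean/sd cross-validated AUC per panel size, plus the full-data ranking."""

    sizes: list[int]
    mean_auc: np.ndarray
    sd_auc: np.ndarray
    ranking: list = field(default_factory=list)
    per_repeat: pd.DataFrame | None = None


def _repeat_seeds(seed: int | None, repeats: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=repeats)]


def cv_auc_sweep(adjusted: AdjustedMatrix | pd.DataFrame, labels: pd.Series,
                 sizes=None, repeats: int = 100, folds: int = 10,
                 seed: int | None = None, rank_once: bool = False,
                 svm_c: float = 1.0) -> PanelCurve:
    """Repeated stratified CV of linear SVMs over a sweep of panel sizes.

    For each repeat, samples are split into stratified folds; within each
    training fold the LASSO ranking is recomputed (unless ``rank_once``) and
    a linear-kernel SVM (cost ``svm_c``) is trained on the top-n features for
    every panel size n. Held-out decision values are pooled per repeat into
    one AUC; the curve reports mean and sd over repeats.
    """
    matrix = adjusted.values if isinstance(adjusted, AdjustedMatrix) else adjusted
    y = _binarize(labels.reindex(matrix.columns)).to_numpy(dtype=float)
    n_samples, n_features = len(matrix.columns), len(matrix.index)
    counts = np.bincount(y.astype(int), minlength=2)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > counts.min():
        raise ValueError(f"folds ({folds}) exceed the smaller class count "
                         f"({counts.min()}); stratified folds (and per-fold AUC "
                         f"pooling) are undefined")
    if sizes is None:
        sizes = list(range(1, n_features + 1))
    sizes = sorted(set(int(s) for s in sizes))
    if max(sizes) > n_features or min(sizes) < 1:
        raise ValueError("panel sizes must lie in 1..n_features")
    X_all = matrix.to_numpy(dtype=float).T
    features = list(matrix.index)
    global_rank = lasso_rank(matrix, labels) if rank_once else None
    per_repeat = np.empty((repeats, len(sizes)))
    for r, rseed in enumerate(_repeat_seeds(seed, repeats)):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rseed)
        dec = {s: np.empty(n_samples) for s in sizes}
        for train, test in skf.split(X_all, y):
            if global_rank is not None:
                rank = global_rank
            else:
                rank = lasso_rank(matrix.iloc[:, train],
                                  pd.Series(y[train], index=matrix.columns[train]))
            cols = [features.index(f) for f in rank]
            for s in sizes:
                sel = cols[:s]
                Xtr, Xte = _standardize(X_all[np.ix_(train, sel)],
                                        X_all[np.ix_(test, sel)])
                svm = SVC(kernel="linear", C=svm_c)
                svm.fit(Xtr, y[train])
                dec[s][test] = svm.decision_function(Xte)
        for j, s in enumerate(sizes):
            per_repeat[r, j] = roc_auc_score(y, dec[s])
    return PanelCurve(sizes=sizes,
                      mean_auc=per_repeat.mean(axis=0),
                      sd_auc=per_repeat.std(axis=0, ddof=1) if repeats > 1
                      else np.zeros(len(sizes)),
                      ranking=global_rank or lasso_rank(matrix, labels),
                      per_repeat=pd.DataFrame(per_repeat, columns=sizes))


def select_minimal_panel(curve: PanelCurve, rule: str = "max") -> tuple[int, list]:
    """Smallest panel size with optimal mean AUC.

    ``rule="max"``: smallest n attaining the maximum mean AUC. ``rule=
    "one_se"``: smallest n whose mean AUC is within one sd (of the best size)
    of the maximum. Returns (size, top features from the curve's ranking).
    """
    if len(curve.sizes) == 0:
        raise ValueError("empty panel curve")
    if rule not in ("max", "one_se"):
        raise ValueError(f"unknown rule {rule!r}")
    mean = np.asarray(curve.mean_auc, dtype=float)
    best = int(np.argmax(mean))
    if rule == "max":
        idx = int(np.flatnonzero(mean == mean[best])[0])
    else:
        cut = mean[best] - float(curve.sd_auc[best])
        idx = int(np.flatnonzero(mean >= cut)[0])
    size = curve.sizes[idx]
    return size, list(curve.ranking[:size])


@dataclass
class PanelMetrics:
    """Operating characteristics of a fixed panel under repeated CV."""

    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    degenerate: bool = False


def evaluate_panel(adjusted: AdjustedMatrix | pd.DataFrame, labels: pd.Series,
                   panel, repeats: int = 100, folds: int = 10,
                   seed: int | None = None, svm_c: float = 1.0) -> PanelMetrics:
    """Cross-validated operating metrics for a fixed feature panel.

    Decision values from every repeat x fold are pooled; AUC is computed on
    the pooled values, the operating threshold maximizes Youden's J
    (sensitivity + specificity - 1), and sensitivity/specificity/PPV/NPV come
    from the pooled confusion counts at that threshold.
    """
    matrix = adjusted.values if isinstance(adjusted, AdjustedMatrix) else adjusted
    missing = [f for f in panel if f not in matrix.index]
    if missing:
        raise KeyError(f"panel features not in matrix: {missing}")
    sub = matrix.loc[list(panel)]
    y = _binarize(labels.reindex(sub.columns)).to_numpy(dtype=float)
    counts = np.bincount(y.astype(int), minlength=2)
    if folds > counts.min():
        raise ValueError(f"folds ({folds}) exceed the smaller class count "
                         f"({counts.min()})")
    X_all = sub.to_numpy(dtype=float).T
    pooled_dec, pooled_y = [], []
    for rseed in _repeat_seeds(seed, repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rseed)
        for train, test in skf.split(X_all, y):
            Xtr, Xte = _standardize(X_all[train], X_all[test])
            svm = SVC(kernel="linear", C=svm_c)
            svm.fit(Xtr, y[train])
            pooled_dec.append(svm.decision_function(Xte))
            pooled_y.append(y[test])
    dec = np.concatenate(pooled_dec)
    yy = np.concatenate(pooled_y)
    auc = float(roc_auc_score(yy, dec))
    fpr, tpr, thresholds = roc_curve(yy, dec)
    j = tpr - fpr
    thr = float(thresholds[int(np.argmax(j))])
    pred = dec >= thr
    tp = float(np.sum(pred & (yy == 1)))
    fp = float(np.sum(pred & (yy == 0)))
    fn = float(np.sum(~pred & (yy == 1)))
    tn = float(np.sum(~pred & (yy == 0)))
    degenerate = (tp + fp == 0) or (tn + fn == 0)
    if degenerate:
        logger.warning("degenerate pooled predictions: all samples on one side "
                       "of the threshold")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return PanelMetrics(auc=auc, sensitivity=sens, specificity=spec, ppv=ppv,
                        npv=npv, threshold=thr, degenerate=degenerate)
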