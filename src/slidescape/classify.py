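"""Feature-based patch classification and threshold-free evaluation.

A gradient-boosted tree classifier (XGBoost) is trained on the 524-entry
patch feature vectors to predict the patch's patient group, with a small
frozen hyperparameter grid selected by 3-fold cross-validated AUROC.
Splits are stratified by class and grouped by patient so that no patient
contributes patches to both sides — stricter than a plain patch-level
split, which would leak slide-correlated patches across the boundary
(``group_by_patient=False`` restores the literal patch-level behavior).

Evaluation reports AUROC with a stratified percentile-bootstrap
confidence interval and the Youden-index threshold that dichotomizes
the continuous score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold
from xgboost import XGBClassifier

DEFAULT_GRID: tuple[dict, ...] = tuple(
    {"max_depth": d, "learning_rate": lr, "n_estimators": n}
    for d in (3, 5) for lr in (0.1, 0.3) for n in (100,)
)


@dataclass(frozen=True)
class EvalResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_test: int
    seed: int
    threshold_youden: float


def split_patches(
    table: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    group_by_patient: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 80–20 train/test split of patch rows.

    Stratification is by class (group column); with patient grouping,
    whole patients are assigned to one side, accumulating shuffled
    patients per class until the test fraction of patches is reached.
    Returns positional (train, test) index arrays.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    y = table["group"].to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    positions = np.arange(len(table))
    for cls in classes:
        cls_pos = positions[y == cls]
        target = test_fraction * cls_pos.size
        if group_by_patient:
            patients = table["patient_id"].to_numpy()[cls_pos]
            uniq = np.array(sorted(set(patients)))
            if uniq.size < 2:
                raise ValueError(f"class {cls!r} needs >= 2 patients to split")
            rng.shuffle(uniq)
            taken = 0
            for p in uniq:
                if taken >= target:
                    break
                sel = cls_pos[patients == p]
                # never put every patient of a class in the test side
                if taken + sel.size >= cls_pos.size:
                    continue
                test_idx.extend(sel.tolist())
                taken += sel.size
        else:
            perm = rng.permutation(cls_pos)
            k = max(1, int(round(target)))
            test_idx.extend(perm[:k].tolist())
    test = np.array(sorted(test_idx), dtype=int)
    train = np.setdiff1d(positions, test)
    return train, test


def _make_model(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(tree_method="hist", eval_metric="logloss",
                         n_jobs=1, random_state=seed, **params)


def fit_patch_classifier(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    cv_folds: int = 3,
    grid=None,
    seed: int = 0,
) -> dict:
    """Grid-searched XGBoost fit with patient-grouped stratified CV.

    Missing feature values pass through natively (tree default
    directions). Degenerate single-class validation folds trigger a
    reshuffled refold (warned). Returns the refit model, the selected
    parameters and the per-combination mean CV AUROC.
    """
    grid = DEFAULT_GRID if grid is None else tuple(grid)
    y = np.asarray(y)
    yb = (y == y.max()).astype(int) if y.dtype.kind not in "iub" else y.astype(int)
    if np.unique(yb).size < 2:
        raise ValueError("both classes must be present")

    def _folds(random_state):
        cv = StratifiedGroupKFold(n_splits=cv_folds, shuffle=True,
                                  random_state=random_state)
        return list(cv.split(X, yb, groups))

    folds = _folds(seed)
    if any(np.unique(yb[va]).size < 2 for _, va in folds):
        warnings.warn("degenerate single-class CV fold; reshuffling folds")
        for bump in range(1, 6):
            folds = _folds(seed + bump)
            if all(np.unique(yb[va]).size == 2 for _, va in folds):
                break

    cv_results = []
    for params in grid:
        aucs = []
        for tr, va in folds:
            if np.unique(yb[va]).size < 2 or np.unique(yb[tr]).size < 2:
                continue
            m = _make_model(params, seed)
            m.fit(X.iloc[tr], yb[tr])
            aucs.append(roc_auc_score(yb[va], m.predict_proba(X.iloc[va])[:, 1]))
        cv_results.append({"params": params,
                           "mean_cv_auroc": float(np.mean(aucs)) if aucs else np.nan})
    best = max(cv_results, key=lambda r: (np.nan_to_num(r["mean_cv_auroc"], nan=-1)))
    model = _make_model(best["params"], seed)
    model.fit(X, yb)
    return {"model": model, "best_params": best["params"],
            "best_cv_auroc": best["mean_cv_auroc"], "cv_results": cv_results}


def youden_threshold(scores, labels) -> float:
    """Score cut-point maximizing Youden's J = sensitivity + specificity − 1.

    Candidates are midpoints between consecutive unique scores (predict
    positive when score > threshold); among maximizers the lowest
    threshold is returned. A single unique score returns that score
    (J = 0).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    u = np.unique(s)
    if u.size == 1:
        return float(u[0])
    mids = (u[:-1] + u[1:]) / 2.0
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best_j, best_t = -np.inf, mids[0]
    for t in mids:
        pred = s > t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def auroc_with_ci(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalResult:
    """AUROC (rank statistic, 0.5 tie credit) with a percentile bootstrap CI.

    Bootstrap resampling is stratified within each class; the interval
    is widened if necessary to cover the point estimate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    auroc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([ip, ineg])
        boots[b] = roc_auc_score(y[idx], s[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EvalResult(auroc=auroc, ci_low=float(min(lo, auroc)),
                      ci_high=float(max(hi, auroc)), n_test=int(s.size),
                      seed=int(seed),
                      threshold_youden=youden_threshold(s, y))
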