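"""Cross-validated elastic-net logistic classifier with serology.

The classifier combines standardized probe M-values (elastic-net
penalized) with a single unpenalized binary serology covariate
(ACPA-positive OR RF-positive; unmeasured serology counts as negative).
Hyperparameters (alpha_mix, lambda) are chosen by stratified k-fold
cross-validation maximizing mean out-of-fold AUC, with deterministic
tie-breaking (larger lambda, then smaller alpha_mix).  The continuous
probability score is dichotomized at the cutoff maximizing Youden's
J = sensitivity + specificity - 1 on the training scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._enet import _sigmoid, default_lambda_grid, enet_path, lambda_max
from .evalstats import auc_mann_whitney

__all__ = [
    "ClassifierModel",
    "encode_serology",
    "train_elastic_net_cv",
    "predict_proba",
    "youden_cutoff",
    "classify",
]

MODEL_FORMAT_VERSION = 1


def encode_serology(sheet: pd.DataFrame) -> pd.Series:
    """Binary serology status: 1 if ACPA or RF positive, else 0.

    Missing/unmeasured markers are treated as negative, matching the
    handling of healthy controls without serology measurements.
    """
    acpa = sheet["acpa"].astype(str).str.lower() == "pos"
    rf = sheet["rf"].astype(str).str.lower() == "pos"
    return (acpa | rf).astype(int).set_axis(sheet["sample_id"].to_numpy())


@dataclass
class ClassifierModel:
    """Sparse penalized-logistic model on standardized M-values."""

    intercept: float
    coef: pd.Series           # probe_id -> coefficient (standardized scale)
    sero_coef: float
    mean: pd.Series           # per-probe training mean of M
    sd: pd.Series             # per-probe training sd of M (>0)
    alpha_mix: float
    lam: float
    cv_auc: float
    cutoff: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def feature_count(self) -> int:
        return int((self.coef.to_numpy() != 0).sum())

    def to_json(self) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "intercept": self.intercept,
            "coef": {p: float(c) for p, c in self.coef.items()},
            "sero_coef": self.sero_coef,
            "mean": {p: float(v) for p, v in self.mean.items()},
            "sd": {p: float(v) for p, v in self.sd.items()},
            "alpha_mix": self.alpha_mix,
            "lambda": self.lam,
            "cv_auc": self.cv_auc,
            "cutoff": self.cutoff,
            "meta": self.meta,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {doc.get('format_version')}")
        return cls(
            intercept=doc["intercept"],
            coef=pd.Series(doc["coef"], dtype=float),
            sero_coef=doc["sero_coef"],
            mean=pd.Series(doc["mean"], dtype=float),
            sd=pd.Series(doc["sd"], dtype=float),
            alpha_mix=doc["alpha_mix"],
            lam=doc["lambda"],
            cv_auc=doc["cv_auc"],
            cutoff=doc["cutoff"],
            meta=doc.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return cls.from_json(Path(path).read_text())


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def train_elastic_net_cv(
    m_matrix: pd.DataFrame,
    labels,
    sero,
    k_folds: int = 5,
    alpha_grid: tuple[float, ...] = (0.1, 0.5, 0.9, 1.0),
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 30,
    lambda_decades: float = 4.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> ClassifierModel:
    """Grid-searched, cross-validated elastic-net logistic fit.

    ``m_matrix`` is probes x samples restricted to the feature panel;
    ``sero`` is the binary serology covariate, entered unpenalized.
    Probe features are standardized within each training fold (and on
    the full data for the final refit), so cross-validation never sees
    held-out statistics.
    """
    if m_matrix.shape[0] == 0:
        raise ValueError("feature panel is empty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X_all = m_matrix.to_numpy(float).T  # samples x probes
    y = np.asarray(labels, float)
    s = np.asarray(sero, float)
    n, p = X_all.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < k_folds={k_folds}"
        )

    pen = np.append(np.ones(p), 0.0)  # serology column unpenalized
    alpha_grid = tuple(sorted(alpha_grid))

    grids: dict[float, np.ndarray] = {}
    if lambda_grid is not None:
        lam_arr = np.asarray(lambda_grid, float)
        for a in alpha_grid:
            grids[a] = lam_arr
    else:
        Z_all, _, _ = _standardize_fit(X_all)
        D_all = np.column_stack([Z_all, s])
        for a in alpha_grid:
            lmax = lambda_max(D_all, y, a, penalty_factors=pen)
            grids[a] = default_lambda_grid(lmax, n_lambda, lambda_decades)

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X_all, y))
    for _, val_idx in folds:
        if len(np.unique(y[val_idx])) < 2:
            raise ValueError("degenerate fold with a single class")

    # mean out-of-fold AUC per (alpha, lambda)
    mean_auc: dict[tuple[float, float], float] = {}
    for a in alpha_grid:
        lams = grids[a]
        fold_aucs = np.zeros((len(folds), lams.size))
        for fi, (tr, va) in enumerate(folds):
            Ztr, mu, sd = _standardize_fit(X_all[tr])
            Dtr = np.column_stack([Ztr, s[tr]])
            Zva = (X_all[va] - mu) / sd
            Dva = np.column_stack([Zva, s[va]])
            fits = enet_path(Dtr, y[tr], lams, a, penalty_factors=pen,
                             tol=tol, max_iter=max_iter)
            for li, fit in enumerate(fits):
                scores = _sigmoid(fit.intercept + Dva @ fit.coef)
                fold_aucs[fi, li] = auc_mann_whitney(scores, y[va])
        for li, lam in enumerate(lams):
            mean_auc[(a, float(lam))] = float(fold_aucs[:, li].mean())

    # ties -> larger lambda, then smaller alpha_mix
    best = max(mean_auc.items(), key=lambda kv: (kv[1], kv[0][1], -kv[0][0]))
    (best_alpha, best_lam), best_auc = best

    Z_all, mu, sd = _standardize_fit(X_all)
    D_all = np.column_stack([Z_all, s])
    path_lams = grids[best_alpha][grids[best_alpha] >= best_lam]
    fit = enet_path(D_all, y, path_lams, best_alpha, penalty_factors=pen,
                    tol=tol, max_iter=max_iter)[-1]
    coef = fit.coef[:p]
    if not np.any(coef != 0):
        warnings.warn("final model has no nonzero probe coefficients", stacklevel=2)
    return ClassifierModel(
        intercept=float(fit.intercept),
        coef=pd.Series(coef, index=m_matrix.index),
        sero_coef=float(fit.coef[p]),
        mean=pd.Series(mu, index=m_matrix.index),
        sd=pd.Series(sd, index=m_matrix.index),
        alpha_mix=float(best_alpha),
        lam=float(best_lam),
        cv_auc=best_auc,
        meta={"k_folds": k_folds, "seed": seed,
              "alpha_grid": list(alpha_grid),
              "n_lambda": int(grids[best_alpha].size)},
    )


def predict_proba(model: ClassifierModel, m_matrix: pd.DataFrame, sero) -> pd.Series:
    """Probability score s = logistic(w0 + sum w_j z_j + w_sero * sero)."""
    needed = model.coef.index[model.coef.to_numpy() != 0]
    missing = [p for p in needed if p not in m_matrix.index]
    if missing:
        raise ValueError(f"input matrix is missing model probes: {missing[:10]}")
    present = [p for p in model.coef.index if p in m_matrix.index]
    X = m_matrix.loc[present].to_numpy(float).T
    w = model.coef.loc[present].to_numpy()
    mu = model.mean.loc[present].to_numpy()
    sd = model.sd.loc[present].to_numpy()
    z = (X - mu) / sd
    lin = model.intercept + z @ w + model.sero_coef * np.asarray(sero, float)
    return pd.Series(_sigmoid(lin), index=m_matrix.columns, name="score")


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints of adjacent distinct sorted
    scores plus the minimum score (the all-positive boundary), under the
    rule "score >= c => positive".  Ties are broken by highest
    sensitivity, then smallest cutoff.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("need at least two distinct scores")
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0])
    n_case = (y == 1).sum()
    n_ctrl = (y == 0).sum()
    best = None
    for c in candidates:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n_case
        spec = (~pred & (y == 0)).sum() / n_ctrl
        j = sens + spec - 1.0
        key = (j, sens, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return float(best[1])


def classify(scores, cutoff: float) -> np.ndarray:
    """Dichotomize scores: score >= cutoff is a positive (RA) call."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    return (np.asarray(scores, float) >= cutoff).astype(int)
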