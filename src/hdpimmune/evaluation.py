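"""Repeated cross-validated AUROC estimation, model selection and transfer.

Predictive performance is estimated with repeated stratified k-fold
cross-validation (default 200 repeats of 5 folds, i.e. 80%/20% splits):
each repeat yields one out-of-fold predicted probability per sample and one
pooled AUROC.  The headline summary is the median of the per-repeat AUROCs
with a 2.5%–97.5% quantile interval; significance comes from a two-sided
Mann-Whitney U-test comparing the per-sample median out-of-fold
probabilities of cases vs controls.  AUROC itself is the normalized
Mann-Whitney U statistic (ties counted half), so the two views are dual.

A model trained on one cohort can be *transferred* to a chronologically
later cohort: its final full-data fit predicts the target samples without
refitting, and AUROC/Mann-Whitney significance are computed there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .models import ModelFit, ModelSpec, fit_model, predict

__all__ = ["CVConfig", "CVReport", "auroc", "mann_whitney_p", "repeated_cv",
           "select_best_model", "transfer_evaluate"]


def auroc(scores, labels) -> float:
    """Area under the ROC curve via rank sums: U / (n1 * n0), ties half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUROC")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when the combined sample size is <= 20 and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 20 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class CVConfig:
    n_repeats: int = 200
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CVReport:
    spec: ModelSpec
    auroc_per_repeat: np.ndarray
    oof_probability: pd.Series  # per-sample median out-of-fold probability
    p_value: float
    final_fit: ModelFit
    alpha: float = 0.05

    @property
    def median_auroc(self) -> float:
        return float(np.median(self.auroc_per_repeat))

    @property
    def auroc_interval(self) -> tuple[float, float]:
        """2.5%–97.5% quantile interval of the per-repeat AUROCs."""
        lo, hi = np.quantile(self.auroc_per_repeat, [0.025, 0.975])
        return float(lo), float(hi)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        lo, hi = self.auroc_interval
        return {
            "median_auroc": self.median_auroc,
            "auroc_interval_2.5": lo,
            "auroc_interval_97.5": hi,
            "n_repeats": int(len(self.auroc_per_repeat)),
            "p_value": self.p_value,
            "significant": bool(self.significant),
            "n_selected_features": self.final_fit.n_selected(),
            "selected_features": self.final_fit.selected_features,
            "estimator": self.spec.estimator,
            "fusion": self.spec.fusion,
        }


def _as_index_and_n(data) -> tuple[pd.Index, int]:
    if isinstance(data, dict):
        first = next(iter(data.values()))
        return first.index, len(first)
    return data.index, len(data)


def _subset(data, idx: np.ndarray):
    if isinstance(data, dict):
        return {k: v.iloc[idx] for k, v in data.items()}
    return data.iloc[idx]


def _fold_stream(n: int, y: np.ndarray, cv: CVConfig):
    """Deterministic repeat-indexed fold assignments, shared across candidate
    models run with the same CVConfig."""
    for r in range(cv.n_repeats):
        seed = (cv.seed * 100003 + r) % (2**31)
        skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=seed)
        yield r, list(skf.split(np.zeros(n), y))


def repeated_cv(data, labels, spec: ModelSpec | None = None,
                cv: CVConfig | None = None) -> CVReport:
    """Repeated stratified k-fold cross-validation of one candidate model.

    ``data`` is a feature table or, for late fusion, a stratum->table
    mapping.  Every sample is scored out-of-fold exactly once per repeat;
    per-repeat AUROC is computed on the pooled out-of-fold probabilities.
    Ends with a final fit on the whole dataset.
    """
    spec = spec or ModelSpec()
    cv = cv or CVConfig()
    y = np.asarray(labels)
    index, n = _as_index_and_n(data)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if min(n1, n0) < cv.n_folds:
        raise ValueError(
            f"each class needs >= n_folds={cv.n_folds} samples, got {n1}/{n0}")
    aurocs = np.empty(cv.n_repeats)
    probs = np.empty((cv.n_repeats, n))
    for r, folds in _fold_stream(n, y, cv):
        oof = np.empty(n)
        for f, (train, test) in enumerate(folds):
            fit = fit_model(_subset(data, train), y[train],
                            replace(spec, seed=(spec.seed + 7919 * r + f) % (2**31)))
            oof[test] = predict(fit, _subset_table_for_predict(data, test))
        aurocs[r] = auroc(oof, y)
        probs[r] = oof
    agg = pd.Series(np.median(probs, axis=0), index=index, name="oof_probability")
    p = mann_whitney_p(agg[y == 1].to_numpy(), agg[y == 0].to_numpy())
    final = fit_model(data, y, spec)
    return CVReport(spec, aurocs, agg, p, final, alpha=cv.alpha)


def _subset_table_for_predict(data, idx):
    sub = _subset(data, idx)
    if isinstance(sub, dict):
        return pd.concat(list(sub.values()), axis=1)
    return sub


def select_best_model(candidates: list[ModelSpec], data, labels,
                      cv: CVConfig | None = None) -> CVReport:
    """Run repeated CV per candidate on a shared fold stream and return the
    report with the highest median AUROC; ties break toward the sparser
    final model, then lexicographic spec order."""
    if not candidates:
        raise ValueError("empty candidate list")
    cv = cv or CVConfig()
    reports = [repeated_cv(data, labels, spec, cv) for spec in candidates]
    best = min(
        range(len(reports)),
        key=lambda i: (-reports[i].median_auroc,
                       reports[i].final_fit.n_selected(),
                       candidates[i].sort_key()),
    )
    return reports[best]


def transfer_evaluate(fit: ModelFit, target_table, target_labels) -> dict:
    """Apply a trained model to a later cohort without refitting.

    Returns the transfer AUROC and the two-sided Mann-Whitney p-value of the
    predicted probabilities by target label.
    """
    if isinstance(target_table, dict):
        target_table = pd.concat(list(target_table.values()), axis=1)
    y = np.asarray(target_labels)
    p = predict(fit, target_table)
    return {
        "auroc": auroc(p, y),
        "p_value": mann_whitney_p(p[y == 1], p[y == 0]),
        "predictions": pd.Series(p, index=target_table.index,
                                 name="transfer_probability"),
    }
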