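"""Sparse logistic classifiers and fusion strategies for case/control models.

Candidate estimators:

* ``lasso`` — L1-penalized logistic regression, penalty chosen by inner
  stratified cross-validation maximizing AUROC;
* ``adaptive_lasso`` — two-stage fit: ridge pilot coefficients define
  per-feature weights 1/(|b0|^gamma + eps), then a weighted-L1 logistic fit
  (implemented by rescaling columns, so the inner-CV machinery is shared);
* ``stabl_lasso`` / ``stabl_adaptive_lasso`` — stability selection: the base
  estimator is refit on many subsamples with label-independent decoy
  features (permuted copies of the real columns) appended; the per-feature
  selection frequency over the regularization path is compared against the
  decoy frequencies to pick the threshold minimizing a false-discovery
  proxy, and the surviving features get a ridge-stabilized final refit.

Fusion across feature strata (frequencies and the four stimulation
conditions): *early* fusion concatenates all strata into one design matrix;
*late* fusion fits one model per stratum and stacks their out-of-fold
predicted probabilities with a logistic combiner.

All estimators standardize features with training-data statistics, so the
fits are invariant to per-feature rescaling of the inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["ModelSpec", "ModelFit", "fit_model", "fit_lasso",
           "fit_adaptive_lasso", "fit_stability_selected", "fit_fused",
           "predict"]

ESTIMATORS = ("lasso", "adaptive_lasso", "stabl_lasso", "stabl_adaptive_lasso")


@dataclass(frozen=True)
class ModelSpec:
    estimator: str = "lasso"
    fusion: str = "early"
    #: log10 range and length of the inverse-penalty (C) path.
    path_min_log10: float = -2.0
    path_max_log10: float = 2.0
    path_length: int = 50
    inner_cv_folds: int = 5
    #: stability-selection settings
    n_subsamples: int = 50
    subsample_fraction: float = 0.5
    decoys_per_feature: int = 1
    threshold: float | None = None  # manual override of the frequency threshold
    stability_path_length: int = 20
    #: ceiling on the decoy-estimated false-discovery proxy; if no threshold
    #: reaches it, the stability-selected model is empty
    fdp_max: float = 0.2
    #: adaptive-lasso settings
    gamma: float = 1.0
    eps: float = 1e-8
    standardize: bool = True
    ridge_refit_C: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.fusion not in ("early", "late"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample fraction must be in (0, 1)")
        if self.n_subsamples < 2 and self.estimator.startswith("stabl"):
            raise ValueError("stability selection needs >= 2 subsamples")
        if self.decoys_per_feature < 1 and self.estimator.startswith("stabl"):
            raise ValueError("stability selection needs >= 1 decoy per feature")

    def path(self) -> np.ndarray:
        return np.logspace(self.path_min_log10, self.path_max_log10,
                           self.path_length)

    def sort_key(self) -> tuple:
        return (ESTIMATORS.index(self.estimator), self.fusion)


@dataclass
class ModelFit:
    """A fitted (possibly two-layer) sparse classifier.

    ``coef``/``intercept`` act on standardized features for single-layer
    fits.  Late-fusion fits carry per-stratum sub-fits plus a logistic
    combiner over their predicted probabilities.
    """

    feature_names: list[str]
    coef: np.ndarray | None = None
    intercept: float = 0.0
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    stratum_fits: dict[str, "ModelFit"] | None = None
    combiner: "ModelFit | None" = None
    spec: ModelSpec | None = None
    selection_frequency: dict[str, float] | None = None
    stability_threshold: float | None = None

    @property
    def selected_features(self) -> list[str]:
        if self.stratum_fits is not None:
            out: list[str] = []
            for f in self.stratum_fits.values():
                out.extend(f.selected_features)
            return out
        if self.coef is None:
            return []
        return [f for f, c in zip(self.feature_names, self.coef) if c != 0.0]

    def n_selected(self) -> int:
        return len(self.selected_features)

    def decision_values(self, table: pd.DataFrame) -> np.ndarray:
        X = _design(table, self.feature_names)
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_scale
        return X @ self.coef + self.intercept

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if self.stratum_fits is not None:
            with warnings.catch_warnings():
                # each stratum sub-fit sees the other strata's columns
                warnings.simplefilter("ignore", UserWarning)
                probs = np.column_stack([
                    f.predict_proba(table) for f in self.stratum_fits.values()])
            z = probs @ self.combiner.coef + self.combiner.intercept
            return _sigmoid(z)
        return _sigmoid(self.decision_values(table))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"feature_names": self.feature_names,
                   "intercept": float(self.intercept)}
        if self.coef is not None:
            nz = {f: float(c) for f, c in zip(self.feature_names, self.coef)
                  if c != 0.0}
            d["coefficients"] = nz
        if self.scaler_mean is not None:
            d["scaler_mean"] = self.scaler_mean.tolist()
            d["scaler_scale"] = self.scaler_scale.tolist()
        if self.stratum_fits is not None:
            d["stratum_fits"] = {k: v.to_dict() for k, v in self.stratum_fits.items()}
            d["combiner"] = self.combiner.to_dict()
        if self.spec is not None:
            d["spec"] = asdict(self.spec)
        if self.selection_frequency is not None:
            d["selection_frequency"] = self.selection_frequency
        if self.stability_threshold is not None:
            d["stability_threshold"] = self.stability_threshold
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _design(table: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise KeyError(
            f"feature columns required by the model are missing: {missing[:10]}"
            + ("..." if len(missing) > 10 else ""))
    extra = set(table.columns) - set(feature_names)
    if extra:
        warnings.warn(f"{len(extra)} extra feature columns ignored", stacklevel=2)
    return table[feature_names].to_numpy(dtype=float)


def _standardize(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not enabled:
        return X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature column(s) "
                      "standardized to zero and never selected", stacklevel=2)
        sd = np.where(constant, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _check_labels(y: np.ndarray, n_min: int = 2) -> None:
    y = np.asarray(y)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 < n_min or n0 < n_min:
        raise ValueError(f"need >= {n_min} samples per class, got {n1} cases / {n0} controls")


def _l1_logistic(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                             intercept_scaling=1000.0, max_iter=2000, tol=1e-6,
                             random_state=0)
    clf.fit(X, y)
    return clf


def _prevalence_intercept(y: np.ndarray) -> float:
    prev = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    return float(np.log(prev / (1 - prev)))


def _inner_cv_choose_C(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                       seed: int) -> float:
    """Pick the inverse penalty maximizing inner-CV AUROC over the path."""
    from .evaluation import auroc  # local import to avoid a cycle

    path = spec.path()
    n_folds = min(spec.inner_cv_folds, int((y == 1).sum()), int((y == 0).sum()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    scores = np.zeros(len(path))
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            continue
        for i, C in enumerate(path):
            clf = _l1_logistic(X[train], y[train], C)
            s = X[test] @ clf.coef_.ravel() + clf.intercept_[0]
            scores[i] += auroc(s, y[test])
    # ties toward the sparser (smaller C) end of the path
    return float(path[int(np.argmax(scores))])


def fit_lasso(table: pd.DataFrame, labels, spec: ModelSpec | None = None) -> ModelFit:
    """L1-penalized logistic fit with inner-CV penalty choice."""
    spec = spec or ModelSpec(estimator="lasso")
    y = np.asarray(labels)
    _check_labels(y)
    X = table.to_numpy(dtype=float)
    Xs, mean, scale = _standardize(X, spec.standardize)
    C = _inner_cv_choose_C(Xs, y, spec, spec.seed)
    clf = _l1_logistic(Xs, y, C)
    coef = clf.coef_.ravel().copy()
    # in the empty-model limit the (conceptually unpenalized) intercept is
    # the log-odds of the class prevalence
    intercept = (float(clf.intercept_[0]) if coef.any()
                 else _prevalence_intercept(y))
    return ModelFit(list(table.columns), coef, intercept, mean, scale, spec=spec)


def _pilot_weights(Xs: np.ndarray, y: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Adaptive-lasso weights from a ridge pilot fit."""
    pilot = LogisticRegression(l1_ratio=0.0, C=1.0, solver="lbfgs", max_iter=2000)
    pilot.fit(Xs, y)
    b0 = np.abs(pilot.coef_.ravel())
    return 1.0 / (b0**spec.gamma + spec.eps)


def fit_adaptive_lasso(table: pd.DataFrame, labels,
                       spec: ModelSpec | None = None) -> ModelFit:
    """Two-stage adaptive lasso: ridge pilot, then weighted-L1 logistic fit.

    The weighted-L1 problem is solved as a plain lasso on columns divided by
    their weights; coefficients are mapped back to the original scale.
    """
    spec = spec or ModelSpec(estimator="adaptive_lasso")
    y = np.asarray(labels)
    _check_labels(y)
    X = table.to_numpy(dtype=float)
    Xs, mean, scale = _standardize(X, spec.standardize)
    w = _pilot_weights(Xs, y, spec)
    Xw = Xs / w
    C = _inner_cv_choose_C(Xw, y, spec, spec.seed)
    clf = _l1_logistic(Xw, y, C)
    coef = clf.coef_.ravel() / w
    intercept = (float(clf.intercept_[0]) if coef.any()
                 else _prevalence_intercept(y))
    return ModelFit(list(table.columns), coef, intercept, mean, scale, spec=spec)


def _stability_frequencies(Xs: np.ndarray, y: np.ndarray, spec: ModelSpec,
                           rng: np.random.Generator) -> np.ndarray:
    """Selection frequency per real+decoy column: max over the penalty path
    of the fraction of subsamples in which the coefficient is nonzero."""
    n, p = Xs.shape
    decoys = np.empty((n, p * spec.decoys_per_feature))
    for r in range(spec.decoys_per_feature):
        for j in range(p):
            decoys[:, r * p + j] = rng.permutation(Xs[:, j])
    Xa = np.hstack([Xs, decoys])
    # the weak-penalty end is capped at C=1 so subsample fits stay sparse;
    # an unconstrained path would inflate every selection frequency
    path = np.logspace(-2.5, 0.0, spec.stability_path_length)
    n_sub = max(2, int(round(spec.subsample_fraction * n)))
    counts = np.zeros((len(path), Xa.shape[1]))
    weights = "adaptive" in spec.estimator
    done = 0
    for b in range(spec.n_subsamples):
        idx = rng.choice(n, size=n_sub, replace=False)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            continue
        Xb = Xa[idx]
        if weights:
            wb = _pilot_weights(Xb, yb, spec)
            Xb = Xb / wb
        for i, C in enumerate(path):
            clf = _l1_logistic(Xb, yb, C)
            counts[i] += clf.coef_.ravel() != 0.0
        done += 1
    if done == 0:
        raise ValueError("no valid subsamples (single-class draws only)")
    return (counts / done).max(axis=0)


def _fdp_threshold(freq_real: np.ndarray, freq_decoy: np.ndarray,
                   fdp_max: float = 0.2) -> float:
    """Frequency cutoff minimizing the decoy-based false-discovery proxy
    (1 + #decoys passing) / max(1, #real passing); ties resolve to the
    larger (sparser) threshold.  If even the best cutoff cannot push the
    proxy to ``fdp_max`` or below, nothing is selected: on null data real
    and decoy frequencies are exchangeable and the proxy hovers around 1."""
    grid = np.arange(0.10, 1.01, 0.01)
    best_t, best_fdp = 1.01, np.inf
    for t in grid:
        r = int((freq_real >= t).sum())
        d = int((freq_decoy >= t).sum())
        fdp = (1.0 + d) / max(r, 1)
        if fdp <= best_fdp:  # <= keeps the largest minimizing threshold
            best_fdp, best_t = fdp, t
    if best_fdp > fdp_max:
        return 1.01
    return float(best_t)


def fit_stability_selected(table: pd.DataFrame, labels,
                           spec: ModelSpec | None = None) -> ModelFit:
    """Decoy-calibrated stability selection with a ridge-stabilized refit.

    The base sparse estimator (lasso or adaptive lasso) is refit on
    ``n_subsamples`` half-subsamples with one permuted decoy per real
    feature appended.  Features whose selection frequency exceeds the
    decoy-calibrated threshold enter a final L2-regularized logistic refit.
    """
    spec = spec or ModelSpec(estimator="stabl_lasso")
    y = np.asarray(labels)
    _check_labels(y)
    X = table.to_numpy(dtype=float)
    Xs, mean, scale = _standardize(X, spec.standardize)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 41]))
    freq = _stability_frequencies(Xs, y, spec, rng)
    p = X.shape[1]
    freq_real, freq_decoy = freq[:p], freq[p:]
    thr = spec.threshold if spec.threshold is not None else _fdp_threshold(
        freq_real, freq_decoy, spec.fdp_max)
    support = freq_real >= thr
    coef = np.zeros(p)
    if support.any():
        refit = LogisticRegression(l1_ratio=0.0, C=spec.ridge_refit_C,
                                   solver="lbfgs", max_iter=5000)
        refit.fit(Xs[:, support], y)
        coef[support] = refit.coef_.ravel()
        intercept = float(refit.intercept_[0])
    else:
        prevalence = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        intercept = float(np.log(prevalence / (1 - prevalence)))
    return ModelFit(list(table.columns), coef, intercept, mean, scale,
                    spec=spec,
                    selection_frequency=dict(zip(table.columns, freq_real)),
                    stability_threshold=thr)


_SINGLE_FITTERS = {
    "lasso": fit_lasso,
    "adaptive_lasso": fit_adaptive_lasso,
    "stabl_lasso": fit_stability_selected,
    "stabl_adaptive_lasso": fit_stability_selected,
}


def _fit_single(table: pd.DataFrame, labels, spec: ModelSpec) -> ModelFit:
    return _SINGLE_FITTERS[spec.estimator](table, labels, spec)


def fit_fused(tables_by_stratum: dict[str, pd.DataFrame], labels,
              spec: ModelSpec | None = None) -> ModelFit:
    """Fit across feature strata by early or late fusion.

    Early fusion concatenates the stratum tables column-wise and fits one
    model.  Late fusion fits one model per stratum, computes out-of-fold
    predicted probabilities on the training data (stratified 5-fold, so the
    combiner never sees in-sample predictions), trains a logistic combiner
    on them, and refits the stratum models on the full training data.
    """
    spec = spec or ModelSpec()
    if not tables_by_stratum:
        raise ValueError("empty stratum mapping")
    y = np.asarray(labels)
    _check_labels(y)
    names = list(tables_by_stratum)
    index = tables_by_stratum[names[0]].index
    for nm in names[1:]:
        if not tables_by_stratum[nm].index.equals(index):
            raise ValueError(f"sample sets differ across strata ({names[0]!r} vs {nm!r})")
    seen: set[str] = set()
    for nm in names:
        overlap = seen & set(tables_by_stratum[nm].columns)
        if overlap:
            raise ValueError(f"strata share columns: {sorted(overlap)[:5]}")
        seen |= set(tables_by_stratum[nm].columns)

    if spec.fusion == "early" or len(names) == 1 and spec.fusion == "early":
        merged = pd.concat([tables_by_stratum[nm] for nm in names], axis=1)
        return _fit_single(merged, y, spec)

    # late fusion
    n = len(index)
    n_folds = min(5, int((y == 1).sum()), int((y == 0).sum()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=(spec.seed + 9973) % (2**31))
    oof = np.full((n, len(names)), np.nan)
    for train, test in skf.split(np.zeros(n), y):
        for k, nm in enumerate(names):
            sub = tables_by_stratum[nm]
            f = _fit_single(sub.iloc[train], y[train],
                            replace(spec, seed=spec.seed + 13 * k))
            oof[test, k] = f.predict_proba(sub.iloc[test])
    combiner_clf = LogisticRegression(l1_ratio=0.0, C=1000.0, solver="lbfgs",
                                      max_iter=5000)
    combiner_clf.fit(oof, y)
    combiner = ModelFit([f"stratum:{nm}" for nm in names],
                        combiner_clf.coef_.ravel().copy(),
                        float(combiner_clf.intercept_[0]))
    stratum_fits = {
        nm: _fit_single(tables_by_stratum[nm], y,
                        replace(spec, seed=spec.seed + 13 * k))
        for k, nm in enumerate(names)}
    all_names: list[str] = []
    for nm in names:
        all_names.extend(tables_by_stratum[nm].columns)
    return ModelFit(all_names, stratum_fits=stratum_fits, combiner=combiner,
                    spec=spec)


def fit_model(data, labels, spec: ModelSpec | None = None) -> ModelFit:
    """Dispatch: a single table goes to the configured estimator, a stratum
    mapping to :func:`fit_fused`."""
    spec = spec or ModelSpec()
    if isinstance(data, dict):
        return fit_fused(data, labels, spec)
    return _fit_single(data, labels, spec)


def predict(fit: ModelFit, table: pd.DataFrame) -> np.ndarray:
    """Per-sample predicted case probability, in input row order.

    The table must carry every training-feature column; extras are ignored
    with a warning.  Missing columns raise ``KeyError`` naming them — this
    drives the cross-timepoint transfer contract.
    """
    return fit.predict_proba(table)
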