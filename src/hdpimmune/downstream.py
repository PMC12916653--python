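"""Downstream analyses: univariate persistence, confounders, subtypes.

The sparse multivariable models are statistically stringent; a complementary
univariate screen (two-sided Mann-Whitney per feature, unadjusted alpha =
0.05, with Benjamini-Hochberg q-values reported alongside for transparency)
identifies case/control-different features per cohort.  Intersecting the
per-cohort significant sets across the three cohorts yields the 7-region
Venn decomposition and the *persistent* features found in every cohort.

Confounder adjustment refits the outcome on the cross-validated model
predictions jointly with candidate confounders (BMI, parity, maternal age,
gestational diabetes, blood pressure, visit timing); per-term drop-one
likelihood-ratio tests decide whether the model remains significantly
predictive once confounders are accounted for.  A linear auxiliary model of
the predictions on the confounders, with per-term F statistics, is reported
alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import mann_whitney_p

__all__ = ["PersistenceConfig", "PersistenceReport", "univariate_screen",
           "persistence_venn", "confounder_adjustment", "subtype_stratify",
           "riskfactor_correlation"]

DEFAULT_CONFOUNDERS = ("bmi", "parity", "age", "gestational_diabetes",
                       "systolic", "diastolic", "visit_timing")


@dataclass(frozen=True)
class PersistenceConfig:
    alpha: float = 0.05
    cohorts: tuple[str, ...] = ("AP", "PP", "ML")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def univariate_screen(table: pd.DataFrame, labels,
                      config: PersistenceConfig | None = None) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney screen of cases vs controls.

    Returns one row per feature with the p-value, the direction (sign of
    case median minus control median), a significance flag at the
    unadjusted alpha, and a Benjamini-Hochberg q-value.  Constant features
    get p = 1 and direction 0.
    """
    config = config or PersistenceConfig()
    y = np.asarray(labels)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")
    case = table.loc[y == 1]
    control = table.loc[y == 0]
    pvals = np.empty(table.shape[1])
    direction = np.empty(table.shape[1], dtype=int)
    for j, col in enumerate(table.columns):
        x1 = case[col].to_numpy(dtype=float)
        x0 = control[col].to_numpy(dtype=float)
        if np.unique(np.concatenate([x1, x0])).size == 1:
            pvals[j], direction[j] = 1.0, 0
            continue
        pvals[j] = mann_whitney_p(x1, x0)
        direction[j] = int(np.sign(np.median(x1) - np.median(x0)))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "feature": table.columns,
        "p_value": pvals,
        "direction": direction,
        "significant": pvals < config.alpha,
        "q_value": qvals,
    }).set_index("feature")


@dataclass
class PersistenceReport:
    """Venn decomposition of per-cohort significant feature sets."""

    cohorts: tuple[str, ...]
    significant: dict[str, set[str]]
    directions: dict[str, dict[str, int]]
    region_counts: dict[str, int]
    triple_intersection: list[str]
    pairwise: dict[tuple[str, str], list[str]]

    def triple_direction_consistent(self, feature: str) -> bool:
        d = {c: self.directions[c].get(feature, 0) for c in self.cohorts}
        signs = set(d.values())
        return len(signs) == 1 and 0 not in signs

    def to_dict(self) -> dict:
        return {
            "cohorts": list(self.cohorts),
            "region_counts": self.region_counts,
            "triple_intersection": [
                {"feature": f,
                 "directions": {c: self.directions[c].get(f, 0) for c in self.cohorts},
                 "direction_consistent": self.triple_direction_consistent(f)}
                for f in self.triple_intersection],
            "pairwise_intersections": {
                "&".join(k): sorted(v) for k, v in self.pairwise.items()},
            "n_significant": {c: len(self.significant[c]) for c in self.cohorts},
        }


def persistence_venn(reports: dict[str, pd.DataFrame],
                     config: PersistenceConfig | None = None) -> PersistenceReport:
    """Three-cohort Venn decomposition of univariate screen results.

    ``reports`` maps cohort label to the output of
    :func:`univariate_screen`; all screens must share one feature
    vocabulary.  The 7 Venn regions are keyed by membership pattern, e.g.
    ``"AP&PP"`` for features significant in exactly those two cohorts.
    """
    config = config or PersistenceConfig()
    cohorts = tuple(c for c in config.cohorts if c in reports)
    if len(cohorts) != 3:
        raise ValueError(f"need screens for three cohorts, got {sorted(reports)}")
    vocab = set(reports[cohorts[0]].index)
    for c in cohorts[1:]:
        if set(reports[c].index) != vocab:
            raise ValueError(f"cohort {c!r} has a different feature vocabulary")
    sig = {c: set(reports[c].index[reports[c]["significant"]]) for c in cohorts}
    directions = {c: reports[c]["direction"].to_dict() for c in cohorts}
    region_counts: dict[str, int] = {}
    union = set().union(*sig.values())
    for feature_set, key in _venn_regions(cohorts):
        members = union
        for c in cohorts:
            members = members & sig[c] if c in feature_set else members - sig[c]
        region_counts[key] = len(members)
    a, b, c3 = cohorts
    triple = sorted(sig[a] & sig[b] & sig[c3])
    pairwise = {
        (a, b): sorted(sig[a] & sig[b]),
        (a, c3): sorted(sig[a] & sig[c3]),
        (b, c3): sorted(sig[b] & sig[c3]),
    }
    return PersistenceReport(cohorts, sig, directions, region_counts, triple,
                             pairwise)


def _venn_regions(cohorts: tuple[str, ...]):
    a, b, c = cohorts
    yield {a}, a
    yield {b}, b
    yield {c}, c
    yield {a, b}, f"{a}&{b}"
    yield {a, c}, f"{a}&{c}"
    yield {b, c}, f"{b}&{c}"
    yield {a, b, c}, f"{a}&{b}&{c}"


def _logit_llf(endog: np.ndarray, exog: np.ndarray) -> tuple[float, object, bool]:
    """Fit a logistic model, falling back to a ridge-penalized fit under
    (quasi-)separation; returns (log-likelihood, result, penalized_flag)."""
    model = sm.Logit(endog, exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            if np.isfinite(res.llf) and np.all(np.isfinite(res.bse)):
                return float(res.llf), res, False
        except Exception:
            pass
        res = model.fit_regularized(method="l1", alpha=1e-4, disp=0,
                                    maxiter=500)
        return float(model.loglike(res.params)), res, True


def confounder_adjustment(predictions, outcome, confounders: pd.DataFrame,
                          alpha: float = 0.05) -> dict:
    """Joint logistic adjustment of model predictions for confounders.

    Fits ``outcome ~ prediction + confounders`` and reports per-term
    drop-one likelihood-ratio chi-square statistics and p-values; the model
    "remains significantly predictive" when the prediction term's p-value is
    below alpha.  An auxiliary linear model ``prediction ~ confounders``
    with per-term F statistics is reported alongside.  Rows with missing
    confounder values are dropped (count reported).
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(outcome, dtype=float)
    conf = confounders.apply(pd.to_numeric, errors="coerce")
    complete = ~conf.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    conf = conf.loc[complete.to_numpy()]
    pred, y = pred[complete.to_numpy()], y[complete.to_numpy()]

    terms = ["prediction"] + list(conf.columns)
    X = np.column_stack([np.ones(len(y)), pred, conf.to_numpy(dtype=float)])
    llf_full, res_full, penalized = _logit_llf(y, X)
    term_stats = {}
    for i, term in enumerate(terms, start=1):
        X_red = np.delete(X, i, axis=1)
        llf_red, _, pen_red = _logit_llf(y, X_red)
        lr = max(0.0, 2.0 * (llf_full - llf_red))
        term_stats[term] = {
            "lr_chi2": lr,
            "p_value": float(stats.chi2.sf(lr, df=1)),
            "coef": float(res_full.params[i]),
        }
    # auxiliary linear model: prediction ~ confounders, per-term F tests
    aux = sm.OLS(pred, sm.add_constant(conf.to_numpy(dtype=float))).fit()
    aux_f = {
        col: {"F": float(aux.tvalues[i + 1] ** 2),
              "p_value": float(aux.pvalues[i + 1])}
        for i, col in enumerate(conf.columns)
    }
    return {
        "terms": term_stats,
        "prediction_p_value": term_stats["prediction"]["p_value"],
        "remains_predictive": term_stats["prediction"]["p_value"] < alpha,
        "penalized_fallback": penalized,
        "n_dropped_missing": n_dropped,
        "auxiliary_linear_f": aux_f,
    }


def subtype_stratify(values, metadata: pd.DataFrame,
                     min_group: int = 5) -> dict:
    """Mann-Whitney contrasts of one persistent feature among HDP subtypes.

    Cases only.  Contrasts: early (<=34 wks) vs late onset; mild vs severe
    preeclampsia; gestational hypertension vs preeclampsia/HELLP.  Levels
    with fewer than 2 cases are skipped with a flag; groups below
    ``min_group`` carry an under-powered warning flag.
    """
    v = pd.Series(np.asarray(values, dtype=float), index=metadata.index)
    cases = metadata[metadata["outcome"] == 1]
    vc = v.loc[cases.index]
    out: dict[str, dict] = {}

    def _contrast(name: str, mask_a: pd.Series, mask_b: pd.Series,
                  label_a: str, label_b: str) -> None:
        a = vc[mask_a.to_numpy(dtype=bool)].dropna()
        b = vc[mask_b.to_numpy(dtype=bool)].dropna()
        if len(a) < 2 or len(b) < 2:
            out[name] = {"skipped": True,
                         "n": {label_a: int(len(a)), label_b: int(len(b))}}
            return
        out[name] = {
            "skipped": False,
            "p_value": mann_whitney_p(a.to_numpy(), b.to_numpy()),
            "n": {label_a: int(len(a)), label_b: int(len(b))},
            "underpowered": bool(min(len(a), len(b)) < min_group),
        }

    early = cases["early_onset"] == 1
    _contrast("early_vs_late_onset", early, ~early, "early", "late")
    sev = cases["severity"].astype(str)
    _contrast("mild_vs_severe", sev == "mild", sev == "severe", "mild", "severe")
    gh = cases["gest_htn"] == 1
    _contrast("gest_htn_vs_preeclampsia", gh, ~gh, "gest_htn", "pe_hellp")
    return out


def riskfactor_correlation(values, confounders: pd.DataFrame,
                           factors: tuple[str, ...] = ("bmi", "systolic",
                                                       "diastolic")) -> pd.DataFrame:
    """Spearman rank correlation of one feature against CVD risk factors."""
    v = np.asarray(values, dtype=float)
    rows = []
    for factor in factors:
        if factor not in confounders.columns:
            continue
        x = pd.to_numeric(confounders[factor], errors="coerce").to_numpy()
        ok = np.isfinite(v) & np.isfinite(x)
        if ok.sum() < 3:
            raise ValueError(f"need >= 3 paired observations for {factor!r}")
        if np.unique(v[ok]).size == 1 or np.unique(x[ok]).size == 1:
            rows.append({"factor": factor, "rho": np.nan, "p_value": np.nan,
                         "n": int(ok.sum()), "defined": False})
            continue
        rho, p = stats.spearmanr(v[ok], x[ok])
        rows.append({"factor": factor, "rho": float(rho), "p_value": float(p),
                     "n": int(ok.sum()), "defined": True})
    return pd.DataFrame(rows).set_index("factor")
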