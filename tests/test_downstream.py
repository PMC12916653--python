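"""Univariate screen, Venn persistence, confounders, subtypes, correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import planted_effects, small_config
from hdpimmune.downstream import (PersistenceConfig, confounder_adjustment,
                                  persistence_venn, riskfactor_correlation,
                                  subtype_stratify, univariate_screen)
from hdpimmune.evaluation import mann_whitney_p
from hdpimmune.synthetic import generate_confounders, generate_feature_table


def screen_frame(sig_features, all_features, directions=None):
    """Minimal screen result with the given significant feature ids."""
    directions = directions or {}
    return pd.DataFrame({
        "p_value": [0.01 if f in sig_features else 0.5 for f in all_features],
        "direction": [directions.get(f, 1) for f in all_features],
        "significant": [f in sig_features for f in all_features],
        "q_value": 0.5,
    }, index=pd.Index(all_features, name="feature"))


def venn_region_oracle(sets: dict[str, set], universe: set) -> dict[str, int]:
    """Region counts by exhaustive per-feature membership enumeration."""
    labels = list(sets)
    counts: dict[str, int] = {}
    for f in universe:
        member = [c for c in labels if f in sets[c]]
        if not member:
            continue
        key = "&".join(member)
        counts[key] = counts.get(key, 0) + 1
    for c in labels:
        counts.setdefault(c, 0)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            counts.setdefault(f"{a}&{b}", 0)
    counts.setdefault("&".join(labels), 0)
    return counts


class TestUnivariateScreen:
    def test_pvalues_match_single_implementation(self, rng):
        """Screen p-values equal mann_whitney_p feature by feature."""
        table = pd.DataFrame(rng.normal(size=(30, 5)),
                             columns=[f"f{j}" for j in range(5)])
        y = np.array([1, 0] * 15)
        screen = univariate_screen(table, y)
        for col in table.columns:
            expected = mann_whitney_p(table[col][y == 1].to_numpy(),
                                      table[col][y == 0].to_numpy())
            assert screen.loc[col, "p_value"] == expected

    def test_disjoint_supports_tiny_p(self, rng):
        table = pd.DataFrame({"sep": np.r_[rng.uniform(10, 11, 20),
                                           rng.uniform(0, 1, 20)],
                              "noise": rng.normal(size=40)})
        y = np.array([1] * 20 + [0] * 20)
        screen = univariate_screen(table, y)
        assert screen.loc["sep", "p_value"] < 1e-6
        assert screen.loc["sep", "direction"] == 1

    def test_constant_features_not_significant(self):
        table = pd.DataFrame({"c1": np.ones(20), "c2": np.full(20, 3.0)})
        y = np.array([1, 0] * 10)
        screen = univariate_screen(table, y)
        assert (screen["p_value"] == 1.0).all()
        assert (screen["direction"] == 0).all()
        assert not screen["significant"].any()

    def test_type_one_rate_calibrated(self):
        """Null data: the significant fraction stays near alpha."""
        rates = []
        for seed in range(10):
            table, meta = generate_feature_table(small_config(seed=seed))
            screen = univariate_screen(table, meta["outcome"].to_numpy())
            rates.append(screen["significant"].mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


class TestPersistenceVenn:
    FEATURES = [f"f{j}" for j in range(8)]

    def test_disjoint_sets_have_empty_intersections(self):
        reports = {
            "AP": screen_frame({"f0"}, self.FEATURES),
            "PP": screen_frame({"f1"}, self.FEATURES),
            "ML": screen_frame({"f2"}, self.FEATURES),
        }
        rep = persistence_venn(reports)
        assert rep.triple_intersection == []
        assert rep.region_counts["AP&PP&ML"] == 0
        assert rep.region_counts["AP"] == 1

    def test_matches_enumeration_oracle(self):
        sets = {"AP": {"f0", "f1", "f2"}, "PP": {"f1", "f2", "f3"},
                "ML": {"f2", "f4"}}
        reports = {c: screen_frame(s, self.FEATURES) for c, s in sets.items()}
        rep = persistence_venn(reports)
        oracle = venn_region_oracle(sets, set(self.FEATURES))
        # oracle counts exclusive regions; compare all 7
        assert rep.region_counts == oracle
        assert rep.triple_intersection == ["f2"]
        assert rep.region_counts["AP&PP"] == 1  # f1 only (f2 is in all three)

    def test_region_counts_sum_to_union(self, rng):
        sets = {c: set(rng.choice(self.FEATURES, size=4, replace=False))
                for c in ("AP", "PP", "ML")}
        reports = {c: screen_frame(s, self.FEATURES) for c, s in sets.items()}
        rep = persistence_venn(reports)
        assert sum(rep.region_counts.values()) == len(set().union(*sets.values()))

    def test_mismatched_vocabulary_rejected(self):
        reports = {
            "AP": screen_frame(set(), self.FEATURES),
            "PP": screen_frame(set(), self.FEATURES),
            "ML": screen_frame(set(), self.FEATURES[:-1]),
        }
        with pytest.raises(ValueError, match="vocabulary"):
            persistence_venn(reports)

    def test_planted_persistent_features_in_triple(self):
        """Two features planted in all three cohorts land in the triple
        intersection (effect 1.5, n=40/arm)."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            screens = {}
            for k, cohort in enumerate(("AP", "PP", "ML")):
                cfg = small_config(seed=seed * 10 + k, n_cases=40, n_controls=40,
                                   cohort=cohort, effects=planted_effects(1.5, n=2))
                table, meta = generate_feature_table(cfg)
                screens[cohort] = univariate_screen(table, meta["outcome"].to_numpy())
            rep = persistence_venn(screens)
            planted = {e.feature for e in planted_effects(1.5, n=2)}
            hits += planted <= set(rep.triple_intersection)
        assert hits >= 4


class TestConfounderAdjustment:
    def test_zero_confounders_reduces_to_single_covariate_lrt(self, rng):
        n = 80
        pred = rng.uniform(0.1, 0.9, n)
        y = rng.binomial(1, pred)
        res = confounder_adjustment(pred, y, pd.DataFrame(index=range(n)))
        import statsmodels.api as sm
        X = sm.add_constant(pred)
        full = sm.Logit(y, X).fit(disp=0)
        null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        lr = 2 * (full.llf - null.llf)
        expected = stats.chi2.sf(lr, df=1)
        assert res["prediction_p_value"] == pytest.approx(expected, rel=1e-6)

    def test_null_confounder_p_uniform(self):
        """A confounder independent of predictions yields uniform p-values."""
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            n = 80
            pred = rng.uniform(0.2, 0.8, n)
            y = rng.binomial(1, pred)
            conf = pd.DataFrame({"bmi": rng.normal(27, 5, n)})
            res = confounder_adjustment(pred, y, conf)
            pvals.append(res["terms"]["bmi"]["p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_full_confounding_removes_prediction_signal(self):
        """When predictions are a deterministic function of BMI and outcome is
        driven by BMI, the prediction term loses significance."""
        nonsig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 500)
            n = 100
            bmi = rng.normal(28, 5, n)
            z = (bmi - 28) / 5
            y = rng.binomial(1, 1 / (1 + np.exp(-1.5 * z)))
            pred = 1 / (1 + np.exp(-z))  # BMI alone
            res = confounder_adjustment(pred, y, pd.DataFrame({"bmi": bmi}))
            nonsig += res["prediction_p_value"] > 0.05
        assert nonsig >= 8

    def test_missing_rows_dropped_and_counted(self, rng):
        n = 50
        pred = rng.uniform(0.2, 0.8, n)
        y = rng.binomial(1, pred)
        conf = pd.DataFrame({"bmi": rng.normal(27, 4, n)})
        conf.iloc[3, 0] = np.nan
        res = confounder_adjustment(pred, y, conf)
        assert res["n_dropped_missing"] == 1

    def test_auxiliary_linear_f_reported(self, rng):
        n = 60
        bmi = rng.normal(28, 5, n)
        pred = 0.5 + 0.02 * (bmi - 28) + rng.normal(0, 0.05, n)
        y = rng.binomial(1, 0.5, n)
        res = confounder_adjustment(pred, y, pd.DataFrame({"bmi": bmi}))
        assert res["auxiliary_linear_f"]["bmi"]["p_value"] < 0.05


class TestSubtypeStratify:
    def _meta(self, n_cases=30, seed=0):
        cfg = small_config(seed=seed, n_cases=n_cases, n_controls=20)
        return generate_confounders(cfg)

    def test_null_contrasts_mostly_non_significant(self):
        """Identical subtype distributions: each contrast stays above
        p = 0.05 in at least ~90% of null replicates."""
        outcomes = []
        for seed in range(30):
            meta = self._meta(seed=seed)
            rng = np.random.default_rng(seed)
            res = subtype_stratify(rng.normal(size=len(meta)), meta)
            outcomes.extend(r["p_value"] > 0.05 for r in res.values()
                            if not r["skipped"])
        assert np.mean(outcomes) >= 0.85

    def test_single_member_level_skipped(self):
        meta = self._meta(n_cases=30, seed=1).copy()
        cases = meta["outcome"] == 1
        meta.loc[cases, "early_onset"] = 0.0
        first_case = meta.index[cases][0]
        meta.loc[first_case, "early_onset"] = 1.0
        res = subtype_stratify(np.zeros(len(meta)), meta)
        assert res["early_vs_late_onset"]["skipped"]

    def test_planted_subtype_shift_detected(self):
        """A 1.5 SD shift between onset groups reaches p < 0.05 in most seeds."""
        sig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            meta = self._meta(n_cases=30, seed=seed).copy()
            cases = meta["outcome"] == 1
            # force a balanced 15/15 onset split among cases
            idx = meta.index[cases]
            meta.loc[idx, "early_onset"] = ([1.0] * 15 + [0.0] * 15)[:len(idx)]
            rng = np.random.default_rng(seed + 900)
            v = rng.normal(size=len(meta))
            v[meta["early_onset"].to_numpy() == 1.0] += 1.5
            res = subtype_stratify(v, meta)
            sig += res["early_vs_late_onset"]["p_value"] < 0.05
        assert sig >= 8


class TestRiskfactorCorrelation:
    def test_identity_feature_has_rho_one(self, rng):
        conf = pd.DataFrame({"bmi": rng.normal(27, 4, 30)})
        res = riskfactor_correlation(conf["bmi"].to_numpy(), conf)
        assert res.loc["bmi", "rho"] == pytest.approx(1.0)

    def test_independent_feature_small_rho(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            conf = pd.DataFrame({"bmi": rng.normal(27, 4, 100)})
            res = riskfactor_correlation(rng.normal(size=100), conf)
            hits += abs(res.loc["bmi", "rho"]) < 0.2
        assert hits >= 9

    def test_five_point_worked_example(self):
        """Spearman rho on a worked 5-point set against the rank formula."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        bmi = np.array([30.0, 22.0, 28.0, 25.0, 35.0])
        conf = pd.DataFrame({"bmi": bmi})
        rx = stats.rankdata(x)
        rb = stats.rankdata(bmi)
        d2 = ((rx - rb) ** 2).sum()
        rho_formula = 1 - 6 * d2 / (5 * (25 - 1))  # no ties: classic formula
        res = riskfactor_correlation(x, conf)
        assert res.loc["bmi", "rho"] == pytest.approx(rho_formula, abs=1e-12)

    def test_constant_vector_flagged_undefined(self):
        conf = pd.DataFrame({"bmi": np.full(10, 25.0)})
        res = riskfactor_correlation(np.arange(10.0), conf)
        assert not res.loc["bmi", "defined"]

    def test_too_few_pairs_rejected(self):
        conf = pd.DataFrame({"bmi": [25.0, np.nan, np.nan, np.nan]})
        with pytest.raises(ValueError, match="bmi"):
            riskfactor_correlation(np.arange(4.0), conf)
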