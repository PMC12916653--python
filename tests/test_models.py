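"""Sparse classifiers: selection behavior, stability selection, fusion, predict."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import planted_effects, small_config
from hdpimmune.evaluation import auroc
from hdpimmune.models import (ModelSpec, fit_adaptive_lasso, fit_fused,
                              fit_lasso, fit_model, fit_stability_selected,
                              predict)


def separable_dataset(seed: int, n: int = 100, p: int = 50):
    """One feature tracking the labels perfectly, the rest pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array([1, 0] * (n // 2))
    X = rng.standard_normal((n, p))
    X[:, 0] = y * 2.0 + rng.standard_normal(n) * 0.05
    cols = [f"f{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestLasso:
    def test_separating_feature_selected(self):
        hits = 0
        for seed in range(10):
            table, y = separable_dataset(seed)
            fit = fit_lasso(table, y, ModelSpec(seed=seed))
            hits += "f0" in fit.selected_features
        assert hits >= 9

    def test_permuted_labels_near_chance(self):
        """Training AUROC of the fit under permuted labels is unremarkable
        out of sample (checked via held-out split)."""
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(6):
            table, y = separable_dataset(seed, n=120)
            yp = rng.permutation(y)
            fit = fit_lasso(table.iloc[:80], yp[:80], ModelSpec(seed=seed))
            aucs.append(auroc(predict(fit, table.iloc[80:]), yp[80:]))
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_infinite_penalty_gives_intercept_only(self):
        table, y = separable_dataset(0)
        y = np.array([1] * 30 + [0] * 70)  # unbalanced prevalence 0.3
        spec = ModelSpec(path_min_log10=-6, path_max_log10=-6, path_length=1)
        fit = fit_lasso(table, y, spec)
        assert fit.selected_features == []
        p = predict(fit, table)
        assert np.allclose(p, p[0])
        assert p[0] == pytest.approx(0.3, abs=0.05)

    def test_single_class_rejected(self):
        table, _ = separable_dataset(0)
        with pytest.raises(ValueError, match="per class"):
            fit_lasso(table, np.ones(len(table)), ModelSpec())

    def test_scale_equivariance(self):
        """Multiplying a feature column by 10 leaves predictions unchanged."""
        table, y = separable_dataset(3)
        fit1 = fit_lasso(table, y, ModelSpec(seed=1))
        scaled = table.copy()
        scaled["f0"] = scaled["f0"] * 10.0
        fit2 = fit_lasso(scaled, y, ModelSpec(seed=1))
        np.testing.assert_allclose(predict(fit1, table), predict(fit2, scaled),
                                   atol=1e-8)

    def test_sparsity_monotone_along_path(self):
        """Stronger L1 penalty never grows the selected set."""
        from hdpimmune.models import _l1_logistic, _standardize
        table, y = separable_dataset(7, n=80, p=40)
        Xs, _, _ = _standardize(table.to_numpy(), True)
        sizes = []
        for C in np.logspace(-3, 1, 15):
            clf = _l1_logistic(Xs, y, C)
            sizes.append(int((clf.coef_ != 0).sum()))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_leakage_guard_outlier_in_test_fold(self):
        """A wild outlier outside the training rows cannot move the fit."""
        table, y = separable_dataset(5)
        fit_clean = fit_lasso(table.iloc[:80], y[:80], ModelSpec(seed=2))
        poisoned = table.copy()
        poisoned.iloc[95] = 1e6  # test-only row
        fit_poisoned = fit_lasso(poisoned.iloc[:80], y[:80], ModelSpec(seed=2))
        # a leaked outlier would move the scaler mean by ~1e4; only float
        # summation-order noise is tolerated
        np.testing.assert_allclose(fit_clean.coef, fit_poisoned.coef, atol=1e-9)
        np.testing.assert_allclose(fit_clean.scaler_mean, fit_poisoned.scaler_mean,
                                   atol=1e-9)


class TestAdaptiveLasso:
    def test_gamma_zero_reduces_to_plain_lasso(self):
        table, y = separable_dataset(1)
        plain = fit_lasso(table, y, ModelSpec(estimator="lasso", seed=4))
        degenerate = fit_adaptive_lasso(
            table, y, ModelSpec(estimator="adaptive_lasso", gamma=0.0, seed=4))
        assert set(plain.selected_features) == set(degenerate.selected_features)

    def test_no_sparser_than_lasso_rarely(self):
        """Adaptive weighting sparsifies: selected set usually no larger."""
        wins = 0
        for seed in range(10):
            table, y = separable_dataset(seed)
            nl = fit_lasso(table, y, ModelSpec(seed=seed)).n_selected()
            na = fit_adaptive_lasso(
                table, y, ModelSpec(estimator="adaptive_lasso", seed=seed)).n_selected()
            wins += na <= nl
        assert wins >= 8


class TestStabilitySelection:
    def test_pure_noise_selects_nothing_mostly(self):
        empty = 0
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            table = pd.DataFrame(rng.standard_normal((60, 80)),
                                 columns=[f"f{j}" for j in range(80)])
            y = np.array([1, 0] * 30)
            fit = fit_stability_selected(
                table, y, ModelSpec(estimator="stabl_lasso", seed=seed))
            empty += fit.n_selected() == 0
        assert empty >= 8

    def test_planted_features_pass_threshold(self):
        """5 planted features at effect 2.0 (n=80, p=200) are all recovered
        in >= 90% of seeds."""
        full = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 300)
            y = np.array([1, 0] * 40)
            X = rng.standard_normal((80, 200))
            X[:, :5] += 2.0 * y[:, None]
            table = pd.DataFrame(X, columns=[f"f{j}" for j in range(200)])
            fit = fit_stability_selected(
                table, y, ModelSpec(estimator="stabl_lasso", seed=seed))
            full += set(f"f{j}" for j in range(5)) <= set(fit.selected_features)
        assert full / n_seeds >= 0.9

    def test_unreachable_threshold_gives_empty_model(self):
        table, y = separable_dataset(2)
        fit = fit_stability_selected(
            table, y, ModelSpec(estimator="stabl_lasso", threshold=1.01, seed=0))
        assert fit.n_selected() == 0
        assert np.allclose(predict(fit, table), y.mean(), atol=1e-9)

    def test_invalid_stability_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(estimator="stabl_lasso", n_subsamples=1)
        with pytest.raises(ValueError):
            ModelSpec(estimator="stabl_lasso", decoys_per_feature=0)


class TestFusion:
    def _strata(self, seed: int, informative: bool = True):
        rng = np.random.default_rng(seed)
        y = np.array([1, 0] * 30)
        idx = pd.Index([f"s{i}" for i in range(60)], name="sample_id")
        a = rng.standard_normal((60, 20))
        if informative:
            a[:, :4] += 1.8 * y[:, None]
        b = rng.standard_normal((60, 20))
        sa = pd.DataFrame(a, index=idx, columns=[f"a{j}" for j in range(20)])
        sb = pd.DataFrame(b, index=idx, columns=[f"b{j}" for j in range(20)])
        return sa, sb, y

    def test_single_stratum_late_close_to_early(self):
        from hdpimmune.evaluation import CVConfig, repeated_cv
        sa, _, y = self._strata(0)
        early = repeated_cv({"a": sa}, y, ModelSpec(fusion="early"),
                            CVConfig(n_repeats=3, seed=5))
        late = repeated_cv({"a": sa}, y, ModelSpec(fusion="late"),
                           CVConfig(n_repeats=3, seed=5))
        assert abs(early.median_auroc - late.median_auroc) <= 0.02

    def test_noise_stratum_does_not_hurt_late_fusion(self):
        from hdpimmune.evaluation import CVConfig, repeated_cv
        sa, sb, y = self._strata(1)
        alone = repeated_cv({"a": sa}, y, ModelSpec(fusion="late"),
                            CVConfig(n_repeats=3, seed=6))
        fused = repeated_cv({"a": sa, "b": sb}, y, ModelSpec(fusion="late"),
                            CVConfig(n_repeats=3, seed=6))
        assert abs(fused.median_auroc - alone.median_auroc) <= 0.05

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_fused({}, np.array([1, 0]))

    def test_mismatched_samples_rejected(self):
        sa, sb, y = self._strata(2)
        sb = sb.iloc[:-1]
        with pytest.raises(ValueError, match="differ"):
            fit_fused({"a": sa, "b": sb}, y, ModelSpec(fusion="late"))


class TestPredict:
    def test_training_probabilities_reproducible(self):
        table, y = separable_dataset(4)
        fit = fit_lasso(table, y, ModelSpec(seed=0))
        np.testing.assert_array_equal(predict(fit, table), predict(fit, table))

    def test_row_permutation_permutes_outputs(self):
        table, y = separable_dataset(4)
        fit = fit_lasso(table, y, ModelSpec(seed=0))
        perm = np.random.default_rng(1).permutation(len(table))
        np.testing.assert_allclose(predict(fit, table.iloc[perm]),
                                   predict(fit, table)[perm])

    def test_missing_column_named_in_error(self):
        table, y = separable_dataset(4)
        fit = fit_lasso(table, y, ModelSpec(seed=0))
        with pytest.raises(KeyError, match="f0"):
            predict(fit, table.drop(columns=["f0"]))

    def test_extra_columns_warn_and_are_ignored(self):
        table, y = separable_dataset(4)
        fit = fit_lasso(table, y, ModelSpec(seed=0))
        extra = table.copy()
        extra["junk"] = 1.0
        with pytest.warns(UserWarning, match="extra"):
            p = predict(fit, extra)
        np.testing.assert_allclose(p, predict(fit, table))

    def test_fit_model_dispatch(self):
        table, y = separable_dataset(6)
        single = fit_model(table, y, ModelSpec(seed=1))
        fused = fit_model({"only": table}, y, ModelSpec(fusion="late", seed=1))
        assert single.stratum_fits is None
        assert fused.stratum_fits is not None
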