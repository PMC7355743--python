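"""Linear/logistic association models, scans, selection and FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from _oracles import odds_ratio_2x2, table_2x2_from, woolf_se_2x2
from pedigrs import assoc
from pedigrs.containers import DosageMatrix
from pedigrs.errors import DataError, SeparationError


class TestFitLinear:
    def test_exact_relationship_recovered(self):
        x = pd.Series(np.arange(10.0))
        res, ve = assoc.fit_linear(2.0 * x, x)
        assert res.estimate == pytest.approx(2.0, abs=1e-10)
        assert ve.full_model_r2 == pytest.approx(1.0, abs=1e-10)

    def test_permuted_exposure_is_null(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=400))
        x = pd.Series(rng.permutation(y.to_numpy()))
        res, _ = assoc.fit_linear(y, x)
        assert abs(res.estimate) < 2 * res.se

    def test_standardized_estimate_equals_pearson_r(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(size=300))
        y = 0.4 * x + pd.Series(rng.normal(size=300))
        res, _ = assoc.fit_linear(y, x)
        r = np.corrcoef(x, y)[0, 1]
        assert res.estimate * x.std() / y.std() == pytest.approx(r, abs=1e-10)

    def test_ci_covers_and_brackets_estimate(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=500))
        y = 1.5 * x + pd.Series(rng.normal(size=500))
        res, _ = assoc.fit_linear(y, x)
        assert res.ci_lo <= res.estimate <= res.ci_hi

    def test_collinear_covariates_error_names_columns(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.normal(size=50))
        cov = pd.DataFrame({"a": x * 2.0})
        with pytest.raises(DataError, match="rank deficient"):
            assoc.fit_linear(pd.Series(rng.normal(size=50)), x, cov)

    def test_constant_exposure_rejected(self):
        with pytest.raises(DataError, match="constant"):
            assoc.fit_linear(pd.Series(np.arange(10.0)),
                             pd.Series(np.ones(10)))


class TestFitLogistic:
    def test_null_exposure_or_near_one(self):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.integers(0, 2, 600))
        x = pd.Series(rng.normal(size=600))
        res, _ = assoc.fit_logistic(y, x)
        assert res.ci_lo <= 0.0 <= res.ci_hi  # log-OR CI covers zero

    def test_per_tenth_or_identity(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=500))
        logit = -0.5 + 1.2 * x
        y = pd.Series((rng.random(500) < 1 / (1 + np.exp(-logit))).astype(int))
        res, _ = assoc.fit_logistic(y, x)
        assert res.odds_ratio_per_tenth == pytest.approx(
            np.exp(res.estimate / 10), abs=1e-12
        )

    def test_large_effect_scale_recovered(self):
        """A log-OR of 3.86 per score unit (odds ratio ~47) is the scale a
        strongly predictive weighted score reaches; it must be recovered."""
        rng = np.random.default_rng(6)
        x = pd.Series(rng.normal(1.18, 0.13, 5000))
        logit = -4.9 + 3.86 * x
        y = pd.Series((rng.random(5000) < 1 / (1 + np.exp(-logit))).astype(int))
        res, _ = assoc.fit_logistic(y, x)
        assert abs(res.estimate - 3.86) < 2 * res.se

    def test_binary_exposure_matches_2x2_closed_forms(self):
        rng = np.random.default_rng(7)
        x = pd.Series(rng.integers(0, 2, 800))
        logit = -1.0 + 0.9 * x
        y = pd.Series((rng.random(800) < 1 / (1 + np.exp(-logit))).astype(int))
        res, _ = assoc.fit_logistic(y, x)
        a, b, c, d = table_2x2_from(x, y)
        assert res.odds_ratio == pytest.approx(odds_ratio_2x2(a, b, c, d),
                                               abs=1e-8)
        assert res.se == pytest.approx(woolf_se_2x2(a, b, c, d), abs=1e-8)

    def test_perfect_separation_raises(self):
        y = pd.Series([0.0] * 25 + [1.0] * 25)
        x = pd.Series(np.r_[np.zeros(25), np.ones(25)])
        with pytest.raises(SeparationError):
            assoc.fit_logistic(y, x)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            assoc.fit_logistic(pd.Series(np.zeros(20)),
                               pd.Series(np.arange(20.0)))


class TestQuantileContrast:
    @staticmethod
    def _simulate(seed, slope):
        rng = np.random.default_rng(seed)
        s = pd.Series(rng.normal(size=900))
        from pedigrs import score as score_mod

        strata = score_mod.quantile_strata(s, 4)
        logit = -1.0 + slope * s
        y = pd.Series((rng.random(900) < 1 / (1 + np.exp(-logit))).astype(int))
        return y, strata

    def test_null_rates_cover_or_one(self):
        y, strata = self._simulate(8, 0.0)
        results = assoc.quantile_contrast(y, strata, reference="Q1")
        for res in results.values():
            assert res.ci_lo <= 0.0 <= res.ci_hi

    def test_two_by_two_collapse_equals_cross_product_ratio(self):
        y, strata = self._simulate(9, 0.8)
        collapsed = strata.map(lambda q: "top" if q == "Q4" else "rest")
        results = assoc.quantile_contrast(y, collapsed, reference="rest")
        a, b, c, d = table_2x2_from((strata == "Q4").astype(int), y)
        assert results["top"].odds_ratio == pytest.approx(
            odds_ratio_2x2(a, b, c, d), abs=1e-6
        )

    def test_monotone_risk_gives_monotone_odds_in_expectation(self):
        logors = np.zeros(3)
        for seed in range(40):
            y, strata = self._simulate(100 + seed, 0.8)
            results = assoc.quantile_contrast(y, strata, reference="Q1")
            logors += [results[q].estimate for q in ("Q2", "Q3", "Q4")]
        assert logors[0] < logors[1] < logors[2]

    def test_missing_reference_is_an_error(self):
        y, strata = self._simulate(10, 0.0)
        with pytest.raises(DataError):
            assoc.quantile_contrast(y, strata, reference="Q9")


def _dosage_frame(rng, n, m):
    values = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    return DosageMatrix(
        individuals=[f"i{i}" for i in range(n)],
        snps=[f"s{j}" for j in range(m)],
        values=values,
        mask=np.zeros((n, m), bool),
    )


class TestPerSnpScan:
    def test_row_per_snp(self):
        rng = np.random.default_rng(11)
        d = _dosage_frame(rng, 300, 7)
        y = pd.Series(rng.normal(size=300), index=d.individuals)
        table = assoc.per_snp_scan(d, y)
        assert len(table) == 7 and table["error"].isna().all()

    def test_null_scan_hit_rate_near_alpha(self):
        hits = 0
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            d = _dosage_frame(rng, 300, 44)
            y = pd.Series(rng.normal(size=300), index=d.individuals)
            table = assoc.per_snp_scan(d, y)
            hits += int((table["p"] < 0.05).sum())
            total += 44
        # expected 5%; allow generous binomial slack around 22/440
        assert 8 <= hits <= 40

    def test_causal_snp_tops_the_adjusted_ranking(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            d = _dosage_frame(rng, 400, 15)
            y = pd.Series(0.8 * d.values[:, 3] + rng.normal(size=400),
                          index=d.individuals)
            table = assoc.per_snp_scan(d, y)
            if table.sort_values("fdr").iloc[0]["snp_id"] == "s3":
                wins += 1
        assert wins >= 9


class TestStepwiseAic:
    def test_strong_causal_snp_is_selected(self):
        found = 0
        for seed in range(5):
            rng = np.random.default_rng(400 + seed)
            d = _dosage_frame(rng, 500, 10)
            frame = d.to_frame()
            frame.index = pd.Index(d.individuals)
            y = pd.Series(0.7 * frame["s4"] + rng.normal(size=500),
                          index=frame.index)
            if "s4" in assoc.stepwise_aic(y, frame):
                found += 1
        assert found == 5

    def test_all_null_selection_is_sparse(self):
        """Under the null, AIC admits each candidate with probability
        P(chi2_1 > 2) ~ 0.157, so with two candidates the selected set is
        empty in the majority of runs and with eight candidates the mean
        number selected stays near 8 * 0.157."""
        empties = 0
        for seed in range(11):
            rng = np.random.default_rng(500 + seed)
            d = _dosage_frame(rng, 600, 2)
            frame = d.to_frame()
            frame.index = pd.Index(d.individuals)
            y = pd.Series(rng.normal(size=600), index=frame.index)
            if not assoc.stepwise_aic(y, frame):
                empties += 1
        assert empties >= 6

        n_selected = []
        for seed in range(11):
            rng = np.random.default_rng(600 + seed)
            d = _dosage_frame(rng, 600, 8)
            frame = d.to_frame()
            frame.index = pd.Index(d.individuals)
            y = pd.Series(rng.normal(size=600), index=frame.index)
            n_selected.append(len(assoc.stepwise_aic(y, frame)))
        assert np.mean(n_selected) < 3.5

    def test_selected_model_beats_full_and_empty(self):
        rng = np.random.default_rng(12)
        d = _dosage_frame(rng, 400, 8)
        frame = d.to_frame()
        frame.index = pd.Index(d.individuals)
        y = pd.Series(0.5 * frame["s1"] - 0.4 * frame["s6"]
                      + rng.normal(size=400), index=frame.index)
        selected = assoc.stepwise_aic(y, frame)

        def aic(cols):
            X = sm.add_constant(frame[cols]) if cols else \
                pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
            return sm.OLS(y, X).fit().aic

        assert aic(selected) <= aic(list(frame.columns)) + 1e-9
        assert aic(selected) <= aic([]) + 1e-9


class TestBhFdr:
    def test_equal_pvalues_stay_equal(self):
        np.testing.assert_allclose(assoc.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-6, 1, 100)
        q = assoc.bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_order_preserving_on_sorted_input(self):
        rng = np.random.default_rng(14)
        p = np.sort(rng.uniform(1e-6, 1, 50))
        q = assoc.bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [0.1, np.nan], []])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(DataError):
            assoc.bh_fdr(bad)


class TestVarianceExplained:
    def test_reduced_equals_full_gives_zero(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        X = sm.add_constant(pd.DataFrame({"x": x}))
        fit = sm.OLS(y, X).fit()
        ve = assoc.variance_explained(fit, fit)
        assert ve.component_r2 == pytest.approx(0.0, abs=1e-12)

    def test_noise_exposure_contributes_nothing(self):
        rng = np.random.default_rng(16)
        n = 4000
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        full = sm.OLS(y, sm.add_constant(pd.DataFrame({"x": x, "z": noise}))).fit()
        red = sm.OLS(y, sm.add_constant(pd.DataFrame({"x": x}))).fit()
        ve = assoc.variance_explained(full, red)
        assert ve.component_r2 == pytest.approx(0.0, abs=0.005)

    def test_different_n_is_an_error(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=50)
        fit1 = sm.OLS(y, np.ones((50, 1))).fit()
        fit2 = sm.OLS(y[:40], np.ones((40, 1))).fit()
        with pytest.raises(DataError):
            assoc.variance_explained(fit1, fit2)
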