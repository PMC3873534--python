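import numpy as np
import pandas as pd
import pytest
from math import comb
from scipy import stats

from hhspike.popstats import (
    anesthesia_glm,
    binomial_fraction_test,
    classify_rates,
    fast_pair_enrichment,
    fit_gmm_aic,
    heterogeneity_tests,
    residual_multimodality,
)


class TestGMM:
    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_gmm_aic(np.arange(5))

    def test_single_gaussian_selects_one_component(self):
        rng = np.random.default_rng(0)
        hits = sum(
            fit_gmm_aic(rng.normal(10, 2, 200), seed=s).n_components == 1
            for s in range(10)
        )
        assert hits >= 8

    def test_weights_and_assignments_partition(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(10, 1, 100),
                            [np.inf, np.nan]])
        fit = fit_gmm_aic(x, seed=0)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert fit.assignments.size == 200  # non-finite excluded
        assert set(fit.assignments) <= set(range(fit.n_components))

    def test_constant_sample_single_floored_component(self):
        fit = fit_gmm_aic(np.full(20, 3.0))
        assert fit.n_components == 1
        assert fit.sds[0] > 0


class TestClassifyRates:
    def test_examples(self):
        assert list(classify_rates([0.6, 15.0])) == ["slow", "fast"]

    def test_boundary_is_fast(self):
        assert classify_rates([2.0])[0] == "fast"

    def test_empty(self):
        assert classify_rates([]).size == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_rates([-1.0])


class TestBinomial:
    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.02, 0.5))
            pmf = np.array([stats.binom.pmf(j, n, p0) for j in range(n + 1)])
            # two-sided minimum-likelihood method
            expect = pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()
            assert binomial_fraction_test(k, n, p0) == pytest.approx(
                min(expect, 1.0), rel=1e-6
            )

    def test_observed_pair_counts_overwhelm_chance(self):
        assert binomial_fraction_test(417, 813, 0.05) < 1e-15

    def test_chance_level_counts_not_significant(self):
        # expectation at the 5% level is ~40.7 of 813
        assert binomial_fraction_test(41, 813, 0.05) > 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binomial_fraction_test(0, 0)


class TestFisher:
    def test_closed_form_diagonal_table(self):
        pairs = pd.DataFrame(
            {
                "unit_a": [f"f{i}" for i in range(10)] + [f"s{i}" for i in range(10)],
                "unit_b": [f"f{i}" for i in range(10, 20)] + [f"s{i}" for i in range(10, 20)],
                "significant": [True] * 10 + [False] * 10,
            }
        )
        classes = {f"f{i}": "fast" for i in range(20)}
        classes.update({f"s{i}": "slow" for i in range(20)})
        p, odds, table = fast_pair_enrichment(pairs, classes)
        assert p == pytest.approx(2.0 / comb(20, 10), rel=1e-9)

    def test_independent_classes_not_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for rep in range(20):
            n = 120
            fast = rng.random(n) < 0.5
            sig = rng.random(n) < 0.3  # independent of class
            pairs = pd.DataFrame(
                {
                    "unit_a": [f"a{i}" for i in range(n)],
                    "unit_b": [f"b{i}" for i in range(n)],
                    "significant": sig,
                }
            )
            classes = {}
            for i in range(n):
                classes[f"a{i}"] = "fast" if fast[i] else "slow"
                classes[f"b{i}"] = "fast"
            p, _, _ = fast_pair_enrichment(pairs, classes)
            hits += p > 0.05
        assert hits >= 18

    def test_degenerate_margin_rejected(self):
        pairs = pd.DataFrame(
            {"unit_a": ["a"], "unit_b": ["b"], "significant": [True]}
        )
        with pytest.raises(ValueError):
            fast_pair_enrichment(pairs, {"a": "fast", "b": "fast"})


class TestHeterogeneity:
    def _pairs(self, fractions, per_patient=20):
        rows = []
        for p_idx, f in enumerate(fractions):
            n_sig = int(round(f * per_patient))
            for k in range(per_patient):
                rows.append(
                    {
                        "patient_id": f"P{p_idx}",
                        "epoch_id": f"P{p_idx}-E{k % 2}",
                        "significant": k < n_sig,
                    }
                )
        return pd.DataFrame(rows)

    def test_extreme_heterogeneity_significant(self):
        pairs = self._pairs([1.0, 0.0, 0.0, 0.0, 0.0])
        res = heterogeneity_tests(pairs)
        # closed form: one patient all-significant among five -> chi2 = N·...
        tab = pd.crosstab(pairs["patient_id"], pairs["significant"]).to_numpy()
        chi2_expected = stats.chi2_contingency(tab, correction=False)[0]
        assert res["between_patients_chi2"] == pytest.approx(chi2_expected)
        assert res["between_patients_p"] < 1e-6

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(100):
            rows = []
            for p_idx in range(5):
                for k in range(30):
                    rows.append(
                        {
                            "patient_id": f"P{p_idx}",
                            "epoch_id": f"P{p_idx}-E{k % 2}",
                            "significant": bool(rng.random() < 0.3),
                        }
                    )
            ps.append(heterogeneity_tests(pd.DataFrame(rows))["between_patients_p"])
        # Kolmogorov-Smirnov against uniform (chi-square null is asymptotic)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        pairs = self._pairs([0.5])
        with pytest.raises(ValueError):
            heterogeneity_tests(pairs)


def _covariates(n, rng, midazolam=None):
    if midazolam is None:
        midazolam = rng.random(n) < 0.5
    return pd.DataFrame(
        {
            "sevoflurane_pct": rng.uniform(0.5, 3.0, n),
            "temperature_c": rng.normal(36.5, 0.5, n),
            "minutes_since_last_change": rng.uniform(0, 30, n),
            "midazolam_at_induction": midazolam,
            "propofol_at_induction": rng.random(n) < 0.5,
            "decadron_use": rng.random(n) < 0.3,
            "fentanyl_use": rng.choice(["induction", "intervals", "none"], n),
            "gas_carrier": rng.choice(["air", "NO", "neither"], n),
        }
    )


class TestGLM:
    def test_effect_recovery(self):
        rng = np.random.default_rng(0)
        n = 200
        cov = _covariates(n, rng)
        y = 20.0 + 11.0 * cov["midazolam_at_induction"].to_numpy() + rng.normal(0, 5, n)
        report = anesthesia_glm(y, cov)
        row = report.per_variable.set_index("variable").loc["midazolam_at_induction"]
        assert row["significant_after_fdr"]
        assert abs(row["effect"] - 11.0) <= 2.0

    def test_too_few_units_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            anesthesia_glm(np.ones(5), _covariates(5, rng))

    def test_constant_covariate_skipped(self):
        rng = np.random.default_rng(2)
        cov = _covariates(50, rng, midazolam=np.zeros(50, bool))
        report = anesthesia_glm(rng.normal(10, 2, 50), cov)
        row = report.per_variable.set_index("variable").loc["midazolam_at_induction"]
        assert np.isnan(row["p_value"])
        assert not row["significant_after_fdr"]

    def test_bh_rejects_at_least_bonferroni(self):
        rng = np.random.default_rng(3)
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            ps = rng.random(8) ** 2  # some small p-values
            bh = multipletests(ps, alpha=0.2, method="fdr_bh")[0].sum()
            bonf = (ps < 0.2 / ps.size).sum()
            assert bh >= bonf


class TestResidualDip:
    def test_two_class_residuals_stay_bimodal(self):
        rng = np.random.default_rng(4)
        n = 222
        cov = _covariates(n, rng)
        classes = rng.random(n) < 0.5
        y = np.where(classes, rng.normal(15, 2, n), rng.normal(0.6, 0.2, n))
        y = y + 0.5 * cov["sevoflurane_pct"].to_numpy()
        report = anesthesia_glm(y, cov)
        res = residual_multimodality(report, n_reference=500, seed=0)
        assert res.p_value < 0.05

    def test_degenerate_input_propagates(self):
        rng = np.random.default_rng(5)
        report = anesthesia_glm(rng.normal(5, 1, 12), _covariates(12, rng))
        report.residuals = report.residuals[:3]
        with pytest.raises(ValueError):
            residual_multimodality(report)
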