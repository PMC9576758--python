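"""Response orientation, nested OLS likelihood-ratio tests, and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenocopy import (
    SyntheticConfig,
    adjust_fdr,
    fit_nested_models,
    fit_three_predictor_model,
    generate_cohort,
    orient_response,
)
from phenocopy.response import NestedModelResult


def gaussian_ml_loglik(y, X):
    """Independent oracle: profile Gaussian log-likelihood of an OLS fit,
    computed from first principles via lstsq residuals."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n = y.size
    return -n / 2 * (np.log(2 * np.pi * rss / n) + 1)


def response_table(values, kinds):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(len(values))],
            "drug_id": "d1",
            "value": values,
            "metric_kind": kinds,
            "dataset_tag": "t",
        }
    )


class TestOrientation:
    def test_act_area_negated_so_lower_means_sensitive(self):
        table = response_table([1.0, 3.0], ["act_area", "act_area"])
        out = orient_response(table)
        assert out["value"].tolist() == [-1.0, -3.0]
        # the sample with the larger activity area is now the most sensitive
        assert out["value"].idxmin() == 1

    def test_ic50_z_and_auc_pass_through(self):
        table = response_table([0.5, -0.2], ["ic50_z", "auc"])
        out = orient_response(table)
        assert out["value"].tolist() == [0.5, -0.2]

    def test_orientation_is_idempotent(self):
        table = response_table([1.0, 3.0], ["act_area", "act_area"])
        once = orient_response(table)
        twice = orient_response(once)
        assert twice["value"].tolist() == once["value"].tolist()

    def test_unknown_metric_kind_raises(self):
        table = response_table([1.0], ["viability"])
        with pytest.raises(ValueError, match="metric_kind"):
            orient_response(table)


class TestNestedModels:
    def test_lr_chi2_matches_loglik_oracle_on_random_designs(self, rng):
        """chi2 = n ln(RSS0/RSS1) must equal twice the Gaussian ML
        log-likelihood gain of the wider model, to 1e-8."""
        for _ in range(100):
            n = int(rng.integers(25, 60))
            mut = rng.integers(0, 2, size=n)
            phe = rng.integers(0, 2, size=n)
            if len(np.unique(mut)) < 2 or len(np.unique(np.column_stack([mut, phe]), axis=0)) < 3:
                continue
            y = rng.normal(size=n) - 0.5 * phe
            res = fit_nested_models(y, mut, phe, n_min=20)
            if res.degenerate:
                continue
            X0 = np.column_stack([np.ones(n), mut])
            X1 = np.column_stack([np.ones(n), mut, phe])
            expected = 2 * (gaussian_ml_loglik(y, X1) - gaussian_ml_loglik(y, X0))
            assert res.chi2 == pytest.approx(expected, abs=1e-8)
            assert res.p_raw == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-10)

    def test_closed_form_chi2_for_known_rss_ratio(self, rng):
        # halving the RSS at n=100 must give chi2 = 100 ln 2
        n = 100
        mut = np.zeros(n)
        mut[:50] = 1
        phe = np.zeros(n)
        phe[25:75] = 1
        y = rng.normal(size=n)
        res = fit_nested_models(y, mut, phe)
        X0 = np.column_stack([np.ones(n), mut])
        X1 = np.column_stack([np.ones(n), mut, phe])
        rss = lambda X: float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
        assert res.chi2 == pytest.approx(n * np.log(rss(X0) / rss(X1)), abs=1e-8)

    def test_f_variant_matches_statsmodels_partial_f_test(self, rng):
        import statsmodels.api as sm

        n = 80
        mut = rng.integers(0, 2, size=n)
        phe = rng.integers(0, 2, size=n)
        y = rng.normal(size=n) - 0.3 * phe
        res = fit_nested_models(y, mut, phe, test="f")
        reduced = sm.OLS(y, sm.add_constant(mut[:, None])).fit()
        full = sm.OLS(y, sm.add_constant(np.column_stack([mut, phe]))).fit()
        f_stat, f_p, _ = full.compare_f_test(reduced)
        assert res.chi2 == pytest.approx(f_stat, abs=1e-8)
        assert res.p_raw == pytest.approx(f_p, abs=1e-10)
        with pytest.raises(ValueError, match="unknown test"):
            fit_nested_models(y, mut, phe, test="wald")

    def test_phenocopy_equal_to_mutation_is_degenerate(self, rng):
        mut = rng.integers(0, 2, size=50)
        y = rng.normal(size=50)
        res = fit_nested_models(y, mut, mut.copy())
        assert res.degenerate
        assert np.isnan(res.chi2)

    def test_constant_phenocopy_is_degenerate(self, rng):
        mut = rng.integers(0, 2, size=50)
        res = fit_nested_models(rng.normal(size=50), mut, np.ones(50))
        assert res.degenerate

    def test_too_few_complete_cases_raises(self, rng):
        y = rng.normal(size=30)
        y[:15] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            fit_nested_models(y, np.arange(30) % 2, np.arange(30) // 15)

    def test_sensitivity_association_gives_negative_coefficient(self, rng):
        n = 300
        phe = rng.integers(0, 2, size=n)
        mut = rng.integers(0, 2, size=n)
        y = rng.normal(size=n) - 1.0 * phe
        res = fit_nested_models(y, mut, phe)
        assert res.coef_phenocopy < 0
        assert res.p_raw < 1e-6


class TestThreePredictorModel:
    def test_pathogenic_must_imply_mutation(self, rng):
        n = 40
        mut = np.zeros(n)
        path = np.ones(n)
        with pytest.raises(ValueError, match="pathogenic"):
            fit_three_predictor_model(rng.normal(size=n), mut, path, rng.integers(0, 2, n))

    def test_absent_pathogenic_column_dropped_and_flagged(self, rng):
        n = 60
        mut = rng.integers(0, 2, size=n)
        phe = rng.integers(0, 2, size=n)
        res = fit_three_predictor_model(rng.normal(size=n), mut, np.zeros(n), phe)
        assert res.degenerate
        assert res.coef_pathogenic is None
        assert np.isfinite(res.chi2)  # phenocopy term still tested

    def test_all_zero_predictors_raise(self, rng):
        n = 40
        with pytest.raises(ValueError, match="constant"):
            fit_three_predictor_model(rng.normal(size=n), np.zeros(n), np.zeros(n), np.zeros(n))

    def test_pathogenic_driven_response_dominates_mutation_coefficient(self):
        # activation equals the pathogenic subset of mutations, so response is
        # driven by pathogenic status alone: its coefficient must dwarf the
        # mutation coefficient and point toward sensitivity
        cfg = SyntheticConfig(
            seed=21,
            n_cancer_types=1,
            samples_per_type=500,
            alteration_rate_per_type=0.4,
            pathogenic_fraction=0.5,
            penetrance=1.0,
            cnv_rate=0.0,
            annotation_error_rate=0.0,
            drug_effect=1.0,
            response_noise_sd=1.0,
            n_drugs=2,
            on_target_fraction=0.5,
        )
        bundle = generate_cohort(cfg)
        truth = bundle.sample_truth
        drug = bundle.on_target_drugs[0]
        resp = bundle.drug_response.query("drug_id == @drug").set_index("sample_id")["value"]
        resp = resp.loc[bundle.samples]
        phe = np.random.default_rng(0).integers(0, 2, size=len(truth))
        res = fit_three_predictor_model(
            resp.to_numpy(), truth["mutation"].to_numpy(), truth["pathogenic"].to_numpy(), phe
        )
        assert res.coef_pathogenic < 0
        assert abs(res.coef_pathogenic) > abs(res.coef_mutation)


class TestFDR:
    @staticmethod
    def result(p, tag="t"):
        return NestedModelResult(
            drug_id="d", pathway_name="p", dataset_tag=tag, n=30,
            coef_mutation=0.0, coef_phenocopy=0.0,
            pvalue_mutation=1.0, pvalue_phenocopy=1.0,
            chi2=0.0, df=1, p_raw=p,
        )

    @staticmethod
    def brute_force_bh(pvals):
        """Step-up from the definition: q_i = min over j>=i of m*p_(j)/j."""
        m = len(pvals)
        order = np.argsort(pvals)
        q = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, m * pvals[idx] / rank)
            q[idx] = running
        return q

    def test_single_test_q_equals_p(self):
        out = adjust_fdr([self.result(0.03)])
        assert out[0].q_bh == pytest.approx(0.03)

    def test_textbook_step_up_example(self):
        results = [self.result(p) for p in (0.01, 0.02, 0.03, 0.04)]
        out = adjust_fdr(results)
        assert [r.q_bh for r in out] == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_p_vectors(self, rng):
        for _ in range(20):
            pvals = rng.uniform(size=int(rng.integers(1, 40)))
            out = adjust_fdr([self.result(p) for p in pvals])
            assert [r.q_bh for r in out] == pytest.approx(list(self.brute_force_bh(pvals)))

    def test_q_values_monotone_in_p(self, rng):
        pvals = rng.uniform(size=50)
        out = adjust_fdr([self.result(p) for p in pvals])
        ordered = sorted(out, key=lambda r: r.p_raw)
        qs = [r.q_bh for r in ordered]
        assert all(a <= b + 1e-15 for a, b in zip(qs, qs[1:]))

    def test_per_dataset_family_corrects_within_tags(self):
        results = [self.result(0.03, "A"), self.result(0.04, "A"), self.result(0.01, "B")]
        out = adjust_fdr(results, family="per-dataset")
        assert out[2].q_bh == pytest.approx(0.01)
        assert out[0].q_bh == pytest.approx(0.04)

    def test_degenerate_results_stay_outside_family(self, rng):
        bad = self.result(np.nan)
        bad.degenerate = True
        out = adjust_fdr([self.result(0.02), bad])
        assert out[1].q_bh is None
        assert out[0].q_bh == pytest.approx(0.02)

    def test_empty_family_raises(self):
        bad = self.result(np.nan)
        bad.degenerate = True
        with pytest.raises(ValueError, match="no non-degenerate"):
            adjust_fdr([bad])
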