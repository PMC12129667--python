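"""Association stage: OLS additive model, Bonferroni control, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divescan.assoc import (
    bonferroni_threshold,
    gc_lambda_median,
    ols_additive,
    run_two_stage,
    ttest_groups,
)
from divescan.peaks import CandidateSet, Peak
from divescan.simulate import (
    PhenotypeParams,
    SimulationParams,
    sample_genotypes,
    simulate_panel,
    simulate_phenotype,
)


def toy_phenotypes(rng, n=60, dosage=None):
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "phenotype": rng.normal(70, 8, n),
            "age": rng.normal(65, 8, n),
            "height": rng.normal(158, 6, n),
            "weight": rng.normal(60, 9, n),
            "dive_duration": rng.normal(30, 8, n),
            "population": ["A"] * n,
        }
    )
    if dosage is not None:
        table["phenotype"] += -10.0 * dosage
    return table


class TestOlsAdditive:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, 60).astype(float)
        pheno = toy_phenotypes(rng, dosage=dosage)
        rec = ols_additive(dosage, pheno)
        # brute-force normal equations with the same design
        X = np.column_stack(
            [np.ones(60), dosage]
            + [pheno[c].to_numpy() for c in ("age", "height", "weight", "dive_duration")]
        )
        y = pheno["phenotype"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (60 - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert rec.beta == pytest.approx(beta[1], abs=1e-8)
        assert rec.se == pytest.approx(se, abs=1e-8)
        assert rec.t_stat == pytest.approx(rec.beta / rec.se, abs=1e-10)

    def test_constant_phenotype_flagged(self):
        rng = np.random.default_rng(2)
        pheno = toy_phenotypes(rng)
        pheno["phenotype"] = 50.0
        rec = ols_additive(rng.integers(0, 3, 60).astype(float), pheno)
        assert rec.beta == 0.0 and rec.p_value == 1.0

    def test_collinear_dosage_rejected_by_name(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, 60).astype(float)
        pheno = toy_phenotypes(rng)
        pheno["dup"] = dosage
        with pytest.raises(ValueError, match="dup"):
            ols_additive(dosage, pheno, covariates=("age", "dup"))

    def test_age_squared_recorded(self):
        rng = np.random.default_rng(4)
        rec = ols_additive(
            rng.integers(0, 3, 60).astype(float), toy_phenotypes(rng),
            include_age_squared=True,
        )
        assert "age_sq" in rec.model_terms

    def test_too_few_cases_rejected(self):
        rng = np.random.default_rng(5)
        pheno = toy_phenotypes(rng, n=10)
        with pytest.raises(ValueError):
            ols_additive(np.ones(10), pheno)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 10, 0.005), (0.05, 1, 0.05), (0.01, 4, 0.0025)]
    )
    def test_threshold_values(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, abs=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestGcLambda:
    def test_uniform_pvalues_near_one(self):
        rng = np.random.default_rng(6)
        lam = gc_lambda_median(rng.uniform(0, 1, 10_000) + 1e-12)
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_doubled_statistics_double_lambda(self):
        rng = np.random.default_rng(7)
        chisq = 2 * rng.chisquare(1, 10_000)
        lam = gc_lambda_median(stats.chi2.sf(chisq, df=1) + 1e-300)
        assert lam == pytest.approx(2.0, abs=0.15)

    def test_all_half_is_exactly_one(self):
        assert gc_lambda_median([0.5] * 200) == pytest.approx(1.0, abs=1e-12)

    def test_order_invariant_and_validated(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.01, 1, 500)
        assert gc_lambda_median(p) == gc_lambda_median(np.sort(p))
        with pytest.raises(ValueError):
            gc_lambda_median(np.concatenate([p, [0.0]]))


class TestTtest:
    def test_identical_groups_null(self):
        vals = np.concatenate([np.arange(5.0), np.arange(5.0)])
        labels = ["a"] * 5 + ["b"] * 5
        res = ttest_groups(vals, labels)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_toy(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        res = ttest_groups(np.concatenate([x, y]), ["a"] * 4 + ["b"] * 4)
        # pooled t by hand: means 2.5 / 4.5, pooled var = 5/3
        pooled = np.sqrt(5 / 3 * (1 / 4 + 1 / 4))
        assert res.t_stat == pytest.approx(-2.0 / pooled, abs=1e-12)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(-2.0 / pooled), df=6), abs=1e-12
        )

    def test_power_matches_noncentral_t_oracle(self):
        rng = np.random.default_rng(9)
        n = 30
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            vals = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
            res = ttest_groups(vals, ["a"] * n + ["b"] * n)
            rejections += res.p_value <= 0.05
        ncp = 1.0 / np.sqrt(2 / n)
        tcrit = stats.t.ppf(0.975, df=2 * n - 2)
        power = 1 - stats.nct.cdf(tcrit, df=2 * n - 2, nc=ncp) + stats.nct.cdf(
            -tcrit, df=2 * n - 2, nc=ncp
        )
        assert rejections / n_rep == pytest.approx(power, abs=0.035)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ttest_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestTwoStage:
    def test_empty_candidates_empty_report(self, null_gm):
        pheno = simulate_phenotype(null_gm, PhenotypeParams(seed=1))
        report = run_two_stage(null_gm, pheno, CandidateSet(peaks=[], n_requested=10))
        assert report.records == [] and report.significant == []

    def test_threshold_for_ten_candidates(self, null_gm):
        pheno = simulate_phenotype(null_gm, PhenotypeParams(seed=2))
        peaks = [
            Peak(chrom="chr1", start=1 + j, end=1 + j, top_snp=f"snp{j}",
                 top_llr=5.0 - j * 0.1, top_pos=1 + j)
            for j in range(10)
        ]
        report = run_two_stage(
            null_gm, pheno, CandidateSet(peaks=peaks, n_requested=10), alpha=0.05
        )
        assert report.threshold == pytest.approx(0.005)
        assert len(report.records) == 10

    def test_causal_candidate_detected(self):
        params = SimulationParams(n_snps=300, sample_sizes=(29, 31, 25), seed=31)
        gm = sample_genotypes(simulate_panel(params), seed=32)
        pheno = simulate_phenotype(
            gm, PhenotypeParams(causal_snp="snp100", beta_per_allele=-10.0,
                                noise_sd=8.0, seed=33)
        )
        peaks = [
            Peak(chrom="chr1", start=1, end=1, top_snp=s, top_llr=1.0,
                 top_pos=j + 1)
            for j, s in enumerate(["snp100", "snp5", "snp40"])
        ]
        report = run_two_stage(gm, pheno, CandidateSet(peaks=peaks, n_requested=3))
        assert "snp100" in report.significant

    def test_within_population_subset(self):
        params = SimulationParams(n_snps=100, sample_sizes=(40, 40, 40), seed=41)
        gm = sample_genotypes(simulate_panel(params), seed=42)
        pheno = simulate_phenotype(gm, PhenotypeParams(causal_snp="snp0", seed=43))
        peaks = [Peak(chrom="chr1", start=1, end=1, top_snp="snp0", top_llr=1.0, top_pos=1)]
        report = run_two_stage(
            gm, pheno, CandidateSet(peaks=peaks, n_requested=1),
            subset_population="JEJ", n_pcs=2,
        )
        assert report.records[0].n_used == 40
        assert report.subset_population == "JEJ"
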