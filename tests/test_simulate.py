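"""Generator behaviour: drift model, genotype sampling, phenotypes, artifacts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divescan.simulate import (
    PhenotypeParams,
    SimulationParams,
    SweepSpec,
    inject_artifacts,
    sample_genotypes,
    simulate_panel,
    simulate_phenotype,
)
from divescan.qc import estimate_k0


class TestSimulatePanel:
    def test_zero_drift_is_identity(self):
        params = SimulationParams(n_snps=500, branch_drift=(0.0, 0.0, 0.0), seed=3)
        panel = simulate_panel(params)
        for row in panel.pop_freqs:
            np.testing.assert_array_equal(row, panel.root_freqs)

    def test_seed_determinism(self):
        params = SimulationParams(n_snps=300, seed=7)
        a, b = simulate_panel(params), simulate_panel(params)
        np.testing.assert_array_equal(a.root_freqs, b.root_freqs)
        np.testing.assert_array_equal(a.pop_freqs, b.pop_freqs)
        np.testing.assert_array_equal(a.selected_loci, b.selected_loci)

    def test_frequencies_inside_unit_interval(self):
        params = SimulationParams(n_snps=2000, branch_drift=(0.02, 0.02, 0.05), seed=5)
        panel = simulate_panel(params)
        assert np.all(panel.pop_freqs > 0) and np.all(panel.pop_freqs < 1)

    def test_drift_is_unbiased(self):
        params = SimulationParams(n_snps=30_000, seed=9)
        panel = simulate_panel(params)
        for row in panel.pop_freqs:
            assert abs(row.mean() - panel.root_freqs.mean()) < 0.005

    def test_selected_loci_have_larger_focal_displacement(self):
        params = SimulationParams(n_snps=10_000, n_selected=100, selection_boost=50.0, seed=13)
        panel = simulate_panel(params)
        disp = np.abs(panel.pop_freqs[0] - panel.root_freqs)
        sel = np.zeros(params.n_snps, dtype=bool)
        sel[panel.selected_loci] = True
        stat = stats.mannwhitneyu(disp[sel], disp[~sel], alternative="greater")
        assert stat.pvalue < 1e-10

    def test_sweep_pins_focal_frequencies(self):
        sw = SweepSpec(center_index=50)
        params = SimulationParams(n_snps=100, sweeps=(sw,), seed=1)
        panel = simulate_panel(params)
        assert panel.pop_freqs[0, 50] == pytest.approx(0.33)
        assert panel.root_freqs[50] == pytest.approx(0.07)
        # flanks displaced by the decaying profile on both sides
        for j, w in enumerate(sw.flank_weights, start=1):
            expected = 0.07 + w * (0.33 - 0.07)
            assert panel.pop_freqs[0, 50 - j] == pytest.approx(expected)
            assert panel.pop_freqs[0, 50 + j] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_snps": 0},
            {"selection_boost": 0.5},
            {"branch_drift": (-0.01, 0.004, 0.02)},
            {"sample_sizes": (1, 50, 50)},
            {"root_freq_law": ("uniform", 0.0, 1.0)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**{"n_snps": 100, **kwargs})


class TestSampleGenotypes:
    def test_fixed_frequencies_give_constant_genotypes(self):
        params = SimulationParams(n_snps=4, branch_drift=(0.0, 0.0, 0.0), seed=0)
        panel = simulate_panel(params)
        panel.pop_freqs[:, 0] = 0.0
        panel.pop_freqs[:, 1] = 1.0
        gm = sample_genotypes(panel, sizes=(5, 5, 5), seed=1)
        assert np.all(gm.calls[:, 0] == 0)
        assert np.all(gm.calls[:, 1] == 2)

    def test_sample_frequency_matches_binomial_error(self):
        params = SimulationParams(n_snps=1, branch_drift=(0.0, 0.0, 0.0),
                                  root_freq_law=("uniform", 0.499, 0.501), seed=2)
        panel = simulate_panel(params)
        panel.pop_freqs[:] = 0.5
        gm = sample_genotypes(panel, sizes=(5000, 2, 2), seed=3)
        focal = gm.calls[gm.populations == "JEJ", 0]
        freq = focal.sum() / (2 * focal.size)
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / (2 * 5000))

    def test_positions_follow_spacing(self):
        params = SimulationParams(n_snps=10, spacing_bp=3000, seed=0)
        gm = sample_genotypes(simulate_panel(params), sizes=(2, 2, 2), seed=0)
        assert list(gm.variants["pos"]) == [1 + 3000 * j for j in range(10)]


class TestSimulatePhenotype:
    def test_null_phenotype_has_no_genetic_signal(self):
        params = SimulationParams(n_snps=50, seed=21)
        gm = sample_genotypes(simulate_panel(params), sizes=(40, 40, 40), seed=22)
        pheno = simulate_phenotype(
            gm,
            PhenotypeParams(
                causal_snp="snp0", beta_per_allele=0.0,
                covariate_effects={"age": 0, "height": 0, "weight": 0, "dive_duration": 0},
                seed=23,
            ),
        )
        dosage = gm.dosage("snp0")
        slope, _, _, p, _ = stats.linregress(dosage, pheno["phenotype"])
        assert p > 0.01 or abs(slope) < 1.0

    def test_seed_determinism(self):
        params = SimulationParams(n_snps=20, seed=4)
        gm = sample_genotypes(simulate_panel(params), sizes=(10, 10, 10), seed=5)
        a = simulate_phenotype(gm, PhenotypeParams(causal_snp="snp1", seed=6))
        b = simulate_phenotype(gm, PhenotypeParams(causal_snp="snp1", seed=6))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_causal_snp_rejected(self):
        params = SimulationParams(n_snps=5, seed=1)
        gm = sample_genotypes(simulate_panel(params), sizes=(5, 5, 5), seed=2)
        with pytest.raises(KeyError):
            simulate_phenotype(gm, PhenotypeParams(causal_snp="nope", seed=0))

    def test_ols_recovers_effect_within_ci(self):
        """OLS on 85 samples recovers beta = -10 within 2 SE in >= 90% of replicates."""
        import statsmodels.api as sm

        params = SimulationParams(
            n_snps=1, branch_drift=(0.0, 0.0, 0.0),
            root_freq_law=("uniform", 0.329, 0.331), sample_sizes=(29, 31, 25), seed=31,
        )
        panel = simulate_panel(params)
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            gm = sample_genotypes(panel, seed=1000 + rep)
            pheno = simulate_phenotype(
                gm, PhenotypeParams(causal_snp="snp0", beta_per_allele=-10.0,
                                    noise_sd=8.0, seed=2000 + rep)
            )
            X = sm.add_constant(gm.dosage("snp0"))
            fit = sm.OLS(pheno["phenotype"].to_numpy(), X).fit()
            beta, se = fit.params[1], fit.bse[1]
            if beta - 2 * se <= -10.0 <= beta + 2 * se:
                hits += 1
        assert hits / n_rep >= 0.90


class TestInjectArtifacts:
    def test_zero_counts_identity(self, null_gm):
        out, truth = inject_artifacts(null_gm, n_flips=0, n_related_pairs=0, seed=0)
        np.testing.assert_array_equal(out.calls, null_gm.calls)
        assert truth.flipped_variants == [] and truth.related_pairs == []

    @pytest.fixture(scope="class")
    @staticmethod
    def fixable_gm():
        # a Beta(0.2, 0.2) root law concentrates mass near 0/1, so the sample
        # contains exactly-fixed sites for the flip machinery to target
        params = SimulationParams(
            n_snps=1000, root_freq_law=("beta", 0.2, 0.2),
            sample_sizes=(30, 30, 30), seed=41,
        )
        return sample_genotypes(simulate_panel(params), seed=42)

    def test_flips_recode_panel_b(self, fixable_gm):
        out, truth = inject_artifacts(fixable_gm, n_flips=3, seed=43)
        assert len(truth.flipped_variants) == 3
        b = np.isin(np.array(out.sample_ids), truth.panel_b_samples)
        for vid in truth.flipped_variants:
            j = out.variant_index(vid)
            np.testing.assert_array_equal(out.calls[b, j], 2 - fixable_gm.calls[b, j])
            np.testing.assert_array_equal(out.calls[~b, j], fixable_gm.calls[~b, j])

    def test_related_pair_has_zero_k0(self, fixable_gm):
        out, truth = inject_artifacts(fixable_gm, n_related_pairs=1, seed=44)
        assert len(truth.related_pairs) == 1
        est = estimate_k0(out, truth.related_pairs[0])
        assert est.k0 <= 0.1

    def test_capacity_errors(self, fixable_gm):
        with pytest.raises(ValueError):
            inject_artifacts(fixable_gm, n_related_pairs=fixable_gm.n_samples)
        with pytest.raises(ValueError):
            inject_artifacts(fixable_gm, n_flips=fixable_gm.n_variants + 1)
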