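"""Generator contracts: LD structure, QTL power, disease model, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from pydantic import ValidationError
from scipy import stats

from gatescore import (
    ArchitectureSpec,
    GeneSpec,
    LdBlockSpec,
    simulate_cohort,
    simulate_ld_panel,
    simulate_qtl_study,
)


def one_block(n_snps=3, rho=0.0, maf=(0.3, 0.3), block_id="b0", chrom="1", pos=1_000_000):
    return LdBlockSpec(
        block_id=block_id, chrom=chrom, start_pos=pos, n_snps=n_snps, rho=rho, maf_range=maf
    )


def single_snp_arch(beta=0.5, noise_sd=1.0, core=None, prevalence=0.01,
                    trait_snps=None, n_snps=1, rho=0.0):
    block = one_block(n_snps=n_snps, rho=rho)
    gene = GeneSpec(
        gene_id="g",
        chrom="2",
        tss_pos=1,
        trans_effects={"b0": [beta] + [0.0] * (n_snps - 1)},
        expression_noise_sd=noise_sd,
    )
    return ArchitectureSpec(
        blocks=[block],
        genes=[gene],
        core_genes=core or {},
        prevalence_target=prevalence,
        trait_associated_snps=trait_snps,
    )


class TestLdPanel:
    def test_independent_block_has_no_ld(self):
        panel = simulate_ld_panel([one_block(n_snps=5, rho=0.0, maf=(0.2, 0.5))], 10_000, seed=2)
        R = np.corrcoef(panel.dosages, rowvar=False)
        off = np.abs(R[np.triu_indices(5, 1)])
        assert off.mean() < 0.05

    def test_adjacent_dosage_correlation_matches_rho(self):
        # calibrated thresholded-Gaussian construction: dosage corr -> rho
        panel = simulate_ld_panel([one_block(rho=0.9, maf=(0.35, 0.35))], 50_000, seed=1)
        R = np.corrcoef(panel.dosages, rowvar=False)
        assert R[0, 1] == pytest.approx(0.9, abs=0.03)
        assert R[1, 2] == pytest.approx(0.9, abs=0.03)

    def test_cross_block_independence(self):
        blocks = [
            one_block(rho=0.8, maf=(0.3, 0.3), block_id="x", chrom="1"),
            one_block(rho=0.8, maf=(0.3, 0.3), block_id="y", chrom="2"),
        ]
        panel = simulate_ld_panel(blocks, 20_000, seed=4)
        R = np.corrcoef(panel.dosages, rowvar=False)
        assert np.abs(R[:3, 3:]).max() < 0.05

    def test_same_seed_identical_panels(self):
        a = simulate_ld_panel([one_block()], 200, seed=9)
        b = simulate_ld_panel([one_block()], 200, seed=9)
        assert np.array_equal(a.dosages, b.dosages)

    def test_dosages_in_range_and_hardy_weinberg_freq(self):
        panel = simulate_ld_panel([one_block(maf=(0.25, 0.25))], 30_000, seed=5)
        assert panel.dosages.min() >= 0 and panel.dosages.max() <= 2
        assert panel.dosages.mean() / 2 == pytest.approx(0.25, abs=0.01)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            one_block(rho=1.0)
        with pytest.raises(ValidationError):
            one_block(rho=-0.1)
        with pytest.raises(ValidationError):
            one_block(maf=(0.0, 0.3))
        with pytest.raises(ValidationError):
            one_block(maf=(0.3, 0.6))
        with pytest.raises(ValueError):
            simulate_ld_panel([one_block()], 1, seed=0)

    def test_unattainable_rho_for_unequal_mafs_raises(self):
        # thresholded-Gaussian dosage correlation is bounded when MAFs differ
        with pytest.raises(ValueError, match="unattainable"):
            simulate_ld_panel([one_block(rho=0.9, maf=(0.05, 0.5), n_snps=5)], 100, seed=0)


class TestQtlStudy:
    def test_anchor_snp_power_matches_noncentral_chisq(self):
        """Causal SNP (0.5 SD effect) clears P<1e-6 as often as theory says."""
        arch = single_snp_arch(beta=0.5)
        panel = simulate_ld_panel(arch.blocks, 500, seed=0)
        hits = 0
        for seed in range(100):
            ss = simulate_qtl_study(panel, arch, 20_000, seed=seed)
            hits += int(ss["pvalue"].iloc[0] < 1e-6)
        # oracle: NCP = n beta^2 2f(1-f) / residual variance, at the 1e-6 threshold
        var_x = 2 * 0.3 * 0.7
        ncp = 20_000 * 0.25 * var_x / 1.0
        power = stats.ncx2.sf(stats.chi2.ppf(1 - 1e-6, 1), 1, ncp)
        assert power > 0.999  # theory says near-certain detection
        assert hits >= 95

    def test_null_gene_pvalues_uniform(self):
        arch = single_snp_arch(beta=0.0, n_snps=60)
        panel = simulate_ld_panel(arch.blocks, 500, seed=1)
        ss = simulate_qtl_study(panel, arch, 4000, seed=123)
        frac = (ss["pvalue"] < 0.05).mean()
        lo, hi = stats.binom.ppf([0.005, 0.995], 60, 0.05) / 60
        assert lo <= frac <= hi
        assert stats.kstest(ss["pvalue"], "uniform").pvalue > 0.01

    def test_trait_associated_snp_masking(self):
        arch = single_snp_arch(n_snps=6, trait_snps=["b0_s0", "b0_s2", "b0_s4"])
        panel = simulate_ld_panel(arch.blocks, 500, seed=1)
        ss = simulate_qtl_study(panel, arch, 2000, seed=5)
        assert set(ss["snp_id"]) == {"b0_s0", "b0_s2", "b0_s4"}

    def test_empty_gene_list_rejected(self):
        block = one_block()
        with pytest.raises(ValidationError):
            # core_genes referencing a gene that does not exist
            ArchitectureSpec(blocks=[block], genes=[], core_genes={"g": 0.1})
        arch = ArchitectureSpec(blocks=[block], genes=[])
        panel = simulate_ld_panel([block], 100, seed=0)
        with pytest.raises(ValueError, match="no genes"):
            simulate_qtl_study(panel, arch, 1000, seed=0)

    def test_summary_stats_internally_consistent(self):
        arch = single_snp_arch(beta=0.2, n_snps=4)
        panel = simulate_ld_panel(arch.blocks, 500, seed=1)
        ss = simulate_qtl_study(panel, arch, 5000, seed=2)
        z = ss["beta"] / ss["se"]
        expected = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(ss["pvalue"], expected, rtol=0.1)


class TestCohort:
    def test_intercept_only_prevalence(self):
        arch = single_snp_arch(beta=0.3, prevalence=0.01)  # no core genes
        panel = simulate_ld_panel(arch.blocks, 500, seed=0)
        cohort = simulate_cohort(panel, arch, 100_000, seed=7)
        assert 0.008 <= cohort.prevalence <= 0.012

    def test_core_gene_coefficient_recovered_by_logistic_ml(self):
        """Logistic fit of outcome on the generating expression gives ~coef."""
        import statsmodels.api as sm

        arch = single_snp_arch(beta=0.5, core={"g": 0.3}, prevalence=0.05)
        panel = simulate_ld_panel(arch.blocks, 500, seed=0)
        cohort = simulate_cohort(panel, arch, 200_000, seed=8)
        x = cohort.true_expression["g"].to_numpy()
        X = np.column_stack([np.ones(len(x)), x])
        fit = sm.GLM(cohort.outcome, X, family=sm.families.Binomial()).fit()
        assert fit.params[1] == pytest.approx(0.3, abs=0.05)

    def test_same_seed_identical_outcomes(self):
        arch = single_snp_arch(core={"g": 0.2}, prevalence=0.05)
        panel = simulate_ld_panel(arch.blocks, 500, seed=0)
        a = simulate_cohort(panel, arch, 2000, seed=3)
        b = simulate_cohort(panel, arch, 2000, seed=3)
        assert np.array_equal(a.outcome, b.outcome)
        assert a.covariates.equals(b.covariates)

    def test_covariates_shape_and_independence(self):
        arch = single_snp_arch(prevalence=0.1)
        panel = simulate_ld_panel(arch.blocks, 500, seed=0)
        cohort = simulate_cohort(panel, arch, 20_000, seed=4)
        assert list(cohort.covariates.columns) == ["sex"] + [f"pc{i}" for i in range(1, 21)]
        r = np.corrcoef(cohort.covariates["pc1"], cohort.dosages[:, 0])[0, 1]
        assert abs(r) < 0.03

    def test_unreachable_prevalence_raises(self):
        block = one_block(maf=(0.4, 0.4))
        gene = GeneSpec(gene_id="g", chrom="2", tss_pos=1, trans_effects={"b0": [0.1, 0, 0]})
        arch = ArchitectureSpec(
            blocks=[block],
            genes=[gene],
            direct_snp_effects={"b0_s0": 60.0},  # carriers are near-certain cases
            prevalence_target=0.001,
        )
        panel = simulate_ld_panel([block], 500, seed=0)
        with pytest.raises(ValueError, match="unreachable"):
            simulate_cohort(panel, arch, 5000, seed=0)


class TestArchitectureSpec:
    def test_yaml_roundtrip(self, tmp_path):
        arch = single_snp_arch(core={"g": 0.2})
        p = tmp_path / "arch.yaml"
        arch.to_yaml(p)
        again = ArchitectureSpec.from_yaml(p)
        assert again == arch

    def test_reference_validation(self):
        block = one_block()
        with pytest.raises(ValidationError, match="unknown block"):
            ArchitectureSpec(
                blocks=[block],
                genes=[GeneSpec(gene_id="g", chrom="1", tss_pos=1, trans_effects={"nope": [0.1]})],
            )
        with pytest.raises(ValidationError, match="length"):
            ArchitectureSpec(
                blocks=[block],
                genes=[GeneSpec(gene_id="g", chrom="1", tss_pos=1, trans_effects={"b0": [0.1]})],
            )
        with pytest.raises(ValidationError, match="overlapping"):
            ArchitectureSpec(
                blocks=[
                    one_block(block_id="a", pos=1000),
                    one_block(block_id="b", pos=1500),
                ],
                genes=[],
            )
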