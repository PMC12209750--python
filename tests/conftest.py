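"""Shared fixtures: small panels, a reusable synthetic analysis run."""

from __future__ import annotations

import numpy as np
import pytest

from gatescore import LdBlockSpec, ReferencePanel, SnpRecord, run_synthetic_pipeline
from gatescore.synthetic import sparse_architecture


@pytest.fixture(scope="session")
def tiny_panel() -> ReferencePanel:
    """Two independent 3-SNP blocks on different chromosomes, n=2000."""
    blocks = [
        LdBlockSpec(block_id="bA", chrom="1", start_pos=1_000_000, n_snps=3, rho=0.6, maf_range=(0.3, 0.3)),
        LdBlockSpec(block_id="bB", chrom="2", start_pos=5_000_000, n_snps=3, rho=0.0, maf_range=(0.2, 0.4)),
    ]
    from gatescore import simulate_ld_panel

    return simulate_ld_panel(blocks, 2000, seed=11)


def manual_panel(columns: dict[str, np.ndarray], chrom: str = "1", start: int = 100_000,
                 spacing: int = 10_000) -> ReferencePanel:
    """Build a panel directly from named dosage columns (for LD fixtures)."""
    snps = []
    for k, name in enumerate(columns):
        freq = float(np.clip(columns[name].mean() / 2.0, 1e-6, 1 - 1e-6))
        snps.append(
            SnpRecord(
                snp_id=name,
                chrom=chrom,
                pos=start + k * spacing,
                effect_allele="A",
                other_allele="G",
                allele_freq=freq,
            )
        )
    return ReferencePanel(snps=snps, dosages=np.column_stack(list(columns.values())))


@pytest.fixture(scope="session")
def demo_run():
    """A small but complete synthetic analysis: 5 genes, 2 core, 12 trans loci.

    Enough trans loci per gene for MR eligibility, enough cohort size for
    the core genes to show clear association.
    """
    arch = sparse_architecture(
        n_genes=5, n_core=2, trans_blocks_per_gene=12, core_coef=0.7
    )
    run = run_synthetic_pipeline(arch, n_ref=1500, n_study=10_000, n_cohort=20_000, seed=3)
    return arch, run
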