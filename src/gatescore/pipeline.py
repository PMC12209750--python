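"""End-to-end orchestration: summary statistics -> scores -> associations.

`analyze` is the real-data entry point (summary statistics + panel +
cohort + gene annotation); `run_synthetic_pipeline` wraps it behind the
synthetic generators so the whole analysis can be exercised with no
external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .association import (
    NullModel,
    association_table,
    fit_null,
    test_cis_score,
    test_gate_score,
)
from .config import GateConfig
from .containers import Cohort, ReferencePanel
from .ingest import (
    Clump,
    classify_cis_trans,
    clump,
    filter_by_pvalue,
    mask_hla,
)
from .ldweights import WeightVector, clump_weights
from .scoring import GateScore, LocusScore, aggregate_trans, cis_score, locus_score
from .synthetic import (
    ArchitectureSpec,
    simulate_cohort,
    simulate_ld_panel,
    simulate_qtl_study,
)

logger = logging.getLogger(__name__)


@dataclass
class GateAnalysis:
    """Everything the downstream validation stages consume."""

    null: NullModel
    clumps: dict[str, list[Clump]] = field(default_factory=dict)
    weights: dict[str, list[WeightVector]] = field(default_factory=dict)
    locus_scores: dict[str, list[LocusScore]] = field(default_factory=dict)
    gate_scores: dict[str, GateScore] = field(default_factory=dict)
    cis_scores: dict[str, LocusScore] = field(default_factory=dict)
    trans_results: pd.DataFrame = field(default_factory=pd.DataFrame)
    cis_results: pd.DataFrame = field(default_factory=pd.DataFrame)
    skipped_genes: dict[str, str] = field(default_factory=dict)


def analyze(
    sumstats: pd.DataFrame,
    panel: ReferencePanel,
    cohort: Cohort,
    genes: pd.DataFrame,
    config: GateConfig | None = None,
) -> GateAnalysis:
    """Run the scoring and association stages of the GATE analysis.

    Per gene: extraction filter, HLA mask, cis/trans split, clumping,
    LD-adjusted weights, locus scores, genome-wide trans aggregation
    with the Hill effective number, then efficient score tests of the
    trans and cis scores against one shared logistic null
    (sex + genotypic PCs).
    """
    cfg = config or GateConfig()
    df = filter_by_pvalue(sumstats, cfg.extraction_p)
    df = mask_hla(df, chrom=cfg.hla_chrom, start=cfg.hla_start, end=cfg.hla_end)
    df = df.assign(is_cis=classify_cis_trans(df, genes, cis_window=cfg.cis_window))

    null = fit_null(cohort.outcome, cohort.covariates)
    out = GateAnalysis(null=null)
    trans_results, cis_results = [], []

    for gene_id, gdf in df.groupby("gene_id", sort=True):
        gene_clumps: list[Clump] = []
        for cis_flag in (False, True):
            sub = gdf[gdf["is_cis"] == cis_flag]
            if sub.empty:
                continue
            gene_clumps.extend(
                clump(
                    sub,
                    panel,
                    extraction_p=cfg.extraction_p,
                    anchor_p=cfg.anchor_p,
                    r2_threshold=cfg.r2_threshold,
                    window=cfg.clump_window,
                    is_cis=cis_flag,
                )
            )
        if not gene_clumps:
            out.skipped_genes[str(gene_id)] = "no clumps passing anchor threshold"
            continue
        wvs = [clump_weights(c, panel, svd_rtol=cfg.svd_rtol) for c in gene_clumps]
        lss = [locus_score(cohort, wv) for wv in wvs]
        out.clumps[str(gene_id)] = gene_clumps
        out.weights[str(gene_id)] = wvs
        out.locus_scores[str(gene_id)] = lss

        trans_lss = [ls for ls in lss if not ls.is_cis]
        if trans_lss:
            study = gene_clumps[0].study
            gs = aggregate_trans(trans_lss, study=study)
            out.gate_scores[str(gene_id)] = gs
            trans_results.append(test_gate_score(null, gs))
        else:
            out.skipped_genes[str(gene_id)] = "no trans loci"
        cis_wvs = [wv for wv in wvs if wv.is_cis]
        if cis_wvs:
            cs = cis_score(cohort, cis_wvs)
            out.cis_scores[str(gene_id)] = cs
            cis_results.append(test_cis_score(null, cs))

    out.trans_results = association_table(trans_results)
    out.cis_results = association_table(cis_results)
    logger.info(
        "analyzed %d genes (%d skipped)", len(out.gate_scores), len(out.skipped_genes)
    )
    return out


@dataclass
class SyntheticRun:
    panel: ReferencePanel
    sumstats: pd.DataFrame
    cohort: Cohort
    genes: pd.DataFrame
    analysis: GateAnalysis


def gene_annotation_frame(arch: ArchitectureSpec) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in arch.genes],
            "chrom": [g.chrom for g in arch.genes],
            "tss_pos": [g.tss_pos for g in arch.genes],
        }
    )


def run_synthetic_pipeline(
    arch: ArchitectureSpec,
    n_ref: int,
    n_study: int,
    n_cohort: int,
    seed: int,
    config: GateConfig | None = None,
    study: str = "SYNTH",
) -> SyntheticRun:
    """Generate panel, QTL study and cohort from one seed, then analyze.

    The three stages use distinct streams derived from ``seed`` so the
    QTL study sample is independent of the target cohort (two-sample
    design, no overlap).
    """
    panel = simulate_ld_panel(arch.blocks, n_ref, seed=seed)
    sumstats = simulate_qtl_study(panel, arch, n_study, seed=seed + 1, study=study)
    cohort = simulate_cohort(panel, arch, n_cohort, seed=seed + 2)
    genes = gene_annotation_frame(arch)
    analysis = analyze(sumstats, panel, cohort, genes, config=config)
    return SyntheticRun(
        panel=panel, sumstats=sumstats, cohort=cohort, genes=genes, analysis=analysis
    )
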