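"""Synthetic data with the statistical structure the GATE analysis assumes.

Three generators cover the whole input surface of the pipeline:

* :func:`simulate_ld_panel` — an LD reference panel built from AR(1) blocks
  of common variants (stands in for the 1000 Genomes panel);
* :func:`simulate_qtl_study` — univariate SNP-on-expression summary
  statistics from an independent draw of study individuals (emulating
  eQTLGen-style trans-eQTL and deCODE/INTERVAL/UKB-Olink-style trans-pQTL
  studies, including the restriction of trans statistics to a designated
  subset of trait-associated SNPs);
* :func:`simulate_cohort` — a target cohort with a binary disease mediated
  by the standardized expression of designated "core" genes (the sparse
  effector architecture: many weak trans effects of common variants
  coalescing on a few effector genes), plus optional direct (pleiotropic)
  SNP effects, at a configurable prevalence (~1% by default in the shipped
  architectures).

Dosage generation uses a latent multivariate Gaussian per haplotype,
thresholded at the allele-frequency quantile and summed over two
haplotypes, which yields Hardy-Weinberg dosages.  The latent adjacent
correlation is calibrated (via the bivariate normal CDF) so that the
*dosage* correlation of adjacent SNPs converges to the requested ``rho``,
not to an attenuated tetrachoric value.

Every generator is a pure function of its spec and an integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize, stats
from scipy.special import expit

from .containers import Cohort, ReferencePanel, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LdBlockSpec",
    "GeneSpec",
    "ArchitectureSpec",
    "simulate_ld_panel",
    "simulate_qtl_study",
    "simulate_cohort",
    "sparse_architecture",
    "PanelGenerator",
]


# ---------------------------------------------------------------------------
# Specs (validated, YAML round-trippable)
# ---------------------------------------------------------------------------


class LdBlockSpec(BaseModel):
    """One LD block: ``n_snps`` SNPs with AR(1) adjacent dosage correlation.

    SNPs are placed every ``spacing`` bp from ``start_pos``; allele
    frequencies are drawn uniformly from ``maf_range`` (in (0, 0.5]).
    SNP ids are deterministic: ``{block_id}_s{k}``.
    """

    block_id: str
    chrom: str
    start_pos: int = Field(ge=1)
    n_snps: int = Field(ge=1)
    rho: float
    maf_range: tuple[float, float] = (0.2, 0.5)
    spacing: int = Field(1000, ge=1)

    @field_validator("rho")
    @classmethod
    def _rho_range(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {v}")
        return v

    @field_validator("maf_range")
    @classmethod
    def _maf_range(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {v}")
        return v

    @property
    def end_pos(self) -> int:
        return self.start_pos + (self.n_snps - 1) * self.spacing

    def snp_ids(self) -> list[str]:
        return [f"{self.block_id}_s{k}" for k in range(self.n_snps)]


class GeneSpec(BaseModel):
    """One gene: TSS location, cis and trans genetic effects, noise level.

    ``trans_effects`` maps block_id -> per-SNP effect sizes (expression
    units per effect allele); ``cis_effects`` likewise for the optional
    cis block near the TSS.
    """

    gene_id: str
    chrom: str
    tss_pos: int = Field(ge=1)
    cis_block: str | None = None
    cis_effects: list[float] | None = None
    trans_effects: dict[str, list[float]] = {}
    expression_noise_sd: float = Field(1.0, gt=0)


class ArchitectureSpec(BaseModel):
    """The full generative architecture: LD blocks, genes, disease model.

    ``core_genes`` maps gene_id -> log-odds coefficient per SD of that
    gene's expression; ``direct_snp_effects`` maps snp_id -> per-allele
    log-odds effect on disease that bypasses expression (pleiotropy);
    ``trait_associated_snps``, if set, restricts which SNPs carry trans
    summary statistics (emulating designs that test only a designated
    trait-associated SNP panel).
    """

    blocks: list[LdBlockSpec]
    genes: list[GeneSpec]
    core_genes: dict[str, float] = {}
    direct_snp_effects: dict[str, float] = {}
    prevalence_target: float = Field(0.01, gt=0, lt=1)
    trait_associated_snps: list[str] | None = None

    @model_validator(mode="after")
    def _check_references(self) -> "ArchitectureSpec":
        ids = [b.block_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate block_id")
        by_id = {b.block_id: b for b in self.blocks}
        # non-overlapping, position-sorted per chromosome
        by_chrom: dict[str, list[LdBlockSpec]] = {}
        for b in self.blocks:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, blist in by_chrom.items():
            prev_end = -1
            for b in sorted(blist, key=lambda b: b.start_pos):
                if b.start_pos <= prev_end:
                    raise ValueError(f"overlapping blocks on chromosome {chrom}")
                prev_end = b.end_pos
        gene_ids = {g.gene_id for g in self.genes}
        if len(gene_ids) != len(self.genes):
            raise ValueError("duplicate gene_id")
        for g in self.genes:
            refs = dict(g.trans_effects)
            if g.cis_block is not None:
                refs[g.cis_block] = g.cis_effects or []
            for bid, effects in refs.items():
                if bid not in by_id:
                    raise ValueError(f"gene {g.gene_id} references unknown block {bid}")
                if len(effects) != by_id[bid].n_snps:
                    raise ValueError(
                        f"gene {g.gene_id}, block {bid}: effect vector length "
                        f"{len(effects)} != n_snps {by_id[bid].n_snps}"
                    )
        unknown_core = set(self.core_genes) - gene_ids
        if unknown_core:
            raise ValueError(f"core_genes not in genes: {sorted(unknown_core)}")
        all_snps = {s for b in self.blocks for s in b.snp_ids()}
        for sid in self.direct_snp_effects:
            if sid not in all_snps:
                raise ValueError(f"direct_snp_effects references unknown SNP {sid}")
        if self.trait_associated_snps is not None:
            bad = set(self.trait_associated_snps) - all_snps
            if bad:
                raise ValueError(f"trait_associated_snps unknown: {sorted(bad)[:5]}")
        return self

    @property
    def block_map(self) -> dict[str, LdBlockSpec]:
        return {b.block_id: b for b in self.blocks}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArchitectureSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Latent-Gaussian haplotype machinery
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _latent_adjacent_corr(rho: float, t1: float, t2: float) -> float:
    """Latent Gaussian correlation giving binary correlation ``rho``.

    Haplotype alleles are indicators 1{Z < t}; their correlation under a
    bivariate normal with latent correlation r is
    (Phi2(t1, t2; r) - p1 p2) / sqrt(p1 q1 p2 q2).  Solve for r so the
    indicator (hence dosage) correlation equals the requested rho.
    """
    if rho == 0.0:
        return 0.0
    p1, p2 = stats.norm.cdf(t1), stats.norm.cdf(t2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    target_p11 = rho * denom + p1 * p2

    def f(r: float) -> float:
        cov = [[1.0, r], [r, 1.0]]
        return stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([t1, t2]) - target_p11

    hi = 1.0 - 1e-9
    if f(hi) < 0:
        raise ValueError(
            f"adjacent dosage correlation {rho} unattainable for allele "
            f"frequencies {p1:.3f}, {p2:.3f} (thresholded Gaussian bound)"
        )
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))


@dataclass
class PanelGenerator:
    """The generative process behind a simulated panel.

    Frozen once built: fresh cohorts and QTL-study samples are drawn from
    the *same* allele frequencies and latent LD structure, so reference
    panel, QTL studies and target cohort share one population.
    """

    blocks: list[LdBlockSpec]
    mafs: list[np.ndarray]          # per block, per SNP
    latent_corrs: list[np.ndarray]  # per block, length n_snps-1

    @classmethod
    def build(cls, blocks: list[LdBlockSpec], rng: np.random.Generator) -> "PanelGenerator":
        mafs, corrs = [], []
        for b in blocks:
            lo, hi = b.maf_range
            maf = rng.uniform(lo, hi, size=b.n_snps) if hi > lo else np.full(b.n_snps, lo)
            t = stats.norm.ppf(maf)
            r = np.array(
                [
                    _latent_adjacent_corr(round(b.rho, 10), round(t[k], 6), round(t[k + 1], 6))
                    for k in range(b.n_snps - 1)
                ]
            )
            mafs.append(maf)
            corrs.append(r)
        return cls(blocks=blocks, mafs=mafs, latent_corrs=corrs)

    def snp_records(self) -> list[SnpRecord]:
        records = []
        for b, maf in zip(self.blocks, self.mafs):
            for k, sid in enumerate(b.snp_ids()):
                records.append(
                    SnpRecord(
                        snp_id=sid,
                        chrom=b.chrom,
                        pos=b.start_pos + k * b.spacing,
                        effect_allele="A",
                        other_allele="G",
                        allele_freq=float(maf[k]),
                    )
                )
        return records

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an (n, total_snps) dosage matrix: two thresholded haplotypes."""
        cols = []
        for b, maf, r in zip(self.blocks, self.mafs, self.latent_corrs):
            t = stats.norm.ppf(maf)
            z = np.empty((2 * n, b.n_snps))
            z[:, 0] = rng.standard_normal(2 * n)
            for k in range(1, b.n_snps):
                eps = rng.standard_normal(2 * n)
                z[:, k] = r[k - 1] * z[:, k - 1] + np.sqrt(1 - r[k - 1] ** 2) * eps
            hap = (z < t).astype(np.float64)
            cols.append(hap[:n] + hap[n:])
        return np.concatenate(cols, axis=1)


def simulate_ld_panel(
    blocks: list[LdBlockSpec], n_individuals: int, seed: int
) -> ReferencePanel:
    """Simulate an LD reference panel from AR(1) block specifications.

    Within a block, adjacent-SNP dosage correlation converges to the
    block's ``rho`` as n grows; distinct blocks are independent.  The
    output is fully determined by (blocks, n_individuals, seed).
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals for a reference panel")
    rng = np.random.default_rng(seed)
    gen = PanelGenerator.build(blocks, rng)
    dosages = gen.draw(n_individuals, rng)
    return ReferencePanel(snps=gen.snp_records(), dosages=dosages, generator=gen)


# ---------------------------------------------------------------------------
# QTL summary-statistic study
# ---------------------------------------------------------------------------


def _gene_expression(
    arch: ArchitectureSpec,
    gene: GeneSpec,
    dosages: np.ndarray,
    col_of: dict[str, int],
    rng: np.random.Generator,
    include_cis: bool = True,
) -> np.ndarray:
    """expression = sum(effect x dosage) over effect SNPs + Gaussian noise."""
    n = dosages.shape[0]
    y = rng.normal(0.0, gene.expression_noise_sd, size=n)
    effect_map = dict(gene.trans_effects)
    if include_cis and gene.cis_block is not None and gene.cis_effects:
        effect_map[gene.cis_block] = gene.cis_effects
    for bid, effects in effect_map.items():
        for sid, beta in zip(arch.block_map[bid].snp_ids(), effects):
            if beta != 0.0:
                y += beta * dosages[:, col_of[sid]]
    return y


def simulate_qtl_study(
    panel: ReferencePanel,
    arch: ArchitectureSpec,
    n_study: int,
    seed: int,
    study: str = "SYNTH",
    qtl_type: str = "transcript",
) -> pd.DataFrame:
    """Simulate univariate QTL summary statistics on a fresh study sample.

    A fresh sample of ``n_study`` individuals is drawn from the panel's
    generative process (two-sample design: no overlap with any cohort).
    Expression of each gene is regressed univariately on each SNP — or on
    ``arch.trait_associated_snps`` only, if set — and the table of
    (beta, se, p, n, study) rows is returned in the summary-stats dialect.

    Power: the anchor-SNP non-centrality is approximately
    ``n_study * beta^2 * 2 f (1-f) / var(expression)``; callers should size
    ``n_study`` so anchors clear the clump threshold (e.g. beta=0.2,
    f=0.3, var=1 gives NCP ~ 336 at n_study=20,000, far beyond P<1e-6).
    """
    if not arch.genes:
        raise ValueError("architecture contains no genes")
    if panel.generator is None:
        raise ValueError("panel has no attached generative process")
    rng = np.random.default_rng(seed)
    X = panel.generator.draw(n_study, rng)
    col_of = {s.snp_id: j for j, s in enumerate(panel.snps)}
    snp_list = panel.snps
    if arch.trait_associated_snps is not None:
        keep = set(arch.trait_associated_snps)
        snp_list = [s for s in snp_list if s.snp_id in keep]
    cols = np.array([col_of[s.snp_id] for s in snp_list])
    Xs = X[:, cols]
    Xc = Xs - Xs.mean(axis=0)
    sxx = np.sum(Xc * Xc, axis=0)
    if np.any(sxx == 0):
        raise ValueError("monomorphic SNP in study draw; increase n_study or MAF")

    frames = []
    for gene in arch.genes:
        y = _gene_expression(arch, gene, X, col_of, rng)
        yc = y - y.mean()
        syy = float(yc @ yc)
        beta = (Xc.T @ yc) / sxx
        df_resid = n_study - 2
        sigma2 = np.maximum(syy - beta**2 * sxx, 0.0) / df_resid
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf)
        pval = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [s.snp_id for s in snp_list],
                    "chrom": [s.chrom for s in snp_list],
                    "pos": [s.pos for s in snp_list],
                    "effect_allele": [s.effect_allele for s in snp_list],
                    "other_allele": [s.other_allele for s in snp_list],
                    "gene_id": gene.gene_id,
                    "beta": beta,
                    "se": se,
                    "pvalue": pval,
                    "n": n_study,
                    "study": study,
                    "qtl_type": qtl_type,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Target cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    panel: ReferencePanel,
    arch: ArchitectureSpec,
    n: int,
    seed: int,
    n_pcs: int = 20,
    incident_fraction: float = 0.4,
    proteomics_fraction: float = 0.0,
) -> Cohort:
    """Simulate the target cohort with a core-gene-mediated binary disease.

    Liability (log-odds) = intercept + sum over core genes of
    coef x standardized expression + sum of direct per-SNP effects x dosage.
    The intercept is solved numerically so the expected prevalence equals
    ``arch.prevalence_target``.  Expression is standardized to unit
    variance before the coefficient is applied, so core-gene coefficients
    are log odds ratios per SD of expression.  Covariates (sex, ``n_pcs``
    genotypic PCs) are simulated independent of genotype: they are
    nuisance adjustments, not objects of study here.
    """
    if panel.generator is None:
        raise ValueError("panel has no attached generative process")
    rng = np.random.default_rng(seed)
    X = panel.generator.draw(n, rng)
    col_of = {s.snp_id: j for j, s in enumerate(panel.snps)}

    expr = {}
    eta = np.zeros(n)
    for gene in arch.genes:
        y = _gene_expression(arch, gene, X, col_of, rng)
        sd = y.std()
        if sd == 0:
            raise ValueError(f"gene {gene.gene_id}: constant expression")
        z = (y - y.mean()) / sd
        expr[gene.gene_id] = z
        if gene.gene_id in arch.core_genes:
            eta += arch.core_genes[gene.gene_id] * z
    for sid, effect in arch.direct_snp_effects.items():
        eta += effect * X[:, col_of[sid]]

    def mean_prev(c: float) -> float:
        return float(expit(c + eta).mean())

    lo, hi = -40.0, 40.0
    if not (mean_prev(lo) - arch.prevalence_target < 0 < mean_prev(hi) - arch.prevalence_target):
        raise ValueError(
            f"prevalence_target {arch.prevalence_target} unreachable: achievable "
            f"range [{mean_prev(lo):.4g}, {mean_prev(hi):.4g}] given liability spread"
        )
    intercept = optimize.brentq(
        lambda c: mean_prev(c) - arch.prevalence_target, lo, hi, xtol=1e-10
    )
    prob = expit(intercept + eta)
    outcome = rng.binomial(1, prob).astype(np.int64)

    sex = rng.integers(0, 2, size=n)
    pcs = rng.standard_normal((n, n_pcs))
    covariates = pd.DataFrame({"sex": sex})
    for k in range(n_pcs):
        covariates[f"pc{k + 1}"] = pcs[:, k]

    incident = np.zeros(n, dtype=np.int64)
    cases = np.flatnonzero(outcome == 1)
    if len(cases):
        incident[cases] = rng.binomial(1, incident_fraction, size=len(cases))
    proteomics = (
        (rng.random(n) < proteomics_fraction).astype(np.int64)
        if proteomics_fraction > 0
        else np.zeros(n, dtype=np.int64)
    )

    return Cohort(
        sample_ids=[f"S{i:07d}" for i in range(n)],
        snps=panel.snps,
        dosages=X,
        outcome=outcome,
        covariates=covariates,
        incident_flag=incident,
        proteomics_subset_flag=proteomics,
        true_expression=pd.DataFrame(expr),
    )


# ---------------------------------------------------------------------------
# Canonical sparse-effector architecture
# ---------------------------------------------------------------------------


def sparse_architecture(
    n_genes: int = 50,
    n_core: int = 3,
    trans_blocks_per_gene: int = 7,
    snps_per_block: int = 3,
    trans_beta: float = 0.3,
    core_coef: float = 0.7,
    prevalence: float = 0.01,
    rho: float = 0.4,
    maf_range: tuple[float, float] = (0.25, 0.45),
    pleiotropy_sd: float = 0.0,
    seed: int = 0,
) -> ArchitectureSpec:
    """A ready-made omnigenic-style architecture for pipeline exercises.

    Each gene gets one cis block near its TSS and ``trans_blocks_per_gene``
    trans blocks on other chromosomes; the first SNP of every block is
    causal for expression with effect ``trans_beta`` per allele.  The
    expression noise SD is set so total expression variance is ~1, making
    per-SNP effects interpretable as SDs of expression.  The first
    ``n_core`` genes carry a disease coefficient of ``core_coef`` log-odds
    per SD of expression; disease prevalence defaults to ~1%, the rare-
    disease regime of a biobank autoimmune phenotype.  ``pleiotropy_sd``
    > 0 adds direct N(0, sd^2) log-odds effects to each causal trans SNP
    of core genes (violating the exclusion restriction, for MR stress
    tests); drawn reproducibly from ``seed``.
    """
    rng = np.random.default_rng(seed)
    blocks: list[LdBlockSpec] = []
    genes: list[GeneSpec] = []
    direct: dict[str, float] = {}
    mean_maf = 0.5 * (maf_range[0] + maf_range[1])
    var_per_snp = 2.0 * mean_maf * (1.0 - mean_maf)
    genetic_var = (trans_blocks_per_gene + 1) * trans_beta**2 * var_per_snp
    noise_sd = float(np.sqrt(max(1.0 - genetic_var, 0.25)))
    pos = 1_000_000
    for g in range(n_genes):
        gene_chrom = str(g % 4 + 1)
        trans_effects: dict[str, list[float]] = {}
        for t in range(trans_blocks_per_gene):
            bid = f"g{g}t{t}"
            bchrom = str((g + t) % 8 + 10)  # away from the gene's chromosome
            blocks.append(
                LdBlockSpec(
                    block_id=bid,
                    chrom=bchrom,
                    start_pos=pos,
                    n_snps=snps_per_block,
                    rho=rho,
                    maf_range=maf_range,
                )
            )
            trans_effects[bid] = [trans_beta] + [0.0] * (snps_per_block - 1)
            if pleiotropy_sd > 0 and g < n_core:
                direct[f"{bid}_s0"] = float(rng.normal(0.0, pleiotropy_sd))
            pos += 5_000_000
        cis_id = f"g{g}cis"
        blocks.append(
            LdBlockSpec(
                block_id=cis_id,
                chrom=gene_chrom,
                start_pos=pos,
                n_snps=snps_per_block,
                rho=rho,
                maf_range=maf_range,
            )
        )
        genes.append(
            GeneSpec(
                gene_id=f"gene{g:03d}",
                chrom=gene_chrom,
                tss_pos=pos + 1_000,
                cis_block=cis_id,
                cis_effects=[trans_beta] + [0.0] * (snps_per_block - 1),
                trans_effects=trans_effects,
                expression_noise_sd=noise_sd,
            )
        )
        pos += 5_000_000
    core = {f"gene{i:03d}": core_coef for i in range(n_core)}
    return ArchitectureSpec(
        blocks=blocks,
        genes=genes,
        core_genes=core,
        direct_snp_effects=direct,
        prevalence_target=prevalence,
    )
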