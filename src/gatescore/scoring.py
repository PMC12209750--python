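"""Locus scores, genome-wide aggregated trans (GATE) scores, Hill numbers.

A locus-specific score is the product of a clump's LD-adjusted weight
vector with the target cohort's dosage matrix (dosages centered at twice
the allele frequency, missing values mean-imputed per SNP).  The GATE
score for a gene is the element-wise sum of its *trans* locus scores;
cis loci are scored separately and never enter the aggregate.

The effective number of trans-QTLs behind a GATE score is the Hill
number / diversity index ``2**H`` where ``H`` is the Shannon entropy (in
bits) of the normalized locus-score variances p_i = sigma_i^2 / sum_j
sigma_j^2 — ranging from 1 (one dominant locus) to K (equal variances).
Variances are computed in the target cohort, so the index describes the
scores actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import Cohort
from .ldweights import WeightVector

logger = logging.getLogger(__name__)

__all__ = [
    "LocusScore",
    "GateScore",
    "locus_score",
    "cis_score",
    "aggregate_trans",
    "diversity_index",
]


@dataclass
class LocusScore:
    gene_id: str
    clump_id: str
    values: np.ndarray
    variance: float
    is_cis: bool

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


@dataclass
class GateScore:
    """Per-individual aggregated trans score for one gene."""

    gene_id: str
    values: np.ndarray
    n_loci: int
    locus_variances: list[float]
    effective_n: float
    study: str = ""
    score_sd: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not 1.0 - 1e-9 <= self.effective_n <= self.n_loci + 1e-9:
            raise ValueError("effective_n must lie in [1, K]")


def locus_score(cohort: Cohort, wv: WeightVector) -> LocusScore:
    """Score = centered dosage matrix @ weights, over cohort individuals.

    Dosages are centered by twice the cohort allele frequency (column
    mean), making scores mean-zero; association results are invariant to
    this given the intercept in the null model.  Missing dosages are
    mean-imputed per SNP.  SNPs absent from the cohort are dropped with a
    warning; if all are absent the locus cannot be scored.
    """
    idx = cohort.snp_index
    present = [s for s in wv.snp_ids if s in idx]
    if not present:
        raise KeyError(
            f"{wv.gene_id}/{wv.clump_id}: no weight SNPs present in cohort"
        )
    if len(present) < len(wv.snp_ids):
        logger.warning(
            "%s/%s: scoring on %d/%d SNPs present in cohort",
            wv.gene_id,
            wv.clump_id,
            len(present),
            len(wv.snp_ids),
        )
    keep = [i for i, s in enumerate(wv.snp_ids) if s in idx]
    X = cohort.columns(present).astype(float, copy=True)
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
        logger.warning(
            "%s/%s: mean-imputed %.3g%% missing dosages",
            wv.gene_id,
            wv.clump_id,
            100.0 * nan_mask.mean(),
        )
    Xc = X - col_mean
    values = Xc @ wv.weights[keep]
    var = float(values.var(ddof=1)) if len(values) > 1 else 0.0
    return LocusScore(
        gene_id=wv.gene_id,
        clump_id=wv.clump_id,
        values=values,
        variance=var,
        is_cis=wv.is_cis,
    )


def cis_score(cohort: Cohort, cis_wvs: list[WeightVector]) -> LocusScore:
    """Combined cis score for one gene (sum over its cis clumps)."""
    if not cis_wvs:
        raise ValueError("no cis weight vectors supplied")
    if any(not wv.is_cis for wv in cis_wvs):
        raise ValueError("cis_score received a trans weight vector")
    parts = [locus_score(cohort, wv) for wv in cis_wvs]
    values = np.sum([p.values for p in parts], axis=0)
    return LocusScore(
        gene_id=parts[0].gene_id,
        clump_id="cis",
        values=values,
        variance=float(values.var(ddof=1)) if len(values) > 1 else 0.0,
        is_cis=True,
    )


def diversity_index(variances: list[float] | np.ndarray) -> float:
    """Hill number 2**H of the normalized variance distribution.

    H is the Shannon entropy in bits of p_i = sigma_i^2 / sum sigma_j^2,
    with 0*log(0) = 0.  Equals K for equal variances and 1 when a single
    locus dominates; invariant to rescaling and permutation.
    """
    v = np.asarray(variances, dtype=float)
    if v.size == 0 or np.any(v < 0):
        raise ValueError("variances must be non-negative and non-empty")
    total = v.sum()
    if total == 0:
        raise ValueError("all locus variances are zero")
    p = v / total
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log2(nz)))
    return float(2.0**entropy)


def aggregate_trans(locus_scores: list[LocusScore], study: str = "") -> GateScore:
    """Element-wise sum of a gene's trans locus scores, with Hill number.

    Cis loci are excluded; a gene with zero trans loci cannot be
    aggregated (callers skip it with a logged reason).
    """
    trans = [ls for ls in locus_scores if not ls.is_cis]
    if not trans:
        raise ValueError("no trans loci to aggregate")
    gene_ids = {ls.gene_id for ls in trans}
    if len(gene_ids) != 1:
        raise ValueError(f"locus scores span multiple genes: {sorted(gene_ids)}")
    values = np.sum([ls.values for ls in trans], axis=0)
    variances = [ls.variance for ls in trans]
    return GateScore(
        gene_id=gene_ids.pop(),
        values=values,
        n_loci=len(trans),
        locus_variances=variances,
        effective_n=diversity_index(variances),
        study=study,
        score_sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    )
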