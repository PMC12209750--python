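"""LD-corrected multivariable weights from univariate summary statistics.

Within a clump, the vector of univariate regression coefficients is
multiplied by the (pseudo)inverse of the SNP-genotype correlation matrix
from the reference panel, converting marginal effects into multivariable
weights corrected for linkage disequilibrium.  A truncated-SVD
pseudoinverse handles ill-conditioned clumps of highly correlated SNPs:
singular values below ``svd_rtol`` x the largest are discarded, which
splits weight evenly across duplicated SNPs and leaves the resulting
locus score unchanged.

Correlations are computed on centered dosages; no standardization beyond
the correlation itself, so weights stay on the per-allele scale of the
input betas.  No shrinkage of R is applied by default (``ridge`` offers
an optional diagonal inflation for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ReferencePanel
from .ingest import Clump

__all__ = ["WeightVector", "snp_correlation", "adjust_weights", "clump_weights"]


@dataclass
class WeightVector:
    """Per-clump multivariable SNP weights (expression units per allele)."""

    gene_id: str
    clump_id: str
    snp_ids: list[str]
    weights: np.ndarray
    condition_number: float
    rank_used: int
    is_cis: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.snp_ids):
            raise ValueError("weights and snp_ids length mismatch")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weight")


def snp_correlation(panel: ReferencePanel, snp_ids: list[str]) -> np.ndarray:
    """Dosage correlation matrix of the given SNPs in the reference panel."""
    return panel.correlation(snp_ids)


def adjust_weights(
    betas: np.ndarray,
    R: np.ndarray,
    svd_rtol: float = 1e-6,
    gene_id: str = "",
    clump_id: str = "",
    snp_ids: list[str] | None = None,
    is_cis: bool = False,
    ridge: float = 0.0,
) -> WeightVector:
    """w = pinv(R) @ betas with singular values < svd_rtol * s_max dropped."""
    betas = np.asarray(betas, dtype=float).ravel()
    R = np.asarray(R, dtype=float)
    if R.shape != (len(betas), len(betas)):
        raise ValueError(f"R shape {R.shape} incompatible with {len(betas)} betas")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if ridge > 0.0:
        R = R + ridge * np.eye(len(betas))

    U, s, Vt = np.linalg.svd(R, hermitian=True)
    keep = s >= svd_rtol * s[0]
    rank_used = int(keep.sum())
    cond = float(s[0] / s[-1]) if s[-1] > 0 else float("inf")
    w = Vt[keep].T @ ((U[:, keep].T @ betas) / s[keep])
    return WeightVector(
        gene_id=gene_id,
        clump_id=clump_id,
        snp_ids=list(snp_ids) if snp_ids is not None else [str(i) for i in range(len(betas))],
        weights=w,
        condition_number=cond,
        rank_used=rank_used,
        is_cis=is_cis,
    )


def clump_weights(
    c: Clump, panel: ReferencePanel, svd_rtol: float = 1e-6
) -> WeightVector:
    """Convenience: LD-adjusted weights for one clump against the panel."""
    ids = c.snp_ids
    R = snp_correlation(panel, ids) if len(ids) > 1 else np.eye(1)
    return adjust_weights(
        c.betas,
        R,
        svd_rtol=svd_rtol,
        gene_id=c.gene_id,
        clump_id=c.clump_id,
        snp_ids=ids,
        is_cis=c.is_cis,
    )


def weight_table(wvs: list[WeightVector]):
    import pandas as pd

    rows = []
    for wv in wvs:
        for sid, w in zip(wv.snp_ids, wv.weights):
            rows.append(
                {
                    "gene_id": wv.gene_id,
                    "clump_id": wv.clump_id,
                    "snp_id": sid,
                    "weight": w,
                    "condition_number": wv.condition_number,
                    "rank_used": wv.rank_used,
                }
            )
    return pd.DataFrame(rows)
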