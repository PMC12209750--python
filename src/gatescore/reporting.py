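"""Core-gene filtering, validation criteria and report tables.

Candidate core genes must have an effective number of trans-QTLs
strictly greater than five and GATE-score association with disease at
P strictly below 1e-5; a secondary list admits genes within 200 kb of a
reported GWAS hit at the relaxed threshold P < 1e-3.  Validation
criteria combine GWAS-hit proximity, Mendelian randomization support
(P < 0.01, >= 10 instruments), measured-protein association (same
direction, magnitude at least twice the trans-score effect), and
curated experimental/drug/monogenic annotations supplied as a table —
the engine never scrapes literature.

The attenuation check encodes the expectation that if a protein is
causal, the effect size of the measured level exceeds that of a
genotypic score proxying it by a factor 1/r, where r is the correlation
of score with measured level (r^2 ~ 2% implies a ratio near 7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "GwasHitInterval",
    "filter_core_genes",
    "secondary_candidates",
    "gwas_proximity",
    "protein_validation",
    "attenuation_check",
    "assemble_validation_table",
    "score_correlation_matrix",
]


@dataclass(frozen=True)
class GwasHitInterval:
    """A reported GWAS association: position and attributed gene labels."""

    chrom: str
    pos: int
    attributed_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")


def filter_core_genes(
    associations: pd.DataFrame,
    min_effective_n: float = 5.0,
    max_p: float = 1e-5,
) -> pd.DataFrame:
    """Initial core-gene candidates: effective_n > 5 AND p < 1e-5 (strict)."""
    required = {"effective_n", "pvalue"}
    missing = required - set(associations.columns)
    if missing:
        raise ValueError(f"association table missing column(s): {sorted(missing)}")
    keep = (associations["effective_n"] > min_effective_n) & (
        associations["pvalue"] < max_p
    )
    logger.info("core-gene filter: %d / %d scores retained", int(keep.sum()), len(keep))
    return associations[keep].reset_index(drop=True)


def secondary_candidates(
    associations: pd.DataFrame,
    gwas_hit_flags: pd.Series | dict[str, bool],
    max_p: float = 1e-3,
) -> pd.DataFrame:
    """Genes near a GWAS hit with trans-score association at P < 1e-3."""
    flags = associations["gene_id"].map(
        gwas_hit_flags if isinstance(gwas_hit_flags, dict) else gwas_hit_flags.to_dict()
    )
    keep = (associations["pvalue"] < max_p) & flags.fillna(False).astype(bool)
    return associations[keep].reset_index(drop=True)


def gwas_proximity(
    gene_chrom: str,
    gene_tss: int,
    hits: list[GwasHitInterval],
    window: int = 200_000,
) -> tuple[bool, list[str]]:
    """Is any GWAS hit within ``window`` bp (closed) of the gene's TSS?

    Returns the flag and the attributed-gene labels of matching hits.
    Orthogonal to the GATE score itself, since cis SNPs are excluded
    from the score.
    """
    chrom = str(gene_chrom).removeprefix("chr")
    labels: list[str] = []
    found = False
    for h in hits:
        if str(h.chrom).removeprefix("chr") == chrom and abs(h.pos - gene_tss) <= window:
            found = True
            labels.extend(h.attributed_genes)
    return found, list(dict.fromkeys(labels))


def protein_validation(trans_log_or: float, protein_log_or: float, ratio: float = 2.0) -> bool:
    """Measured-protein criterion: same sign and |protein| >= ratio x |trans|."""
    if trans_log_or == 0:
        return False
    same_direction = np.sign(protein_log_or) == np.sign(trans_log_or)
    return bool(same_direction and abs(protein_log_or) >= ratio * abs(trans_log_or))


def attenuation_check(
    r2_score_protein: float,
    trans_log_or: float,
    protein_log_or: float,
    factor_range: tuple[float, float] = (0.5, 2.0),
) -> tuple[float, float, bool]:
    """Predicted vs observed protein:score effect-size ratio.

    predicted = 1/sqrt(r^2); observed = protein / trans.  ``consistent``
    if observed lies within ``factor_range`` x predicted.  Monotone
    decreasing in r^2: the better the score proxies the protein, the
    smaller the expected attenuation.
    """
    if not 0.0 < r2_score_protein <= 1.0:
        raise ValueError("r2 must be in (0, 1]")
    if trans_log_or == 0:
        raise ValueError("trans effect must be nonzero")
    predicted = 1.0 / np.sqrt(r2_score_protein)
    observed = protein_log_or / trans_log_or
    lo, hi = factor_range
    consistent = bool(lo * predicted <= observed <= hi * predicted)
    return float(predicted), float(observed), consistent


def assemble_validation_table(
    candidates: pd.DataFrame,
    gwas_flags: dict[str, bool] | None = None,
    gwas_labels: dict[str, list[str]] | None = None,
    mr_results: pd.DataFrame | None = None,
    protein_results: pd.DataFrame | None = None,
    curated: pd.DataFrame | None = None,
    h2_trans: dict[str, float] | None = None,
    r2_score_protein: dict[str, float] | None = None,
    mr_p: float = 0.01,
    protein_ratio: float = 2.0,
) -> pd.DataFrame:
    """One row per candidate gene with a boolean column per criterion.

    Curated criteria (mouse model, drug effect, monogenic disease) come
    from a user-supplied annotation table indexed by gene_id; genes
    absent from an input are rendered as missing (pd.NA), never as
    False.  The MR column is populated only for eligible genes
    (>= 10 instruments).
    """
    if candidates.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "study", "effective_n", "trans_log_or_std", "trans_p",
                "gwas_hit_within_200kb", "gwas_hit_labels", "mr_pass",
                "protein_log_or_std", "protein_p", "protein_pass",
                "r2_score_protein", "h2_trans", "ratio_r2_h2",
                "mouse_model", "drug_effect", "monogenic",
            ]
        )
    mr_map = (
        mr_results.set_index("gene_id") if mr_results is not None else pd.DataFrame()
    )
    prot_map = (
        protein_results.set_index("gene_id") if protein_results is not None else pd.DataFrame()
    )
    cur_map = curated.set_index("gene_id") if curated is not None else pd.DataFrame()

    rows = []
    for row in candidates.itertuples():
        g = row.gene_id
        rec: dict = {
            "gene_id": g,
            "study": getattr(row, "study", ""),
            "effective_n": row.effective_n,
            "trans_log_or_std": row.log_or_std,
            "trans_p": row.pvalue,
            "gwas_hit_within_200kb": (gwas_flags or {}).get(g, pd.NA),
            "gwas_hit_labels": ";".join((gwas_labels or {}).get(g, [])),
        }
        if g in mr_map.index and bool(mr_map.loc[g, "eligible"]):
            rec["mr_pass"] = bool(mr_map.loc[g, "pvalue"] < mr_p)
        else:
            rec["mr_pass"] = pd.NA
        if g in prot_map.index:
            p_lor = float(prot_map.loc[g, "log_or_std"])
            rec["protein_log_or_std"] = p_lor
            rec["protein_p"] = float(prot_map.loc[g, "pvalue"])
            rec["protein_pass"] = protein_validation(
                row.log_or_std, p_lor, ratio=protein_ratio
            )
        else:
            rec["protein_log_or_std"] = pd.NA
            rec["protein_p"] = pd.NA
            rec["protein_pass"] = pd.NA
        r2 = (r2_score_protein or {}).get(g)
        h2 = (h2_trans or {}).get(g)
        rec["r2_score_protein"] = r2 if r2 is not None else pd.NA
        rec["h2_trans"] = h2 if h2 is not None else pd.NA
        rec["ratio_r2_h2"] = (
            r2 / h2 if (r2 is not None and h2 is not None and h2 > 0) else pd.NA
        )
        for crit in ("mouse_model", "drug_effect", "monogenic"):
            rec[crit] = (
                bool(cur_map.loc[g, crit])
                if g in cur_map.index and crit in cur_map.columns
                else pd.NA
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def score_correlation_matrix(scores: dict[str, np.ndarray]) -> pd.DataFrame:
    """Correlation matrix of GATE scores, ordered by hierarchical clustering.

    Average-linkage clustering on 1 - |correlation|; the diagonal is
    reported as 1 (zeroing it is a display convention only).  Weak
    off-diagonal correlation indicates that genes do not share most of
    their trans-QTLs.
    """
    genes = list(scores)
    if len(genes) < 2:
        raise ValueError("need at least two scores")
    M = np.column_stack([scores[g] for g in genes])
    R = np.corrcoef(M, rowvar=False)
    dist = 1.0 - np.abs(R)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    order = hierarchy.leaves_list(
        hierarchy.average(squareform(dist, checks=False))
    )
    ordered = [genes[i] for i in order]
    return pd.DataFrame(R[np.ix_(order, order)], index=ordered, columns=ordered)
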