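"""QTL summary-statistic ingestion, filtering and clumping.

Summary statistics are tables of univariate per-SNP regression
coefficients of gene expression (transcript or circulating protein), one
row per SNP x gene.  This module applies the extraction p-value filter,
masks the HLA trans-QTL hotspot (chr6:25-34 Mb), classifies associations
as cis or trans relative to the gene's transcription start site, and
groups associated SNPs into clumps — PLINK-style greedy p-ordered
clumping against a reference-panel LD matrix, each clump anchored by a
lead SNP below the anchor threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ReferencePanel, SnpRecord

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "gene_id",
    "beta",
    "se",
    "pvalue",
    "n",
    "study",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _norm_chrom(values: pd.Series) -> pd.Series:
    return values.astype(str).str.removeprefix("chr")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene location: chromosome and transcription start position (1-based)."""

    gene_id: str
    chrom: str
    tss_pos: int


def load_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chrom, tss_pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"gene_id", "chrom", "tss_pos"} - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing column(s): {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("gene annotation contains duplicate gene_id")
    df["chrom"] = _norm_chrom(df["chrom"])
    return df


def load_summary_stats(
    path: str | Path,
    study: str | None = None,
    qtl_type: str | None = None,
) -> pd.DataFrame:
    """Load a QTL summary-statistics TSV into the canonical table.

    Rows with missing beta/se/pvalue, or with se <= 0 or pvalue outside
    (0, 1], are dropped with a logged count.  p-values are cross-checked
    against the normal approximation 2*Phi(-|beta/se|); rows deviating by
    more than 10% (relative) trigger a warning, not removal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing required column(s): {missing}")
    if study is not None:
        df["study"] = study
    if qtl_type is not None:
        df["qtl_type"] = qtl_type
    df["chrom"] = _norm_chrom(df["chrom"])

    n0 = len(df)
    df = df.dropna(subset=["beta", "se", "pvalue"])
    df = df[(df["se"] > 0) & (df["pvalue"] > 0) & (df["pvalue"] <= 1)]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("dropped %d malformed summary-statistic rows", dropped)

    expected = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    with np.errstate(divide="ignore"):
        rel = np.abs(np.log(df["pvalue"].to_numpy() / np.maximum(expected, 1e-300)))
    n_bad = int((rel > np.log(1.1)).sum())
    if n_bad:
        logger.warning(
            "%d rows have p-values inconsistent with beta/se under the normal "
            "approximation (>10%% relative)",
            n_bad,
        )
    return df.reset_index(drop=True)


def filter_by_pvalue(assocs: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain rows with pvalue strictly below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    out = assocs[assocs["pvalue"] < threshold].reset_index(drop=True)
    logger.info("p-value filter at %g: %d -> %d rows", threshold, len(assocs), len(out))
    return out


def mask_hla(
    assocs: pd.DataFrame,
    chrom: str = "6",
    start: int = 25_000_000,
    end: int = 34_000_000,
) -> pd.DataFrame:
    """Remove SNPs in the HLA region (chr6:25-34 Mb, closed interval).

    The HLA region is a trans-QTL hotspot whose associations with
    autoimmune disease are confounded by direct HLA effects; it is
    excluded before any score computation.  Idempotent.
    """
    in_hla = (
        (_norm_chrom(assocs["chrom"]) == chrom)
        & (assocs["pos"] >= start)
        & (assocs["pos"] <= end)
    )
    if in_hla.any():
        logger.info("HLA mask removed %d rows", int(in_hla.sum()))
    return assocs[~in_hla].reset_index(drop=True)


def classify_cis_trans(
    assocs: pd.DataFrame,
    genes: pd.DataFrame,
    cis_window: int = 1_000_000,
) -> pd.Series:
    """Boolean ``is_cis`` per row: same chromosome and |pos - TSS| <= window.

    The window boundary is inclusive (closed interval); classification
    depends only on |distance|, never on strand.  Unknown gene ids raise.
    """
    gmap = genes.set_index("gene_id")
    unknown = set(assocs["gene_id"]) - set(gmap.index)
    if unknown:
        raise KeyError(f"gene_id(s) absent from annotation: {sorted(unknown)[:5]}")
    gchrom = assocs["gene_id"].map(gmap["chrom"]).astype(str)
    gtss = assocs["gene_id"].map(gmap["tss_pos"])
    is_cis = (_norm_chrom(assocs["chrom"]) == gchrom) & (
        (assocs["pos"] - gtss).abs() <= cis_window
    )
    return is_cis.rename("is_cis")


def harmonize_alleles(assocs: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Re-sign betas to the panel's counted (effect) allele.

    Rows whose alleles match the panel's pair but are swapped get their
    beta sign flipped; strand flips (complemented pairs) are resolved the
    same way.  Strand-ambiguous A/T and C/G SNPs, SNPs absent from the
    panel, and allele pairs that cannot be reconciled are dropped with a
    warning.
    """
    idx = panel.snp_index
    keep_rows, betas = [], []
    n_ambig = n_mismatch = n_absent = 0
    for row in assocs.itertuples():
        j = idx.get(row.snp_id)
        if j is None:
            n_absent += 1
            continue
        ea, oa = str(row.effect_allele), str(row.other_allele)
        if _COMPLEMENT.get(ea) == oa:
            n_ambig += 1
            continue
        p = panel.snps[j]
        pair = (ea, oa)
        comp = (_COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?"))
        if pair == (p.effect_allele, p.other_allele) or comp == (p.effect_allele, p.other_allele):
            flip = 1.0
        elif pair == (p.other_allele, p.effect_allele) or comp == (p.other_allele, p.effect_allele):
            flip = -1.0
        else:
            n_mismatch += 1
            continue
        keep_rows.append(row.Index)
        betas.append(flip * row.beta)
    if n_ambig or n_mismatch or n_absent:
        logger.warning(
            "allele harmonization dropped %d ambiguous, %d mismatched, "
            "%d panel-absent SNPs",
            n_ambig,
            n_mismatch,
            n_absent,
        )
    out = assocs.loc[keep_rows].copy()
    out["beta"] = betas
    return out.reset_index(drop=True)


@dataclass
class Clump:
    """A locus: LD-grouped associated SNPs anchored by a lead SNP."""

    gene_id: str
    clump_id: str
    chrom: str
    lead_snp: SnpRecord
    members: pd.DataFrame  # rows of the association table for member SNPs
    span: tuple[int, int]
    is_cis: bool
    study: str

    def __post_init__(self) -> None:
        if self.lead_snp.snp_id not in set(self.members["snp_id"]):
            raise ValueError("lead SNP must be a clump member")
        lo, hi = self.span
        if not ((self.members["pos"] >= lo) & (self.members["pos"] <= hi)).all():
            raise ValueError("span does not cover all members")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.members["snp_id"])

    @property
    def betas(self) -> np.ndarray:
        return self.members["beta"].to_numpy(dtype=float)


def clump(
    assocs: pd.DataFrame,
    panel: ReferencePanel,
    extraction_p: float = 1e-5,
    anchor_p: float = 1e-6,
    r2_threshold: float = 0.1,
    window: int = 1_000_000,
    is_cis: bool = False,
) -> list[Clump]:
    """Greedy p-ordered clumping of one gene's associations.

    SNPs are first filtered at ``extraction_p``.  Repeatedly, the
    unassigned SNP with the smallest p-value below ``anchor_p`` becomes a
    lead (ties broken by (chrom, pos)); every unassigned SNP on the same
    chromosome within ``window`` bp of the lead with panel r^2 >=
    ``r2_threshold`` joins its clump.  Clumps are disjoint and each
    contains at least one SNP below ``anchor_p``.  SNPs absent from the
    panel are excluded with a warning.
    """
    gene_ids = assocs["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValueError(f"clump() expects one gene, got {len(gene_ids)}")
    gene_id = str(gene_ids[0])

    df = assocs[assocs["pvalue"] < extraction_p].copy()
    present = df["snp_id"].isin(panel.snp_index)
    if (~present).any():
        logger.warning(
            "gene %s: %d SNP(s) absent from reference panel, excluded",
            gene_id,
            int((~present).sum()),
        )
        df = df[present]
    if df.empty:
        return []
    df["chrom"] = _norm_chrom(df["chrom"])
    df = df.sort_values(
        ["pvalue", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)

    unassigned = np.ones(len(df), dtype=bool)
    clumps: list[Clump] = []
    snp_map = {s.snp_id: s for s in panel.snps}
    while True:
        cand = np.flatnonzero(unassigned & (df["pvalue"].to_numpy() < anchor_p))
        if len(cand) == 0:
            break
        lead_i = int(cand[0])
        lead = df.iloc[lead_i]
        near = (
            unassigned
            & (df["chrom"] == lead["chrom"]).to_numpy()
            & ((df["pos"] - lead["pos"]).abs() <= window).to_numpy()
        )
        near_idx = np.flatnonzero(near)
        other_ids = df.iloc[near_idx]["snp_id"].tolist()
        r2 = panel.r2_with(str(lead["snp_id"]), other_ids)
        member_idx = near_idx[(r2 >= r2_threshold) | (np.array(other_ids) == lead["snp_id"])]
        members = df.iloc[member_idx].sort_values("pos").reset_index(drop=True)
        unassigned[member_idx] = False
        kind = "cis" if is_cis else "trans"
        clumps.append(
            Clump(
                gene_id=gene_id,
                clump_id=f"{gene_id}_{kind}{len(clumps)}",
                chrom=str(lead["chrom"]),
                lead_snp=snp_map[str(lead["snp_id"])],
                members=members,
                span=(int(members["pos"].min()), int(members["pos"].max())),
                is_cis=is_cis,
                study=str(lead["study"]),
            )
        )
    return clumps


def clump_table(clumps: list[Clump]) -> pd.DataFrame:
    """Summarize clumps as the TSV-ready table."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in clumps],
            "clump_id": [c.clump_id for c in clumps],
            "lead_snp": [c.lead_snp.snp_id for c in clumps],
            "n_snps": [len(c.members) for c in clumps],
            "span_start": [c.span[0] for c in clumps],
            "span_end": [c.span[1] for c in clumps],
            "is_cis": [c.is_cis for c in clumps],
            "study": [c.study for c in clumps],
        }
    )
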