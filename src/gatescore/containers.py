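"""Shared in-memory containers: SNPs, the LD reference panel, the cohort.

The reference panel stands in for the 1000 Genomes panel used to compute LD
correlation matrices; the cohort is the target dataset (genotype dosages,
binary disease status, sex and genotypic principal components) in which the
scores are computed and tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP; dosages count copies of ``effect_allele``."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    allele_freq: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must be distinct")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1 (1-based)")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError(f"{self.snp_id}: allele_freq must be in (0,1)")


class _SnpIndexMixin:
    """Column lookup shared by panel and cohort genotype matrices."""

    snps: list[SnpRecord]
    dosages: np.ndarray

    def __len__(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_index(self) -> dict[str, int]:
        cached = getattr(self, "_snp_index", None)
        if cached is None:
            cached = {s.snp_id: j for j, s in enumerate(self.snps)}
            object.__setattr__(self, "_snp_index", cached)
        return cached

    def columns(self, snp_ids: list[str]) -> np.ndarray:
        """Dosage submatrix for the requested SNPs, in the requested order."""
        idx = self.snp_index
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise KeyError(f"SNPs absent from genotype matrix: {missing[:5]}")
        return self.dosages[:, [idx[s] for s in snp_ids]]


@dataclass
class ReferencePanel(_SnpIndexMixin):
    """LD reference genotypes: individuals x SNPs dosage matrix in [0, 2]."""

    snps: list[SnpRecord]
    dosages: np.ndarray
    generator: object | None = None  # generative process, set by the simulator

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage matrix shape does not match SNP list")
        sd = self.dosages.std(axis=0)
        if np.any(sd == 0):
            bad = [self.snps[j].snp_id for j in np.flatnonzero(sd == 0)]
            raise ValueError(
                f"constant dosage column(s) in panel (monomorphic): {bad[:5]}; "
                "increase panel size or allele frequency"
            )

    # ---- LD queries -------------------------------------------------

    def correlation(self, snp_ids: list[str]) -> np.ndarray:
        """Pearson correlation matrix of the dosages of the given SNPs."""
        X = self.columns(snp_ids)
        if np.any(X.std(axis=0) == 0):
            raise ValueError("constant dosage column: correlation undefined")
        R = np.corrcoef(X, rowvar=False)
        return np.atleast_2d(R)

    def r2_with(self, snp_id: str, other_ids: list[str]) -> np.ndarray:
        """Squared correlation of one SNP with each of a list of SNPs."""
        x = self.columns([snp_id])[:, 0]
        Y = self.columns(other_ids)
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0)
        denom = np.sqrt((xc @ xc) * np.sum(Yc * Yc, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Yc.T @ xc) / denom
        return r**2

    # ---- serialization ----------------------------------------------

    def to_vcf(self, path: str | Path) -> None:
        """Write the panel as an uncompressed VCF with a DS (dosage) FORMAT."""
        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">')
        for chrom in dict.fromkeys(s.chrom for s in self.snps):
            header.contigs.add(chrom)
        n = len(self)
        sample_names = [f"ind{i}" for i in range(n)]
        for name in sample_names:
            header.add_sample(name)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for j, s in enumerate(self.snps):
                rec = vcf.new_record(
                    contig=s.chrom,
                    start=s.pos - 1,
                    stop=s.pos,
                    alleles=(s.other_allele, s.effect_allele),
                    id=s.snp_id,
                )
                col = self.dosages[:, j]
                for i, name in enumerate(sample_names):
                    rec.samples[name]["DS"] = float(col[i])
                vcf.write(rec)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "ReferencePanel":
        """Read a panel from VCF; uses DS if present, else sums GT alleles."""
        snps: list[SnpRecord] = []
        cols: list[np.ndarray] = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if len(rec.alts or ()) != 1:
                    logger.warning("skipping non-biallelic record %s", rec.id)
                    continue
                values = []
                for sample in rec.samples.values():
                    if "DS" in sample and sample["DS"] is not None:
                        values.append(float(sample["DS"]))
                    else:
                        gt = sample.get("GT", ())
                        values.append(float(sum(a or 0 for a in gt)))
                col = np.asarray(values)
                freq = float(col.mean() / 2.0)
                freq = min(max(freq, 1e-9), 1 - 1e-9)
                snps.append(
                    SnpRecord(
                        snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                        chrom=str(rec.chrom),
                        pos=rec.pos,
                        effect_allele=rec.alts[0],
                        other_allele=rec.ref,
                        allele_freq=freq,
                    )
                )
                cols.append(col)
        return cls(snps=snps, dosages=np.column_stack(cols))

    def to_traw(self, path: str | Path) -> None:
        """Write PLINK-style transposed raw text (.traw dialect).

        Columns: CHR SNP (C)M POS COUNTED ALT then one dosage column per
        individual; dosages count the COUNTED (effect) allele.
        """
        meta = pd.DataFrame(
            {
                "CHR": [s.chrom for s in self.snps],
                "SNP": [s.snp_id for s in self.snps],
                "(C)M": 0,
                "POS": [s.pos for s in self.snps],
                "COUNTED": [s.effect_allele for s in self.snps],
                "ALT": [s.other_allele for s in self.snps],
            }
        )
        geno = pd.DataFrame(
            self.dosages.T, columns=[f"0_ind{i}" for i in range(len(self))]
        )
        pd.concat([meta, geno], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_traw(cls, path: str | Path) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t")
        fixed = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
        dosages = df.drop(columns=fixed).to_numpy(dtype=float).T
        snps = []
        for j, row in df.iterrows():
            freq = float(dosages[:, j].mean() / 2.0)
            freq = min(max(freq, 1e-9), 1 - 1e-9)
            snps.append(
                SnpRecord(
                    snp_id=str(row["SNP"]),
                    chrom=str(row["CHR"]),
                    pos=int(row["POS"]),
                    effect_allele=str(row["COUNTED"]),
                    other_allele=str(row["ALT"]),
                    allele_freq=freq,
                )
            )
        return cls(snps=snps, dosages=dosages)


@dataclass
class Cohort(_SnpIndexMixin):
    """Target cohort: dosages, binary outcome, sex + 20 genotypic PCs."""

    sample_ids: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray
    outcome: np.ndarray
    covariates: pd.DataFrame
    incident_flag: np.ndarray | None = None
    proteomics_subset_flag: np.ndarray | None = None
    true_expression: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.dosages.shape != (n, len(self.snps)):
            raise ValueError("dosage matrix shape mismatch")
        self.outcome = np.asarray(self.outcome)
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        if len(self.covariates) != n:
            raise ValueError("covariate rows do not align with sample_ids")

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    def phenotype_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": self.sample_ids, "outcome": self.outcome})
        out = pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)
        if self.incident_flag is not None:
            out["incident_flag"] = self.incident_flag
        if self.proteomics_subset_flag is not None:
            out["proteomics_subset_flag"] = self.proteomics_subset_flag
        return out

    def to_phenotype_tsv(self, path: str | Path) -> None:
        self.phenotype_frame().to_csv(path, sep="\t", index=False)
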