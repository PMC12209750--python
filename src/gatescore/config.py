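"""Pipeline-wide thresholds and tunables.

Every cutoff used by the filtering, clumping and validation stages lives in
one :class:`GateConfig` object so that a whole analysis is reproducible from
a single YAML file.  Defaults follow the published GATE protocol: SNPs enter
at P < 1e-5, clumps are anchored at P < 1e-6 (relaxed to 1e-5 for
trait-associated-SNP designs such as eQTLGen phase 1), the HLA region
chr6:25-34 Mb is masked, candidate core genes require an effective number of
trans-QTLs > 5 and GATE-score association P < 1e-5, GWAS-hit proximity uses
a 200 kb window, and Mendelian randomization requires >= 10 instruments.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class GateConfig(BaseModel):
    """All thresholds of the GATE analysis, with protocol defaults."""

    # SNP extraction / clumping
    extraction_p: float = Field(1e-5, gt=0, le=1)
    anchor_p: float = Field(1e-6, gt=0, le=1)
    r2_threshold: float = Field(0.1, gt=0, le=1)
    clump_window: int = Field(1_000_000, ge=1)

    # cis/trans classification and the HLA mask
    cis_window: int = Field(1_000_000, ge=0)
    hla_chrom: str = "6"
    hla_start: int = 25_000_000
    hla_end: int = 34_000_000

    # LD-weight numerics
    svd_rtol: float = Field(1e-6, gt=0)

    # core-gene filtering
    min_effective_n: float = 5.0
    gate_p: float = 1e-5
    secondary_p: float = 1e-3
    gwas_window: int = 200_000

    # Mendelian randomization
    mr_min_instruments: int = 10
    mr_p: float = 0.01

    # protein validation
    protein_ratio: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GateConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


DEFAULT_CONFIG = GateConfig()
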