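"""Summary-stats loading, filters, HLA mask, cis/trans, clumping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gatescore import (
    classify_cis_trans,
    clump,
    filter_by_pvalue,
    harmonize_alleles,
    load_summary_stats,
    mask_hla,
)
from gatescore.ingest import REQUIRED_COLUMNS

from .conftest import manual_panel


def assoc_frame(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "snp_id": "s",
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "gene_id": "g",
        "beta": 0.1,
        "se": 0.02,
        "pvalue": 1e-7,
        "n": 1000,
        "study": "S",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestLoad:
    def test_well_formed_file(self, tmp_path):
        df = assoc_frame([{"snp_id": f"s{i}", "pvalue": 1e-6} for i in range(3)])
        p = tmp_path / "ss.tsv"
        df.to_csv(p, sep="\t", index=False)
        out = load_summary_stats(p)
        assert len(out) == 3
        assert list(out.columns[: len(REQUIRED_COLUMNS)]) == REQUIRED_COLUMNS

    def test_zero_se_row_dropped(self, tmp_path, caplog):
        df = assoc_frame([{"snp_id": "a"}, {"snp_id": "b", "se": 0.0}])
        p = tmp_path / "ss.tsv"
        df.to_csv(p, sep="\t", index=False)
        with caplog.at_level("WARNING"):
            out = load_summary_stats(p)
        assert list(out["snp_id"]) == ["a"]
        assert any("dropped 1" in m for m in caplog.messages)

    def test_missing_column_is_hard_error(self, tmp_path):
        df = assoc_frame([{}]).drop(columns=["se"])
        p = tmp_path / "ss.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="se"):
            load_summary_stats(p)

    def test_inconsistent_pvalue_warns_but_keeps(self, tmp_path, caplog):
        df = assoc_frame([{"beta": 0.1, "se": 0.02, "pvalue": 0.5}])
        p = tmp_path / "ss.tsv"
        df.to_csv(p, sep="\t", index=False)
        with caplog.at_level("WARNING"):
            out = load_summary_stats(p)
        assert len(out) == 1
        assert any("inconsistent" in m for m in caplog.messages)


class TestFilters:
    def test_pvalue_filter_is_strict(self):
        df = assoc_frame([{"snp_id": "a", "pvalue": 1e-6}, {"snp_id": "b", "pvalue": 1e-4}])
        assert list(filter_by_pvalue(df, 1e-5)["snp_id"]) == ["a"]
        # boundary: exactly at threshold is excluded
        df2 = assoc_frame([{"pvalue": 1e-5}])
        assert filter_by_pvalue(df2, 1e-5).empty

    def test_threshold_one_keeps_all_and_empty_in_empty_out(self):
        df = assoc_frame([{"pvalue": 0.99}, {"pvalue": 1e-10}])
        assert len(filter_by_pvalue(df, 1.0)) == 2
        assert filter_by_pvalue(df.iloc[:0], 0.5).empty

    @pytest.mark.parametrize(
        ("chrom", "pos", "kept"),
        [
            ("6", 30_000_000, False),
            ("6", 25_000_000, False),  # closed lower boundary
            ("6", 34_000_000, False),  # closed upper boundary
            ("6", 24_999_999, True),
            ("6", 34_000_001, True),
            ("7", 30_000_000, True),
            ("chr6", 30_000_000, False),  # chr-prefixed dialect
        ],
    )
    def test_hla_mask_boundaries(self, chrom, pos, kept):
        df = assoc_frame([{"chrom": chrom, "pos": pos}])
        assert (len(mask_hla(df)) == 1) is kept

    def test_hla_mask_idempotent(self):
        df = assoc_frame(
            [{"chrom": "6", "pos": 26_000_000}, {"chrom": "1", "pos": 26_000_000}]
        )
        once = mask_hla(df)
        twice = mask_hla(once)
        pd.testing.assert_frame_equal(once, twice)


class TestCisTrans:
    genes = pd.DataFrame(
        {"gene_id": ["g"], "chrom": ["1"], "tss_pos": [10_000_000]}
    )

    @pytest.mark.parametrize(
        ("chrom", "pos", "expect_cis"),
        [
            ("1", 10_150_000, True),            # 150 kb away
            ("2", 10_150_000, False),           # other chromosome
            ("1", 11_000_000, True),            # exactly at window: closed
            ("1", 11_000_001, False),
            ("1", 9_000_000, True),             # symmetric in |distance|
            ("1", 8_999_999, False),
        ],
    )
    def test_window_semantics(self, chrom, pos, expect_cis):
        df = assoc_frame([{"chrom": chrom, "pos": pos}])
        assert classify_cis_trans(df, self.genes, cis_window=1_000_000).iloc[0] is np.bool_(
            expect_cis
        )

    def test_unknown_gene_raises(self):
        df = assoc_frame([{"gene_id": "nope"}])
        with pytest.raises(KeyError, match="nope"):
            classify_cis_trans(df, self.genes)


class TestHarmonize:
    def _panel(self):
        rng = np.random.default_rng(0)
        return manual_panel({"s1": rng.integers(0, 3, 500).astype(float)})

    def test_swapped_alleles_flip_beta(self):
        panel = self._panel()  # panel counts A vs G
        df = assoc_frame(
            [
                {"snp_id": "s1", "effect_allele": "A", "other_allele": "G", "beta": 0.5},
                {"snp_id": "s1", "effect_allele": "G", "other_allele": "A", "beta": 0.5},
            ]
        )
        out = harmonize_alleles(df, panel)
        assert np.allclose(out["beta"], [0.5, -0.5])

    def test_ambiguous_and_absent_snps_dropped(self, caplog):
        panel = self._panel()
        df = assoc_frame(
            [
                {"snp_id": "s1", "effect_allele": "A", "other_allele": "T"},  # ambiguous
                {"snp_id": "missing"},
            ]
        )
        with caplog.at_level("WARNING"):
            out = harmonize_alleles(df, panel)
        assert out.empty


class TestClump:
    def _panel_with_positions(self, positions):
        """lead + strong-LD neighbor (r^2 ~ 0.8) + independent distant SNP."""
        rng = np.random.default_rng(42)
        x1 = rng.binomial(2, 0.3, 20_000).astype(float)
        x2 = x1.copy()
        flip = rng.random(20_000) < 0.11
        x2[flip] = rng.binomial(2, 0.3, int(flip.sum()))
        x3 = rng.binomial(2, 0.3, 20_000).astype(float)
        from gatescore import ReferencePanel, SnpRecord

        names = ["lead", "friend", "far"]
        cols = [x1, x2, x3]
        snps = [
            SnpRecord(n, "1", p, "A", "G", float(c.mean() / 2))
            for n, p, c in zip(names, positions, cols)
        ]
        return ReferencePanel(snps=snps, dosages=np.column_stack(cols))

    def test_correlated_neighbor_joins_anchor_clump(self):
        panel = self._panel_with_positions([1_000_000, 1_050_000, 9_000_000])
        r2 = panel.r2_with("lead", ["friend"])[0]
        assert r2 > 0.5  # constructed LD
        df = assoc_frame(
            [
                {"snp_id": "lead", "pos": 1_000_000, "pvalue": 1e-9},
                {"snp_id": "friend", "pos": 1_050_000, "pvalue": 1e-7},
                {"snp_id": "far", "pos": 9_000_000, "pvalue": 1e-8},
            ]
        )
        clumps = clump(df, panel, anchor_p=1e-6, r2_threshold=0.5)
        assert len(clumps) == 2
        by_lead = {c.lead_snp.snp_id: c for c in clumps}
        assert set(by_lead) == {"lead", "far"}
        assert set(by_lead["lead"].snp_ids) == {"lead", "friend"}
        assert by_lead["lead"].span == (1_000_000, 1_050_000)

    def test_independent_anchors_make_separate_clumps(self):
        panel = self._panel_with_positions([1_000_000, 1_050_000, 9_000_000])
        df = assoc_frame(
            [
                {"snp_id": "lead", "pos": 1_000_000, "pvalue": 1e-9},
                {"snp_id": "far", "pos": 9_000_000, "pvalue": 1e-8},
            ]
        )
        clumps = clump(df, panel, anchor_p=1e-6)
        assert len(clumps) == 2

    def test_no_anchor_means_no_clumps(self):
        panel = self._panel_with_positions([1_000_000, 1_050_000, 9_000_000])
        df = assoc_frame([{"snp_id": "lead", "pos": 1_000_000, "pvalue": 1e-5}])
        assert clump(df, panel, anchor_p=1e-6) == []

    def test_snp_absent_from_panel_excluded_with_warning(self, caplog):
        panel = self._panel_with_positions([1_000_000, 1_050_000, 9_000_000])
        df = assoc_frame(
            [
                {"snp_id": "lead", "pos": 1_000_000, "pvalue": 1e-9},
                {"snp_id": "ghost", "pos": 1_010_000, "pvalue": 1e-9},
            ]
        )
        with caplog.at_level("WARNING"):
            clumps = clump(df, panel, anchor_p=1e-6)
        assert len(clumps) == 1 and clumps[0].lead_snp.snp_id == "lead"
        assert any("absent" in m for m in caplog.messages)

    def test_clumps_disjoint_and_anchored(self, tiny_panel):
        """Property: every SNP in at most one clump; every clump has an anchor."""
        rng = np.random.default_rng(1)
        ids = [s.snp_id for s in tiny_panel.snps]
        df = assoc_frame(
            [
                {
                    "snp_id": sid,
                    "chrom": tiny_panel.snps[i].chrom,
                    "pos": tiny_panel.snps[i].pos,
                    "pvalue": float(10.0 ** -rng.uniform(5, 12)),
                }
                for i, sid in enumerate(ids)
            ]
        )
        clumps = clump(df, tiny_panel, anchor_p=1e-6)
        seen: list[str] = []
        for c in clumps:
            assert c.members["pvalue"].min() < 1e-6
            seen.extend(c.snp_ids)
        assert len(seen) == len(set(seen))
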