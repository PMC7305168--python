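"""TE quantification: fractional family counting, unique-copy counts,
upregulated-copy summaries, ERV-proximal gene effects, LTR metaplots."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methtx import diffexpr, te
from methtx.intervals import TranscriptModel


def te_table(rows):
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "family", "te_class"]
    )
    df["copy_id"] = (
        df["chrom"] + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
        + ":" + df["family"]
    )
    df["length"] = df["end"] - df["start"]
    df["repeat_class"] = "LTR/" + df["te_class"]
    return df


def aln_table(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "start", "end", "strand", "n_hits"]
    )


ANNOT = te_table(
    [
        ("chr1", 1000, 5000, "+", "famA", "ERVK"),
        ("chr1", 10_000, 14_000, "+", "famA", "ERVK"),
        ("chr1", 20_000, 24_000, "-", "famB", "ERV1"),
        ("chr1", 24_000, 28_000, "+", "famB", "ERV1"),
    ]
)


class TestFamilyCounting:
    def test_multimapper_splits_mass_between_families(self):
        aln = aln_table(
            [
                ("r1", "chr1", 1000, 1080, "+", 4),
                ("r1", "chr1", 10_000, 10_080, "+", 4),
                ("r1", "chr1", 20_000, 20_080, "-", 4),
                ("r1", "chr1", 24_000, 24_080, "+", 4),
            ]
        )
        counts = te.count_te_families(aln, ANNOT)
        assert counts["famA"] == pytest.approx(0.5)
        assert counts["famB"] == pytest.approx(0.5)

    def test_unique_read_contributes_full_mass(self):
        aln = aln_table([("r1", "chr1", 1500, 1580, "+", 1)])
        counts = te.count_te_families(aln, ANNOT)
        assert counts["famA"] == pytest.approx(1.0)

    def test_non_te_read_goes_to_unassigned(self):
        aln = aln_table([("r1", "chr1", 500_000, 500_080, "+", 1)])
        counts = te.count_te_families(aln, ANNOT)
        assert counts["unassigned"] == pytest.approx(1.0)

    def test_inconsistent_n_hits_rejected(self):
        aln = aln_table(
            [("r1", "chr1", 1000, 1080, "+", 2), ("r1", "chr1", 2000, 2080, "+", 3)]
        )
        with pytest.raises(ValueError, match="n_hits"):
            te.count_te_families(aln, ANNOT)

    @given(
        reads=st.lists(
            st.tuples(
                st.integers(1, 4),                   # n_hits
                st.integers(0, 29_000),              # base position
            ),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_conservation_on_fuzzed_tables(self, reads):
        rows = []
        for i, (n_hits, pos) in enumerate(reads):
            for h in range(n_hits):
                p = (pos + h * 3777) % 29_000
                rows.append((f"r{i}", "chr1", p, p + 80, "+", n_hits))
        counts = te.count_te_families(aln_table(rows), ANNOT)
        assert counts.sum() == pytest.approx(len(reads), abs=1e-6)

    def test_copy_support_implies_family_mass(self):
        aln = aln_table(
            [("r1", "chr1", 1500, 1580, "+", 1), ("r2", "chr1", 23_000, 23_080, "-", 2),
             ("r2", "chr1", 25_000, 25_080, "+", 2)]
        )
        fam = te.count_te_families(aln, ANNOT)
        copies = te.count_te_copies(aln, ANNOT)
        for copy_id, c in copies.items():
            if c > 0:
                family = ANNOT.set_index("copy_id").loc[copy_id, "family"]
                assert fam[family] > 0


class TestCopyCounting:
    def test_multimappers_excluded(self):
        aln = aln_table(
            [("r1", "chr1", 1000, 1080, "+", 2), ("r1", "chr1", 10_000, 10_080, "+", 2)]
        )
        assert te.count_te_copies(aln, ANNOT).sum() == 0

    def test_unique_read_spanning_two_copies_counts_in_both(self):
        aln = aln_table([("r1", "chr1", 23_960, 24_040, "+", 1)])
        counts = te.count_te_copies(aln, ANNOT)
        assert counts["chr1:20000-24000:famB"] == 1
        assert counts["chr1:24000-28000:famB"] == 1

    def test_empty_annotation_gives_empty_matrix(self):
        aln = aln_table([("r1", "chr1", 10, 90, "+", 1)])
        counts = te.count_te_copies(aln, ANNOT.iloc[:0])
        assert counts.empty


class TestCopyUpSummary:
    def make_de(self, copy_ids, up_ids):
        return pd.DataFrame(
            {"up": [c in up_ids for c in copy_ids]}, index=pd.Index(copy_ids)
        )

    def test_percentage(self):
        annot = te_table(
            [("chr1", i * 1000, i * 1000 + 500, "+", "fam", "ERVK") for i in range(10)]
        )
        de = self.make_de(annot["copy_id"], set(annot["copy_id"][:3]))
        summary = te.copy_up_summary(de, annot)
        assert summary.loc[0, "pct_up"] == pytest.approx(30.0)

    def test_identical_length_sets_give_p_one(self):
        annot = te_table(
            [("chr1", i * 1000, i * 1000 + 500, "+", "fam", "ERVK") for i in range(10)]
        )
        de = self.make_de(annot["copy_id"], set(annot["copy_id"][:5]))
        summary = te.copy_up_summary(de, annot)
        assert summary.loc[0, "size_p"] == pytest.approx(1.0)

    def test_no_up_copies_skips_size_test(self):
        annot = te_table([("chr1", 0, 500, "+", "fam", "ERVK")])
        de = self.make_de(annot["copy_id"], set())
        assert np.isnan(te.copy_up_summary(de, annot).loc[0, "size_p"])

    def test_planted_long_copy_upregulation_detected(self):
        """When only copies longer than 5 kb are planted up, the size test is
        significant with up copies longer than not-up copies."""
        rng = np.random.default_rng(21)
        rows = []
        lengths = rng.integers(500, 8000, 60)
        for i, ln in enumerate(lengths):
            rows.append(("chr1", i * 10_000, i * 10_000 + int(ln), "+", "fam", "ERVK"))
        annot = te_table(rows)
        up = set(annot.loc[annot["length"] > 5000, "copy_id"])
        summary = te.copy_up_summary(self.make_de(annot["copy_id"], up), annot)
        assert summary.loc[0, "size_p"] < 0.001
        assert summary.loc[0, "median_len_up"] > summary.loc[0, "median_len_not_up"]


class TestErvProximal:
    def make_gene(self, gid, tss, strand="+"):
        exons = [(tss, tss + 500), (tss + 1000, tss + 1500)]
        if strand == "-":
            exons = [(tss - 500, tss), (tss - 1500, tss - 1000)]
            exons = [(s, e) for s, e in exons]
        return TranscriptModel(gid, gid + ".t1", "chr1", strand, exons)

    def test_distance_rule_inclusion(self):
        up = te_table([("chr1", 100_000, 104_000, "+", "famA", "ERVK")])
        genes = [
            self.make_gene("near", 100_000 - 15_000),   # 15 kb away -> in
            self.make_gene("far", 100_000 - 25_000),    # 25 kb away -> out
            self.make_gene("border", 104_000 + 20_000), # exactly 20 kb -> out
        ]
        de = pd.DataFrame(
            {"log2fc": [2.0, 0.0, 0.0], "p": [1e-9] * 3, "p_adj": [1e-9] * 3},
            index=["near", "far", "border"],
        )
        res = te.erv_proximal_genes(up, genes, de, up, seed=1)
        assert res["proximal_genes"] == ["near"]

    def test_no_up_ervs_gives_empty_proximal_set(self):
        genes = [self.make_gene("g", 1000)]
        de = pd.DataFrame({"log2fc": [0.0], "p": [1.0], "p_adj": [1.0]}, index=["g"])
        res = te.erv_proximal_genes(ANNOT.iloc[:0], genes, de, ANNOT, seed=1)
        assert res["proximal_genes"] == []

    def test_seeded_control_selection_is_reproducible(self, default_annotation, default_counts):
        from methtx.simulate import sample_sheet

        de = pd.DataFrame(
            {
                "log2fc": np.random.default_rng(1).normal(size=len(default_counts.gene_counts)),
                "p": 0.5,
                "p_adj": 0.5,
            },
            index=default_counts.gene_counts.index,
        )
        tes = default_annotation.tes
        up = tes[tes["reactivated"]]
        r1 = te.erv_proximal_genes(up, default_annotation.transcripts, de, tes, seed=7)
        r2 = te.erv_proximal_genes(up, default_annotation.transcripts, de, tes, seed=7)
        pd.testing.assert_frame_equal(r1["summary"], r2["summary"])


class TestLtrMetaplot:
    def cov(self, n=60_000):
        return {"chr1": np.ones(n, dtype=np.float32)}

    def test_merge_boundaries(self):
        copies = te_table(
            [
                ("chr1", 10_000, 10_400, "+", "ltr", "ERVK"),
                ("chr1", 17_400, 17_800, "+", "ltr", "ERVK"),  # 7 kb gap -> merged
                ("chr1", 40_000, 40_400, "+", "ltr", "ERVK"),
                ("chr1", 49_400, 49_800, "+", "ltr", "ERVK"),  # 9 kb gap -> separate
            ]
        )
        merged = te.merge_elements(copies, merge_gap=8000)
        assert len(merged) == 3

    def test_bin_count_is_200_per_strand(self):
        copies = te_table([("chr1", 30_000, 30_400, "+", "ltr", "ERVK")])
        res = te.ltr_strand_metaplot(self.cov(), self.cov(), copies, "ltr")
        assert len(res["bin"]) == 200
        assert res["sense_matrix"].shape == (1, 200)

    def test_absent_family_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            te.ltr_strand_metaplot(self.cov(), self.cov(), ANNOT, "nope")

    def test_sense_antisense_swap_on_minus_elements(self):
        copies = te_table([("chr1", 30_000, 30_400, "-", "ltr", "ERVK")])
        fwd = {"chr1": np.zeros(60_000, dtype=np.float32)}
        rev = {"chr1": np.ones(60_000, dtype=np.float32)}
        res = te.ltr_strand_metaplot(fwd, rev, copies, "ltr")
        # the minus-strand element's sense signal comes from the reverse track
        assert np.allclose(res["sense_mean"], 1.0)
        assert np.allclose(res["antisense_mean"], 0.0)
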