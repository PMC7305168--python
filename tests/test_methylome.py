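"""Methylation summarization: pooling, feature/window means, classes,
de novo selection, metaplots, correlation and the DMR caller."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methtx import methylome, simulate


def calls_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "depth", "n_meth"])
    df["pct_meth"] = 100.0 * df["n_meth"] / df["depth"]
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


class TestPoolReplicates:
    def test_counts_are_summed_not_percent_averaged(self):
        a = calls_frame([("chr1", 10, 10, 5)])
        b = calls_frame([("chr1", 10, 10, 0)])
        pooled = methylome.pool_replicates([a, b])
        assert pooled.loc[0, "pct_meth"] == 25.0

    def test_single_input_identity(self):
        a = calls_frame([("chr1", 10, 8, 4), ("chr2", 5, 10, 1)])
        pd.testing.assert_frame_equal(methylome.pool_replicates([a]), a)

    def test_count_weighting_differs_from_mean_of_percentages(self):
        # brute-force oracle: recompute from concatenated raw counts
        a = calls_frame([("chr1", 1, 100, 90), ("chr1", 2, 10, 0), ("chr1", 3, 4, 2)])
        b = calls_frame([("chr1", 1, 10, 0), ("chr1", 2, 100, 90), ("chr1", 3, 4, 2)])
        pooled = methylome.pool_replicates([a, b])
        for i, pos in enumerate([1, 2, 3]):
            depth = a.loc[i, "depth"] + b.loc[i, "depth"]
            n_meth = a.loc[i, "n_meth"] + b.loc[i, "n_meth"]
            assert pooled.loc[i, "pct_meth"] == pytest.approx(100 * n_meth / depth)
        naive = (a["pct_meth"] + b["pct_meth"]) / 2
        assert not np.allclose(pooled["pct_meth"].to_numpy()[:2], naive[:2])

    def test_union_of_positions(self):
        a = calls_frame([("chr1", 1, 5, 1)])
        b = calls_frame([("chr1", 2, 5, 5)])
        pooled = methylome.pool_replicates([a, b])
        assert pooled["start"].tolist() == [1, 2]


class TestFeatureMethylation:
    def test_unweighted_mean_and_halfopen_boundary(self):
        calls = calls_frame(
            [("chr1", 10, 10, 4), ("chr1", 20, 100, 60), ("chr1", 30, 5, 5)]
        )
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [30]})
        res = methylome.feature_methylation(calls, feats)
        # CpG at 30 (== end) excluded; 40% and 60% average to 50 regardless of depth
        assert res.loc[0, "n_cpgs"] == 2
        assert res.loc[0, "mean_pct"] == 50.0

    def test_feature_without_cpgs_is_undefined(self):
        calls = calls_frame([("chr1", 10, 10, 4)])
        feats = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [100, 0], "end": [200, 50]})
        res = methylome.feature_methylation(calls, feats)
        assert res["mean_pct"].isna().all()

    def test_family_min_cpg_rule_drops_sparse_families(self):
        te = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [0, 1000],
                "end": [500, 1500],
                "family": ["famA", "famB"],
                "te_class": ["LINE", "LINE"],
                "length": [500, 500],
            }
        )
        rows = [("chr1", i * 5, 10, 5) for i in range(99)]          # famA: 99 CpGs
        rows += [("chr1", 1000 + i * 5, 10, 5) for i in range(100)]  # famB: 100 CpGs
        fam = methylome.family_methylation(calls_frame(rows), te, min_cpgs=100)
        assert fam["family"].tolist() == ["famB"]


class TestWindows:
    def test_min_cpg_rule_and_means(self):
        calls = calls_frame(
            [("chr1", 0, 10, 0), ("chr1", 10, 10, 0), ("chr1", 20, 10, 10),
             ("chr1", 1100, 10, 10), ("chr1", 1200, 10, 0)]
        )
        w = methylome.window_methylation(calls, {"chr1": 3000}, 1000, min_cpgs=3)
        assert len(w) == 3
        assert w.loc[0, "mean_pct"] == pytest.approx(100 / 3)
        assert np.isnan(w.loc[1, "mean_pct"])  # 2 CpGs < 3
        assert np.isnan(w.loc[2, "mean_pct"])  # 0 CpGs

    def test_window_count_is_ceiling_of_length_over_size(self):
        w = methylome.window_methylation(
            calls_frame([("chr1", 0, 5, 0)]), {"chr1": 2500, "chr2": 2000}, 1000, 1
        )
        assert len(w) == 3 + 2

    def test_class_boundaries_and_partition(self):
        w = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": range(6),
                "end": range(1, 7),
                "n_cpgs": 3,
                "mean_pct": [55.0, 50.0, 10.0, 9.99, 0.0, np.nan],
            }
        )
        props = methylome.classify_windows(w)
        # 55 -> high; 50 and 10 are medium (closed boundaries); <10 -> low
        assert props["high"] == pytest.approx(1 / 5)
        assert props["medium"] == pytest.approx(2 / 5)
        assert props["low"] == pytest.approx(2 / 5)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_undefined_warns_and_returns_empty(self):
        w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1], "n_cpgs": [0],
                          "mean_pct": [np.nan]})
        with pytest.warns(UserWarning):
            props = methylome.classify_windows(w)
        assert props.empty


class TestDeNovoSelection:
    def windows(self, means):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(means)) * 1000,
                "end": (np.arange(len(means)) + 1) * 1000,
                "n_cpgs": 5,
                "mean_pct": means,
            }
        )

    def test_thresholds_are_strict(self):
        early = self.windows([3.0, 3.0, 6.0, np.nan])
        late = self.windows([60.0, 50.0, 60.0, 80.0])
        sel = methylome.select_de_novo_windows(early, late)
        # (3,60) in; (3,50) out (> is strict); (6,60) out; undefined out
        assert sel["start"].tolist() == [0]

    def test_equals_brute_force_filter_and_idempotent(self):
        rng = np.random.default_rng(5)
        means_e = rng.uniform(0, 20, 200)
        means_l = rng.uniform(30, 80, 200)
        early, late = self.windows(means_e), self.windows(means_l)
        sel = methylome.select_de_novo_windows(early, late)
        brute = [
            i for i in range(200) if means_e[i] < 5 and means_l[i] > 50
        ]
        assert sel["start"].tolist() == [i * 1000 for i in brute]
        again = methylome.select_de_novo_windows(
            early[early["start"].isin(sel["start"])].reset_index(drop=True),
            late[late["start"].isin(sel["start"])].reset_index(drop=True),
        )
        assert len(again) == len(sel)

    def test_tiling_mismatch_rejected(self):
        early = self.windows([1.0])
        late = self.windows([60.0, 60.0])
        with pytest.raises(ValueError, match="tiling"):
            methylome.select_de_novo_windows(early, late)


class TestGeneMetaplot:
    def make_transcript(self, strand="+", start=20_000, end=24_000):
        from methtx.intervals import TranscriptModel

        exons = [(start, end)]
        return TranscriptModel("g", "t", "chr1", strand, exons)

    def test_constant_methylome_gives_flat_profile(self):
        calls = calls_frame([("chr1", p, 10, 8) for p in range(0, 50_000, 97)])
        prof = methylome.gene_metaplot(calls, [self.make_transcript()])
        assert len(prof) == 40
        assert np.allclose(prof["mean_pct"].dropna(), 80.0)

    def test_minus_strand_orientation(self):
        # methylation rises with coordinate; on a minus-strand gene the
        # profile must therefore *fall* from 5' to 3'
        rows = [("chr1", p, 100, int(p / 50_000 * 100)) for p in range(0, 50_000, 97)]
        calls = calls_frame(rows)
        prof = methylome.gene_metaplot(calls, [self.make_transcript(strand="-")])
        body = prof["mean_pct"][10:30].to_numpy()
        assert body[0] > body[-1]

    def test_single_gene_matches_brute_force_bins(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(np.arange(18_000, 26_000), 120, replace=False))
        pct = rng.integers(0, 101, len(pos))
        calls = calls_frame([("chr1", int(p), 10, 0) for p in pos])
        calls["pct_meth"] = pct.astype(float)
        t = self.make_transcript(start=20_000, end=24_000)
        prof = methylome.gene_metaplot(calls, [t], flank_bp=2000)
        edges = np.linspace(20_000, 24_000, 21)
        for b in range(20):
            mask = (pos >= edges[b]) & (pos < edges[b + 1])
            expected = pct[mask].mean() if mask.any() else np.nan
            got = prof["mean_pct"].to_numpy()[2 + b]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(np.arange(15_000, 30_000), 200, replace=False))
        calls = calls_frame([("chr1", int(p), 10, int(rng.integers(0, 11))) for p in pos])
        t = self.make_transcript()
        prof1 = methylome.gene_metaplot(calls, [t])
        shifted = calls.copy()
        shifted["start"] += 5000
        t2 = self.make_transcript(start=25_000, end=29_000)
        prof2 = methylome.gene_metaplot(shifted, [t2])
        pd.testing.assert_series_equal(prof1["mean_pct"], prof2["mean_pct"])


class TestSiteMetaplot:
    def test_bin_count_and_flat_profile(self):
        calls = calls_frame([("chr1", p, 10, 8) for p in range(0, 20_000, 53)])
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "strand": ["+"]})
        prof = methylome.site_metaplot(calls, sites, "methylation")
        assert len(prof) == 40
        assert np.allclose(prof["mean"].dropna(), 80.0)

    def test_cpg_density_peaks_at_cgi_promoters(self, default_annotation):
        genes = default_annotation.gene_table
        hcp = genes[genes["promoter_class"] == "HCP"].head(30)
        sites = pd.DataFrame(
            {"chrom": hcp["chrom"], "pos": hcp["tss"], "strand": hcp["strand"]}
        )
        prof = methylome.site_metaplot(
            None, sites, "cpg_density", genome=default_annotation.genome
        )
        center = prof["mean"][18:22].mean()
        flank = prof["mean"][:8].mean()
        assert center > 2 * flank


class TestCorrelation:
    def windows(self, means):
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(len(means)) * 1000,
             "end": (np.arange(len(means)) + 1) * 1000, "n_cpgs": 5,
             "mean_pct": means}
        )

    def test_identity_and_anticorrelation(self):
        x = np.array([10.0, 40.0, 90.0, 20.0])
        assert methylome.methylation_correlation(self.windows(x), self.windows(x)) == pytest.approx(1.0)
        assert methylome.methylation_correlation(
            self.windows(x), self.windows(100 - x)
        ) == pytest.approx(-1.0)

    def test_too_few_common_windows(self):
        x = self.windows([1.0, 2.0, np.nan])
        with pytest.raises(ValueError, match="3 windows"):
            methylome.methylation_correlation(x, x)


class TestGdmrScores:
    def test_single_cpg_and_empty_bed(self):
        calls = calls_frame([("chr1", 100, 100, 47)])
        gdmrs = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150],
                              "name": ["d1"]})
        table = methylome.score_gdmrs({"WT": calls}, gdmrs)
        assert table.loc[0, "WT"] == pytest.approx(47.0)
        empty = methylome.score_gdmrs({"WT": calls}, gdmrs.iloc[:0])
        assert empty.empty


class TestCallDmrs:
    def test_identical_tables_yield_no_dmrs(self):
        a, _, _ = simulate.simulate_dmr_tables(1)
        assert methylome.call_dmrs(a, a).empty

    def test_planted_region_recovered(self):
        a, b, region = simulate.simulate_dmr_tables(2)
        dmrs = methylome.call_dmrs(a, b)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["chrom"] == region["chrom"]
        assert region["start"] <= d["start"] and d["end"] <= region["end"]
        assert d["n_dmcs"] >= 3
        assert abs(d["mean_diff"]) > 20
        assert d["region_p_adj"] < 0.001

    def test_two_dmc_region_rejected(self):
        a, b, _ = simulate.simulate_dmr_tables(3, planted_cpgs=2)
        assert methylome.call_dmrs(a, b).empty

    def test_zero_depth_condition_rejected(self):
        a, b, _ = simulate.simulate_dmr_tables(1)
        z = a.copy()
        z["depth"] = 0
        z["n_meth"] = 0
        with pytest.raises(ValueError, match="zero total depth"):
            methylome.call_dmrs(z, b)

    def test_label_permuted_null_is_clean(self):
        """On null data (both conditions from one distribution) the caller
        stays silent in at least 95% of seeded runs."""
        n_dmr_runs = 0
        for seed in range(100):
            rng = np.random.default_rng([seed, 77])
            pos = np.arange(60) * 60
            tables = []
            for _ in range(2):
                n_meth = rng.binomial(30, 0.5, len(pos))
                tables.append(
                    calls_frame(
                        [("chr1", int(p), 30, int(m)) for p, m in zip(pos, n_meth)]
                    )
                )
            if len(methylome.call_dmrs(*tables)):
                n_dmr_runs += 1
        assert n_dmr_runs <= 5
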