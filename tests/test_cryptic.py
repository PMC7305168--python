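"""Cryptic intragenic initiation caller: worked examples, the exhaustive
pattern oracle, determinism, and the exon-ratio diagnostic."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from methtx import cryptic
from methtx.intervals import TranscriptModel


def make_transcript(tid="g1.t1", gene="g1", n_exons=6, strand="+", start=10_000):
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + 200))
        pos += 1000
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(gene, tid, "chr1", strand, exons)


def exon_de_frame(tid, up, fc=None, fpkm=None):
    n = len(up)
    fc = fc if fc is not None else [10.0 if u else 1.0 for u in up]
    fpkm = fpkm if fpkm is not None else [50.0 if u else 5.0 for u in up]
    return pd.DataFrame(
        {
            "transcript_id": tid,
            "exon_index": np.arange(1, n + 1),
            "log2fc": np.log2(fc),
            "p": [1e-6 if u else 0.5 for u in up],
            "fpkm_b": fpkm,
            "up": up,
        }
    )


def oracle(up, fc, fpkm):
    """Independent literal reimplementation of the seven criteria for a
    single-isoform gene (criterion iii reduces to 'not all exons up')."""
    n = len(up)
    up_idx = [i for i in range(n) if up[i]]
    if not up_idx:
        return False
    if len(up_idx) == n:
        return False                                  # (i) and (iii)
    if up[0]:
        return False                                  # (ii)
    if len(up_idx) < 5:
        consecutive = up_idx == list(range(up_idx[0], up_idx[0] + len(up_idx)))
        if not consecutive:
            return False                              # (iv)
    else:
        span = up_idx[-1] - up_idx[0] + 1
        if span - len(up_idx) > 1:
            return False                              # (v)
    mean_up_fc = np.mean([fc[i] for i in up_idx])
    mean_other_fc = np.mean([fc[i] for i in range(n) if i not in up_idx])
    if not mean_up_fc > 3 * mean_other_fc:
        return False                                  # (vi)
    mean_up_fp = np.mean([fpkm[i] for i in up_idx])
    mean_other_fp = np.mean([fpkm[i] for i in range(n) if i not in up_idx])
    if not mean_up_fp > mean_other_fp:
        return False                                  # (vii)
    return True


class TestCaller:
    def test_downstream_block_yields_call_with_init_exon(self):
        t = make_transcript(n_exons=6)
        up = [False, False, False, True, True, True]
        calls, trace = cryptic.call_cryptic_initiation(
            exon_de_frame("g1.t1", up), [t]
        )
        assert len(calls) == 1
        c = calls.iloc[0]
        assert c["init_exon_index"] == 4
        assert c["init_position"] == t.exons[3][0]
        assert c["pct_up_exons"] == pytest.approx(50.0)

    def test_minus_strand_init_position_is_exon_5prime_end(self):
        t = make_transcript(strand="-", n_exons=6)
        up = [False, False, True, True, True, True]
        calls, _ = cryptic.call_cryptic_initiation(exon_de_frame("g1.t1", up), [t])
        assert calls.iloc[0]["init_position"] == t.exons[2][1]

    def test_first_exon_up_blocks_call(self):
        t = make_transcript()
        up = [True, False, False, True, True, True]
        calls, _ = cryptic.call_cryptic_initiation(exon_de_frame("g1.t1", up), [t])
        assert calls.empty

    def test_gap_tolerance_depends_on_up_count(self):
        t8 = make_transcript(n_exons=8)
        five_with_gap = [False, False, True, True, False, True, True, True]
        calls, _ = cryptic.call_cryptic_initiation(
            exon_de_frame("g1.t1", five_with_gap), [t8]
        )
        assert len(calls) == 1  # 5 up exons, one gap -> (v) tolerates
        three_with_gap = [False, False, True, True, False, True, False, False]
        calls, _ = cryptic.call_cryptic_initiation(
            exon_de_frame("g1.t1", three_with_gap), [t8]
        )
        assert calls.empty      # <5 up exons must be consecutive -> (iv) fails

    def test_isoform_with_all_exons_up_vetoes_gene(self):
        t1 = make_transcript("g1.t1", n_exons=6)
        t2 = TranscriptModel("g1", "g1.t2", "chr1", "+", t1.exons[3:])
        de = pd.concat(
            [
                exon_de_frame("g1.t1", [False, False, False, True, True, True]),
                exon_de_frame("g1.t2", [True, True, True]),
            ]
        )
        calls, _ = cryptic.call_cryptic_initiation(de, [t1, t2])
        assert calls.empty

    def test_te_overlap_exclusion_and_simple_repeat_exemption(self):
        t = make_transcript(n_exons=6)
        init = t.exons[3][0]
        te = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [init - 20],
                "end": [init + 20],
                "strand": ["+"],
                "family": ["IAP"],
                "repeat_class": ["LTR/ERVK"],
            }
        )
        up = [False, False, False, True, True, True]
        calls, _ = cryptic.call_cryptic_initiation(exon_de_frame("g1.t1", up), [t], te)
        assert calls.empty
        te_simple = te.assign(repeat_class="Simple_repeat")
        calls, _ = cryptic.call_cryptic_initiation(
            exon_de_frame("g1.t1", up), [t], te_simple
        )
        assert len(calls) == 1

    def test_missing_fpkm_rejected(self):
        t = make_transcript()
        de = exon_de_frame("g1.t1", [False, True, True, True, True, True])
        de.loc[2, "fpkm_b"] = np.nan
        with pytest.raises(ValueError, match="FPKM"):
            cryptic.call_cryptic_initiation(de, [t])

    def test_fold_change_criterion_vi(self):
        t = make_transcript(n_exons=6)
        up = [False, False, False, True, True, True]
        # up exons only 2x above the others -> criterion (vi) fails
        fc = [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]
        calls, trace = cryptic.call_cryptic_initiation(
            exon_de_frame("g1.t1", up, fc=fc), [t]
        )
        assert calls.empty
        assert not trace.iloc[0]["crit_vi"]

    def test_matches_exhaustive_oracle_over_all_up_patterns(self):
        """Caller accept/reject equals the literal criterion implementation
        for every up/not-up pattern of a 10-exon isoform."""
        t = make_transcript(n_exons=10)
        for bits in itertools.product([False, True], repeat=10):
            up = list(bits)
            fc = [10.0 if u else 1.0 for u in up]
            fpkm = [50.0 if u else 5.0 for u in up]
            de = exon_de_frame("g1.t1", up, fc=fc, fpkm=fpkm)
            calls, _ = cryptic.call_cryptic_initiation(de, [t])
            assert (len(calls) == 1) == oracle(up, fc, fpkm), up

    def test_isoform_tiebreak_is_input_order_independent(self):
        t1 = make_transcript("g1.t1", n_exons=8)
        t2 = TranscriptModel("g1", "g1.t2", "chr1", "+", t1.exons[1:])
        de1 = exon_de_frame("g1.t1", [False] * 4 + [True] * 4)
        de2 = exon_de_frame("g1.t2", [False] * 3 + [True] * 4)
        for frames, models in [
            ((de1, de2), [t1, t2]),
            ((de2, de1), [t2, t1]),
        ]:
            calls, _ = cryptic.call_cryptic_initiation(
                pd.concat(frames, ignore_index=True), models
            )
            # equal up-exon counts: the longer isoform wins deterministically
            assert calls.iloc[0]["transcript_id"] == "g1.t1"

    def test_single_exon_transcript_skipped(self):
        t = TranscriptModel("g1", "g1.t1", "chr1", "+", [(0, 100)])
        de = exon_de_frame("g1.t1", [True])
        calls, trace = cryptic.call_cryptic_initiation(de, [t])
        assert calls.empty and trace.empty


class TestExonRatio:
    def fpkm_frame(self, tid, values_by_cond):
        n = len(next(iter(values_by_cond.values())))
        idx = pd.MultiIndex.from_product(
            [[tid], range(1, n + 1)], names=["transcript_id", "exon_index"]
        )
        return pd.DataFrame(values_by_cond, index=idx)

    def test_uniform_fpkm_gives_unit_ratios(self):
        t = make_transcript(n_exons=6)
        fpkm = self.fpkm_frame("g1.t1", {"WT": [5.0] * 6, "DKO": [5.0] * 6})
        prof = cryptic.exon_ratio_profile(fpkm, [t], ["WT", "DKO"])
        assert np.allclose(prof["ratio"], 1.0)
        assert set(prof["position"]) == {"exon2", "exon3", "exon4", "exon5", "exon_n"}

    def test_four_exon_gene_excluded(self):
        t = make_transcript(n_exons=4)
        fpkm = self.fpkm_frame("g1.t1", {"WT": [5.0] * 4, "DKO": [5.0] * 4})
        assert cryptic.exon_ratio_profile(fpkm, [t], ["WT", "DKO"]).empty

    def test_low_fpkm_gene_excluded(self):
        t = make_transcript(n_exons=6)
        fpkm = self.fpkm_frame("g1.t1", {"WT": [0.5] * 6, "DKO": [0.5] * 6})
        assert cryptic.exon_ratio_profile(fpkm, [t], ["WT", "DKO"]).empty

    def test_planted_downstream_shift_detected(self):
        transcripts = [make_transcript(f"g{i}.t1", f"g{i}", 6, start=10_000 + 20_000 * i)
                       for i in range(20)]
        frames = []
        for i, t in enumerate(transcripts):
            wt = [5.0] * 6
            dko = [5.0] + [50.0] * 5 if i < 10 else [5.0] * 6
            frames.append(self.fpkm_frame(t.transcript_id, {"WT": wt, "DKO": dko}))
        prof = cryptic.exon_ratio_profile(pd.concat(frames), transcripts, ["WT", "DKO"])
        med = prof.groupby(["condition", "position"])["ratio"].median()
        assert med["DKO"]["exon3"] > med["WT"]["exon3"]
        assert prof.attrs["wilcoxon"]["exon3"] < 0.01


class TestSiteReport:
    def test_empty_calls_give_empty_bundle(self):
        out = cryptic.cryptic_site_report(
            cryptic._empty_calls(), {}, {"chr1": "ACGT"}, []
        )
        assert out == {}

    def test_profiles_have_forty_bins(self, default_annotation, pooled_calls):
        truth = default_annotation.ground_truth["cryptic_genes"][:5]
        models = {t.transcript_id: t for t in default_annotation.transcripts}
        calls = pd.DataFrame(
            {
                "gene_id": [c["gene_id"] for c in truth],
                "transcript_id": [c["transcript_id"] for c in truth],
                "chrom": [c["chrom"] for c in truth],
                "strand": [models[c["transcript_id"]].strand for c in truth],
                "init_position": [c["init_position"] for c in truth],
            }
        )
        out = cryptic.cryptic_site_report(
            calls, {"WT": pooled_calls["WT"]}, default_annotation.genome,
            default_annotation.transcripts,
        )
        for key, prof in out.items():
            assert len(prof) == 40, key

    def test_cryptic_sites_are_cpg_dense_and_wt_methylated(
        self, default_annotation, pooled_calls
    ):
        """Planted initiation sites sit in methylated CpG-dense gene bodies:
        CpG density peaks at the center and WT methylation stays high,
        whereas canonical TSS of HCP genes are CpG-dense but unmethylated."""
        truth = default_annotation.ground_truth["cryptic_genes"]
        models = {t.transcript_id: t for t in default_annotation.transcripts}
        calls = pd.DataFrame(
            {
                "gene_id": [c["gene_id"] for c in truth],
                "transcript_id": [c["transcript_id"] for c in truth],
                "chrom": [c["chrom"] for c in truth],
                "strand": [models[c["transcript_id"]].strand for c in truth],
                "init_position": [c["init_position"] for c in truth],
            }
        )
        out = cryptic.cryptic_site_report(
            calls, {"WT": pooled_calls["WT"]}, default_annotation.genome,
            default_annotation.transcripts,
        )
        dens = out["cryptic_cpg_density"]["mean"].to_numpy()
        assert dens[19:21].mean() > 1.5 * dens[:8].mean()
        meth = out["cryptic_meth_WT"]["mean"].to_numpy()
        assert meth[18:22].mean() > 60
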