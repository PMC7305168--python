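"""Detection of cryptic intragenic transcription initiation from exon-level
differential expression, plus the genome-wide exon-ratio diagnostic.

A gene is called when, in a hypomethylated condition, a block of downstream
exons of one isoform is upregulated while the first exon is not — the
signature of a transcript initiating from a normally methylated site inside
the gene body. Seven criteria gate a call (evaluated per isoform, exon
indices in transcription order):

(i)    fewer than 100% of exons upregulated;
(ii)   the first exon is not upregulated;
(iii)  no isoform of the same gene has 100% upregulated exons;
(iv)   with <5 upregulated exons, they are consecutive;
(v)    with >=5, at most one gap exon inside the upregulated span;
(vi)   the mean linear fold change of upregulated exons exceeds 3x that of
       the other exons;
(vii)  the mean FPKM (upregulated condition) of upregulated exons exceeds
       that of the other exons.

One isoform is kept per gene (most upregulated exons, then longest spliced
transcript, then lexicographic id) and a call is excluded when the inferred
initiation position +-50 bp overlaps a TE copy (other than simple repeats or
low-complexity DNA) or, when provided, an annotated alternative promoter.
The initiation position is the genomic 5' start of the 5'-most upregulated
exon — an automatable surrogate for manual inspection of coverage tracks,
flagged as inferred in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from . import methylome

CRITERIA = ("i", "ii", "iii", "iv", "v", "vi", "vii")

#: RepeatMasker classes that do not count as transposons for the exclusion.
NON_TE_REPEAT_CLASSES = ("Simple_repeat", "Low_complexity")


def evaluate_isoform_criteria(
    up: list[bool],
    fold_changes: list[float],
    fpkm_up_condition: list[float],
    fc_ratio: float = 3.0,
) -> dict[str, bool]:
    """Criteria (i), (ii), (iv)-(vii) for one isoform's exon vectors.

    ``up``, ``fold_changes`` (linear scale) and ``fpkm_up_condition`` are
    aligned per exon in transcription order. Criterion (iii) is gene-level
    and evaluated by the caller.
    """
    n = len(up)
    up_idx = [i for i, u in enumerate(up) if u]
    n_up = len(up_idx)
    if n_up == 0 or n < 2:
        return {c: False for c in ("i", "ii", "iv", "v", "vi", "vii")}
    trace = {}
    trace["i"] = n_up < n
    trace["ii"] = not up[0]
    span = up_idx[-1] - up_idx[0] + 1
    if n_up < 5:
        trace["iv"] = span == n_up
        trace["v"] = True
    else:
        trace["iv"] = True
        trace["v"] = (span - n_up) <= 1
    fc = np.asarray(fold_changes, dtype=float)
    fp = np.asarray(fpkm_up_condition, dtype=float)
    mask = np.zeros(n, dtype=bool)
    mask[up_idx] = True
    if n_up < n:
        trace["vi"] = fc[mask].mean() > fc_ratio * fc[~mask].mean()
        trace["vii"] = fp[mask].mean() > fp[~mask].mean()
    else:
        trace["vi"] = False
        trace["vii"] = False
    return trace


def call_cryptic_initiation(
    exon_de: pd.DataFrame,
    transcripts: list,
    te_annotation: pd.DataFrame | None = None,
    alt_promoters: pd.DataFrame | None = None,
    fc_ratio: float = 3.0,
    te_margin: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the seven-criterion caller to an exon DE table.

    ``exon_de`` needs columns transcript_id, exon_index (1-based,
    transcription order), log2fc, fpkm_b (FPKM in the upregulated condition)
    and the ``up`` flag at the exon policy; missing FPKM is an error. Returns
    ``(calls, trace)``: one accepted call per gene, and the full criterion
    trace for every isoform with at least one upregulated exon.
    """
    if exon_de["fpkm_b"].isna().any():
        raise ValueError("missing FPKM in exon DE table")
    models = {t.transcript_id: t for t in transcripts}
    per_tx = dict(tuple(exon_de.groupby("transcript_id")))

    full_up_genes = set()
    candidates = []
    for tid, grp in per_tx.items():
        t = models.get(tid)
        if t is None or t.n_exons < 2:
            continue
        grp = grp.sort_values("exon_index")
        if not np.array_equal(grp["exon_index"].to_numpy(), np.arange(1, len(grp) + 1)):
            raise ValueError(f"exon indices of {tid} are not contiguous from 1")
        up = grp["up"].tolist()
        if not any(up):
            continue
        if all(up):
            full_up_genes.add(t.gene_id)
        trace = evaluate_isoform_criteria(
            up, (2.0 ** grp["log2fc"]).tolist(), grp["fpkm_b"].tolist(), fc_ratio
        )
        up_idx = [i + 1 for i, u in enumerate(up) if u]
        candidates.append(
            {
                "gene_id": t.gene_id,
                "transcript_id": tid,
                "n_exons": t.n_exons,
                "n_up": len(up_idx),
                "up_exons": up_idx,
                "pct_up_exons": 100.0 * len(up_idx) / t.n_exons,
                **{f"crit_{c}": trace.get(c, False) for c in ("i", "ii", "iv", "v", "vi", "vii")},
            }
        )
    trace_df = pd.DataFrame(candidates)
    if trace_df.empty:
        return _empty_calls(), trace_df
    trace_df["crit_iii"] = ~trace_df["gene_id"].isin(full_up_genes)
    passing = trace_df[
        trace_df[[f"crit_{c}" for c in CRITERIA]].all(axis=1)
    ].copy()
    if passing.empty:
        return _empty_calls(), trace_df

    # one isoform per gene: most up exons, then longest spliced transcript,
    # then lexicographic transcript_id — deterministic whatever the input order
    passing["tx_length"] = [models[t].length for t in passing["transcript_id"]]
    passing = passing.sort_values(
        ["gene_id", "n_up", "tx_length", "transcript_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).drop_duplicates("gene_id")

    te_tree = _te_trees(te_annotation) if te_annotation is not None else {}
    alt_tree = _interval_trees(alt_promoters) if alt_promoters is not None else {}
    calls = []
    for row in passing.itertuples(index=False):
        t = models[row.transcript_id]
        init_exon = min(row.up_exons)
        s, e = t.exons[init_exon - 1]
        init_pos = s if t.strand == "+" else e
        lo, hi = init_pos - te_margin, init_pos + te_margin
        te_hit = bool(te_tree.get(t.chrom) and te_tree[t.chrom].overlap(lo, hi))
        alt_hit = bool(alt_tree.get(t.chrom) and alt_tree[t.chrom].overlap(lo, hi))
        calls.append(
            {
                "gene_id": row.gene_id,
                "transcript_id": row.transcript_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "init_exon_index": init_exon,
                "init_position": init_pos,
                "init_position_inferred": True,
                "up_exons": row.up_exons,
                "pct_up_exons": row.pct_up_exons,
                "te_overlap_excluded": te_hit,
                "alt_promoter_excluded": alt_hit,
            }
        )
    calls_df = pd.DataFrame(calls)
    accepted = calls_df[
        ~calls_df["te_overlap_excluded"] & ~calls_df["alt_promoter_excluded"]
    ].reset_index(drop=True)
    return accepted, trace_df


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "gene_id", "transcript_id", "chrom", "strand", "init_exon_index",
            "init_position", "init_position_inferred", "up_exons",
            "pct_up_exons", "te_overlap_excluded", "alt_promoter_excluded",
        ]
    )


def _te_trees(te: pd.DataFrame) -> dict[str, IntervalTree]:
    masked = te[~te["repeat_class"].isin(NON_TE_REPEAT_CLASSES)]
    return _interval_trees(masked)


def _interval_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            tree.addi(s, e)
        trees[chrom] = tree
    return trees


# ---------------------------------------------------------------------------
# Exon-ratio diagnostic

def exon_ratio_profile(
    exon_fpkm: pd.DataFrame,
    transcripts: list,
    conditions: list[str],
    min_exons: int = 5,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Ratio of downstream-exon FPKM over first-exon FPKM, per condition.

    ``exon_fpkm`` is indexed by (transcript_id, exon_index) with one column
    of group-mean FPKM per condition. For every transcript with at least
    ``min_exons`` exons and FPKM above ``min_fpkm`` in at least one condition
    (mean over exons), the ratios exon_k / exon_1 for k = 2..5 and for the
    last exon are reported; transcripts whose first exon has zero FPKM in a
    condition are excluded there. Wilcoxon rank-sum p-values compare the two
    first conditions at each position.
    """
    rows = []
    for t in transcripts:
        if t.n_exons < min_exons:
            continue
        try:
            sub = exon_fpkm.loc[t.transcript_id]
        except KeyError:
            continue
        if float(sub[conditions].mean(axis=0).max()) <= min_fpkm:
            continue
        for cond in conditions:
            first = sub.loc[1, cond]
            if first == 0:
                continue
            positions = list(range(2, 6)) + [t.n_exons]
            labels = ["exon2", "exon3", "exon4", "exon5", "exon_n"]
            for pos, label in zip(positions, labels):
                rows.append(
                    {
                        "transcript_id": t.transcript_id,
                        "condition": cond,
                        "position": label,
                        "ratio": sub.loc[pos, cond] / first,
                    }
                )
    profile = pd.DataFrame(rows)
    if profile.empty or len(conditions) < 2:
        profile.attrs["wilcoxon"] = {}
        return profile
    tests = {}
    a, b = conditions[:2]
    for label, grp in profile.groupby("position"):
        x = grp.loc[grp["condition"] == a, "ratio"]
        y = grp.loc[grp["condition"] == b, "ratio"]
        if len(x) and len(y):
            tests[label] = float(
                stats.mannwhitneyu(x, y, alternative="two-sided")[1]
            )
    profile.attrs["wilcoxon"] = tests
    return profile


def cryptic_site_report(
    calls: pd.DataFrame,
    calls_by_genotype: dict[str, pd.DataFrame],
    genome: dict[str, str],
    transcripts: list,
    half_width: int = 5000,
    bin_size: int = 250,
) -> dict[str, pd.DataFrame]:
    """Methylation and CpG-density metaplots at cryptic initiation sites,
    with canonical TSS of the called genes as the contrast."""
    out: dict[str, pd.DataFrame] = {}
    if calls.empty:
        return out
    sites = calls.rename(columns={"init_position": "pos"})[["chrom", "pos", "strand"]]
    models = {t.transcript_id: t for t in transcripts}
    tss = pd.DataFrame(
        {
            "chrom": [models[t].chrom for t in calls["transcript_id"]],
            "pos": [models[t].tss for t in calls["transcript_id"]],
            "strand": [models[t].strand for t in calls["transcript_id"]],
        }
    )
    for label, pts in (("cryptic", sites), ("tss", tss)):
        out[f"{label}_cpg_density"] = methylome.site_metaplot(
            None, pts, mode="cpg_density", genome=genome,
            half_width=half_width, bin_size=bin_size,
        )
        for genotype, calls_table in calls_by_genotype.items():
            out[f"{label}_meth_{genotype}"] = methylome.site_metaplot(
                calls_table, pts, mode="methylation",
                half_width=half_width, bin_size=bin_size,
            )
    return out
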