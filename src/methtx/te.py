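"""Transposable-element expression: family counts with multi-mapping
weighting, unique-read copy counts, upregulated-copy summaries, effects on
ERV-proximal genes, and strand-resolved LTR metaplots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from . import diffexpr

ERV_CLASSES = ("ERV1", "ERVK", "ERVL")


def _copy_trees(te: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in te.groupby("chrom"):
        tree = IntervalTree()
        for row in grp.itertuples(index=False):
            tree.addi(row.start, row.end, (row.copy_id, row.family))
        trees[chrom] = tree
    return trees


def count_te_families(
    alignments: pd.DataFrame, te_annotation: pd.DataFrame
) -> pd.Series:
    """Fractional family counts with multi-mapping weighting.

    Each alignment record carries mass ``1/n_hits``. A record overlapping
    (>= 1 bp) copies of k distinct families splits its mass equally between
    them; a record overlapping no TE contributes to ``unassigned``. Total
    mass across families plus unassigned equals the number of distinct reads.
    """
    per_read = alignments.groupby("read_id")["n_hits"]
    if (per_read.nunique() > 1).any():
        raise ValueError("inconsistent n_hits within a read")
    trees = _copy_trees(te_annotation)
    masses: dict[str, float] = {}
    unassigned = 0.0
    for row in alignments.itertuples(index=False):
        mass = 1.0 / row.n_hits
        tree = trees.get(row.chrom)
        hits = tree.overlap(row.start, row.end) if tree is not None else ()
        families = {iv.data[1] for iv in hits}
        if not families:
            unassigned += mass
            continue
        share = mass / len(families)
        for fam in families:
            masses[fam] = masses.get(fam, 0.0) + share
    out = pd.Series(masses, dtype=float).sort_index()
    out["unassigned"] = unassigned
    return out


def count_te_copies(
    alignments: pd.DataFrame, te_annotation: pd.DataFrame
) -> pd.Series:
    """Integer per-copy counts from uniquely mapping reads only.

    A unique read overlapping k copies increments all k (a documented
    convention for reads spanning adjacent annotations). Multi-mapping reads
    contribute nothing.
    """
    trees = _copy_trees(te_annotation)
    counts = pd.Series(0, index=te_annotation["copy_id"], dtype=int)
    unique = alignments[alignments["n_hits"] == 1]
    for row in unique.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            counts[iv.data[0]] += 1
    return counts


def family_count_matrix(
    alignments_by_sample: dict[str, pd.DataFrame], te_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Fractional family counts for every sample (columns) in one matrix."""
    cols = {
        sample: count_te_families(aln, te_annotation)
        for sample, aln in alignments_by_sample.items()
    }
    return pd.DataFrame(cols).fillna(0.0)


def copy_count_matrix(
    alignments_by_sample: dict[str, pd.DataFrame], te_annotation: pd.DataFrame
) -> pd.DataFrame:
    cols = {
        sample: count_te_copies(aln, te_annotation)
        for sample, aln in alignments_by_sample.items()
    }
    return pd.DataFrame(cols)


def copy_up_summary(
    copy_de: pd.DataFrame, te_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-family percentage of upregulated copies and an up/not-up size test.

    ``copy_de`` must carry the ``up`` flag from the copy policy (fold change
    > 3, adjusted p < 0.001) indexed by copy_id; copies absent from the DE
    table count as not upregulated. The size comparison is a two-sided
    Wilcoxon rank-sum test on copy lengths, skipped (p NaN) for families with
    no upregulated or no non-upregulated copies.
    """
    te = te_annotation.set_index("copy_id")
    up_ids = set(copy_de.index[copy_de["up"]])
    rows = []
    for family, grp in te.groupby("family", sort=True):
        lengths = grp["length"].to_numpy()
        is_up = grp.index.isin(up_ids)
        n_up = int(is_up.sum())
        n_copies = len(grp)
        if 0 < n_up < n_copies:
            p = float(
                stats.mannwhitneyu(
                    lengths[is_up], lengths[~is_up], alternative="two-sided"
                )[1]
            )
            median_up = float(np.median(lengths[is_up]))
        else:
            p, median_up = np.nan, np.nan
        rows.append(
            {
                "family": family,
                "te_class": grp["te_class"].iloc[0],
                "n_copies": n_copies,
                "n_up": n_up,
                "pct_up": 100.0 * n_up / n_copies,
                "median_len_up": median_up,
                "median_len_not_up": float(np.median(lengths[~is_up]))
                if n_up < n_copies
                else np.nan,
                "size_p": p,
            }
        )
    return pd.DataFrame(rows)


def _tss_distance_to_copies(transcripts: list, copies: pd.DataFrame) -> pd.Series:
    """Distance from each gene TSS to the nearest edge of any listed copy."""
    dist = {}
    by_chrom = {
        c: (g["start"].to_numpy(), g["end"].to_numpy())
        for c, g in copies.sort_values("start").groupby("chrom")
    }
    for t in transcripts:
        arrs = by_chrom.get(t.chrom)
        if arrs is None:
            dist[t.gene_id] = np.inf
            continue
        starts, ends = arrs
        tss = t.tss
        inside = (starts <= tss) & (tss < ends)
        if inside.any():
            dist[t.gene_id] = 0
            continue
        d = np.minimum(np.abs(starts - tss), np.abs(ends - tss))
        dist[t.gene_id] = int(d.min()) if len(d) else np.inf
    return pd.Series(dist)


def erv_proximal_genes(
    up_erv_copies: pd.DataFrame,
    transcripts: list,
    gene_de: pd.DataFrame,
    te_annotation: pd.DataFrame,
    seed: int,
    max_distance: int = 20_000,
    policy: str = "genes",
) -> dict:
    """Expression effect on genes near upregulated ERV copies.

    The proximal set contains genes whose TSS lies strictly closer than
    ``max_distance`` to any upregulated ERV copy (nearest-edge distance,
    strand-ignored). Comparison sets: all genes, all ERV-proximal genes (near
    any annotated ERV copy), and a seeded random sample of the latter of the
    proximal set's size. Reports per-set log2fc summaries, the fraction
    flagged up at the gene policy, and a two-sided Wilcoxon rank-sum test of
    proximal versus random-control log2fc.
    """
    gene_de = diffexpr.call_de(gene_de, policy)
    one_per_gene: dict[str, object] = {}
    for t in transcripts:
        one_per_gene.setdefault(t.gene_id, t)
    models = [t for g, t in one_per_gene.items() if g in gene_de.index]

    proximal_ids: list[str] = []
    if len(up_erv_copies):
        d_up = _tss_distance_to_copies(models, up_erv_copies)
        proximal_ids = sorted(d_up.index[d_up < max_distance])
    erv_all = te_annotation[te_annotation["te_class"].isin(ERV_CLASSES)]
    d_all = _tss_distance_to_copies(models, erv_all)
    erv_any_ids = sorted(d_all.index[d_all < max_distance])
    rng = np.random.default_rng(seed)
    n = len(proximal_ids)
    if n and len(erv_any_ids):
        random_ids = sorted(
            rng.choice(erv_any_ids, size=min(n, len(erv_any_ids)), replace=False)
        )
    else:
        random_ids = []
    sets = {
        "genes_erv_up": proximal_ids,
        "all_genes": sorted(gene_de.index),
        "genes_erv_all": erv_any_ids,
        "genes_erv_rand": random_ids,
    }
    summary = []
    for label, ids in sets.items():
        sub = gene_de.loc[gene_de.index.intersection(ids)]
        summary.append(
            {
                "set": label,
                "n": len(sub),
                "median_log2fc": float(sub["log2fc"].median()) if len(sub) else np.nan,
                "mean_log2fc": float(sub["log2fc"].mean()) if len(sub) else np.nan,
                "pct_up": 100.0 * sub["up"].mean() if len(sub) else np.nan,
            }
        )
    if proximal_ids and random_ids:
        wilcoxon_p = float(
            stats.mannwhitneyu(
                gene_de.loc[proximal_ids, "log2fc"],
                gene_de.loc[random_ids, "log2fc"],
                alternative="two-sided",
            )[1]
        )
    else:
        wilcoxon_p = np.nan
    return {
        "summary": pd.DataFrame(summary),
        "proximal_genes": proximal_ids,
        "wilcoxon_p": wilcoxon_p,
    }


def merge_elements(copies: pd.DataFrame, merge_gap: int = 8000) -> pd.DataFrame:
    """Merge same-chromosome copies separated by less than ``merge_gap`` bp.

    The merged element keeps the strand of its first (leftmost) member; its
    start is the 5' start in that orientation.
    """
    merged_rows = []
    for chrom, grp in copies.sort_values("start").groupby("chrom"):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start - cur["end"] < merge_gap:
                cur["end"] = max(cur["end"], row.end)
                cur["n_members"] += 1
            else:
                if cur is not None:
                    merged_rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": row.start,
                    "end": row.end,
                    "strand": row.strand,
                    "n_members": 1,
                }
        if cur is not None:
            merged_rows.append(cur)
    return pd.DataFrame(merged_rows)


def ltr_strand_metaplot(
    coverage_fwd: dict[str, np.ndarray],
    coverage_rev: dict[str, np.ndarray],
    te_annotation: pd.DataFrame,
    family: str,
    merge_gap: int = 8000,
    half_width: int = 5000,
    bin_size: int = 50,
) -> dict:
    """Sense/antisense signal around the starts of a named LTR family.

    Family copies are merged when closer than ``merge_gap``; per merged
    element, both-strand coverage is extracted over +-``half_width`` from the
    element's 5' start and averaged in ``bin_size`` bp bins. Sense is defined
    relative to the element's annotated strand; profiles are oriented so bin 1
    is the most upstream. Returns mean profiles and the per-element matrices.
    """
    copies = te_annotation[te_annotation["family"] == family]
    if copies.empty:
        raise ValueError(f"family {family!r} absent from the TE annotation")
    elements = merge_elements(copies, merge_gap)
    nbins = 2 * half_width // bin_size
    sense_rows, anti_rows = [], []
    for el in elements.itertuples(index=False):
        anchor = el.start if el.strand == "+" else el.end
        lo = anchor - half_width
        fwd = _extract(coverage_fwd.get(el.chrom), lo, nbins, bin_size)
        rev = _extract(coverage_rev.get(el.chrom), lo, nbins, bin_size)
        if el.strand == "-":
            fwd, rev = rev[::-1], fwd[::-1]
        sense_rows.append(fwd)
        anti_rows.append(rev)
    sense = np.vstack(sense_rows)
    anti = np.vstack(anti_rows)
    centers = np.arange(-half_width + bin_size // 2, half_width, bin_size)
    return {
        "bin": centers,
        "sense_mean": np.nanmean(sense, axis=0),
        "antisense_mean": np.nanmean(anti, axis=0),
        "sense_matrix": sense,
        "antisense_matrix": anti,
        "elements": elements,
    }


def _extract(cov: np.ndarray | None, lo: int, nbins: int, bin_size: int) -> np.ndarray:
    out = np.full(nbins, np.nan)
    if cov is None:
        return out
    for b in range(nbins):
        s, e = lo + b * bin_size, lo + (b + 1) * bin_size
        s0, e0 = max(s, 0), min(e, len(cov))
        if e0 > s0:
            out[b] = cov[s0:e0].mean()
    return out
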