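"""Methylation summarization: pooling, feature/window means, window classes,
de novo region selection, metaplots, correlations, gDMR scoring and a DMR
caller.

Conventions shared by every operation here:

* A call table is a data frame with columns chrom, start, depth, n_meth,
  pct_meth, sorted by (chrom, start); ``start`` is the plus-strand C position.
* Feature and window means weight every CpG equally (the mean of per-CpG
  percentages), never read-weighted.
* A mean over fewer CpGs than the configured minimum is *undefined* and
  propagated as NaN, never as 0 — zero is a valid methylation level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import point_interval_means, tile_genome

WINDOW_COLUMNS = ["chrom", "start", "end", "n_cpgs", "mean_pct"]


def pool_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool replicate call tables by summing methylated and total read counts.

    The pooled percentage is recomputed from the summed counts, so it is
    count-weighted, not the mean of per-replicate percentages. CpGs present in
    any input appear in the output.
    """
    if not tables:
        raise ValueError("need at least one call table")
    cat = pd.concat(tables, ignore_index=True)
    pooled = (
        cat.groupby(["chrom", "start"], as_index=False)
        .agg(depth=("depth", "sum"), n_meth=("n_meth", "sum"))
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    pooled["pct_meth"] = 100.0 * pooled["n_meth"] / pooled["depth"]
    return pooled[["chrom", "start", "depth", "n_meth", "pct_meth"]]


def feature_methylation(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    min_cpgs: int = 1,
) -> pd.DataFrame:
    """Unweighted mean of per-CpG methylation over each feature interval.

    ``features`` needs chrom/start/end columns; the result adds ``n_cpgs`` and
    ``mean_pct`` (NaN when fewer than ``min_cpgs`` CpGs fall in the feature;
    the half-open convention excludes a CpG exactly at ``end``).
    """
    out = features.reset_index(drop=True).copy()
    means, counts = point_interval_means(calls, "pct_meth", out)
    out["n_cpgs"] = counts
    out["mean_pct"] = np.where(counts >= min_cpgs, means, np.nan)
    return out


def family_methylation(
    calls: pd.DataFrame,
    te_annotation: pd.DataFrame,
    min_cpgs: int = 1,
    min_length: int | None = None,
) -> pd.DataFrame:
    """Per-TE-family mean methylation over all CpGs in all copies of a family.

    ``min_cpgs`` implements the cross-dataset rule that keeps only families
    covered by at least that many CpGs (use 100 for LTR/LINE comparisons
    between datasets). ``min_length`` optionally drops copies at or below a
    length cutoff first (400 bp for the genomic-feature panel).
    """
    te = te_annotation
    if min_length is not None:
        te = te[te["length"] > min_length]
    per_copy = feature_methylation(calls, te[["chrom", "start", "end"]])
    per_copy["family"] = te["family"].to_numpy()
    per_copy["te_class"] = te["te_class"].to_numpy()
    per_copy["sum_pct"] = per_copy["mean_pct"] * per_copy["n_cpgs"]
    fam = (
        per_copy.groupby(["family", "te_class"], as_index=False)
        .agg(n_cpgs=("n_cpgs", "sum"), sum_pct=("sum_pct", "sum"))
    )
    fam["mean_pct"] = np.where(
        fam["n_cpgs"] >= min_cpgs, fam["sum_pct"] / fam["n_cpgs"], np.nan
    )
    fam = fam[fam["n_cpgs"] >= min_cpgs].drop(columns="sum_pct")
    return fam.reset_index(drop=True)


def window_methylation(
    calls: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_size: int = 1000,
    min_cpgs: int = 3,
) -> pd.DataFrame:
    """Mean methylation in a fixed tiling anchored at coordinate 0.

    Windows containing fewer than ``min_cpgs`` CpGs have an undefined mean.
    """
    windows = tile_genome(chrom_sizes, window_size)
    return feature_methylation(calls, windows, min_cpgs=min_cpgs)


def classify_windows(windows: pd.DataFrame) -> pd.Series:
    """Proportions of defined windows in high (>50%), medium ([10,50]) and
    low (<10%) methylation classes.

    Both boundaries belong to the medium class. Proportions sum to 1 over
    defined windows; an all-undefined input returns an empty series with a
    warning.
    """
    mean = windows["mean_pct"].dropna()
    if mean.empty:
        warnings.warn("no windows with a defined methylation mean")
        return pd.Series(dtype=float)
    labels = pd.Series(
        np.select([mean > 50, mean < 10], ["high", "low"], default="medium"),
        index=mean.index,
    )
    return labels.value_counts(normalize=True).reindex(
        ["high", "medium", "low"], fill_value=0.0
    )


def select_de_novo_windows(
    windows_early: pd.DataFrame, windows_late: pd.DataFrame
) -> pd.DataFrame:
    """Windows de novo methylated between two stages: mean <5% in the early
    (preimplantation) stage and >50% in the late stage, both strict and both
    defined; the two inputs must share one tiling."""
    key = ["chrom", "start", "end"]
    if not windows_early[key].reset_index(drop=True).equals(
        windows_late[key].reset_index(drop=True)
    ):
        raise ValueError("window tilings differ between inputs")
    early = windows_early["mean_pct"].to_numpy()
    late = windows_late["mean_pct"].to_numpy()
    keep = (early < 5) & (late > 50)  # NaN compares False on both sides
    out = windows_early.loc[keep, key].reset_index(drop=True)
    out["mean_early"] = early[keep]
    out["mean_late"] = late[keep]
    return out


# ---------------------------------------------------------------------------
# Metaplots

def _bin_means(pos: np.ndarray, pct: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean pct per half-open bin defined by monotone increasing edges."""
    idx = np.searchsorted(edges, pos, "right") - 1
    nbins = len(edges) - 1
    ok = (idx >= 0) & (idx < nbins) & (pos < edges[-1])
    sums = np.bincount(idx[ok], weights=pct[ok], minlength=nbins)
    counts = np.bincount(idx[ok], minlength=nbins)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def gene_metaplot(
    calls: pd.DataFrame,
    transcripts: list,
    flank_bp: int = 10_000,
    exclude_chroms: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Average methylation profile over gene bodies and flanks.

    Each gene body is split into 20 equal bins oriented 5'->3'; each flank is
    tiled in ten 1 kb bins (labels -10..-1 upstream of the TSS, +1..+10
    downstream of the TTS). The profile is the unweighted mean over genes of
    per-bin means. Genes shorter than 20 bp are skipped; ``n_genes`` reports
    contributions per bin.
    """
    flank_bins = flank_bp // 1000
    labels = (
        [f"up{i}" for i in range(-flank_bins, 0)]
        + [f"body{i}" for i in range(1, 21)]
        + [f"down{i}" for i in range(1, flank_bins + 1)]
    )
    by_chrom = {c: g for c, g in calls.groupby("chrom")}
    profiles = []
    n_skipped = 0
    for t in transcripts:
        if t.chrom in exclude_chroms:
            continue
        start, end = t.start, t.end
        if end - start < 20:
            n_skipped += 1
            continue
        grp = by_chrom.get(t.chrom)
        if grp is None:
            continue
        pos = grp["start"].to_numpy()
        pct = grp["pct_meth"].to_numpy()
        body_edges = np.linspace(start, end, 21)
        up_edges = np.arange(start - flank_bp, start + 1, 1000, dtype=float)
        down_edges = np.arange(end, end + flank_bp + 1, 1000, dtype=float)
        row = np.concatenate(
            [
                _bin_means(pos, pct, up_edges),
                _bin_means(pos, pct, body_edges),
                _bin_means(pos, pct, down_edges),
            ]
        )
        if t.strand == "-":
            row = row[::-1]
        profiles.append(row)
    if not profiles:
        raise ValueError("no usable genes for the metaplot")
    mat = np.vstack(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
    out = pd.DataFrame(
        {
            "bin": labels,
            "mean_pct": mean,
            "n_genes": np.sum(~np.isnan(mat), axis=0),
        }
    )
    out.attrs["n_skipped_short"] = n_skipped
    return out


def site_metaplot(
    calls: pd.DataFrame | None,
    sites: pd.DataFrame,
    mode: str = "methylation",
    genome: dict[str, str] | None = None,
    half_width: int = 5000,
    bin_size: int = 250,
) -> pd.DataFrame:
    """Profile around single-position sites in fixed-width bins.

    ``sites`` needs chrom/pos/strand columns. In ``methylation`` mode the
    profile is the mean CpG methylation per bin; in ``cpg_density`` mode it is
    the number of CpG dinucleotides per bin scaled to CpGs/kb, computed from
    the genome sequence. Bins are strand-oriented (bin 1 is the most upstream).
    Sites closer than ``half_width`` to a contig edge contribute partial bins
    and are flagged in the ``n_partial`` attribute.
    """
    if mode not in ("methylation", "cpg_density"):
        raise ValueError(f"unknown site metaplot mode {mode!r}")
    if mode == "cpg_density" and genome is None:
        raise ValueError("cpg_density mode needs the genome sequence")
    nbins = 2 * half_width // bin_size
    rows, n_partial = [], 0
    by_chrom = {c: g for c, g in calls.groupby("chrom")} if calls is not None else {}
    for site in sites.itertuples(index=False):
        left = site.pos - half_width
        edges = np.arange(left, site.pos + half_width + 1, bin_size, dtype=float)
        if mode == "methylation":
            grp = by_chrom.get(site.chrom)
            if grp is None:
                continue
            row = _bin_means(
                grp["start"].to_numpy(), grp["pct_meth"].to_numpy(), edges
            )
        else:
            seq = genome[site.chrom]
            counts = np.zeros(nbins)
            for b in range(nbins):
                s = int(edges[b])
                e = int(edges[b + 1])
                s0, e0 = max(s, 0), min(e + 1, len(seq))  # +1 catches boundary CpG
                counts[b] = seq.count("CG", s0, e0) if e0 > s0 else np.nan
            row = counts * 1000.0 / bin_size
        partial = left < 0
        if genome is not None and site.chrom in genome:
            partial = partial or site.pos + half_width > len(genome[site.chrom])
        if partial:
            n_partial += 1
        if site.strand == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        return pd.DataFrame({"bin": [], "mean": [], "n_sites": []})
    mat = np.vstack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
    centers = np.arange(-half_width + bin_size // 2, half_width, bin_size)
    out = pd.DataFrame(
        {"bin": centers, "mean": mean, "n_sites": np.sum(~np.isnan(mat), axis=0)}
    )
    out.attrs["n_partial"] = n_partial
    return out


def methylation_correlation(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Pearson correlation of window means over windows defined in both."""
    key = ["chrom", "start", "end"]
    merged = a[key + ["mean_pct"]].merge(b[key + ["mean_pct"]], on=key, suffixes=("_a", "_b"))
    merged = merged.dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 windows defined in both inputs")
    r, _ = stats.pearsonr(merged["mean_pct_a"], merged["mean_pct_b"])
    return float(r)


def score_gdmrs(
    calls_by_genotype: dict[str, pd.DataFrame], gdmrs: pd.DataFrame
) -> pd.DataFrame:
    """Mean methylation of each germline DMR interval per genotype.

    Returns a wide table (one row per DMR, one column per genotype); cells
    with no covered CpG are NaN.
    """
    out = gdmrs[["chrom", "start", "end"]].reset_index(drop=True).copy()
    if "name" in gdmrs:
        out["name"] = gdmrs["name"].to_numpy()
    for genotype, calls in calls_by_genotype.items():
        means, _ = point_interval_means(calls, "pct_meth", out)
        out[genotype] = means
    return out


# ---------------------------------------------------------------------------
# DMR calling

def call_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    dmc_p: float = 0.01,
    dmc_diff: float = 20.0,
    max_gap: int = 250,
    min_dmcs: int = 3,
    region_alpha: float = 0.001,
    region_diff: float = 20.0,
) -> pd.DataFrame:
    """Call differentially methylated regions between two pooled conditions.

    Per CpG covered in both conditions, a two-sided Fisher exact test on the
    (methylated, unmethylated) read counts defines differentially methylated
    CpGs (DMCs: p < ``dmc_p`` and |pct difference| > ``dmc_diff``). Candidate
    regions are maximal runs of DMCs at most ``max_gap`` bp apart; the region
    p-value combines its DMC p-values by Stouffer's method and is BH-adjusted
    across candidates. Reported regions satisfy at least ``min_dmcs`` DMCs,
    |mean difference| > ``region_diff`` and adjusted p < ``region_alpha``.

    The difference is oriented b minus a. The regioning distance and Stouffer
    combination are this package's own choices; the three reporting criteria
    are the published contract.
    """
    if calls_a["depth"].sum() == 0 or calls_b["depth"].sum() == 0:
        raise ValueError("a condition has zero total depth")
    key = ["chrom", "start"]
    merged = calls_a[key + ["depth", "n_meth", "pct_meth"]].merge(
        calls_b[key + ["depth", "n_meth", "pct_meth"]], on=key, suffixes=("_a", "_b")
    )
    merged = merged[(merged["depth_a"] > 0) & (merged["depth_b"] > 0)]
    merged["diff"] = merged["pct_meth_b"] - merged["pct_meth_a"]
    cand = merged[np.abs(merged["diff"]) > dmc_diff]
    if cand.empty:
        return _empty_dmrs()
    pvals = np.array(
        [
            stats.fisher_exact(
                [[ma, da - ma], [mb, db - mb]], alternative="two-sided"
            )[1]
            for ma, da, mb, db in zip(
                cand["n_meth_a"], cand["depth_a"], cand["n_meth_b"], cand["depth_b"]
            )
        ]
    )
    dmcs = cand.loc[pvals < dmc_p].copy()
    dmcs["p"] = pvals[pvals < dmc_p]
    if dmcs.empty:
        return _empty_dmrs()
    dmcs = dmcs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    new_chrom = dmcs["chrom"] != dmcs["chrom"].shift()
    gap = dmcs["start"] - dmcs["start"].shift()
    region_id = (new_chrom | (gap > max_gap)).cumsum()
    regions = []
    for _, grp in dmcs.groupby(region_id):
        # Stouffer needs p strictly inside (0, 1)
        p = np.clip(grp["p"].to_numpy(), 1e-300, 1 - 1e-16)
        if len(p) == 1:
            region_p = float(p[0])
        else:
            region_p = float(stats.combine_pvalues(p, method="stouffer")[1])
        regions.append(
            {
                "chrom": grp["chrom"].iloc[0],
                "start": int(grp["start"].min()),
                "end": int(grp["start"].max()) + 2,  # include the CpG dinucleotide
                "n_dmcs": len(grp),
                "mean_diff": float(grp["diff"].mean()),
                "region_p": region_p,
            }
        )
    out = pd.DataFrame(regions)
    out["region_p_adj"] = multipletests(out["region_p"], method="fdr_bh")[1]
    keep = (
        (out["n_dmcs"] >= min_dmcs)
        & (np.abs(out["mean_diff"]) > region_diff)
        & (out["region_p_adj"] < region_alpha)
    )
    return out[keep].reset_index(drop=True)


def _empty_dmrs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "n_dmcs", "mean_diff", "region_p", "region_p_adj"]
    )
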