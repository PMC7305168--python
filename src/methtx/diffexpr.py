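"""Count normalization, FPKM and a negative-binomial Wald test.

The differential-expression engine is a transparent stand-in for the heavier
tools usually run at this step: median-of-ratios size factors, a common
(across-feature) moment estimate of the NB dispersion, and a Wald test on
pseudo-counted log2 fold changes. There is no dispersion-trend or LFC
shrinkage, no independent filtering and no outlier handling; the published
significance policies are applied verbatim by :func:`call_de`.

Group-B-over-group-A orientation is used throughout: positive log2fc means
higher in group B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5
MIN_DISPERSION = 0.01


@dataclass(frozen=True)
class DEPolicy:
    """An up/down calling policy: fold-change threshold, alpha, and whether
    alpha applies to the BH-adjusted or to the raw p-value."""

    fc_threshold: float
    alpha: float
    adjusted: bool


#: Published significance policies per feature type.
POLICIES: dict[str, DEPolicy] = {
    "genes": DEPolicy(3.0, 0.001, adjusted=True),
    "te_copies": DEPolicy(3.0, 0.001, adjusted=True),
    "te_families": DEPolicy(2.0, 0.001, adjusted=True),
    "exons": DEPolicy(3.0, 0.001, adjusted=False),
}


def size_factors(counts: pd.DataFrame, min_usable: int = 100) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Features with a zero count in any sample are unusable for the ratio
    median; when fewer than ``min_usable`` remain, library-size scaling is
    used instead with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all-zero count matrix")
    usable = (mat > 0).all(axis=1)
    if usable.sum() >= min_usable:
        logs = np.log(mat[usable])
        log_geo = logs.mean(axis=1)
        factors = np.exp(np.median(logs - log_geo[:, None], axis=0))
    else:
        warnings.warn(
            f"only {int(usable.sum())} features usable for median-of-ratios; "
            "falling back to library-size scaling"
        )
        libs = mat.sum(axis=0)
        factors = libs / np.exp(np.mean(np.log(libs)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_library_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Per-sample library size on a common scale: the size factor times the
    geometric mean of factor-corrected raw library sizes."""
    libs = counts.sum(axis=0).astype(float)
    base = np.exp(np.mean(np.log(libs / factors)))
    return factors * base


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    factors: pd.Series | None = None,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million on normalized library sizes.

    ``FPKM_ij = 1e9 * count_ij / (length_i * N_j)`` with ``N_j`` the
    normalized library size. When ``groups`` maps group labels to sample
    lists, per-group mean FPKM columns are appended as ``fpkm_<group>``.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("feature lengths must be positive for every feature")
    if factors is None:
        factors = size_factors(counts)
    nlib = normalized_library_sizes(counts, factors)
    if (nlib <= 0).any():
        raise ValueError("zero library size")
    out = 1e9 * counts.div(nlib, axis=1).div(lengths, axis=0)
    if groups:
        for label, samples in groups.items():
            out[f"fpkm_{label}"] = out[samples].mean(axis=1)
    return out


def estimate_dispersion(
    norm: np.ndarray, group_sizes: list[int], min_dispersion: float = MIN_DISPERSION
) -> float:
    """Common NB dispersion by method of moments, pooled across groups.

    Per feature, the within-group variance (pooled over groups) and the
    overall mean give a moment estimate ``(v - m) / m^2``; the common value is
    a 5%-trimmed mean over features with mean > 1, floored at
    ``min_dispersion``. A single common dispersion keeps the Wald statistic
    close to normal at small replicate numbers, where per-feature moment
    estimates produce heavy t-like tails.
    """
    parts = np.split(norm, np.cumsum(group_sizes)[:-1], axis=1)
    dfs = np.array([g.shape[1] - 1 for g in parts], dtype=float)
    if dfs.sum() <= 0:
        return min_dispersion
    v = sum(g.var(axis=1, ddof=1) * df for g, df in zip(parts, dfs) if df > 0) / dfs.sum()
    m = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    ok = np.isfinite(alpha) & (m > 1)
    if not ok.any():
        return min_dispersion
    return float(max(min_dispersion, stats.trim_mean(alpha[ok], 0.05)))


def nb_wald_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series | None = None,
    min_dispersion: float = MIN_DISPERSION,
) -> pd.DataFrame:
    """Per-feature NB Wald test of group B versus group A.

    log2fc = log2((m_b + 0.5) / (m_a + 0.5)) on normalized group means; the
    standard error comes from the delta method under NB variance
    ``m + alpha m^2`` evaluated at the pseudo-counted means, with a common
    dispersion (:func:`estimate_dispersion`); two-sided normal p-values are
    BH-adjusted within the tested set. With a single replicate in either
    group, fold changes are reported and p is missing.
    """
    samples = list(group_a) + list(group_b)
    sub = counts[samples]
    if factors is None:
        factors = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / factors[samples].to_numpy()
    na, nb = len(group_a), len(group_b)
    ma = norm[:, :na].mean(axis=1)
    mb = norm[:, na:].mean(axis=1)
    log2fc = np.log2((mb + PSEUDOCOUNT) / (ma + PSEUDOCOUNT))
    out = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "mean_a": ma,
            "mean_b": mb,
            "log2fc": log2fc,
        },
        index=counts.index,
    )
    if na < 2 or nb < 2:
        warnings.warn("a group has a single sample: p-values are not computed")
        out["se"] = np.nan
        out["p"] = np.nan
        out["p_adj"] = np.nan
        out.attrs["dispersion"] = np.nan
        return out
    alpha = estimate_dispersion(norm, [na, nb], min_dispersion)

    def var_term(m: np.ndarray, n: int) -> np.ndarray:
        ms = m + PSEUDOCOUNT
        return (ms + alpha * ms**2) / (n * ms**2)

    se = np.sqrt(var_term(ma, na) + var_term(mb, nb)) / np.log(2)
    z = log2fc / se
    p = 2 * stats.norm.sf(np.abs(z))
    out["se"] = se
    out["p"] = p
    out["p_adj"] = multipletests(p, method="fdr_bh")[1]
    out.attrs["dispersion"] = alpha
    return out


def call_de(results: pd.DataFrame, policy: str | DEPolicy) -> pd.DataFrame:
    """Flag up/down features under a named significance policy.

    ``up`` requires fold change above the policy threshold (in the B-over-A
    direction) and the policy's significance criterion; ``down`` is symmetric.
    """
    if isinstance(policy, str):
        try:
            policy = POLICIES[policy]
        except KeyError:
            raise ValueError(
                f"unknown policy {policy!r}; known: {sorted(POLICIES)}"
            ) from None
    pcol = "p_adj" if policy.adjusted else "p"
    sig = results[pcol] < policy.alpha
    lfc = np.log2(policy.fc_threshold)
    out = results.copy()
    out["up"] = sig & (results["log2fc"] > lfc)
    out["down"] = sig & (results["log2fc"] < -lfc)
    return out
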