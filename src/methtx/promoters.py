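"""Promoter CpG-class (LCP/ICP/HCP) classification and the three-group
assignment of upregulated genes.

The classifier slides 500 bp windows in 20 bp steps over the promoter
(TSS -1 kb .. +1 kb) and computes, per window, the observed/expected CpG
ratio ``n_CpG * L / (n_C * n_G)`` and the GC content. A promoter is HCP if
any window has CpG ratio > 0.65 and GC > 55%, LCP if no window has CpG
ratio > 0.45, and ICP otherwise. N bases are excluded from all counts and
from the window length; a trailing partial window (< 500 bp) is not
evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW = 500
STEP = 20

HCP_RATIO = 0.65
HCP_GC = 55.0
LCP_RATIO = 0.45


@dataclass
class PromoterProfile:
    gene_id: str
    cls: str
    window_stats: pd.DataFrame  # offset, cpg_ratio, gc_content

    @property
    def max_ratio(self) -> float:
        return float(self.window_stats["cpg_ratio"].max())


def window_stats(sequence: str, window: int = WINDOW, step: int = STEP) -> pd.DataFrame:
    """Sliding-window CpG observed/expected ratio and GC content.

    Windows are anchored at the sequence start; only full windows are
    evaluated. A CpG dinucleotide is attributed to the window containing its
    C, counted on the given strand only. The ratio is 0 when a window has no
    C or no G; windows that are entirely N are dropped.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return pd.DataFrame(columns=["offset", "cpg_ratio", "gc_content"])
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_n = (arr == b"N").astype(np.int64)
    # CpG with its C at position i (the G may sit in the next window)
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[:-1] = is_c[:-1] & (arr[1:] == b"G")
    cum = lambda x: np.concatenate([[0], np.cumsum(x)])
    cc, cg, cn, ccpg = cum(is_c), cum(is_g), cum(is_n), cum(is_cpg)
    starts = np.arange(0, n - window + 1, step)
    ends = starts + window
    n_c = cc[ends] - cc[starts]
    n_g = cg[ends] - cg[starts]
    n_n = cn[ends] - cn[starts]
    n_cpg = ccpg[ends] - ccpg[starts]
    eff_len = window - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((n_c > 0) & (n_g > 0), n_cpg * eff_len / (n_c * n_g), 0.0)
        gc = np.where(eff_len > 0, 100.0 * (n_c + n_g) / eff_len, np.nan)
    out = pd.DataFrame({"offset": starts, "cpg_ratio": ratio, "gc_content": gc})
    return out[eff_len > 0].reset_index(drop=True)


def classify_sequence(sequence: str) -> str:
    """LCP/ICP/HCP class of a promoter sequence (see module docstring)."""
    stats = window_stats(sequence)
    if stats.empty:
        raise ValueError("promoter sequence has no evaluable window (all N or too short)")
    return _classify_stats(stats)


def _classify_stats(stats: pd.DataFrame) -> str:
    hcp = ((stats["cpg_ratio"] > HCP_RATIO) & (stats["gc_content"] > HCP_GC)).any()
    if hcp:
        return "HCP"
    if (stats["cpg_ratio"] > LCP_RATIO).any():
        return "ICP"
    return "LCP"


def classify_promoter(sequence: str, gene_id: str = "") -> PromoterProfile:
    stats = window_stats(sequence)
    if stats.empty:
        raise ValueError("promoter sequence has no evaluable window (all N or too short)")
    return PromoterProfile(gene_id=gene_id, cls=_classify_stats(stats), window_stats=stats)


def promoter_interval(transcript, upstream: int = 1000, downstream: int = 1000) -> tuple[str, int, int]:
    """Genomic interval of TSS -upstream .. +downstream in transcription
    orientation, clipped at 0."""
    tss = transcript.tss
    if transcript.strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream, tss + upstream
    return transcript.chrom, max(lo, 0), hi


def classify_promoters(
    genome: dict[str, str],
    transcripts: list,
    upstream: int = 1000,
    downstream: int = 1000,
) -> pd.DataFrame:
    """Classify each transcript's promoter from the genome sequence.

    Returns gene_id, transcript_id, cls and the maximal window CpG ratio.
    Promoters truncated by a contig edge are evaluated on the available
    sequence and flagged.
    """
    rows = []
    for t in transcripts:
        chrom, lo, hi = promoter_interval(t, upstream, downstream)
        seq = genome[chrom][lo : min(hi, len(genome[chrom]))]
        prof = classify_promoter(seq, gene_id=t.gene_id)
        rows.append(
            {
                "gene_id": t.gene_id,
                "transcript_id": t.transcript_id,
                "cls": prof.cls,
                "max_cpg_ratio": prof.max_ratio,
                "truncated": hi - lo < upstream + downstream,
            }
        )
    return pd.DataFrame(rows)


def assign_groups(
    upregulated: list[str],
    promoter_classes: pd.Series,
    promoter_meth_wt: pd.Series,
    meth_threshold: float = 30.0,
) -> pd.DataFrame:
    """Partition upregulated genes into the three promoter groups.

    Group 1: LCP. Group 2: ICP or HCP with wild-type promoter methylation
    (measured over TSS -1000..+500) below ``meth_threshold``. Group 3: ICP or
    HCP with methylation at or above it (the boundary is inclusive in group 3).
    Genes without a defined promoter methylation get group NaN and are
    reported via the ``defined`` flag rather than silently dropped.
    """
    rows = []
    for gene in upregulated:
        cls = promoter_classes.get(gene)
        if cls is None:
            raise KeyError(f"no promoter class for gene {gene}")
        meth = promoter_meth_wt.get(gene, np.nan)
        if cls == "LCP":
            group: float = 1
        elif np.isnan(meth):
            group = np.nan
        elif meth < meth_threshold:
            group = 2
        else:
            group = 3
        rows.append(
            {
                "gene_id": gene,
                "cls": cls,
                "promoter_meth_wt": meth,
                "group": group,
                "defined": cls == "LCP" or not np.isnan(meth),
            }
        )
    return pd.DataFrame(rows)
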