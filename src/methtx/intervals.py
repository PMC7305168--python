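"""Core genomic-interval types and coordinate conventions.

All coordinates inside the package are 0-based, half-open ``[start, end)``,
on named chromosomes. External formats (GTF, methylation-caller tables) are
converted on read and on write; BED and bedGraph are native.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive. ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A gene isoform as an ordered list of exons.

    Exons are stored in *transcription* order: exon 1 is the 5'-most exon of
    the mature transcript, so coordinates ascend on ``+`` transcripts and
    descend on ``-`` transcripts. Exons must not overlap each other.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"bad exon [{s},{e}) in {self.transcript_id}")
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        expect = by_start if self.strand == "+" else by_start[::-1]
        if self.exons != expect:
            raise ValueError(
                f"exons of {self.transcript_id} are not in transcription order"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site (a point)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[0][1]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def length(self) -> int:
        """Spliced transcript length (sum of exon lengths) in bp."""
        return sum(e - s for s, e in self.exons)

    def exon_index(self, start: int, end: int) -> int:
        """1-based index in transcription order of the exon [start, end)."""
        return self.exons.index((start, end)) + 1


def tile_genome(chrom_sizes: dict[str, int], window_size: int) -> pd.DataFrame:
    """Non-overlapping tiling of every chromosome from coordinate 0.

    The last window of a chromosome is truncated at the chromosome end, so the
    number of windows is ``ceil(size / window_size)`` per chromosome.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    frames = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, window_size)
        ends = np.minimum(starts + window_size, size)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def point_interval_means(
    points: pd.DataFrame,
    values: str,
    intervals: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of a point-attached value over each interval.

    ``points`` must have columns ``chrom``/``start`` and be sorted by them;
    a point belongs to an interval when ``interval.start <= point < interval.end``
    (half-open). Returns ``(means, counts)`` aligned with ``intervals`` rows;
    ``means`` is NaN where an interval contains no point.
    """
    means = np.full(len(intervals), np.nan)
    counts = np.zeros(len(intervals), dtype=int)
    for chrom, grp in points.groupby("chrom", sort=False):
        pos = grp["start"].to_numpy()
        val = grp[values].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(val)])
        mask = (intervals["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        lo = np.searchsorted(pos, intervals.loc[mask, "start"].to_numpy(), "left")
        hi = np.searchsorted(pos, intervals.loc[mask, "end"].to_numpy(), "left")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            m = (csum[hi] - csum[lo]) / n
        means[mask] = np.where(n > 0, m, np.nan)
        counts[mask] = n
    return means, counts
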