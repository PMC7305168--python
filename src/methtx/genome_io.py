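"""Readers and writers for the external formats the pipeline touches.

Dialect contracts
-----------------
* methratio TSV (BSMAP): columns chrom, pos (1-based C position), strand,
  context, ratio, eff_CT, C_count, CT_count. Strand-resolved cytosines of one
  CpG are merged onto the plus-strand C position by summing counts.
* Bismark coverage: chrom, start (1-based), end, percent, count_methylated,
  count_unmethylated. Assumed CpG-resolved already (the format carries no
  strand column).
* GTF2.2: 1-based closed coordinates, exon features with gene_id and
  transcript_id attributes.
* RepeatMasker-style TSV: header chrom, start, end, strand, family,
  repeat_class with 0-based half-open coordinates and UCSC-style class/family
  strings such as ``LTR/ERVK``.
* BED / bedGraph: native 0-based half-open.

Chromosome names are matched by exact string equality; ``strip_chr_prefix``
must be requested explicitly, nothing is renamed silently.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import TranscriptModel

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "start", "depth", "n_meth", "pct_meth"]

#: Repeat classes recognised at the TE-class level; everything else maps to
#: ``other`` (simple repeats, low-complexity DNA, DNA transposons, ...).
TE_CLASSES = ("SINE", "LINE", "ERV1", "ERVK", "ERVL")

METHRATIO_COLUMNS = [
    "chrom", "pos", "strand", "context", "ratio", "eff_CT", "C_count", "CT_count",
]
BISMARK_COV_COLUMNS = [
    "chrom", "start", "end", "pct", "count_meth", "count_unmeth",
]


def _finalize_calls(df: pd.DataFrame, min_depth: int, merge_strands: bool) -> pd.DataFrame:
    if merge_strands:
        df = (
            df.groupby(["chrom", "start"], as_index=False, sort=False)
            .agg(depth=("depth", "sum"), n_meth=("n_meth", "sum"))
        )
    df = df[df["depth"] >= min_depth].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pct_meth"] = np.where(
            df["depth"] > 0, 100.0 * df["n_meth"] / df["depth"], np.nan
        )
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df[CALL_COLUMNS]


def read_methylation_calls(
    path: str | Path,
    dialect: str,
    min_depth: int,
    strip_chr_prefix: bool = False,
) -> pd.DataFrame:
    """Read a per-CpG methylation call table.

    Returns a data frame with columns chrom, start (0-based plus-strand C
    position), depth, n_meth, pct_meth, containing only CpGs with
    ``depth >= min_depth``, sorted by (chrom, start).
    """
    path = Path(path)
    if dialect == "methratio":
        df = _read_strict(path, METHRATIO_COLUMNS, skip_header_token="chr")
        df["pos"] = _to_int(df, "pos", path)
        df["n_meth"] = _to_int(df, "C_count", path)
        df["depth"] = _to_int(df, "CT_count", path)
        # key each CpG by its plus-strand C: a '-' record reports the G
        # position, one base downstream of the plus-strand C
        df["start"] = np.where(df["strand"] == "-", df["pos"] - 2, df["pos"] - 1)
        merge = True
    elif dialect == "bismark_cov":
        df = _read_strict(path, BISMARK_COV_COLUMNS)
        df["n_meth"] = _to_int(df, "count_meth", path)
        df["depth"] = df["n_meth"] + _to_int(df, "count_unmeth", path)
        df["start"] = _to_int(df, "start", path) - 1
        merge = False
    else:
        raise ValueError(f"unknown methylation-call dialect {dialect!r}")
    if (df["n_meth"] > df["depth"]).any():
        bad = int(df.index[df["n_meth"] > df["depth"]][0]) + 1
        raise ValueError(f"{path}: line {bad}: methylated count exceeds depth")
    if (df["start"] < 0).any():
        raise ValueError(f"{path}: non-positive genomic position")
    if strip_chr_prefix:
        df["chrom"] = df["chrom"].str.replace(r"^chr", "", regex=True)
    return _finalize_calls(df[["chrom", "start", "depth", "n_meth"]], min_depth, merge)


def write_methylation_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a call table in the Bismark-coverage dialect (1-based)."""
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["start"] + 1,
            "end": calls["start"] + 1,
            "pct": calls["pct_meth"],
            "count_meth": calls["n_meth"],
            "count_unmeth": calls["depth"] - calls["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _read_strict(path: Path, columns: list[str], skip_header_token: str | None = None) -> pd.DataFrame:
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and skip_header_token and parts[0] == skip_header_token:
                continue
            if len(parts) != len(columns):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(columns)} columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    return pd.DataFrame(rows, columns=columns)


def _to_int(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    try:
        return df[col].astype(int)
    except ValueError as exc:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        lineno = int(bad[0]) + 1 if len(bad) else "?"
        raise ValueError(f"{path}: line {lineno}: malformed {col} field") from exc


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features of a GTF into per-isoform transcript models.

    Exons are grouped by transcript_id, converted to 0-based half-open
    coordinates, and ordered in transcription orientation.
    """
    path = Path(path)
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature != "exon":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}: line {lineno}: exon without transcript_id")
            gid = attr.get("gene_id", tid)
            rec = exons.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []}
            )
            if rec["strand"] != strand:
                raise ValueError(
                    f"{path}: line {lineno}: mixed strands within transcript {tid}"
                )
            if rec["chrom"] != chrom:
                raise ValueError(
                    f"{path}: line {lineno}: transcript {tid} spans chromosomes"
                )
            rec["exons"].append((int(start) - 1, int(end)))
    models = []
    for tid, rec in exons.items():
        order = sorted(rec["exons"], reverse=rec["strand"] == "-")
        models.append(
            TranscriptModel(
                gene_id=rec["gene_id"],
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=order,
            )
        )
    return models


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in sorted(t.exons):
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tmethtx\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker-style TE annotation

def classify_repeat(repeat_class: str) -> str:
    """Map a UCSC RepeatMasker class/family string to a coarse TE class."""
    fields = repeat_class.split("/")
    for token in reversed(fields):
        for cls in TE_CLASSES:
            if token.startswith(cls) or (cls == "ERVL" and "ERVL" in token):
                return cls
    return "other"


def read_repeatmasker(path: str | Path) -> pd.DataFrame:
    """Read a RepeatMasker-style TSV into a TE-copy table.

    Returns a data frame with columns chrom, start, end, strand, family,
    repeat_class (the raw class/family string), te_class, copy_id, length.
    No length filtering is applied here; consumers decide (the genomic-feature
    methylation panel drops elements <= 400 bp, family counting does not).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "strand", "family", "repeat_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TE annotation columns {sorted(missing)}")
    df = df.copy()
    df["te_class"] = df["repeat_class"].map(classify_repeat)
    unknown = df.loc[df["te_class"] == "other", "repeat_class"].unique()
    for cls in unknown:
        logger.warning("repeat class %r mapped to te_class 'other'", cls)
    df["copy_id"] = (
        df["chrom"].astype(str)
        + ":"
        + df["start"].astype(str)
        + "-"
        + df["end"].astype(str)
        + ":"
        + df["family"]
    )
    df["length"] = df["end"] - df["start"]
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_repeatmasker(te: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "strand", "family", "repeat_class"]
    te[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / bedGraph

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3- or 6-column BED file (0-based half-open, native)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Count matrices and alignment tables

def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample count/abundance matrix (TSV, first column id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.select_dtypes(include="number") < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_alignment_table(path: str | Path) -> pd.DataFrame:
    """Read a simplified alignment table: read_id, chrom, start, end, strand, n_hits.

    Every record of a read must carry the same n_hits, equal to the read's
    number of genomic alignments.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"read_id", "chrom", "start", "end", "strand", "n_hits"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing alignment columns {sorted(missing)}")
    per_read = df.groupby("read_id")["n_hits"]
    if (per_read.nunique() > 1).any():
        raise ValueError(f"{path}: inconsistent n_hits within a read")
    return df


def write_alignment_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["read_id", "chrom", "start", "end", "strand", "n_hits"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")
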