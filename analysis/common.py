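"""Shared loading helpers for the numbered analysis scripts.

Every script reads the simulated study written by ``01_simulate.py`` under
``results/sim`` and writes its tables under ``results/``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from methtx import genome_io, methylome

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results"


def load_annotation():
    genome = genome_io.read_fasta(SIM / "genome.fa")
    transcripts = genome_io.read_gtf(SIM / "transcripts.gtf")
    cgis = genome_io.read_bed(SIM / "cgis.bed")
    gdmrs = genome_io.read_bed(SIM / "gdmrs.bed")
    tes = genome_io.read_repeatmasker(SIM / "repeatmasker.tsv")
    return genome, transcripts, cgis, gdmrs, tes


def load_pooled_calls(min_depth: int = 5) -> dict[str, pd.DataFrame]:
    pooled = {}
    by_genotype: dict[str, list] = {}
    for p in sorted(SIM.glob("calls_*.cov")):
        genotype = p.stem.split("_")[1]
        by_genotype.setdefault(genotype, []).append(p)
    for genotype, paths in by_genotype.items():
        pooled[genotype] = methylome.pool_replicates(
            [genome_io.read_methylation_calls(p, "bismark_cov", min_depth) for p in paths]
        )
    return pooled


def load_counts():
    gene_counts = genome_io.read_count_matrix(SIM / "gene_counts.tsv")
    exon_raw = pd.read_csv(SIM / "exon_counts.tsv", sep="\t")
    exon_lengths = pd.Series(
        exon_raw["length"].to_numpy(),
        index=pd.MultiIndex.from_frame(exon_raw[["transcript_id", "exon_index"]]),
    )
    exon_counts = exon_raw.drop(columns="length").set_index(
        ["transcript_id", "exon_index"]
    )
    te_copy_counts = genome_io.read_count_matrix(SIM / "te_copy_counts.tsv")
    samples = pd.read_csv(SIM / "samples.tsv", sep="\t")
    groups = {
        g: samples.loc[samples["genotype"] == g, "sample"].tolist()
        for g in samples["genotype"].unique()
    }
    return gene_counts, exon_counts, exon_lengths, te_copy_counts, samples, groups


def load_alignments():
    return {
        p.stem.replace("alignments_", ""): genome_io.read_alignment_table(p)
        for p in sorted(SIM.glob("alignments_*.tsv"))
    }
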