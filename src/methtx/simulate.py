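"""Synthetic genome, methylomes and count matrices with planted effects.

The generator emulates the statistical structure of a bisulfite + RNA-seq
study of severely hypomethylated mouse embryos:

* genotypes WT (globally methylated, ~85% outside CpG islands), a
  maintenance-methyltransferase knockout (``Dnmt1KO``: the WT landscape
  uniformly scaled down to ~25%, imprinted gDMRs included) and a de novo
  double knockout (``DKO``) whose methylome is a copy of a preimplantation
  ``ICM`` track — methylation is maintained but never acquired — except at
  retained young TE families and gDMRs, which stay high;
* CpG-island promoters unmethylated except for a planted "germline-like"
  set that is methylated in WT and derepressed in the mutants;
* planted derepressed gene sets (germline-like on methylated HCP promoters,
  2C-like on LCP promoters), reactivated TE copies biased toward long
  (full-length) elements, genes driven by nearby reactivated ERVs, planted
  cryptic intragenic initiation events at exon resolution, and 1 kb windows
  de novo methylated between the ICM and the late-embryo stage;
* per-CpG calls with negative-binomial depth (mean 12x, a realistic
  whole-genome bisulfite depth) and beta-binomial methylation counts;
  RNA counts negative-binomial around log-normal baselines; TE reads as an
  alignment table with multi-mapping (``n_hits``) structure.

Everything is deterministic under a fixed seed: one root seed spawns fixed,
named substreams so each stage can be regenerated independently. Every
planted effect is recorded in a ground-truth sidecar consumed by the tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_io, te as te_mod
from .intervals import TranscriptModel

BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed substream ids: reproducibility with modular regeneration
_STREAMS = {
    "annotation": 1, "methylome": 2, "methylome_draws": 5, "counts": 3,
    "coverage": 4,
}


@dataclass
class TEFamilySpec:
    name: str
    te_class: str           # coarse class used for reporting
    repeat_class: str       # RepeatMasker-style class/family string
    n_copies: int
    length_range: tuple[int, int]
    base_reads: float       # expected reads per sample per family in WT
    fc: dict[str, float] = field(default_factory=dict)   # family-level fold change per genotype
    multimap_rate: float = 0.0
    n_reactivated: int = 0  # copies planted strongly up in Dnmt1KO
    reactivated_fc: float = 30.0
    retained: bool = False  # stays highly methylated in DKO/ICM


def default_te_families() -> list[TEFamilySpec]:
    return [
        TEFamilySpec("IAPEz-int", "ERVK", "LTR/ERVK", 60, (2000, 7000), 400,
                     {"Dnmt1KO": 30, "DKO": 2}, 0.7, n_reactivated=18, retained=True),
        TEFamilySpec("IAPLTR1_Mm", "ERVK", "LTR/ERVK", 40, (300, 400), 150,
                     {"Dnmt1KO": 20, "DKO": 2}, 0.6, retained=True),
        TEFamilySpec("MMERVK10C-int", "ERVK", "LTR/ERVK", 40, (3000, 5500), 200,
                     {"Dnmt1KO": 8, "DKO": 2}, 0.5, n_reactivated=3, retained=True),
        TEFamilySpec("MMETn-int", "ERVK", "LTR/ERVK", 30, (1000, 6000), 100,
                     {"Dnmt1KO": 6}, 0.5, n_reactivated=3),
        TEFamilySpec("MMERGLN-int", "ERV1", "LTR/ERV1", 30, (3000, 6000), 150,
                     {"Dnmt1KO": 6}, 0.5, n_reactivated=3),
        TEFamilySpec("MERVL-int", "ERVL", "LTR/ERVL", 40, (4000, 5500), 300,
                     {"DKO": 3}, 0.6),
        TEFamilySpec("MT2_Mm", "ERVL", "LTR/ERVL", 30, (450, 550), 100, {"DKO": 3}, 0.3),
        TEFamilySpec("L1Md_T", "LINE", "LINE/L1", 50, (5000, 7000), 500,
                     {"Dnmt1KO": 5, "DKO": 2}, 0.8, n_reactivated=4),
        TEFamilySpec("Lx5", "LINE", "LINE/L1", 50, (1000, 3000), 300, {}, 0.3),
        TEFamilySpec("B1_Mus1", "SINE", "SINE/Alu", 100, (120, 180), 400, {}, 0.6),
        TEFamilySpec("(TTAGGG)n", "other", "Simple_repeat", 30, (100, 300), 50, {}, 0.0),
    ]


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark (defaults are the
    conditions every test and the acceptance run use)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    isoforms_per_gene: tuple[int, int] = (1, 2)
    exons_per_transcript: tuple[int, int] = (5, 10)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (500, 2500)
    intergenic_gap: tuple[int, int] = (3000, 12000)
    promoter_proportions: dict = field(
        default_factory=lambda: {"HCP": 0.5, "ICP": 0.2, "LCP": 0.3}
    )
    te_families: list[TEFamilySpec] = field(default_factory=default_te_families)

    # methylome
    genotype_meth_means: dict = field(
        default_factory=lambda: {
            # genotype -> (non-CGI mean, CGI mean); ICM non-CGI is the mean of
            # a per-kb block mixture (see icm_block_*)
            "WT": (0.85, 0.03),
            "ICM": (0.12, 0.02),
        }
    )
    dnmt1ko_scale: float = 0.25        # Dnmt1KO = scale x WT, gDMRs included
    icm_block_high_prob: float = 0.08  # fraction of 1 kb blocks retaining high methylation
    icm_block_high_mean: float = 0.80
    gdmr_mean: float = 0.50            # allelic methylation of imprinted gDMRs
    te_retained_mean: float = 0.85
    de_novo_icm_mean: float = 0.01
    beta_binomial_precision: float = 30.0
    depth_mean: float = 12.0
    depth_size: float = 5.0
    n_meth_replicates: int = 2
    n_gdmrs: int = 20
    gdmr_length: int = 1500
    n_de_novo_windows: int = 30

    # expression
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    log_mean_expression: float = 4.0
    log_sd_expression: float = 1.5
    min_planted_baseline: float = 20.0
    n_germline_genes: int = 40
    germline_fc: float = 8.0
    n_twocell_genes: int = 15
    twocell_fc: float = 8.0
    n_cryptic_genes: int = 20
    cryptic_fc: float = 10.0
    erv_driven_fc: float = 2.5
    te_family_dispersion: float = 0.05
    background_read_frac: float = 0.3
    read_length: int = 80

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced-scale configuration for fast unit tests."""
    families = [
        dataclasses.replace(f, n_copies=max(6, f.n_copies // 5),
                            n_reactivated=min(3, f.n_reactivated),
                            base_reads=f.base_reads / 3)
        for f in default_te_families()
    ]
    cfg = SimConfig(
        seed=seed,
        chrom_length=2_200_000,
        n_genes=120,
        te_families=families,
        n_gdmrs=8,
        n_de_novo_windows=10,
        n_germline_genes=14,
        n_twocell_genes=6,
        n_cryptic_genes=6,
    )
    return dataclasses.replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# Annotation

@dataclass
class Annotation:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    cgis: pd.DataFrame
    tes: pd.DataFrame
    gdmrs: pd.DataFrame
    de_novo_windows: pd.DataFrame
    gene_table: pd.DataFrame         # gene_id, chrom, strand, tss, promoter class, planted role
    ground_truth: dict

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _random_sequence(rng: np.random.Generator, length: int, gc: float,
                     cpg_thinning: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(BASES, size=length, p=p)
    if cpg_thinning > 0 and length > 1:
        is_cpg = (seq[:-1] == b"C") & (seq[1:] == b"G")
        idx = np.flatnonzero(is_cpg)
        kill = idx[rng.random(len(idx)) < cpg_thinning]
        seq[kill + 1] = b"A"  # break the CpG, keep GC roughly stable
    return seq

# per promoter class: (GC content, CpG thinning) chosen so the sliding-window
# classifier reproduces the intended class by construction
_PROMOTER_SEQ = {"HCP": (0.60, 0.0), "ICP": (0.50, 0.45), "LCP": (0.40, 0.92)}
_BACKGROUND = (0.42, 0.80)
_GDMR_SEQ = (0.55, 0.30)
_CRYPTIC_SEQ = (0.55, 0.0)
CRYPTIC_PATCH = 500


def simulate_annotation(config: SimConfig) -> Annotation:
    """Lay out genes, TE copies, gDMRs and de novo windows on a synthetic
    genome whose promoter sequences realise the intended CpG classes."""
    rng = config.rng("annotation")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {
        c: _random_sequence(rng, config.chrom_length, *_BACKGROUND)
        for c in chrom_names
    }

    # --- intended promoter classes and planted roles ---------------------
    classes = list(config.promoter_proportions)
    probs = np.array([config.promoter_proportions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    gene_cls = rng.choice(classes, size=config.n_genes, p=probs)
    hcp_idx = np.flatnonzero(gene_cls == "HCP")
    lcp_idx = np.flatnonzero(gene_cls == "LCP")
    if len(hcp_idx) < config.n_germline_genes or len(lcp_idx) < config.n_twocell_genes:
        raise ValueError("not enough HCP/LCP genes to host the planted gene sets")
    germline = set(rng.choice(hcp_idx, size=config.n_germline_genes, replace=False))
    twocell = set(rng.choice(lcp_idx, size=config.n_twocell_genes, replace=False))
    remaining = [i for i in range(config.n_genes) if i not in germline | twocell]
    if len(remaining) < config.n_cryptic_genes:
        raise ValueError("not enough genes left for cryptic-initiation planting")
    cryptic = set(rng.choice(np.array(remaining), size=config.n_cryptic_genes, replace=False))

    # --- gene placement ---------------------------------------------------
    transcripts: list[TranscriptModel] = []
    gene_rows = []
    cryptic_truth = []
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    for chrom, gene_ids in zip(chrom_names, per_chrom):
        cursor = 2000
        for gi in gene_ids:
            gene_id = f"gene{gi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_iso = int(rng.integers(*config.isoforms_per_gene, endpoint=True))
            is_cryptic = gi in cryptic
            if is_cryptic:
                n_iso = 1  # keep a single isoform for planted cryptic genes
            n_exons = int(rng.integers(*config.exons_per_transcript, endpoint=True))
            exon_lens = rng.integers(*config.exon_length, endpoint=True, size=n_exons)
            intron_lens = rng.integers(*config.intron_length, endpoint=True, size=n_exons - 1)
            cursor += int(rng.integers(*config.intergenic_gap, endpoint=True))
            start = cursor + 1100  # leave room for the upstream promoter arm
            coords = []
            pos = start
            for k in range(n_exons):
                coords.append((pos, pos + int(exon_lens[k])))
                pos = coords[-1][1] + (int(intron_lens[k]) if k < n_exons - 1 else 0)
            gene_end = coords[-1][1]
            if gene_end + 2000 > config.chrom_length:
                raise ValueError("genome too short for the requested features")
            cursor = gene_end + 1100
            order = coords if strand == "+" else coords[::-1]
            tx_ids = []
            for iso in range(n_iso):
                exons = order if iso == 0 else order[1:]
                if len(exons) < 2:
                    continue
                tid = f"gene{gi:04d}.t{iso + 1}"
                transcripts.append(
                    TranscriptModel(gene_id, tid, chrom, strand, list(exons))
                )
                tx_ids.append(tid)
            tss = start if strand == "+" else gene_end
            cls = gene_cls[gi]
            # write the promoter sequence (TSS +- 1 kb)
            gc, thin = _PROMOTER_SEQ[cls]
            lo = max(tss - 1000, 0)
            genome[chrom][lo: tss + 1000] = _random_sequence(
                rng, tss + 1000 - lo, gc, thin
            )
            role = "germline" if gi in germline else "2cell" if gi in twocell else \
                "cryptic" if is_cryptic else "none"
            if is_cryptic:
                k = int(rng.integers(3, n_exons))  # first upregulated exon, 3..n-1
                s, e = order[k - 1]
                init_pos = s if strand == "+" else e
                patch_lo = init_pos if strand == "+" else init_pos - CRYPTIC_PATCH
                patch_lo = max(patch_lo, 0)
                genome[chrom][patch_lo: patch_lo + CRYPTIC_PATCH] = _random_sequence(
                    rng, CRYPTIC_PATCH, *_CRYPTIC_SEQ
                )
                cryptic_truth.append(
                    {
                        "gene_id": gene_id,
                        "transcript_id": tx_ids[0],
                        "first_up_exon_index": k,
                        "init_position": int(init_pos),
                        "chrom": chrom,
                        "patch_start": int(patch_lo),
                        "patch_end": int(patch_lo + CRYPTIC_PATCH),
                        "fold_change": config.cryptic_fc,
                    }
                )
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": gene_end,
                    "tss": tss,
                    "promoter_class": cls,
                    "role": role,
                    "primary_transcript": tx_ids[0],
                }
            )
    gene_table = pd.DataFrame(gene_rows)

    # --- CpG islands: promoters of HCP genes ------------------------------
    cgi = gene_table[gene_table["promoter_class"] == "HCP"]
    cgis = pd.DataFrame(
        {
            "chrom": cgi["chrom"],
            "start": np.maximum(cgi["tss"] - 500, 0),
            "end": cgi["tss"] + 500,
            "name": cgi["gene_id"].str.replace("gene", "CGI"),
        }
    ).reset_index(drop=True)

    # --- intergenic space for TEs, gDMRs, de novo windows -----------------
    gaps = _intergenic_gaps(gene_table, config, margin=1500)
    intron_gaps = _intron_gaps(transcripts)
    te_rows = _place_tes(config, rng, gaps, intron_gaps)
    tes = _finish_tes(te_rows)

    gdmrs = _place_intervals(rng, gaps, config.n_gdmrs, config.gdmr_length, "gDMR")
    for row in gdmrs.itertuples(index=False):
        genome[row.chrom][row.start: row.end] = _random_sequence(
            rng, row.end - row.start, *_GDMR_SEQ
        )
    dn = _place_grid_windows(rng, gaps, config.n_de_novo_windows, 1000)

    genome_str = {c: seq.tobytes().decode("ascii") for c, seq in genome.items()}
    reactivated = tes[tes["reactivated"]]["copy_id"].tolist()
    truth = {
        "germline_genes": sorted(gene_table.loc[gene_table["role"] == "germline", "gene_id"]),
        "twocell_genes": sorted(gene_table.loc[gene_table["role"] == "2cell", "gene_id"]),
        "cryptic_genes": cryptic_truth,
        "reactivated_te_copies": reactivated,
        "retained_te_families": [f.name for f in config.te_families if f.retained],
        "de_novo_windows": dn[["chrom", "start", "end"]].to_dict("records"),
        "gdmrs": gdmrs[["chrom", "start", "end"]].to_dict("records"),
    }
    return Annotation(
        genome=genome_str,
        transcripts=transcripts,
        cgis=cgis,
        tes=tes,
        gdmrs=gdmrs,
        de_novo_windows=dn,
        gene_table=gene_table,
        ground_truth=truth,
    )


def _intergenic_gaps(gene_table: pd.DataFrame, config: SimConfig, margin: int) -> list[list]:
    gaps = []
    for chrom in sorted(gene_table["chrom"].unique()):
        sub = gene_table[gene_table["chrom"] == chrom].sort_values("start")
        prev = 1000
        for row in sub.itertuples(index=False):
            if row.start - margin - prev > 2000:
                gaps.append([chrom, prev, row.start - margin])
            prev = row.end + margin
        if config.chrom_length - 1000 - prev > 2000:
            gaps.append([chrom, prev, config.chrom_length - 1000])
    return gaps


def _take_slot(rng: np.random.Generator, gaps: list[list], length: int) -> tuple[str, int]:
    """Reserve a sub-interval of a random gap; shrinks the gap in place."""
    fits = [i for i, (_, s, e) in enumerate(gaps) if e - s >= length + 200]
    if not fits:
        raise ValueError("genome too short: no intergenic space left")
    i = int(rng.choice(fits))
    chrom, s, e = gaps[i]
    start = int(rng.integers(s + 100, e - length - 100, endpoint=True))
    # split the gap around the reserved slot
    gaps[i] = [chrom, s, start - 100]
    gaps.append([chrom, start + length + 100, e])
    return chrom, start


def _intron_gaps(transcripts: list[TranscriptModel]) -> list[list]:
    """Introns of primary isoforms large enough to host short TE copies."""
    gaps = []
    seen = set()
    for t in transcripts:
        if t.gene_id in seen:
            continue
        seen.add(t.gene_id)
        exons = sorted(t.exons)
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 - e1 >= 1000:
                gaps.append([t.chrom, e1, s2])
    return gaps


def _place_tes(config: SimConfig, rng: np.random.Generator, gaps: list[list],
               intron_gaps: list[list]) -> list[dict]:
    rows = []
    for fam in config.te_families:
        lengths = rng.integers(*fam.length_range, endpoint=True, size=fam.n_copies)
        # reactivated copies are drawn from the longer half of the family:
        # full-length elements are the potentially active ones
        order = np.argsort(lengths)[::-1]
        pool = order[: max(fam.n_reactivated, len(order) // 2)]
        reactivated = set(
            rng.choice(pool, size=min(fam.n_reactivated, len(pool)), replace=False)
        )
        intronic_ok = fam.length_range[1] <= 600
        for k in range(fam.n_copies):
            if intronic_ok and intron_gaps and rng.random() < 0.4:
                try:
                    chrom, start = _take_slot(rng, intron_gaps, int(lengths[k]))
                except ValueError:
                    chrom, start = _take_slot(rng, gaps, int(lengths[k]))
            else:
                chrom, start = _take_slot(rng, gaps, int(lengths[k]))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + int(lengths[k]),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "family": fam.name,
                    "repeat_class": fam.repeat_class,
                    "te_class": fam.te_class,
                    "retained": fam.retained,
                    "reactivated": k in reactivated,
                    "reactivated_fc": fam.reactivated_fc if k in reactivated else 1.0,
                }
            )
    return rows


def _finish_tes(rows: list[dict]) -> pd.DataFrame:
    tes = pd.DataFrame(rows)
    if tes.empty:
        dtypes = {
            "chrom": str, "start": int, "end": int, "strand": str,
            "family": str, "repeat_class": str, "te_class": str,
            "retained": bool, "reactivated": bool, "reactivated_fc": float,
            "copy_id": str, "length": int,
        }
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in dtypes.items()})
    tes["copy_id"] = (
        tes["chrom"] + ":" + tes["start"].astype(str) + "-" + tes["end"].astype(str)
        + ":" + tes["family"]
    )
    tes["length"] = tes["end"] - tes["start"]
    return tes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _place_intervals(rng, gaps, n: int, length: int, prefix: str) -> pd.DataFrame:
    rows = []
    for i in range(n):
        chrom, start = _take_slot(rng, gaps, length)
        rows.append({"chrom": chrom, "start": start, "end": start + length,
                     "name": f"{prefix}{i:03d}"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _place_grid_windows(rng, gaps, n: int, window: int) -> pd.DataFrame:
    """Place windows aligned to the genome-wide tiling grid, so the planted
    set coincides exactly with tiling windows."""
    rows = []
    tries = 0
    while len(rows) < n:
        tries += 1
        if tries > 10000:
            raise ValueError("could not place aligned de novo windows")
        fits = [i for i, (_, s, e) in enumerate(gaps) if e - s >= 3 * window]
        if not fits:
            raise ValueError("genome too short for de novo windows")
        i = int(rng.choice(fits))
        chrom, s, e = gaps[i]
        lo = -(-s // window)  # first grid index fully inside
        hi = e // window - 1
        if hi <= lo:
            continue
        g = int(rng.integers(lo, hi))
        start = g * window
        gaps[i] = [chrom, s, start]
        gaps.append([chrom, start + window, e])
        rows.append({"chrom": chrom, "start": start, "end": start + window,
                     "name": f"denovo{len(rows):03d}"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Methylome

def cpg_positions(genome: dict[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        out[chrom] = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
    return out


def _paint(level: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame, value) -> None:
    for row in intervals.itertuples(index=False):
        lo = np.searchsorted(pos, row.start, "left")
        hi = np.searchsorted(pos, row.end, "left")
        level[lo:hi] = value


def latent_methylation(config: SimConfig, annotation: Annotation) -> dict[str, dict[str, np.ndarray]]:
    """Per-CpG latent methylation mean for each genotype.

    Returns ``{chrom: {genotype: array}}`` aligned with
    :func:`cpg_positions`. The WT track is painted first (defaults, CGIs,
    germline promoter CGIs, gDMRs); ICM gets the per-block mixture plus its
    own overrides; DKO is a copy of ICM with retained TE copies and gDMRs
    held high; Dnmt1KO is the WT track uniformly scaled down.
    """
    rng = config.rng("methylome")
    positions = cpg_positions(annotation.genome)
    wt_nc, wt_cgi = config.genotype_meth_means["WT"]
    icm_low, icm_cgi = config.genotype_meth_means["ICM"]
    gene_tab = annotation.gene_table
    germline_cgis = annotation.cgis[
        annotation.cgis["name"].str.replace("CGI", "gene").isin(
            gene_tab.loc[gene_tab["role"] == "germline", "gene_id"]
        )
    ]
    retained = annotation.tes[annotation.tes["retained"]]
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, pos in positions.items():
        n = len(pos)
        sel = lambda df: df[df["chrom"] == chrom]
        # WT
        wt = np.full(n, wt_nc)
        _paint(wt, pos, sel(annotation.cgis), wt_cgi)
        _paint(wt, pos, sel(germline_cgis), 0.80)  # methylated germline promoters
        _paint(wt, pos, sel(annotation.gdmrs), config.gdmr_mean)
        # ICM: block mixture of mostly-low with a minority of retained-high blocks
        blocks = pos // 1000
        n_blocks = int(blocks.max()) + 1 if n else 0
        block_level = np.where(
            rng.random(n_blocks) < config.icm_block_high_prob,
            config.icm_block_high_mean,
            icm_low,
        )
        icm = block_level[blocks] if n else np.empty(0)
        _paint(icm, pos, sel(annotation.cgis), icm_cgi)
        _paint(icm, pos, sel(germline_cgis), icm_cgi)
        _paint(icm, pos, sel(annotation.gdmrs), config.gdmr_mean)
        _paint(icm, pos, sel(retained), config.te_retained_mean)
        _paint(icm, pos, sel(annotation.de_novo_windows), config.de_novo_icm_mean)
        for patch in annotation.ground_truth["cryptic_genes"]:
            if patch["chrom"] == chrom:
                lo = np.searchsorted(pos, patch["patch_start"], "left")
                hi = np.searchsorted(pos, patch["patch_end"], "left")
                icm[lo:hi] = 0.05
        # DKO: maintenance only — the ICM landscape, with retained TE
        # families and gDMRs explicitly held high
        dko = icm.copy()
        _paint(dko, pos, sel(retained), config.te_retained_mean)
        _paint(dko, pos, sel(annotation.gdmrs), config.gdmr_mean)
        out[chrom] = {
            "WT": wt,
            "Dnmt1KO": wt * config.dnmt1ko_scale,
            "DKO": dko,
            "ICM": icm,
        }
    return out


def simulate_methylome(
    config: SimConfig, annotation: Annotation
) -> dict[tuple[str, int], pd.DataFrame]:
    """Per-genotype, per-replicate CpG call tables.

    Depth is truncated negative binomial (minimum 1); methylated counts are
    beta-binomial around the genotype's latent per-CpG mean with the
    configured precision.
    """
    rng = config.rng("methylome_draws")
    latent = latent_methylation(config, annotation)
    positions = cpg_positions(annotation.genome)
    s = config.beta_binomial_precision
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    genotypes = list(next(iter(latent.values())).keys()) if latent else []
    for genotype in genotypes:
        for rep in range(1, config.n_meth_replicates + 1):
            frames = []
            for chrom, pos in positions.items():
                mean = np.clip(latent[chrom][genotype], 1e-3, 1 - 1e-3)
                n = len(pos)
                depth = np.maximum(
                    rng.negative_binomial(
                        config.depth_size,
                        config.depth_size / (config.depth_size + config.depth_mean),
                        n,
                    ),
                    1,
                )
                p = rng.beta(mean * s, (1 - mean) * s)
                n_meth = rng.binomial(depth, p)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "start": pos,
                            "depth": depth,
                            "n_meth": n_meth,
                            "pct_meth": 100.0 * n_meth / depth,
                        }
                    )
                )
            tables[(genotype, rep)] = pd.concat(frames, ignore_index=True)
    return tables


# ---------------------------------------------------------------------------
# Expression

def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean, dtype=float) * dispersion)
    return rng.poisson(lam)


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for genotype in ("WT", "Dnmt1KO", "DKO"):
        for rep in range(1, config.n_replicates + 1):
            rows.append({"sample": f"{genotype}_{rep}", "genotype": genotype,
                         "replicate": rep})
    return pd.DataFrame(rows)


@dataclass
class CountBundle:
    gene_counts: pd.DataFrame
    exon_counts: pd.DataFrame          # MultiIndex (transcript_id, exon_index)
    exon_lengths: pd.Series
    gene_lengths: pd.Series
    alignments: dict[str, pd.DataFrame]
    te_copy_counts: pd.DataFrame
    samples: pd.DataFrame
    size_factors_true: pd.Series
    ground_truth: dict


def simulate_counts(config: SimConfig, annotation: Annotation) -> CountBundle:
    """Gene/exon count matrices, the TE alignment table and TE copy counts.

    Baseline expression per gene is log-normal; counts are negative binomial
    with a per-sample depth multiplier. Planted gene sets multiply all exons;
    planted cryptic events multiply only exons at and downstream of the first
    upregulated exon, in the affected genotype. TE reads carry multi-mapping
    structure (``n_hits``); copy counts are derived from uniquely mapping
    reads of the alignment table.
    """
    rng = config.rng("counts")
    samples = sample_sheet(config)
    sf = pd.Series(
        np.exp(rng.normal(0.0, 0.2, len(samples))), index=samples["sample"]
    )
    genes = annotation.gene_table
    base = pd.Series(
        np.exp(rng.normal(config.log_mean_expression, config.log_sd_expression,
                          len(genes))),
        index=genes["gene_id"],
    )
    # planted genes must be detectable: redraw their baselines above a floor,
    # emulating derepression to readily quantifiable expression
    planted = genes["role"] != "none"
    for gid in genes.loc[planted, "gene_id"]:
        while base[gid] < config.min_planted_baseline:
            base[gid] = float(
                np.exp(rng.normal(config.log_mean_expression, config.log_sd_expression))
            )

    truth = dict(annotation.ground_truth)
    cryptic_by_gene = {c["gene_id"]: c for c in truth["cryptic_genes"]}

    # genotype fold change per gene (whole-gene effects)
    fc = pd.DataFrame(1.0, index=genes["gene_id"], columns=["WT", "Dnmt1KO", "DKO"])
    fc.loc[truth["germline_genes"], ["Dnmt1KO", "DKO"]] = config.germline_fc
    fc.loc[truth["twocell_genes"], "DKO"] = config.twocell_fc

    # ERV-driven genes: TSS < 20 kb from a planted reactivated ERV copy
    react = annotation.tes[
        annotation.tes["reactivated"]
        & annotation.tes["te_class"].isin(("ERV1", "ERVK", "ERVL"))
    ]
    models = {t.transcript_id: t for t in annotation.transcripts}
    primaries = [models[t] for t in genes["primary_transcript"]]
    dist = te_mod._tss_distance_to_copies(primaries, react)
    erv_driven = sorted(
        g for g in dist.index[dist < 20_000]
        if fc.loc[g].eq(1.0).all() and g not in cryptic_by_gene
    )
    fc.loc[erv_driven, "Dnmt1KO"] = config.erv_driven_fc
    truth["erv_driven_genes"] = erv_driven
    truth["planted_gene_fc"] = {
        g: {gt: v for gt, v in row.items() if v != 1.0}
        for g, row in fc.iterrows()
        if not row.eq(1.0).all()
    }

    # --- gene counts ------------------------------------------------------
    gene_mat = {}
    for row in samples.itertuples(index=False):
        mean = base * fc[row.genotype] * sf[row.sample]
        gene_mat[row.sample] = _nb(rng, mean.to_numpy(), config.nb_dispersion)
    gene_counts = pd.DataFrame(gene_mat, index=genes["gene_id"])

    # --- exon counts ------------------------------------------------------
    iso_share = {}
    for gid, grp in pd.Series(
        [t.transcript_id for t in annotation.transcripts],
        index=[t.gene_id for t in annotation.transcripts],
    ).groupby(level=0):
        tids = sorted(grp.tolist())
        share = [1.0] if len(tids) == 1 else [0.7, 0.3]
        for tid, s_ in zip(tids, share):
            iso_share[tid] = s_
    exon_index = []
    exon_mean_rows = []
    exon_len = []
    for t in annotation.transcripts:
        lens = np.array([e - s for s, e in t.exons], dtype=float)
        tx_base = float(base[t.gene_id]) * iso_share[t.transcript_id]
        means = tx_base * lens / lens.mean()
        cry = cryptic_by_gene.get(t.gene_id)
        per_geno = {}
        for genotype in ("WT", "Dnmt1KO", "DKO"):
            g_mean = means * float(fc.loc[t.gene_id, genotype])
            if cry is not None and genotype == "DKO":
                g_mean = g_mean.copy()
                g_mean[cry["first_up_exon_index"] - 1:] *= cry["fold_change"]
            per_geno[genotype] = g_mean
        for k in range(t.n_exons):
            exon_index.append((t.transcript_id, k + 1))
            exon_len.append(lens[k])
            exon_mean_rows.append({g: per_geno[g][k] for g in per_geno})
    idx = pd.MultiIndex.from_tuples(exon_index, names=["transcript_id", "exon_index"])
    exon_means = pd.DataFrame(exon_mean_rows, index=idx)
    exon_mat = {}
    for row in samples.itertuples(index=False):
        mean = exon_means[row.genotype].to_numpy() * sf[row.sample]
        exon_mat[row.sample] = _nb(rng, mean, config.nb_dispersion)
    exon_counts = pd.DataFrame(exon_mat, index=idx)
    exon_lengths = pd.Series(exon_len, index=idx, name="length")
    gene_lengths = pd.Series(
        {t.transcript_id: t.length for t in annotation.transcripts}, name="length"
    )

    # --- TE alignment tables and copy counts ------------------------------
    alignments = {}
    tes = annotation.tes
    fam_specs = {f.name: f for f in config.te_families}
    for row in samples.itertuples(index=False):
        frames = []
        read_no = 0
        for fam_name, fam_copies in tes.groupby("family", sort=True):
            spec = fam_specs[fam_name]
            fam_fc = spec.fc.get(row.genotype, 1.0)
            lens = fam_copies["length"].to_numpy(dtype=float)
            weights = lens / lens.sum()
            # family-level upregulation with planted copies emerges from the
            # reactivated copies; diffuse family fold changes apply otherwise
            if row.genotype == "Dnmt1KO" and spec.n_reactivated > 0:
                copy_fc = np.where(
                    fam_copies["reactivated"], fam_copies["reactivated_fc"], 1.0
                )
            else:
                copy_fc = np.full(len(fam_copies), fam_fc)
            mu = spec.base_reads * weights * copy_fc * sf[row.sample]
            jitter = rng.gamma(
                1.0 / config.te_family_dispersion,
                config.te_family_dispersion,
            )
            n_reads = rng.poisson(mu * jitter)
            frames.append(
                _family_reads(rng, fam_copies, n_reads, spec, config, read_no,
                              row.sample)
            )
            read_no += int(n_reads.sum())
        aln = pd.concat([f for f in frames if len(f)], ignore_index=True) \
            if frames else pd.DataFrame()
        n_bg = rng.poisson(config.background_read_frac * max(read_no, 1))
        bg = _background_reads(rng, annotation.chrom_sizes, n_bg, config, read_no,
                               row.sample)
        alignments[row.sample] = pd.concat([aln, bg], ignore_index=True)
    te_copy_counts = te_mod.copy_count_matrix(alignments, tes) if len(tes) else \
        pd.DataFrame(index=pd.Index([], name="copy_id"), columns=samples["sample"])

    return CountBundle(
        gene_counts=gene_counts,
        exon_counts=exon_counts,
        exon_lengths=exon_lengths,
        gene_lengths=gene_lengths,
        alignments=alignments,
        te_copy_counts=te_copy_counts,
        samples=samples,
        size_factors_true=sf,
        ground_truth=truth,
    )


def _family_reads(rng, fam_copies: pd.DataFrame, n_reads: np.ndarray,
                  spec: TEFamilySpec, config: SimConfig, read_no: int,
                  sample: str) -> pd.DataFrame:
    rows = []
    starts = fam_copies["start"].to_numpy()
    ends = fam_copies["end"].to_numpy()
    chroms = fam_copies["chrom"].to_numpy()
    strands = fam_copies["strand"].to_numpy()
    n_copies = len(fam_copies)
    rid = read_no
    for ci in range(n_copies):
        for _ in range(int(n_reads[ci])):
            rid += 1
            read_id = f"{sample}:r{rid}"
            multi = n_copies > 1 and rng.random() < spec.multimap_rate
            if multi:
                n_hits = int(min(2 + rng.poisson(1.0), n_copies, 6))
            else:
                n_hits = 1
            others = []
            if n_hits > 1:
                pool = [j for j in range(n_copies) if j != ci]
                others = list(rng.choice(pool, size=n_hits - 1, replace=False))
            for cj in [ci] + others:
                span = max(int(ends[cj] - starts[cj]) - config.read_length, 1)
                s = int(starts[cj] + rng.integers(0, span))
                rows.append(
                    {
                        "read_id": read_id,
                        "chrom": chroms[cj],
                        "start": s,
                        "end": min(s + config.read_length, int(ends[cj])),
                        "strand": strands[cj],
                        "n_hits": n_hits,
                    }
                )
    return pd.DataFrame(rows)


def _background_reads(rng, chrom_sizes: dict[str, int], n: int, config: SimConfig,
                      read_no: int, sample: str) -> pd.DataFrame:
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    rows = []
    for i, ci in enumerate(picks):
        s = int(rng.integers(0, chrom_sizes[chroms[ci]] - config.read_length))
        rows.append(
            {
                "read_id": f"{sample}:bg{read_no + i + 1}",
                "chrom": chroms[ci],
                "start": s,
                "end": s + config.read_length,
                "strand": "+" if rng.random() < 0.5 else "-",
                "n_hits": 1,
            }
        )
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "start", "end", "strand", "n_hits"]
    )


# ---------------------------------------------------------------------------
# Focused mini-simulations used for calibration and power checks

def simulate_null_counts(
    n_features: int,
    seed: int,
    n_replicates: int = 3,
    config: SimConfig | None = None,
    n_planted: int = 0,
    fold_change: float = 1.0,
    min_planted_baseline: float | None = None,
) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    """A two-group NB count matrix at the generator's expression defaults,
    with an optional minority of planted fold-change features in group B.

    Returns ``(counts, group_a, group_b, planted_ids)``; with ``n_planted=0``
    the matrix is a pure null.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng([seed, 97])
    mu = np.exp(
        rng.normal(cfg.log_mean_expression, cfg.log_sd_expression, n_features)
    )
    planted = np.zeros(n_features, dtype=bool)
    if n_planted:
        planted[rng.choice(n_features, size=n_planted, replace=False)] = True
        floor = min_planted_baseline or cfg.min_planted_baseline
        low = planted & (mu < floor)
        while low.any():
            mu[low] = np.exp(
                rng.normal(cfg.log_mean_expression, cfg.log_sd_expression, low.sum())
            )
            low = planted & (mu < floor)
    group_a = [f"A{i + 1}" for i in range(n_replicates)]
    group_b = [f"B{i + 1}" for i in range(n_replicates)]
    sf = np.exp(rng.normal(0.0, 0.2, 2 * n_replicates))
    fc = np.where(planted, fold_change, 1.0)
    cols = {}
    for j, s in enumerate(group_a + group_b):
        mean = mu * (fc if j >= n_replicates else 1.0) * sf[j]
        cols[s] = _nb(rng, mean, cfg.nb_dispersion)
    ids = [f"f{i}" for i in range(n_features)]
    counts = pd.DataFrame(cols, index=ids)
    planted_ids = [ids[i] for i in np.flatnonzero(planted)]
    return counts, group_a, group_b, planted_ids


def simulate_dmr_tables(
    seed: int,
    n_background: int = 300,
    depth: int = 30,
    planted_cpgs: int = 5,
    mean_a: float = 0.80,
    mean_b: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two pooled call tables with one planted differential region.

    Background CpGs (spaced 400 bp, methylation 50% in both conditions)
    surround a run of ``planted_cpgs`` CpGs 50 bp apart at ``mean_a`` versus
    ``mean_b``. Returns the two tables and the planted region's coordinates.
    """
    rng = np.random.default_rng([seed, 98])
    bg_pos = np.arange(n_background) * 400
    planted_start = int(bg_pos[-1] + 2000)
    planted_pos = planted_start + np.arange(planted_cpgs) * 50
    pos = np.concatenate([bg_pos, planted_pos])
    means_a = np.concatenate([np.full(n_background, 0.5), np.full(planted_cpgs, mean_a)])
    means_b = np.concatenate([np.full(n_background, 0.5), np.full(planted_cpgs, mean_b)])
    tables = []
    for means in (means_a, means_b):
        n_meth = rng.binomial(depth, means)
        tables.append(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": pos,
                    "depth": depth,
                    "n_meth": n_meth,
                    "pct_meth": 100.0 * n_meth / depth,
                }
            ).sort_values("start").reset_index(drop=True)
        )
    region = {
        "chrom": "chr1",
        "start": int(planted_pos[0]),
        "end": int(planted_pos[-1]) + 2,
    }
    return tables[0], tables[1], region


# ---------------------------------------------------------------------------
# Strand-resolved coverage around LTR elements

def simulate_strand_coverage(
    config: SimConfig, annotation: Annotation, family: str = "IAPLTR1_Mm",
    genotype: str = "Dnmt1KO",
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Synthetic per-strand RNA coverage with sense-dominant transcription
    initiating at the starts of a derepressed LTR family.

    In the affected genotype each element drives a strong sense-strand signal
    downstream of its start and a weaker antisense signal; elsewhere both
    strands carry low noise.
    """
    rng = config.rng("coverage")
    sizes = annotation.chrom_sizes
    fwd = {c: rng.gamma(2.0, 0.25, n).astype(np.float32) for c, n in sizes.items()}
    rev = {c: rng.gamma(2.0, 0.25, n).astype(np.float32) for c, n in sizes.items()}
    active = genotype in ("Dnmt1KO", "DKO")
    copies = annotation.tes[annotation.tes["family"] == family]
    for row in copies.itertuples(index=False):
        n = sizes[row.chrom]
        if row.strand == "+":
            lo, hi = row.start, min(row.start + 3000, n)
            sense, anti = fwd, rev
            alo, ahi = max(row.start - 1500, 0), min(row.start + 500, n)
        else:
            lo, hi = max(row.end - 3000, 0), row.end
            sense, anti = rev, fwd
            alo, ahi = max(row.end - 500, 0), min(row.end + 1500, n)
        if active:
            sense[row.chrom][lo:hi] += 8.0
            anti[row.chrom][alo:ahi] += 2.0
    return fwd, rev


# ---------------------------------------------------------------------------
# Full bundle and disk output

def simulate_all(config: SimConfig, outdir: str | Path | None = None):
    """Run annotation, methylome and count simulation; optionally write every
    artifact (FASTA/GTF/BED/TSV/JSON) under ``outdir``."""
    annotation = simulate_annotation(config)
    methylomes = simulate_methylome(config, annotation)
    counts = simulate_counts(config, annotation)
    if outdir is not None:
        write_bundle(config, annotation, methylomes, counts, Path(outdir))
    return annotation, methylomes, counts


def write_bundle(config: SimConfig, annotation: Annotation, methylomes, counts,
                 outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    genome_io.write_fasta(annotation.genome, outdir / "genome.fa")
    genome_io.write_gtf(annotation.transcripts, outdir / "transcripts.gtf")
    genome_io.write_bed(annotation.cgis, outdir / "cgis.bed")
    genome_io.write_bed(annotation.gdmrs, outdir / "gdmrs.bed")
    genome_io.write_repeatmasker(annotation.tes, outdir / "repeatmasker.tsv")
    for (genotype, rep), table in methylomes.items():
        genome_io.write_methylation_calls(
            table, outdir / f"calls_{genotype}_{rep}.cov"
        )
    genome_io.write_count_matrix(counts.gene_counts, outdir / "gene_counts.tsv")
    exon = counts.exon_counts.reset_index()
    exon.insert(2, "length", counts.exon_lengths.to_numpy())
    exon.to_csv(outdir / "exon_counts.tsv", sep="\t", index=False)
    genome_io.write_count_matrix(counts.te_copy_counts, outdir / "te_copy_counts.tsv")
    for sample, aln in counts.alignments.items():
        genome_io.write_alignment_table(aln, outdir / f"alignments_{sample}.tsv")
    counts.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth = {**counts.ground_truth, "seed": config.seed}
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, default=_json_default)
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
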