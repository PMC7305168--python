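"""End-to-end orchestration: load inputs, run every analysis stage in order,
write tables and a machine-readable manifest.

The stage order mirrors the study design: methylome summaries first
(global levels, window classes, correlations, gDMRs, de novo windows, DMRs),
then promoter classification and gene/exon/TE differential expression, then
the derived analyses (promoter groups of upregulated genes, cryptic
intragenic initiation, TE copy summaries, ERV-proximal gene effects). All
thresholds are configuration defaults, never hard-coded in stage logic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cryptic, diffexpr, genome_io, methylome, promoters, te

logger = logging.getLogger("methtx.pipeline")


@dataclass
class Thresholds:
    min_depth: int = 5
    window_size: int = 1000
    min_cpgs: int = 3
    corr_window_size: int = 1000
    gene_policy: str = "genes"
    exon_policy: str = "exons"
    te_family_policy: str = "te_families"
    te_copy_policy: str = "te_copies"
    group_meth_threshold: float = 30.0
    erv_distance: int = 20_000


@dataclass
class PipelineConfig:
    """Paths, the sample sheet and thresholds for a pipeline run."""

    genome: str
    gtf: str
    cgi_bed: str
    gdmr_bed: str
    te_tsv: str
    gene_counts: str
    exon_counts: str
    te_copy_counts: str
    sample_sheet: str
    calls: dict  # genotype -> list of call-table paths (bismark_cov dialect)
    alignments: dict = field(default_factory=dict)  # sample -> path
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def validate(self) -> None:
        for name in ("genome", "gtf", "cgi_bed", "gdmr_bed", "te_tsv",
                     "gene_counts", "exon_counts", "te_copy_counts",
                     "sample_sheet"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"pipeline input {name} missing: {p}")
        for genotype, paths in self.calls.items():
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(
                        f"call table for {genotype} missing: {p}"
                    )


def _stage(name: str, t0: list):
    logger.info("stage %s (%.1fs elapsed)", name, time.perf_counter() - t0[0])


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write results plus a manifest under ``outdir``.

    Deterministic given the configuration and seed. Stage failures propagate
    with the stage name attached.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = [time.perf_counter()]
    bundle: dict = {}
    stage = "load"
    try:
        genome = genome_io.read_fasta(config.genome)
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        transcripts = genome_io.read_gtf(config.gtf)
        cgis = genome_io.read_bed(config.cgi_bed)
        gdmrs = genome_io.read_bed(config.gdmr_bed)
        tes = genome_io.read_repeatmasker(config.te_tsv)
        samples = pd.read_csv(config.sample_sheet, sep="\t")
        gene_counts = genome_io.read_count_matrix(config.gene_counts)
        exon_raw = pd.read_csv(config.exon_counts, sep="\t")
        exon_lengths = pd.Series(
            exon_raw["length"].to_numpy(),
            index=pd.MultiIndex.from_frame(exon_raw[["transcript_id", "exon_index"]]),
        )
        exon_counts = exon_raw.drop(columns="length").set_index(
            ["transcript_id", "exon_index"]
        )
        te_copy_counts = genome_io.read_count_matrix(config.te_copy_counts)
        missing = set(samples["sample"]) - set(gene_counts.columns)
        if missing:
            raise ValueError(f"samples absent from count matrix: {sorted(missing)}")
        thr = config.thresholds

        stage = "methylome"
        _stage(stage, t0)
        pooled = {
            genotype: methylome.pool_replicates(
                [
                    genome_io.read_methylation_calls(p, "bismark_cov", thr.min_depth)
                    for p in paths
                ]
            )
            for genotype, paths in config.calls.items()
        }
        global_meth = pd.DataFrame(
            [
                {
                    "genotype": g,
                    "global_mean_pct": float(calls["pct_meth"].mean()),
                    "n_cpgs": len(calls),
                }
                for g, calls in pooled.items()
            ]
        )
        windows = {
            g: methylome.window_methylation(calls, chrom_sizes, thr.window_size, thr.min_cpgs)
            for g, calls in pooled.items()
        }
        window_classes = pd.DataFrame(
            {g: methylome.classify_windows(w) for g, w in windows.items()}
        )
        bundle["global_meth"] = global_meth
        bundle["window_classes"] = window_classes
        if "DKO" in pooled and "ICM" in pooled:
            bundle["dko_icm_r"] = methylome.methylation_correlation(
                windows["DKO"], windows["ICM"]
            )
        if "ICM" in pooled and "WT" in pooled:
            bundle["de_novo_windows"] = methylome.select_de_novo_windows(
                windows["ICM"], windows["WT"]
            )
        bundle["gdmr_scores"] = methylome.score_gdmrs(pooled, gdmrs)
        if "WT" in pooled and "Dnmt1KO" in pooled:
            bundle["dmrs_wt_dnmt1ko"] = methylome.call_dmrs(
                pooled["WT"], pooled["Dnmt1KO"]
            )
        one_per_gene: dict[str, object] = {}
        for t in transcripts:
            cur = one_per_gene.get(t.gene_id)
            if cur is None or t.length > cur.length:
                one_per_gene[t.gene_id] = t
        primaries = list(one_per_gene.values())
        bundle["gene_metaplot_wt"] = methylome.gene_metaplot(pooled["WT"], primaries)

        stage = "promoters"
        _stage(stage, t0)
        prom = promoters.classify_promoters(genome, primaries)
        prom = prom.set_index("gene_id")
        prom_meth_iv = pd.DataFrame(
            [
                dict(zip(("chrom", "start", "end"), promoters.promoter_interval(t, 1000, 500)),
                     gene_id=t.gene_id)
                for t in primaries
            ]
        )
        pm = methylome.feature_methylation(pooled["WT"], prom_meth_iv)
        prom_meth = pm.set_index("gene_id")["mean_pct"]
        bundle["promoter_classes"] = prom

        stage = "gene_de"
        _stage(stage, t0)
        groups = {
            g: samples.loc[samples["genotype"] == g, "sample"].tolist()
            for g in samples["genotype"].unique()
        }
        de = {}
        for mutant in ("Dnmt1KO", "DKO"):
            if mutant not in groups or "WT" not in groups:
                continue
            res = diffexpr.nb_wald_test(gene_counts, groups["WT"], groups[mutant])
            res = diffexpr.call_de(res, thr.gene_policy)
            fp = diffexpr.fpkm(
                gene_counts[groups["WT"] + groups[mutant]],
                pd.Series(
                    {t.gene_id: t.length for t in primaries}
                ).reindex(gene_counts.index),
                groups={"WT": groups["WT"], mutant: groups[mutant]},
            )
            res["fpkm_wt"] = fp["fpkm_WT"]
            res[f"fpkm_{mutant.lower()}"] = fp[f"fpkm_{mutant}"]
            de[mutant] = res
            bundle[f"gene_de_{mutant.lower()}"] = res
        if "DKO" in de:
            up = de["DKO"].index[de["DKO"]["up"]].tolist()
            bundle["gene_groups_dko"] = promoters.assign_groups(
                up, prom["cls"], prom_meth, thr.group_meth_threshold
            )

        stage = "exon_de"
        _stage(stage, t0)
        if "DKO" in groups:
            exon_res = diffexpr.nb_wald_test(exon_counts, groups["WT"], groups["DKO"])
            exon_fp = diffexpr.fpkm(
                exon_counts[groups["WT"] + groups["DKO"]],
                exon_lengths,
                groups={"a": groups["WT"], "b": groups["DKO"]},
            )
            exon_res["fpkm_a"] = exon_fp["fpkm_a"]
            exon_res["fpkm_b"] = exon_fp["fpkm_b"]
            exon_res = diffexpr.call_de(exon_res, thr.exon_policy)
            exon_de = exon_res.reset_index()
            bundle["exon_de_dko"] = exon_de
            calls_df, trace = cryptic.call_cryptic_initiation(
                exon_de, transcripts, tes
            )
            bundle["cryptic_calls"] = calls_df
            bundle["cryptic_trace"] = trace
            ratio_fpkm = exon_fp[["fpkm_a", "fpkm_b"]].rename(
                columns={"fpkm_a": "WT", "fpkm_b": "DKO"}
            )
            bundle["exon_ratio"] = cryptic.exon_ratio_profile(
                ratio_fpkm, transcripts, ["WT", "DKO"]
            )
            if len(calls_df):
                bundle["cryptic_site_report"] = cryptic.cryptic_site_report(
                    calls_df, {"WT": pooled["WT"]}, genome, transcripts
                )

        stage = "te"
        _stage(stage, t0)
        # depth normalization for TE matrices comes from the gene counts:
        # median-of-ratios within a small family/copy matrix is dominated by
        # the reactivated families themselves
        gene_factors = diffexpr.size_factors(gene_counts)
        if config.alignments:
            aln = {
                s: genome_io.read_alignment_table(p)
                for s, p in config.alignments.items()
            }
            fam_counts = te.family_count_matrix(aln, tes)
            bundle["te_family_counts"] = fam_counts
            tested = fam_counts.drop(index="unassigned", errors="ignore")
            if "Dnmt1KO" in groups:
                fam_res = diffexpr.nb_wald_test(
                    tested.round().astype(int), groups["WT"], groups["Dnmt1KO"],
                    factors=gene_factors,
                )
                bundle["te_family_de_dnmt1ko"] = diffexpr.call_de(
                    fam_res, thr.te_family_policy
                )
        if "Dnmt1KO" in groups:
            copy_res = diffexpr.nb_wald_test(
                te_copy_counts, groups["WT"], groups["Dnmt1KO"],
                factors=gene_factors,
            )
            copy_res = diffexpr.call_de(copy_res, thr.te_copy_policy)
            bundle["te_copy_de_dnmt1ko"] = copy_res
            bundle["copy_up_summary"] = te.copy_up_summary(copy_res, tes)
            up_ids = copy_res.index[copy_res["up"]]
            up_ervs = tes[
                tes["copy_id"].isin(up_ids)
                & tes["te_class"].isin(te.ERV_CLASSES)
            ]
            if "Dnmt1KO" in de:
                prox = te.erv_proximal_genes(
                    up_ervs, transcripts, de["Dnmt1KO"], tes, seed=config.seed,
                    max_distance=thr.erv_distance,
                )
                bundle["erv_proximal"] = prox["summary"]
                bundle["erv_proximal_wilcoxon_p"] = prox["wilcoxon_p"]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_bundle(bundle, outdir)
    manifest = _manifest(config, bundle)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.tsv", sep="\t")
        elif isinstance(obj, dict):
            for sub, df in obj.items():
                if isinstance(df, pd.DataFrame):
                    df.to_csv(outdir / f"{name}_{sub}.tsv", sep="\t")
    scalars = {
        k: float(v) for k, v in bundle.items() if isinstance(v, (int, float, np.floating))
    }
    (outdir / "scalars.json").write_text(json.dumps(scalars, indent=1, sort_keys=True))


def _manifest(config: PipelineConfig, bundle: dict) -> dict:
    from . import __version__

    def digest(path: str) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()[:16]

    inputs = {}
    for name in ("genome", "gtf", "cgi_bed", "gdmr_bed", "te_tsv", "gene_counts",
                 "exon_counts", "te_copy_counts", "sample_sheet"):
        inputs[name] = digest(getattr(config, name))
    for genotype, paths in config.calls.items():
        for i, p in enumerate(paths):
            inputs[f"calls_{genotype}_{i}"] = digest(p)
    return {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "inputs": inputs,
        "outputs": sorted(bundle.keys()),
    }


def config_for_bundle(simdir: str | Path, seed: int = 0) -> PipelineConfig:
    """Pipeline configuration pointing at a directory written by
    :func:`methtx.simulate.write_bundle`."""
    simdir = Path(simdir)
    calls: dict[str, list[str]] = {}
    for p in sorted(simdir.glob("calls_*.cov")):
        genotype = p.stem.split("_")[1]
        calls.setdefault(genotype, []).append(str(p))
    alignments = {
        p.stem.replace("alignments_", ""): str(p)
        for p in sorted(simdir.glob("alignments_*.tsv"))
    }
    return PipelineConfig(
        genome=str(simdir / "genome.fa"),
        gtf=str(simdir / "transcripts.gtf"),
        cgi_bed=str(simdir / "cgis.bed"),
        gdmr_bed=str(simdir / "gdmrs.bed"),
        te_tsv=str(simdir / "repeatmasker.tsv"),
        gene_counts=str(simdir / "gene_counts.tsv"),
        exon_counts=str(simdir / "exon_counts.tsv"),
        te_copy_counts=str(simdir / "te_copy_counts.tsv"),
        sample_sheet=str(simdir / "samples.tsv"),
        calls=calls,
        alignments=alignments,
        seed=seed,
    )
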