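"""Transposable elements: fractional family counts from the alignment table,
family- and copy-level differential expression in Dnmt1KO, the percentage of
upregulated copies per family with the up/not-up size comparison, effects on
ERV-proximal genes, and the strand-resolved metaplot around IAPLTR1_Mm
element starts."""

import json

import pandas as pd

from common import OUT, SIM, load_alignments, load_annotation, load_counts

from methtx import diffexpr, genome_io, simulate, te


def main() -> None:
    genome, transcripts, _, _, tes = load_annotation()
    _, _, _, te_copy_counts, _, groups = load_counts()
    truth = json.loads((SIM / "ground_truth.json").read_text())

    gene_counts = genome_io.read_count_matrix(SIM / "gene_counts.tsv")
    # depth normalization for TE matrices from the gene counts: within the
    # small family/copy matrices the reactivated families dominate the library
    gene_factors = diffexpr.size_factors(gene_counts)

    aln = load_alignments()
    fam_counts = te.family_count_matrix(aln, tes)
    fam_counts.to_csv(OUT / "te_family_counts.tsv", sep="\t")
    tested = fam_counts.drop(index="unassigned", errors="ignore").round().astype(int)
    fam_de = diffexpr.call_de(
        diffexpr.nb_wald_test(tested, groups["WT"], groups["Dnmt1KO"],
                              factors=gene_factors),
        "te_families",
    )
    fam_de.to_csv(OUT / "te_family_de_dnmt1ko.tsv", sep="\t")
    up_fams = fam_de.index[fam_de["up"]].tolist()
    print(f"TE families up in Dnmt1KO (fc > 2, adj p < 0.001): {up_fams}")

    copy_de = diffexpr.call_de(
        diffexpr.nb_wald_test(te_copy_counts, groups["WT"], groups["Dnmt1KO"],
                              factors=gene_factors),
        "te_copies",
    )
    summary = te.copy_up_summary(copy_de, tes)
    summary.to_csv(OUT / "te_copy_up_summary.tsv", sep="\t", index=False)
    print("\nper-family percentage of upregulated copies (size test p):")
    show = summary[summary["n_up"] > 0]
    print(show[["family", "n_copies", "n_up", "pct_up", "size_p"]]
          .round(4).to_string(index=False))

    gene_de = diffexpr.nb_wald_test(gene_counts, groups["WT"], groups["Dnmt1KO"])
    up_ids = copy_de.index[copy_de["up"]]
    up_ervs = tes[tes["copy_id"].isin(up_ids) & tes["te_class"].isin(te.ERV_CLASSES)]
    prox = te.erv_proximal_genes(
        up_ervs, transcripts, gene_de, tes, seed=truth["seed"]
    )
    prox["summary"].to_csv(OUT / "erv_proximal_genes.tsv", sep="\t", index=False)
    print("\ngenes near upregulated ERVs (<20 kb from TSS):")
    print(prox["summary"].round(3).to_string(index=False))
    print(f"proximal vs random control Wilcoxon p = {prox['wilcoxon_p']:.2e}")

    cfg = simulate.SimConfig(seed=truth["seed"])
    ann = simulate.simulate_annotation(cfg)
    fwd, rev = simulate.simulate_strand_coverage(cfg, ann)
    prof = te.ltr_strand_metaplot(fwd, rev, tes, "IAPLTR1_Mm")
    pd.DataFrame(
        {"bin": prof["bin"], "sense": prof["sense_mean"],
         "antisense": prof["antisense_mean"]}
    ).to_csv(OUT / "iapltr1_strand_metaplot.tsv", sep="\t", index=False)
    print(f"\nIAPLTR1_Mm metaplot over {len(prof['elements'])} merged elements: "
          f"sense peak {prof['sense_mean'].max():.1f} vs antisense "
          f"{prof['antisense_mean'].max():.1f}")


if __name__ == "__main__":
    main()
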