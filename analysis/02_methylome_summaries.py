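"""Methylome summaries across genotypes: global levels, 1 kb window classes,
the DKO-versus-ICM correlation, windows de novo methylated at implantation,
imprinted gDMR scores, a WT gene-body metaplot, and WT-versus-Dnmt1KO DMRs.

Expected structure: near-complete hypomethylation in Dnmt1KO (maintenance
lost everywhere, gDMRs included); DKO methylation mirrors the ICM track
(maintenance without acquisition) with retained high methylation at young TE
families; de novo windows low in ICM/DKO and high in WT.
"""

import pandas as pd

from common import OUT, load_annotation, load_pooled_calls

from methtx import methylome


def main() -> None:
    genome, transcripts, cgis, gdmrs, tes = load_annotation()
    sizes = {c: len(s) for c, s in genome.items()}
    pooled = load_pooled_calls()

    rows = []
    windows = {}
    for genotype, calls in pooled.items():
        windows[genotype] = methylome.window_methylation(calls, sizes)
        props = methylome.classify_windows(windows[genotype])
        rows.append(
            {
                "genotype": genotype,
                "global_mean_pct": calls["pct_meth"].mean(),
                "n_cpgs": len(calls),
                **{f"windows_{k}": v for k, v in props.items()},
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "methylome_summary.tsv", sep="\t", index=False)
    print(summary.round(3).to_string(index=False))

    r = methylome.methylation_correlation(windows["DKO"], windows["ICM"])
    print(f"\nDKO vs ICM window correlation: r = {r:.3f} "
          "(maintenance-only methylation tracks the preimplantation state)")

    de_novo = methylome.select_de_novo_windows(windows["ICM"], windows["WT"])
    de_novo.to_csv(OUT / "de_novo_windows.tsv", sep="\t", index=False)
    print(f"windows de novo methylated at implantation (<5% ICM, >50% WT): "
          f"{len(de_novo)}")

    gdmr_scores = methylome.score_gdmrs(pooled, gdmrs)
    gdmr_scores.to_csv(OUT / "gdmr_scores.tsv", sep="\t", index=False)
    print("\nimprinted gDMR mean methylation (%):")
    print(gdmr_scores[["WT", "Dnmt1KO", "DKO", "ICM"]].mean().round(2).to_string())

    genes = {}
    for t in transcripts:
        cur = genes.get(t.gene_id)
        if cur is None or t.length > cur.length:
            genes[t.gene_id] = t
    meta = methylome.gene_metaplot(pooled["WT"], list(genes.values()))
    meta.to_csv(OUT / "gene_metaplot_wt.tsv", sep="\t", index=False)

    dmrs = methylome.call_dmrs(pooled["WT"], pooled["Dnmt1KO"])
    dmrs.to_csv(OUT / "dmrs_wt_vs_dnmt1ko.tsv", sep="\t", index=False)
    print(f"\nWT vs Dnmt1KO DMRs (>=3 DMCs, |diff| > 20%, adj p < 0.001): "
          f"{len(dmrs)} — hypomethylation is genome-wide")


if __name__ == "__main__":
    main()
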