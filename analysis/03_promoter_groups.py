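"""Promoter CpG classes from sequence and the three-group classification of
genes upregulated in DKO embryos: group 1 (LCP), group 2 (CpG-rich,
unmethylated in WT), group 3 (CpG-rich, methylated in WT — the
germline-gene signature).
"""

import pandas as pd

from common import OUT, load_annotation, load_counts, load_pooled_calls

from methtx import diffexpr, methylome, promoters


def main() -> None:
    genome, transcripts, *_ = load_annotation()
    pooled = load_pooled_calls()
    gene_counts, _, _, _, _, groups = load_counts()

    primaries = {}
    for t in transcripts:
        cur = primaries.get(t.gene_id)
        if cur is None or t.length > cur.length:
            primaries[t.gene_id] = t
    prim = list(primaries.values())

    classes = promoters.classify_promoters(genome, prim).set_index("gene_id")
    classes.to_csv(OUT / "promoter_classes.tsv", sep="\t")
    print("promoter classes:", classes["cls"].value_counts().to_dict())

    meth_iv = pd.DataFrame(
        [
            dict(
                zip(("chrom", "start", "end"),
                    promoters.promoter_interval(t, 1000, 500)),
                gene_id=t.gene_id,
            )
            for t in prim
        ]
    )
    pm = methylome.feature_methylation(pooled["WT"], meth_iv)
    prom_meth = pm.set_index("gene_id")["mean_pct"]

    de = diffexpr.call_de(
        diffexpr.nb_wald_test(gene_counts, groups["WT"], groups["DKO"]), "genes"
    )
    up = de.index[de["up"]].tolist()
    grp = promoters.assign_groups(up, classes["cls"], prom_meth)
    grp.to_csv(OUT / "gene_groups_dko.tsv", sep="\t", index=False)
    print(f"\n{len(up)} genes upregulated in DKO; groups:")
    print(grp["group"].value_counts(dropna=False).sort_index().to_string())
    g3 = grp[grp["group"] == 3]
    print(f"group 3 (methylated CpG-rich promoters): {len(g3)} genes, "
          f"mean WT promoter methylation "
          f"{g3['promoter_meth_wt'].mean():.1f}%")


if __name__ == "__main__":
    main()
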