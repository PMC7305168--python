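"""Generate the synthetic study: a two-chromosome genome with 300 genes,
eleven TE families, CpG islands, imprinted gDMRs, per-genotype methylomes
(WT, Dnmt1KO, DKO, ICM; two replicates each) and RNA count matrices with
planted derepression, reactivated TE copies and cryptic-initiation events.

Writes everything (FASTA/GTF/BED/TSV plus the ground-truth sidecar) under
results/sim.
"""

import argparse

from common import SIM

from methtx import simulate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    cfg = simulate.SimConfig(seed=args.seed)
    ann, methylomes, counts = simulate.simulate_all(cfg, SIM)
    truth = counts.ground_truth
    print(f"wrote simulated study to {SIM}")
    print(f"  genes: {len(ann.gene_table)}, transcripts: {len(ann.transcripts)}, "
          f"TE copies: {len(ann.tes)}")
    print(f"  planted: {len(truth['germline_genes'])} germline-like, "
          f"{len(truth['twocell_genes'])} 2C-like, "
          f"{len(truth['cryptic_genes'])} cryptic-initiation, "
          f"{len(truth['reactivated_te_copies'])} reactivated TE copies, "
          f"{len(truth['de_novo_windows'])} de novo windows")


if __name__ == "__main__":
    main()
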