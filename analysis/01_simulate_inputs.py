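#!/usr/bin/env python
"""Simulate every input the downstream analyses need, with ground truth.

Writes small text inputs (gene table, count matrices, neuron traces, truth
tables) under results/data/.  The per-base coverage tracks are large, so they
go to scratch/data/ as bedGraph; every later step can also regenerate them
deterministically from the same seed.
"""

import argparse
from pathlib import Path

import numpy as np

from pausescape.core_io import write_bedgraph, write_count_matrix, write_gene_table, write_swc
from pausescape.synthetic import (
    SimulationConfig,
    generate_gene_models,
    simulate_chd7_track,
    simulate_count_experiment,
    simulate_neuron_trace,
    simulate_polii_track,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/data"))
parser.add_argument("--scratch", type=Path, default=Path("scratch/data"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)
args.scratch.mkdir(parents=True, exist_ok=True)

# gene universe + pausing tracks (two CHD7 groups, pausing indices 1.5 / 6)
cfg = SimulationConfig(n_genes=1000, seed=args.seed, fpkm_lognorm=(1.5, 0.3))
genes = generate_gene_models(cfg)
write_gene_table(genes, args.outdir / "genes.tsv")
groups = ["high_chd7" if i < 500 else "low_chd7" for i in range(len(genes))]
rnapii, truth = simulate_polii_track(genes, cfg, groups=groups)
chd7 = simulate_chd7_track(genes, [cfg.chd7_levels[g] for g in groups], seed=args.seed + 1)
truth.to_csv(args.outdir / "pausing_truth.tsv", sep="\t", index=False)
write_bedgraph(rnapii, args.scratch / "rnapii.bedgraph")
write_bedgraph(chd7, args.scratch / "chd7.bedgraph")
print(f"wrote {len(genes)} genes; RNAPII track {rnapii.total_reads:,} reads; "
      f"CHD7 track {chd7.total_reads:,} reads")

# linked ATAC / nascent-expression counts, 3 replicates per genotype
ccfg = SimulationConfig(n_genes=2000, seed=args.seed + 2, effect_fraction=0.3)
cgenes = generate_gene_models(ccfg)
write_gene_table(cgenes, args.outdir / "count_genes.tsv")
atac, bru, ctruth = simulate_count_experiment(cgenes, ccfg)
write_count_matrix(atac, args.outdir / "atac_counts.tsv", args.outdir / "atac_design.tsv")
write_count_matrix(bru, args.outdir / "bru_counts.tsv", args.outdir / "bru_design.tsv")
ctruth.to_csv(args.outdir / "counts_truth.tsv", sep="\t", index=False)
n_eff = int(ctruth["affected"].sum())
print(f"wrote count matrices: {len(cgenes)} genes x 6 samples, {n_eff} with true shared-sign effects")

# traced neurons, 20 per genotype (wt branchier than ko)
swc_dir = args.outdir / "traces"
swc_dir.mkdir(exist_ok=True)
rows = []
for label, sub_seed, branch_prob in (("wt", args.seed + 4, 0.6), ("ko", args.seed + 5, 0.2)):
    rng = np.random.default_rng(sub_seed)
    ncfg = SimulationConfig(seed=sub_seed, branch_prob=branch_prob)
    for i in range(20):
        trace, t = simulate_neuron_trace(ncfg, rng)
        write_swc(trace, swc_dir / f"{label}_{i:02d}.swc")
        rows.append((f"{label}_{i:02d}", label, t.n_primary, t.n_branch_points,
                     t.total_length_um, t.longest_neurite_um))
with open(args.outdir / "neuron_truth.tsv", "w") as fh:
    fh.write("neuron\tgenotype\tn_primary\tn_branch_points\ttotal_length_um\tlongest_neurite_um\n")
    for r in rows:
        fh.write("\t".join(str(v) for v in r) + "\n")
print(f"wrote {len(rows)} traced neurons to {swc_dir}")
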