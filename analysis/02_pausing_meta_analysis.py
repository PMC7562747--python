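#!/usr/bin/env python
"""RNAPII pausing-index meta-analysis over CHD7-ranked genes.

Runs the full pipeline (expression filter -> RNAPII-bound filter -> CHD7
ranking -> pausing indices -> 150-bin metagene profiles -> Wilcoxon
comparison) on three independently simulated RNAPII tracks, mirroring a
meta-analysis over three ChIP-Seq datasets, and averages the bin profiles.

Writes pausing_records.tsv, metagene_profile.tsv and group_test.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pausescape.pausing import PausingConfig, run_pausing_pipeline
from pausescape.synthetic import (
    SimulationConfig,
    generate_gene_models,
    simulate_chd7_track,
    simulate_polii_track,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/pausing"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(n_genes=1000, seed=args.seed, fpkm_lognorm=(1.5, 0.3))
genes = generate_gene_models(cfg)
groups = ["high_chd7" if i < 500 else "low_chd7" for i in range(len(genes))]
chd7 = simulate_chd7_track(genes, [cfg.chd7_levels[g] for g in groups], seed=args.seed + 1)
pcfg = PausingConfig()

all_records, tests = [], []
profiles_high, profiles_low = [], []
for k in range(3):  # three RNAPII datasets
    track_cfg = SimulationConfig(n_genes=1000, seed=args.seed + 10 * (k + 1), fpkm_lognorm=(1.5, 0.3))
    rnapii, _ = simulate_polii_track(genes, track_cfg, groups=groups, label=f"rnapii_{k+1}")
    res = run_pausing_pipeline(genes, rnapii, chd7, pcfg)
    df = res.to_frame()
    df.insert(0, "dataset", f"rnapii_{k+1}")
    all_records.append(df)
    profiles_high.append(res.profile_high)
    profiles_low.append(res.profile_low)
    t = res.group_test
    tests.append(
        {
            "dataset": f"rnapii_{k+1}",
            "n_expressed": res.n_expressed,
            "n_rnapii_bound": res.n_rnapii_bound,
            "median_pi_high_chd7": t.extra["median_high_chd7"],
            "median_pi_low_chd7": t.extra["median_low_chd7"],
            "wilcoxon_statistic": t.statistic,
            "wilcoxon_p": t.p,
        }
    )
    print(
        f"{tests[-1]['dataset']}: {res.n_rnapii_bound} RNAPII-bound genes; median pausing index "
        f"{t.extra['median_high_chd7']:.2f} (high CHD7) vs {t.extra['median_low_chd7']:.2f} "
        f"(low CHD7), Wilcoxon p = {t.p:.3g}"
    )

pd.concat(all_records).to_csv(args.outdir / "pausing_records.tsv", sep="\t", index=False)
pd.DataFrame(tests).to_csv(args.outdir / "group_test.tsv", sep="\t", index=False)

profile = pd.DataFrame(
    {
        "bin": np.arange(1, pcfg.n_bins + 1),
        "high_chd7_mean": np.mean(profiles_high, axis=0),
        "low_chd7_mean": np.mean(profiles_low, axis=0),
    }
)
profile.to_csv(args.outdir / "metagene_profile.tsv", sep="\t", index=False)
tss_bins = slice(0, 5)
print(
    "meta profile near the TSS (first 5 bins, mean-normalized coverage): "
    f"high CHD7 {profile['high_chd7_mean'][tss_bins].mean():.2f} vs "
    f"low CHD7 {profile['low_chd7_mean'][tss_bins].mean():.2f} "
    "- the low-CHD7 group shows the stronger promoter-proximal peak"
)
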