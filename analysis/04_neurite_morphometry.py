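#!/usr/bin/env python
"""Sholl analysis and neurite morphometry of simulated genotype groups.

Simulates 20 traced neurons per genotype (wild-type branchier than knockout),
computes per-neuron Sholl profiles and scalar metrics, and compares groups
with unpaired t-tests (scalar metrics) and a two-way genotype x radius ANOVA
(Sholl curves).

Writes sholl_profiles.tsv, morphometry_summary.tsv and tests.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pausescape.morphometry import (
    compare_morphometrics,
    neurite_metrics,
    sholl_anova,
    sholl_profile,
)
from pausescape.synthetic import SimulationConfig, simulate_neuron_trace

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/morphometry"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

traces = {}
for label, sub_seed, branch_prob in (("wt", args.seed + 4, 0.6), ("ko", args.seed + 5, 0.2)):
    rng = np.random.default_rng(sub_seed)
    cfg = SimulationConfig(seed=sub_seed, branch_prob=branch_prob)
    traces[label] = [simulate_neuron_trace(cfg, rng)[0] for _ in range(20)]

profiles = {g: [sholl_profile(t, 10.0) for t in ts] for g, ts in traces.items()}
summaries = {g: [neurite_metrics(t) for t in ts] for g, ts in traces.items()}

rows = []
for g, plist in profiles.items():
    for i, p in enumerate(plist):
        for r, c in zip(p.radii, p.crossings):
            rows.append((f"{g}_{i:02d}", g, r, c))
pd.DataFrame(rows, columns=["neuron", "genotype", "radius_um", "crossings"]).to_csv(
    args.outdir / "sholl_profiles.tsv", sep="\t", index=False
)

summary = pd.DataFrame(
    [
        {"neuron": f"{g}_{i:02d}", "genotype": g, **vars(s)}
        for g, slist in summaries.items()
        for i, s in enumerate(slist)
    ]
)
summary.to_csv(args.outdir / "morphometry_summary.tsv", sep="\t", index=False)
means = summary.groupby("genotype")[["total_length_um", "longest_neurite_um", "n_primary", "n_branch_points"]].mean()
print("genotype means:\n", means.round(2))

tests = compare_morphometrics(summaries["wt"], summaries["ko"])
anova = sholl_anova(profiles["wt"], profiles["ko"], n_radii=8)
test_rows = [
    {"comparison": metric, "method": r.method, "statistic": r.statistic, "p": r.p}
    for metric, r in tests.items()
]
for effect, r in anova.items():
    test_rows.append({"comparison": f"sholl_{effect}", "method": r.method, "statistic": r.statistic, "p": r.p})
pd.DataFrame(test_rows).to_csv(args.outdir / "tests.tsv", sep="\t", index=False)
print(
    f"total neurite length: t = {tests['total_length_um'].statistic:.2f}, "
    f"p = {tests['total_length_um'].p:.3g}; Sholl genotype effect "
    f"F = {anova['A'].statistic:.1f}, p = {anova['A'].p:.3g} "
    "- knockout neurons are shorter and less complex"
)
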