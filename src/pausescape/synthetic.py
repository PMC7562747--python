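"""Synthetic data generators with recorded ground truth.

Every generator is deterministic given its seed and emulates the statistical
structure the downstream stages assume: Poisson read starts for coverage
tracks, negative-binomial replicate counts for two genotypes x 3 replicates
with linked accessibility/expression effects, and planar binary-branching
neuron traces with known morphometrics.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    NeuronTrace,
    Peak,
    SwcNode,
)

__all__ = [
    "SimulationConfig",
    "NeuronTruth",
    "generate_gene_models",
    "simulate_polii_track",
    "simulate_chd7_track",
    "simulate_count_experiment",
    "simulate_neuron_trace",
]

MIN_GENE_GAP = 2_000  # bp between adjacent simulated genes


@dataclass
class SimulationConfig:
    """Knobs for every generator; defaults mirror the modeled study design.

    Rates are reads per base.  ``pausing_rates`` maps the CHD7 group label to
    (lambda_tss, lambda_body); their ratio is the true pausing index.  Counts
    use NB(mean mu * 2^(lfc * group), dispersion alpha) with 3 replicates per
    genotype.
    """

    n_genes: int = 1000
    chrom_sizes: dict[str, int] = field(default_factory=dict)  # empty -> auto-sized chr1
    gene_length_range: tuple[int, int] = (1_500, 4_000)
    fpkm_lognorm: tuple[float, float] = (1.5, 0.8)  # (mu, sigma) of log FPKM
    pausing_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"high_chd7": (6.0, 4.0), "low_chd7": (6.0, 1.0)}
    )
    chd7_levels: dict[str, float] = field(
        default_factory=lambda: {"high_chd7": 5.0, "low_chd7": 0.2}
    )
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    base_mean: float = 100.0
    effect_fraction: float = 0.3  # fraction of genes doubly affected
    effect_size: float = 2.0  # |log2FC| of affected genes
    branch_prob: float = 0.3
    primary_range: tuple[int, int] = (2, 4)
    segment_length_range: tuple[float, float] = (10.0, 40.0)
    max_branch_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_length_range[0] <= 750:
            raise ValueError("minimum gene length must exceed 750 bp")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be > 0")
        if not (0.0 <= self.effect_fraction <= 1.0):
            raise ValueError("effect_fraction must lie in [0, 1]")
        for group, (lam_tss, lam_body) in self.pausing_rates.items():
            if lam_tss < 0 or lam_body < 0:
                raise ValueError(f"{group}: rates must be >= 0")
            if lam_body == 0 and lam_tss > 0:
                raise ValueError(f"{group}: lambda_body = 0 makes the pausing index undefined")
        for group, level in self.chd7_levels.items():
            if level < 0:
                raise ValueError(f"{group}: occupancy level must be >= 0")
        if self.primary_range[0] < 1:
            raise ValueError("need at least one primary neurite")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent stream per generator so adding one does not shift another;
    # crc32 is stable across processes (unlike str.__hash__)
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def generate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes with >= 2 kb gaps, random strand, 1-5 exons."""
    rng = _rng(config, "genes")
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gaps = rng.integers(MIN_GENE_GAP, MIN_GENE_GAP + 3_000, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    fpkm_mu, fpkm_sigma = config.fpkm_lognorm
    fpkms = np.exp(rng.normal(fpkm_mu, fpkm_sigma, size=config.n_genes))

    if config.chrom_sizes:
        chroms = sorted(config.chrom_sizes)
        sizes = dict(config.chrom_sizes)
    else:
        needed = int(lengths.sum() + gaps.sum() + 2 * MIN_GENE_GAP)
        chroms = ["chr1"]
        sizes = {"chr1": needed}

    genes: list[GeneModel] = []
    ci = 0
    cursor = MIN_GENE_GAP
    for i in range(config.n_genes):
        length = int(lengths[i])
        while cursor + length + MIN_GENE_GAP > sizes[chroms[ci]]:
            ci += 1
            cursor = MIN_GENE_GAP
            if ci >= len(chroms):
                raise ValueError("insufficient chromosome space for requested genes")
        start = cursor
        end = start + length
        chrom = chroms[ci]
        n_exons = int(rng.integers(1, 6))
        exons = _make_exons(rng, chrom, start, end, str(strands[i]), n_exons)
        genes.append(
            GeneModel(
                f"gene{i:05d}",
                GenomicInterval(chrom, start, end, str(strands[i])),
                exons,
                float(fpkms[i]),
            )
        )
        cursor = end + int(gaps[i])
    return genes


def _make_exons(rng, chrom, start, end, strand, n_exons) -> tuple[GenomicInterval, ...]:
    length = end - start
    if n_exons == 1:
        return (GenomicInterval(chrom, start, end, strand),)
    # cut the gene into 2*n-1 alternating exon/intron blocks of >= 1 bp
    n_blocks = 2 * n_exons - 1
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_blocks - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for k in range(0, n_blocks, 2):
        exons.append(GenomicInterval(chrom, start + int(bounds[k]), start + int(bounds[k + 1]), strand))
    return tuple(exons)


def _tss_window(gene: GeneModel, upstream: int = 50, downstream: int = 200) -> GenomicInterval:
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.tss - upstream, gene.tss + downstream, "+")
    return GenomicInterval(gene.chrom, gene.tss - downstream + 1, gene.tss + upstream + 1, "-")


def simulate_polii_track(
    genes: list[GeneModel],
    config: SimulationConfig,
    groups: list[str] | None = None,
    label: str = "rnapii",
) -> tuple[CoverageTrack, pd.DataFrame]:
    """Poisson read-start track with group-specific TSS/body enrichment.

    Read starts ~ Poisson(lambda_tss) per base in the TSS window (-50..+200
    around the TSS, transcription direction) and Poisson(lambda_body) per base
    over the rest of the gene territory.  Returns the track and a truth table
    with each gene's group and expected pausing index lambda_tss/lambda_body.
    """
    rng = _rng(config, "polii")
    group_names = sorted(config.pausing_rates)
    if groups is None:
        groups = [group_names[i % len(group_names)] for i in range(len(genes))]
    if len(groups) != len(genes):
        raise ValueError("one group per gene required")

    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end + MIN_GENE_GAP)
    data = {c: np.zeros(s, dtype=np.int64) for c, s in sizes.items()}

    records = []
    for gene, group in zip(genes, groups):
        lam_tss, lam_body = config.pausing_rates[group]
        tssw = _tss_window(gene)
        arr = data[gene.chrom]
        body = gene.interval
        arr[body.start : body.end] += rng.poisson(lam_body, size=len(body))
        lo = max(tssw.start, 0)
        arr[lo : tssw.end] = rng.poisson(lam_tss, size=tssw.end - lo)
        true_pi = math.nan if lam_body == 0 else lam_tss / lam_body
        records.append({"gene_id": gene.gene_id, "group": group, "true_pausing_index": true_pi})
    return CoverageTrack(data, label=label), pd.DataFrame(records)


def simulate_chd7_track(
    genes: list[GeneModel],
    occupancy_levels,
    seed: int,
    label: str = "chd7",
) -> CoverageTrack:
    """Poisson read starts over gene bodies at the given expected reads/base."""
    levels = np.asarray(occupancy_levels, dtype=float)
    if levels.size != len(genes):
        raise ValueError("one occupancy level per gene required")
    if levels.size and levels.min() < 0:
        raise ValueError("occupancy levels must be >= 0")
    rng = np.random.default_rng(seed)
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end + MIN_GENE_GAP)
    data = {c: np.zeros(s, dtype=np.int64) for c, s in sizes.items()}
    for gene, level in zip(genes, levels):
        arr = data[gene.chrom]
        arr[gene.interval.start : gene.interval.end] += rng.poisson(level, size=gene.length)
    return CoverageTrack(data, label=label)


def _nb_draw(rng, mean: float, alpha: float, size) -> np.ndarray:
    if alpha < 1e-8:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_count_experiment(
    genes: list[GeneModel],
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Linked ATAC (promoter peak) and nascent-expression (gene) counts.

    A fraction ``effect_fraction`` of genes receives a shared-sign log2 fold
    change of magnitude ``effect_size`` in both assays (genotype ko vs wt);
    the rest are null.  Counts ~ NB(mu * 2^(lfc * is_ko), alpha) with
    ``n_replicates`` per genotype.  The promoter peak sits inside
    [TSS-1000, TSS+1).  Returns (atac_counts, bru_counts, truth).
    """
    rng = _rng(config, "counts")
    n = len(genes)
    n_eff = int(round(config.effect_fraction * n))
    affected = np.zeros(n, dtype=bool)
    affected[rng.choice(n, size=n_eff, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc = np.where(affected, signs * config.effect_size, 0.0)

    sample_ids = [f"wt_{r+1}" for r in range(config.n_replicates)] + [
        f"ko_{r+1}" for r in range(config.n_replicates)
    ]
    group_labels = ["wt"] * config.n_replicates + ["ko"] * config.n_replicates
    is_ko = np.array([g == "ko" for g in group_labels])

    base_atac = config.base_mean * np.exp(rng.normal(0.0, 0.25, size=n))
    base_bru = config.base_mean * np.exp(rng.normal(0.0, 0.25, size=n))

    peak_ids, gene_ids = [], []
    atac = np.zeros((n, len(sample_ids)), dtype=np.int64)
    bru = np.zeros((n, len(sample_ids)), dtype=np.int64)
    records = []
    for i, gene in enumerate(genes):
        if gene.strand == "+":
            pk_start = max(0, gene.tss - 1000)
            pk_end = gene.tss + 1
        else:
            pk_start = gene.tss
            pk_end = gene.tss + 1001
        peak_id = f"{gene.chrom}:{pk_start}-{pk_end}"
        peak_ids.append(peak_id)
        gene_ids.append(gene.gene_id)
        for j in range(len(sample_ids)):
            fold = 2.0 ** (lfc[i] * (1.0 if is_ko[j] else 0.0))
            atac[i, j] = _nb_draw(rng, base_atac[i] * fold, config.nb_dispersion, None)
            bru[i, j] = _nb_draw(rng, base_bru[i] * fold, config.nb_dispersion, None)
        records.append(
            {
                "gene_id": gene.gene_id,
                "peak_id": peak_id,
                "true_atac_log2fc": lfc[i],
                "true_bru_log2fc": lfc[i],
                "affected": bool(affected[i]),
                "concordant": bool(affected[i]),  # shared-sign construction
            }
        )
    atac_cm = CountMatrix(peak_ids, sample_ids, atac, group_labels)
    bru_cm = CountMatrix(gene_ids, [f"bru_{s}" for s in sample_ids], bru, group_labels)
    return atac_cm, bru_cm, pd.DataFrame(records)


def promoter_peaks_from_truth(truth: pd.DataFrame) -> list[Peak]:
    """Reconstruct the simulated promoter Peak objects from a truth table."""
    peaks = []
    for peak_id in truth["peak_id"]:
        chrom, span = peak_id.rsplit(":", 1)
        start, end = (int(v) for v in span.split("-"))
        peaks.append(Peak(peak_id, GenomicInterval(chrom, start, end)))
    return peaks


@dataclass(frozen=True)
class NeuronTruth:
    n_primary: int
    n_branch_points: int
    total_length_um: float
    longest_neurite_um: float


def simulate_neuron_trace(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[NeuronTrace, NeuronTruth]:
    """Grow a planar binary-branching tree from the soma at the origin.

    Primary neurites leave the soma at evenly spaced, jittered headings; each
    segment extends with a heading perturbation and branches into two with
    probability ``branch_prob`` until ``max_branch_depth``.  Self-intersection
    is allowed (Sholl counts are well-defined regardless).
    """
    if rng is None:
        rng = _rng(config, "neurons")
    n_primary = int(rng.integers(config.primary_range[0], config.primary_range[1] + 1))
    lo, hi = config.segment_length_range
    nodes = [SwcNode(1, 1, 0.0, 0.0, -1)]
    next_id = 2
    total = 0.0
    longest = 0.0
    n_branch = 0

    # stack entries: (parent node id, x, y, heading, depth, path length so far)
    stack = []
    base = rng.uniform(0.0, 2 * math.pi)
    for k in range(n_primary):
        heading = base + 2 * math.pi * k / n_primary + rng.normal(0.0, 0.15)
        stack.append((1, 0.0, 0.0, heading, 0, 0.0))

    while stack:
        parent_id, x, y, heading, depth, path = stack.pop()
        length = float(rng.uniform(lo, hi))
        nx = x + length * math.cos(heading)
        ny = y + length * math.sin(heading)
        node_id = next_id
        next_id += 1
        nodes.append(SwcNode(node_id, 3, nx, ny, parent_id))
        total += length
        path += length
        longest = max(longest, path)
        if depth < config.max_branch_depth and rng.random() < config.branch_prob:
            n_branch += 1
            spread = rng.uniform(0.4, 0.9)
            for sign in (-1.0, 1.0):
                stack.append(
                    (node_id, nx, ny, heading + sign * spread + rng.normal(0.0, 0.1), depth + 1, path)
                )
        elif depth < config.max_branch_depth and rng.random() < 0.5:
            stack.append((node_id, nx, ny, heading + rng.normal(0.0, 0.3), depth + 1, path))

    trace = NeuronTrace(nodes)
    return trace, NeuronTruth(n_primary, n_branch, total, longest)
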