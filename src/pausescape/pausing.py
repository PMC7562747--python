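"""RNAPII pausing-index pipeline over CHD7-ranked genes.

Stages, in order: expressed-gene filter (FPKM >= 1.0, length > 750 bp),
RNAPII-bound filter (TSS-window RPKM > 1.6 and body-window RPKM > 0.5),
CHD7-occupancy ranking (top/bottom k over the whole gene territory),
pausing-index computation (TSS RPKM / body RPKM), 150-bin metagene
profiles, and a two-sample Wilcoxon comparison of the extreme groups.

All windows are taken in transcription direction: the TSS window spans
-50..+200 bp around the TSS, the body window +500 bp to the TTS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CoverageTrack, GeneModel, GenomicInterval, ValidationError
from .stats import TestResult, wilcoxon_ranksum

__all__ = [
    "PausingConfig",
    "PausingRecord",
    "region_rpkm",
    "define_windows",
    "filter_expressed",
    "filter_rnapii_bound",
    "rank_by_chd7",
    "pausing_index",
    "metagene_profile",
    "compare_pausing_groups",
    "run_pausing_pipeline",
]


@dataclass
class PausingConfig:
    min_fpkm: float = 1.0
    min_length_bp: int = 750  # strict >
    tss_window: tuple[int, int] = (-50, 200)  # bp around TSS, transcription direction
    body_start_offset: int = 500
    tss_rpkm_min: float = 1.6
    body_rpkm_min: float = 0.5
    k_extremes: int = 500
    n_bins: int = 150
    # "throughout the gene body" read as the whole gene territory; set to
    # "body_window" to rank on the +500..TTS window instead
    chd7_occupancy_region: str = "gene"
    metagene_norm: str = "per-gene-mean"  # per-gene-mean | per-gene-sum | none

    def __post_init__(self) -> None:
        if self.tss_window[0] >= self.tss_window[1]:
            raise ValueError("TSS window start must precede its end")
        if self.body_start_offset >= self.min_length_bp:
            raise ValueError("body_start_offset must be below the minimum gene length")
        if self.k_extremes < 1 or self.n_bins < 1:
            raise ValueError("k_extremes and n_bins must be >= 1")
        if self.chd7_occupancy_region not in {"gene", "body_window"}:
            raise ValueError("chd7_occupancy_region must be 'gene' or 'body_window'")
        if self.metagene_norm not in {"per-gene-mean", "per-gene-sum", "none"}:
            raise ValueError("unknown metagene normalization")


@dataclass
class PausingRecord:
    gene_id: str
    tss_rpkm: float
    body_rpkm: float
    pausing_index: float
    chd7_body_rpkm: float = float("nan")
    group: str = "unassigned"


def region_rpkm(track: CoverageTrack, region: GenomicInterval) -> float:
    """Reads per kilobase of region per million mapped reads.

    Reads = number of 5' ends inside the half-open region; regions outside
    the track extent contribute zero coverage.
    """
    total = track.total_reads
    if total == 0:
        raise ValidationError("track has zero mapped reads; RPKM undefined")
    reads = track.count_in(region)
    return reads / ((len(region) / 1_000.0) * (total / 1_000_000.0))


def define_windows(gene: GeneModel, config: PausingConfig) -> tuple[GenomicInterval, GenomicInterval]:
    """(tss_window, body_window) in transcription direction, genomic coords.

    '+' strand: tss = [TSS-50, TSS+200), body = [TSS+500, TTS+1).
    '-' strand: both mirrored about the TSS.  Windows are clipped at the
    chromosome origin; a gene too short for a body window is an error.
    """
    up, down = config.tss_window
    if gene.length <= config.body_start_offset:
        raise ValidationError(f"gene {gene.gene_id}: too short for a body window")
    if gene.strand == "+":
        tssw = GenomicInterval(gene.chrom, max(0, gene.tss + up), gene.tss + down, "+")
        body = GenomicInterval(gene.chrom, gene.tss + config.body_start_offset, gene.tts + 1, "+")
    else:
        tssw = GenomicInterval(gene.chrom, max(0, gene.tss - down + 1), gene.tss - up + 1, "-")
        body = GenomicInterval(gene.chrom, gene.tts, gene.tss - config.body_start_offset + 1, "-")
    return tssw, body


def filter_expressed(genes: list[GeneModel], config: PausingConfig) -> list[GeneModel]:
    """Keep genes with fpkm >= min_fpkm and length > min_length_bp."""
    out = []
    for g in genes:
        if g.fpkm is None:
            raise ValidationError(f"gene {g.gene_id} lacks an FPKM value")
        if g.fpkm >= config.min_fpkm and g.length > config.min_length_bp:
            out.append(g)
    return out


def filter_rnapii_bound(
    genes: list[GeneModel], rnapii_track: CoverageTrack, config: PausingConfig
) -> list[GeneModel]:
    """Keep genes with TSS RPKM > tss_rpkm_min and body RPKM > body_rpkm_min."""
    out = []
    for g in genes:
        tssw, body = define_windows(g, config)
        if (
            region_rpkm(rnapii_track, tssw) > config.tss_rpkm_min
            and region_rpkm(rnapii_track, body) > config.body_rpkm_min
        ):
            out.append(g)
    return out


def chd7_occupancy(gene: GeneModel, chd7_track: CoverageTrack, config: PausingConfig) -> float:
    if config.chd7_occupancy_region == "gene":
        return region_rpkm(chd7_track, gene.interval)
    _, body = define_windows(gene, config)
    return region_rpkm(chd7_track, body)


def rank_by_chd7(
    genes: list[GeneModel], chd7_track: CoverageTrack, config: PausingConfig
) -> tuple[list[GeneModel], list[GeneModel]]:
    """(top_k, bottom_k) genes by CHD7 occupancy; ties broken by gene_id."""
    k = config.k_extremes
    if len(genes) < 2 * k:
        raise ValidationError(f"need >= {2 * k} genes to take top/bottom {k}")
    occ = {g.gene_id: chd7_occupancy(g, chd7_track, config) for g in genes}
    descending = sorted(genes, key=lambda g: (-occ[g.gene_id], g.gene_id))
    ascending = sorted(genes, key=lambda g: (occ[g.gene_id], g.gene_id))
    top = descending[:k]
    bottom_ids_excluded = {g.gene_id for g in top}
    bottom = [g for g in ascending if g.gene_id not in bottom_ids_excluded][:k]
    return top, bottom


def pausing_index(gene: GeneModel, rnapii_track: CoverageTrack, config: PausingConfig) -> float:
    """TSS-window RPKM divided by body-window RPKM."""
    tssw, body = define_windows(gene, config)
    body_rpkm = region_rpkm(rnapii_track, body)
    if body_rpkm == 0:
        raise ValidationError(
            f"gene {gene.gene_id}: body RPKM is 0 — the RNAPII-bound filter was bypassed"
        )
    return region_rpkm(rnapii_track, tssw) / body_rpkm


def metagene_profile(
    genes: list[GeneModel], track: CoverageTrack, config: PausingConfig
) -> np.ndarray:
    """Average TSS->TTS coverage profile over ``n_bins`` equal-width bins.

    Each gene's per-base coverage is read in transcription direction, binned,
    normalized per gene (mean 1 by default), then averaged across genes.
    Genes with zero total coverage are excluded from normalization and
    averaging (a warning reports how many).
    """
    if not genes:
        raise ValidationError("metagene profile needs at least one gene")
    n_bins = config.n_bins
    profiles = []
    n_zero = 0
    for g in genes:
        cov = track.slice(g.interval).astype(float)
        if g.strand == "-":
            cov = cov[::-1]
        edges = np.floor(np.linspace(0, cov.size, n_bins + 1)).astype(int)
        sums = np.add.reduceat(cov, edges[:-1])
        widths = np.maximum(np.diff(edges), 1)
        binned = sums / widths
        if config.metagene_norm == "per-gene-mean":
            m = binned.mean()
            if m == 0:
                n_zero += 1
                continue
            binned = binned / m
        elif config.metagene_norm == "per-gene-sum":
            s = binned.sum()
            if s == 0:
                n_zero += 1
                continue
            binned = binned / s
        profiles.append(binned)
    if n_zero:
        warnings.warn(f"{n_zero} gene(s) with zero coverage excluded from the metagene profile")
    if not profiles:
        return np.zeros(n_bins)
    return np.mean(profiles, axis=0)


def compare_pausing_groups(
    high_records: list[PausingRecord], low_records: list[PausingRecord]
) -> TestResult:
    """Two-sided Wilcoxon rank-sum on pausing indices, high vs low CHD7."""
    if not high_records or not low_records:
        raise ValidationError("both groups must be non-empty")
    high = [r.pausing_index for r in high_records]
    low = [r.pausing_index for r in low_records]
    result = wilcoxon_ranksum(high, low)
    result.extra["median_high_chd7"] = result.extra.pop("median_a")
    result.extra["median_low_chd7"] = result.extra.pop("median_b")
    return result


@dataclass
class PausingPipelineResult:
    records: list[PausingRecord]
    n_input: int
    n_expressed: int
    n_rnapii_bound: int
    profile_high: np.ndarray
    profile_low: np.ndarray
    group_test: TestResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def run_pausing_pipeline(
    genes: list[GeneModel],
    rnapii_track: CoverageTrack,
    chd7_track: CoverageTrack,
    config: PausingConfig | None = None,
) -> PausingPipelineResult:
    """Full pipeline: expressed -> RNAPII-bound -> CHD7-ranked -> indices.

    Each stage only shrinks the gene set.  Returns per-gene records for the
    two extreme groups, their metagene profiles on the RNAPII track, and the
    Wilcoxon comparison of pausing indices.
    """
    config = config or PausingConfig()
    expressed = filter_expressed(genes, config)
    bound = filter_rnapii_bound(expressed, rnapii_track, config)
    top, bottom = rank_by_chd7(bound, chd7_track, config)

    records = []
    for group, members in (("high_chd7", top), ("low_chd7", bottom)):
        for g in members:
            tssw, body = define_windows(g, config)
            tss_rpkm = region_rpkm(rnapii_track, tssw)
            body_rpkm = region_rpkm(rnapii_track, body)
            records.append(
                PausingRecord(
                    gene_id=g.gene_id,
                    tss_rpkm=tss_rpkm,
                    body_rpkm=body_rpkm,
                    pausing_index=tss_rpkm / body_rpkm,
                    chd7_body_rpkm=chd7_occupancy(g, chd7_track, config),
                    group=group,
                )
            )
    high = [r for r in records if r.group == "high_chd7"]
    low = [r for r in records if r.group == "low_chd7"]
    return PausingPipelineResult(
        records=records,
        n_input=len(genes),
        n_expressed=len(expressed),
        n_rnapii_bound=len(bound),
        profile_high=metagene_profile(top, rnapii_track, config),
        profile_low=metagene_profile(bottom, rnapii_track, config),
        group_test=compare_pausing_groups(high, low),
    )
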