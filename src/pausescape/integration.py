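"""Integrated differential accessibility / nascent expression analysis.

Covers the downstream stages of the ATAC-seq + Bru-Seq comparison: merging
genotype peak sets into a common set, counting read starts per replicate,
median-of-ratios normalization, a negative-binomial Wald test with BH FDR,
promoter/feature annotation of peaks (nearest TSS, promoter = 1000 bp
upstream to 1 bp downstream of the TSS), quadrant and "doubly significant"
classification of promoter-peak/gene pairs, Kendall's tau association of
the two fold changes, and hypergeometric GO-term enrichment against an
expressed-gene background.

The differential stage is a deliberately simplified NB Wald test
(method-of-moments dispersion, no shrinkage, no outlier refitting).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .core_io import CountMatrix, CoverageTrack, GeneModel, GenomicInterval, Peak, ValidationError
from .stats import TestResult, bh_adjust, kendall_tau_b

__all__ = [
    "IntegrationConfig",
    "DiffResult",
    "AnnotatedPeak",
    "QuadrantRecord",
    "merge_peak_sets",
    "count_in_peaks",
    "size_factors",
    "nb_wald_test",
    "annotate_peaks",
    "quadrant_classify",
    "kendall_association",
    "go_enrichment",
    "load_reported_doubly_significant",
    "FEATURE_CLASSES",
]

FEATURE_CLASSES = ("promoter", "exon", "intron", "downstream", "distal_intergenic")

LOG2FC_PSEUDOCOUNT = 0.5  # added to normalized group means before the log2 ratio
DISPERSION_FLOOR = 1e-8


@dataclass
class IntegrationConfig:
    promoter_upstream: int = 1000
    promoter_downstream: int = 1
    fdr_threshold: float = 0.05
    downstream_max: int = 3000
    merge_bookended: bool = True

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.promoter_downstream, self.downstream_max) < 0:
            raise ValueError("distances must be >= 0")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie in (0, 1)")


@dataclass
class DiffResult:
    feature_id: str
    base_mean: float
    log2_fc: float  # group2 vs group1
    se: float
    p: float
    fdr: float = float("nan")


@dataclass
class AnnotatedPeak:
    peak: Peak
    gene_id: str
    feature_class: str
    tss_distance: int  # signed, transcription direction (negative = upstream)


@dataclass
class QuadrantRecord:
    gene_id: str
    peak_id: str
    atac_log2fc: float
    atac_fdr: float
    bru_log2fc: float
    bru_fdr: float
    doubly_significant: bool
    quadrant: str  # atac/bru sign, e.g. "down/up"
    concordant: bool


def merge_peak_sets(
    set_a: list[Peak], set_b: list[Peak], config: IntegrationConfig | None = None
) -> list[Peak]:
    """Coalesce the union of two peak sets into a common peak set.

    Overlapping intervals always merge; book-ended (touching) ones merge when
    ``merge_bookended`` (bedtools-merge semantics).  Output is sorted and ids
    are assigned as chrom:start-end.
    """
    config = config or IntegrationConfig()
    pool = sorted(
        (p.interval for p in list(set_a) + list(set_b)),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    merged: list[Peak] = []
    cur: list[int | str] | None = None
    for iv in pool:
        if cur is not None and iv.chrom == cur[0]:
            gap_ok = iv.start < cur[2] or (config.merge_bookended and iv.start == cur[2])
            if gap_ok:
                cur[2] = max(cur[2], iv.end)
                continue
        if cur is not None:
            merged.append(_mk_peak(*cur))
        cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(_mk_peak(*cur))
    return merged


def _mk_peak(chrom, start, end) -> Peak:
    return Peak(f"{chrom}:{start}-{end}", GenomicInterval(chrom, start, end))


def count_in_peaks(
    tracks: list[CoverageTrack], peaks: list[Peak], groups: list[str] | None = None
) -> CountMatrix:
    """Read starts inside each (non-overlapping) peak, per replicate track.

    ``groups`` supplies the genotype label per track; by default the part of
    each track label before the last underscore is used.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start)):
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for plist in by_chrom.values():
        for a, b in zip(plist, plist[1:]):
            if b.interval.start < a.interval.end:
                raise ValidationError(
                    f"overlapping peaks {a.peak_id} / {b.peak_id}: counting is ambiguous"
                )
    ordered = [p for plist in by_chrom.values() for p in plist]
    if groups is None:
        groups = [t.label.rsplit("_", 1)[0] for t in tracks]
    counts = np.zeros((len(ordered), len(tracks)), dtype=np.int64)
    for j, track in enumerate(tracks):
        for i, p in enumerate(ordered):
            counts[i, j] = track.count_in(p.interval)
    return CountMatrix([p.peak_id for p in ordered], [t.label for t in tracks], counts, list(groups))


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios normalization factors (one per sample).

    Reference = per-feature geometric mean over samples; a sample's factor is
    the median, over features positive in every sample, of count/reference.
    """
    c = counts.counts.astype(float)
    all_positive = np.all(c > 0, axis=1)
    if not np.any(all_positive):
        raise ValidationError("no feature with positive counts in every sample")
    logc = np.log(c[all_positive])
    log_ref = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_ref, axis=0))
    return factors


def _group_pair(counts: CountMatrix) -> tuple[str, str]:
    groups = list(dict.fromkeys(counts.groups))  # order of first appearance
    if len(groups) != 2:
        raise ValidationError(f"differential test needs exactly two groups, got {groups}")
    return groups[0], groups[1]


def nb_wald_test(
    counts: CountMatrix,
    factors: np.ndarray | None = None,
    pseudocount: float = LOG2FC_PSEUDOCOUNT,
) -> list[DiffResult]:
    """Per-feature negative-binomial Wald test with BH-adjusted FDR.

    log2_fc = log2((mu2 + eps) / (mu1 + eps)) on size-factor-normalized group
    means (group order = first appearance among sample labels).  Dispersion is
    a per-feature method-of-moments estimate with a small floor, moderated by
    the across-feature median (elementwise max) — with 3 replicates per group
    the raw per-feature estimate alone is too noisy to keep the Wald test
    calibrated.  The standard error of log2_fc comes from the delta method;
    the two-sided p uses the normal reference.
    """
    g1, g2 = _group_pair(counts)
    idx1 = counts.group_columns(g1)
    idx2 = counts.group_columns(g2)
    if idx1.size < 2 or idx2.size < 2:
        raise ValidationError("need >= 2 replicates per group")
    if factors is None:
        factors = size_factors(counts)
    factors = np.asarray(factors, dtype=float)
    norm = counts.counts / factors[None, :]
    n1, n2 = norm[:, idx1], norm[:, idx2]
    mu1, mu2 = n1.mean(axis=1), n2.mean(axis=1)
    eps = pseudocount
    lfc = np.log2((mu2 + eps) / (mu1 + eps))

    # pooled method-of-moments NB dispersion: var = mu + alpha mu^2
    pooled_var = (n1.var(axis=1, ddof=1) * (idx1.size - 1) + n2.var(axis=1, ddof=1) * (idx2.size - 1)) / (
        idx1.size + idx2.size - 2
    )
    mu_bar = 0.5 * (mu1 + mu2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu_bar > 0, (pooled_var - mu_bar) / np.square(mu_bar), 0.0)
    alpha = np.clip(alpha, DISPERSION_FLOOR, None)
    alpha = np.maximum(alpha, float(np.median(alpha)))

    # delta method on log2 of each group mean
    def var_log2_mean(mu, n):
        v = (mu + alpha * mu**2) / n  # variance of the group mean under NB
        return v / (np.log(2.0) ** 2 * (mu + eps) ** 2)

    se = np.sqrt(var_log2_mean(mu1, idx1.size) + var_log2_mean(mu2, idx2.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * _sps.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    fdr = bh_adjust(p)
    base_mean = norm.mean(axis=1)
    return [
        DiffResult(fid, float(base_mean[i]), float(lfc[i]), float(se[i]), float(p[i]), float(fdr[i]))
        for i, fid in enumerate(counts.feature_ids)
    ]


def _promoter_window(gene: GeneModel, config: IntegrationConfig) -> GenomicInterval:
    """[TSS - upstream, TSS + downstream) in transcription direction."""
    up, down = config.promoter_upstream, config.promoter_downstream
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, max(0, gene.tss - up), gene.tss + down, "+")
    return GenomicInterval(gene.chrom, max(0, gene.tss - down + 1), gene.tss + up + 1, "-")


def _downstream_window(gene: GeneModel, config: IntegrationConfig) -> GenomicInterval | None:
    d = config.downstream_max
    if d == 0:
        return None
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.tts + 1, gene.tts + 1 + d, "+")
    if gene.tts == 0:
        return None
    return GenomicInterval(gene.chrom, max(0, gene.tts - d), gene.tts, "-")


def annotate_peaks(
    peaks: list[Peak], genes: list[GeneModel], config: IntegrationConfig | None = None
) -> list[AnnotatedPeak]:
    """Assign each peak its nearest-TSS gene and one feature class.

    Nearest is measured TSS to peak midpoint (ties -> smaller gene_id).
    Class precedence: promoter > exon > intron > downstream >
    distal_intergenic, with promoter = overlap of the [TSS-1000, TSS+1)
    window in transcription direction and downstream = within 3000 bp past
    the TTS.
    """
    config = config or IntegrationConfig()
    if not genes:
        raise ValidationError("empty gene list")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_arrays = {c: np.array([g.tss for g in gl]) for c, gl in by_chrom.items()}

    out = []
    for peak in peaks:
        iv = peak.interval
        mid = (iv.start + iv.end) // 2
        candidates = by_chrom.get(iv.chrom)
        if candidates is None:
            # no gene on this chromosome: nearest over all genes is undefined;
            # fall back to a distal call against the globally first gene id
            nearest = min(genes, key=lambda g: g.gene_id)
            out.append(AnnotatedPeak(peak, nearest.gene_id, "distal_intergenic", np.iinfo(np.int32).max))
            continue
        dists = np.abs(tss_arrays[iv.chrom] - mid)
        best = int(np.argmin(dists))  # argmin takes the first minimum; list is gene_id-sorted within equal TSS
        # resolve exact distance ties by gene_id
        tied = np.flatnonzero(dists == dists[best])
        if tied.size > 1:
            best = min(tied, key=lambda i: candidates[i].gene_id)
        gene = candidates[best]
        signed = (mid - gene.tss) if gene.strand == "+" else (gene.tss - mid)

        if iv.overlaps(_promoter_window(gene, config)):
            cls = "promoter"
        elif any(iv.overlaps(e) for e in gene.exons):
            cls = "exon"
        elif iv.overlaps(gene.interval):
            cls = "intron"
        else:
            dw = _downstream_window(gene, config)
            cls = "downstream" if dw is not None and iv.overlaps(dw) else "distal_intergenic"
        out.append(AnnotatedPeak(peak, gene.gene_id, cls, int(signed)))
    return out


def quadrant_classify(
    atac_results: list[DiffResult],
    annotated_peaks: list[AnnotatedPeak],
    bru_results: list[DiffResult],
    config: IntegrationConfig | None = None,
) -> tuple[list[QuadrantRecord], list[str]]:
    """Pair promoter peaks with their gene's expression result.

    A gene with several promoter peaks contributes one record per peak.
    Returns (records, dropped_peak_ids) where dropped peaks are promoter
    peaks whose gene has no expression result.
    """
    config = config or IntegrationConfig()
    atac_by_id = {r.feature_id: r for r in atac_results}
    bru_by_id = {r.feature_id: r for r in bru_results}
    records, dropped = [], []
    for ap in annotated_peaks:
        if ap.feature_class != "promoter":
            continue
        atac = atac_by_id.get(ap.peak.peak_id)
        bru = bru_by_id.get(ap.gene_id)
        if atac is None or bru is None:
            dropped.append(ap.peak.peak_id)
            continue
        records.append(make_quadrant_record(ap.gene_id, ap.peak.peak_id, atac.log2_fc, atac.fdr, bru.log2_fc, bru.fdr, config))
    return records, dropped


def make_quadrant_record(
    gene_id: str,
    peak_id: str,
    atac_log2fc: float,
    atac_fdr: float,
    bru_log2fc: float,
    bru_fdr: float,
    config: IntegrationConfig | None = None,
) -> QuadrantRecord:
    """Apply the sign/threshold rules to one (accessibility, expression) pair."""
    config = config or IntegrationConfig()
    thr = config.fdr_threshold
    doubly = atac_fdr < thr and bru_fdr < thr
    qa = "up" if atac_log2fc > 0 else "down"
    qb = "up" if bru_log2fc > 0 else "down"
    concordant = atac_log2fc * bru_log2fc > 0
    return QuadrantRecord(
        gene_id, peak_id, atac_log2fc, atac_fdr, bru_log2fc, bru_fdr, doubly, f"{qa}/{qb}", concordant
    )


def kendall_association(records: list[QuadrantRecord]) -> TestResult:
    """Kendall's tau-b between ATAC and Bru log2 fold changes."""
    if len(records) < 2:
        raise ValidationError("need >= 2 records")
    x = [r.atac_log2fc for r in records]
    y = [r.bru_log2fc for r in records]
    return kendall_tau_b(x, y)


@dataclass
class GOEnrichment:
    term: str
    k: int  # selected genes in term
    K: int  # background genes in term
    n: int  # selected genes
    N: int  # background genes
    p: float
    bonferroni_p: float


def go_enrichment(
    selected_genes: set[str],
    background_genes: set[str],
    term_map: dict[str, set[str]],
) -> list[GOEnrichment]:
    """Hypergeometric upper-tail enrichment per term, Bonferroni-adjusted.

    The background must contain every selected gene (expressed genes only,
    by design); term gene sets are intersected with the background.  Results
    are sorted by adjusted p.
    """
    from .stats import hypergeom_upper_tail

    stray = selected_genes - background_genes
    if stray:
        raise ValidationError(f"selected genes absent from background: {sorted(stray)[:5]}")
    N = len(background_genes)
    n = len(selected_genes)
    m = len(term_map)
    out = []
    for term, members in term_map.items():
        in_bg = members & background_genes
        K = len(in_bg)
        k = len(in_bg & selected_genes)
        p = hypergeom_upper_tail(k, K, n, N)
        out.append(GOEnrichment(term, k, K, n, N, p, min(1.0, p * m)))
    out.sort(key=lambda r: (r.bonferroni_p, r.p, r.term))
    return out


def load_reported_doubly_significant() -> pd.DataFrame:
    """The 22 published top doubly-significant promoter-peak/gene pairs.

    Columns: gene, chrom, peak_start, atac_log2fc, atac_adj_p, bru_log2fc,
    bru_adj_p, concordance ("Yes"/"No").
    """
    with resources.files("pausescape.data").joinpath("doubly_significant_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
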