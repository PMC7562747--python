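"""Domain types and plain-text readers/writers shared by every stage.

All interval arithmetic is 0-based half-open (BED convention); 1-based
formats are converted at the boundary.  Coverage is stored as read 5'-end
counts per base, so "reads in region" is an exact array sum.  Chromosome
names are matched verbatim — no "chr" aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "GeneModel",
    "CoverageTrack",
    "Peak",
    "CountMatrix",
    "NeuronTrace",
    "SwcNode",
    "parse_gene_table",
    "write_gene_table",
    "parse_bed",
    "write_bed",
    "parse_bedgraph",
    "write_bedgraph",
    "parse_swc",
    "write_swc",
    "read_count_matrix",
    "write_count_matrix",
]


class ValidationError(ValueError):
    """A domain invariant was violated."""


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line."""


STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene with exon structure and optional FPKM.

    TSS is the first transcribed base (start on '+', end-1 on '-');
    TTS is the last (end-1 on '+', start on '-').
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    fpkm: float | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValidationError(f"gene {self.gene_id}: exon on wrong chromosome")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside gene interval")
            if prev_end is not None and exon.start < prev_end:
                raise ValidationError(f"gene {self.gene_id}: exons unsorted or overlapping")
            prev_end = exon.end
        if self.fpkm is not None and self.fpkm < 0:
            raise ValidationError(f"gene {self.gene_id}: negative FPKM")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


class CoverageTrack:
    """Per-base read 5'-end counts, one integer array per chromosome."""

    def __init__(self, data: dict[str, np.ndarray], label: str = "") -> None:
        self.data: dict[str, np.ndarray] = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValidationError(f"{chrom}: coverage must be 1-D")
            if arr.size and arr.min() < 0:
                raise ValidationError(f"{chrom}: negative counts")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValidationError(f"{chrom}: counts must be integral")
                arr = np.round(arr).astype(np.int64)
            self.data[chrom] = arr.astype(np.int64, copy=False)
        self.label = label

    @property
    def total_reads(self) -> int:
        return int(sum(int(arr.sum()) for arr in self.data.values()))

    def count_in(self, region: GenomicInterval) -> int:
        """Read starts whose 5' end lies in ``region``; outside the stored
        extent counts as zero."""
        arr = self.data.get(region.chrom)
        if arr is None:
            return 0
        lo = max(region.start, 0)
        hi = min(region.end, arr.size)
        if hi <= lo:
            return 0
        return int(arr[lo:hi].sum())

    def slice(self, region: GenomicInterval) -> np.ndarray:
        """Per-base counts over ``region``, zero-padded beyond the extent."""
        out = np.zeros(len(region), dtype=np.int64)
        arr = self.data.get(region.chrom)
        if arr is None:
            return out
        lo = max(region.start, 0)
        hi = min(region.end, arr.size)
        if hi > lo:
            out[lo - region.start : hi - region.start] = arr[lo:hi]
        return out


@dataclass(frozen=True)
class Peak:
    peak_id: str
    interval: GenomicInterval
    score: float | None = None


@dataclass
class CountMatrix:
    """Feature-by-sample integer counts with a genotype label per sample."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError("count matrix dimensions inconsistent with labels")
        if len(self.groups) != len(self.sample_ids):
            raise ValidationError("one group label per sample required")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids must be unique")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group], dtype=int)


@dataclass(frozen=True)
class SwcNode:
    node_id: int
    node_type: int  # 1 = soma, anything else treated as neurite
    x: float
    y: float
    parent_id: int  # -1 for the root


class NeuronTrace:
    """Rooted planar tree of traced nodes (soma root, neurite children)."""

    def __init__(self, nodes: list[SwcNode]) -> None:
        if not nodes:
            raise ValidationError("empty trace")
        seen: dict[int, SwcNode] = {}
        roots = []
        for node in nodes:
            if node.node_id in seen:
                raise ValidationError(f"duplicate node id {node.node_id}")
            if node.parent_id == -1:
                roots.append(node)
            elif node.parent_id not in seen:
                raise ValidationError(
                    f"node {node.node_id} references parent {node.parent_id} "
                    "which is absent or defined later"
                )
            seen[node.node_id] = node
        if len(roots) != 1:
            raise ValidationError(f"expected exactly one root, found {len(roots)}")
        self.nodes = list(nodes)
        self.root = roots[0]
        self._by_id = seen
        self._children: dict[int, list[SwcNode]] = {n.node_id: [] for n in nodes}
        for node in nodes:
            if node.parent_id != -1:
                self._children[node.parent_id].append(node)

    def node(self, node_id: int) -> SwcNode:
        return self._by_id[node_id]

    def children(self, node_id: int) -> list[SwcNode]:
        return self._children[node_id]

    def segments(self) -> list[tuple[SwcNode, SwcNode]]:
        """(parent, child) pairs, one per edge."""
        return [(self._by_id[n.parent_id], n) for n in self.nodes if n.parent_id != -1]


# ---------------------------------------------------------------------------
# gene table (TSV, BED12-style block encoding)

_GENE_HEADER = ["gene_id", "chrom", "start", "end", "strand", "exon_sizes", "exon_starts", "fpkm"]


def parse_gene_table(path) -> list[GeneModel]:
    """Read a tab-separated gene table.

    Columns: gene_id, chrom, start, end, strand, exon block sizes, exon block
    starts (comma-separated, relative to gene start), optional fpkm ('.' for
    missing).  A header line matching the canonical column names is skipped.
    """
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[: len(_GENE_HEADER) - 1] == _GENE_HEADER[:-1]:
                continue
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected >= 7 tab-separated fields")
            try:
                gene_id, chrom = fields[0], fields[1]
                start, end = int(fields[2]), int(fields[3])
                strand = fields[4]
                sizes = [int(s) for s in fields[5].rstrip(",").split(",")]
                offsets = [int(s) for s in fields[6].rstrip(",").split(",")]
                fpkm = None
                if len(fields) > 7 and fields[7] not in {"", "."}:
                    fpkm = float(fields[7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != len(offsets):
                raise ParseError(f"{path}:{lineno}: exon sizes/starts length mismatch")
            try:
                interval = GenomicInterval(chrom, start, end, strand)
                exons = tuple(
                    GenomicInterval(chrom, start + off, start + off + size, strand)
                    for off, size in zip(offsets, sizes)
                )
                genes.append(GeneModel(gene_id, interval, exons, fpkm))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_HEADER) + "\n")
        for g in genes:
            sizes = ",".join(str(len(e)) for e in g.exons)
            offsets = ",".join(str(e.start - g.interval.start) for e in g.exons)
            fpkm = "." if g.fpkm is None else repr(float(g.fpkm))
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.strand}\t{sizes}\t{offsets}\t{fpkm}\n"
            )


# ---------------------------------------------------------------------------
# BED

def parse_bed(path) -> list[Peak]:
    """Read BED3+ peaks (0-based half-open).  Column 4 is the peak id when
    present, column 5 the score; missing ids default to chrom:start-end."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{chrom}:{start}-{end}"
            score = None
            if len(fields) > 4 and fields[4] not in {"", "."}:
                score = float(fields[4])
            peaks.append(Peak(name, interval, score))
    return peaks


def write_bed(peaks: list[Peak], path) -> None:
    """Write sorted BED (chrom, start); score '.' when absent."""
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for p in ordered:
            score = "." if p.score is None else repr(float(p.score))
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.peak_id}\t{score}\n")


# ---------------------------------------------------------------------------
# bedGraph

def parse_bedgraph(path, label: str = "") -> CoverageTrack:
    """Read a bedGraph of per-base read-start counts into a CoverageTrack.

    Values must be non-negative integers; overlapping intervals are an error.
    The stored array extends to the largest end seen per chromosome.
    """
    spans: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end or start < 0:
                raise ValidationError(f"{path}:{lineno}: invalid interval {start}-{end}")
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {value}")
            if value != int(value):
                raise ValidationError(f"{path}:{lineno}: non-integral count {value}")
            spans.setdefault(chrom, []).append((start, end, int(value)))

    data = {}
    for chrom, intervals in spans.items():
        intervals.sort()
        size = max(end for _, end, _ in intervals)
        arr = np.zeros(size, dtype=np.int64)
        prev_end = 0
        for start, end, value in intervals:
            if start < prev_end:
                raise ValidationError(f"{path}: overlapping intervals on {chrom} at {start}")
            arr[start:end] = value
            prev_end = end
        data[chrom] = arr
    return CoverageTrack(data, label=label or str(path))


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write run-length-encoded bedGraph, omitting zero stretches."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [arr.size]])
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# SWC

def parse_swc(path) -> NeuronTrace:
    """Read an SWC trace (id, type, x, y, z, radius, parent); z and radius
    are parsed but ignored — the morphometry is planar."""
    nodes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 SWC columns")
            try:
                node_id = int(fields[0])
                node_type = int(fields[1])
                x, y = float(fields[2]), float(fields[3])
                parent = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            nodes.append(SwcNode(node_id, node_type, x, y, parent))
    return NeuronTrace(nodes)


def write_swc(trace: NeuronTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in trace.nodes:
            fh.write(f"{n.node_id} {n.node_type} {n.x!r} {n.y!r} 0.0 1.0 {n.parent_id}\n")


# ---------------------------------------------------------------------------
# count matrix (TSV + design TSV)

def write_count_matrix(cm: CountMatrix, counts_path, design_path) -> None:
    with open(counts_path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(cm.sample_ids) + "\n")
        for i, fid in enumerate(cm.feature_ids):
            fh.write(fid + "\t" + "\t".join(str(int(c)) for c in cm.counts[i]) + "\n")
    with open(design_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in zip(cm.sample_ids, cm.groups):
            fh.write(f"{sid}\t{grp}\n")


def read_count_matrix(counts_path, design_path) -> CountMatrix:
    design: dict[str, str] = {}
    with open(design_path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ParseError(f"{design_path}:1: expected 'sample_id\\tgroup' header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{design_path}:{lineno}: expected 2 fields")
            design[fields[0]] = fields[1]

    feature_ids, rows = [], []
    with open(counts_path) as fh:
        header_fields = fh.readline().rstrip("\n").split("\t")
        if header_fields[0] != "feature_id":
            raise ParseError(f"{counts_path}:1: expected 'feature_id' header column")
        sample_ids = header_fields[1:]
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise ParseError(f"{counts_path}:{lineno}: wrong number of fields")
            feature_ids.append(fields[0])
            try:
                rows.append([int(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{counts_path}:{lineno}: {exc}") from exc
    missing = [s for s in sample_ids if s not in design]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    groups = [design[s] for s in sample_ids]
    return CountMatrix(feature_ids, sample_ids, np.array(rows, dtype=np.int64), groups)
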