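"""Gene and interval data model shared by every analysis stage.

All coordinates are 0-based, half-open ([start, end)) on the internal
representation; format-specific conventions (1-based GTF, etc.) are converted
at the reader/writer boundary only.  A "gene" is a stranded span with an
ordered, non-overlapping exon chain; the transcription start site (TSS) and
termination site (TTS) follow the biological orientation of the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

from intervaltree import IntervalTree

Strand = Literal["+", "-", "."]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span.  ``start`` inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene with an exon chain.

    Invariants: exons lie within the span, are sorted by start, do not
    overlap, and the first/last exon boundaries coincide with the span
    boundaries.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: zero exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise ValueError(
                    f"gene {self.gene_id}: exon on different chrom/strand"
                )
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        if self.exons[0].start != self.span.start or self.exons[-1].end != self.span.end:
            raise ValueError(
                f"gene {self.gene_id}: span must match first exon start and "
                "last exon end"
            )

    @property
    def strand(self) -> Strand:
        return self.span.strand

    @property
    def length(self) -> int:
        return len(self.span)


@dataclass
class ProbeSet:
    """Expression-array probe set with the genomic region it interrogates.

    ``apa_class`` stays ``unassigned`` until last-exon classification runs.
    """

    probe_id: str
    gene_id: str | None
    target: GenomicInterval
    apa_class: Literal["proximal", "distal", "unassigned"] = "unassigned"


@dataclass(frozen=True)
class Peak:
    """ChIP-seq peak call, optionally with a summit position."""

    interval: GenomicInterval
    summit: int | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.summit is not None and not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")


@dataclass
class TagCollection:
    """Aligned-read 5' positions for one ChIP-seq sample.

    ``total_mapped`` is the library-wide RPM denominator; ``tags`` may be a
    filtered subset of the library, never larger than it.
    """

    sample_id: str
    tags: list[tuple[str, int, Strand]]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive")
        if self.total_mapped < len(self.tags):
            raise ValueError("total_mapped smaller than number of tags")


def gene_anchors(g: GeneModel) -> tuple[int, int]:
    """Return (TSS, TTS) in biological orientation.

    On the minus strand the TSS is the span end coordinate (the first
    transcribed base is ``span.end - 1``; the half-open convention makes
    ``span.end`` the natural anchor so that |TSS - TTS| equals gene length).
    """
    if g.strand == "+":
        return g.span.start, g.span.end
    return g.span.end, g.span.start


def last_exon(g: GeneModel) -> GenomicInterval:
    """The 3'-terminal exon in transcript orientation."""
    return g.exons[-1] if g.strand == "+" else g.exons[0]


def normalized_position(g: GeneModel, pos: int) -> float:
    """Map a genomic position inside the gene to [0, 1).

    0 is the TSS side and values approach 1 toward the TTS, regardless of
    strand.
    """
    if not g.span.contains(pos):
        raise ValueError(
            f"position {pos} outside gene {g.gene_id} "
            f"[{g.span.start}, {g.span.end})"
        )
    if g.strand == "+":
        return (pos - g.span.start) / g.length
    return (g.span.end - 1 - pos) / g.length


def promoter_window(g: GeneModel, radius: int = 2000) -> GenomicInterval:
    """Symmetric window of positions p with |p - TSS| < radius, clipped at 0."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    tss, _ = gene_anchors(g)
    return GenomicInterval(
        g.span.chrom, max(0, tss - radius), tss + radius, g.strand
    )


@dataclass
class ProbeMapLog:
    """Bookkeeping for probe-to-gene assignment."""

    n_assigned: int = 0
    n_intergenic: int = 0
    n_ambiguous: int = 0
    excluded_probe_ids: list[str] = field(default_factory=list)


def _gene_trees(genes: Iterable[GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        trees.setdefault((g.span.chrom, g.strand), IntervalTree()).addi(
            g.span.start, g.span.end, g
        )
    return trees


def map_probesets(
    probes: Iterable[ProbeSet], genes: Iterable[GeneModel]
) -> tuple[list[ProbeSet], ProbeMapLog]:
    """Assign each probe set to the gene its target overlaps.

    Probes overlapping no gene are dropped (intergenic).  A probe overlapping
    several genes goes to the unique gene whose last exon it overlaps; if that
    is not unique either, the probe is dropped as ambiguous.  Counts of every
    exclusion are logged — this replaces visual curation with an auditable
    rule.
    """
    trees = _gene_trees(genes)
    log = ProbeMapLog()
    assigned: list[ProbeSet] = []
    for p in probes:
        key = (p.target.chrom, p.target.strand)
        hits = [
            iv.data
            for iv in trees.get(key, IntervalTree()).overlap(
                p.target.start, p.target.end
            )
        ]
        if not hits:
            log.n_intergenic += 1
            log.excluded_probe_ids.append(p.probe_id)
            continue
        if len(hits) == 1:
            gene = hits[0]
        else:
            by_last = [g for g in hits if last_exon(g).overlaps(p.target)]
            if len(by_last) == 1:
                gene = by_last[0]
            else:
                log.n_ambiguous += 1
                log.excluded_probe_ids.append(p.probe_id)
                continue
        assigned.append(replace_gene(p, gene.gene_id))
        log.n_assigned += 1
    return assigned, log


def replace_gene(p: ProbeSet, gene_id: str) -> ProbeSet:
    return ProbeSet(p.probe_id, gene_id, p.target, p.apa_class)
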