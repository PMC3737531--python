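"""Readers and writers for gene annotation, probe, peak and tag files.

Supported dialects: GTF (1-based, inclusive), refFlat and BED12 (0-based,
half-open) for gene models; BED6 for probe sets, peaks and tag positions;
SAM (through pysam) for aligned tags.  Everything is converted to the
internal 0-based half-open convention on the way in and back to the dialect
convention on the way out, so read -> write -> read is the identity.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .genome_model import (
    GeneModel,
    GenomicInterval,
    Peak,
    ProbeSet,
    TagCollection,
)


class AnnotationParseError(ValueError):
    """Malformed record; the message names the offending line number."""

    def __init__(self, path: str | Path, lineno: int, reason: str):
        super().__init__(f"{path}:{lineno}: {reason}")
        self.lineno = lineno


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            yield lineno, line.split("\t")


def _int_field(path, lineno, fields, idx, what) -> int:
    try:
        return int(fields[idx])
    except (IndexError, ValueError):
        raise AnnotationParseError(path, lineno, f"bad {what} field") from None


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, format: str) -> list[GeneModel]:
    """Parse gene models from ``path`` in the named dialect.

    For GTF files holding several transcripts per gene, the transcript with
    the longest genomic span represents the gene.
    """
    readers = {"gtf": _read_gtf, "refflat": _read_refflat, "bed12": _read_bed12}
    try:
        reader = readers[format]
    except KeyError:
        raise ValueError(f"unknown annotation format {format!r}") from None
    return reader(path)


def _build_gene(path, lineno, gene_id, chrom, strand, exons) -> GeneModel:
    if not exons:
        raise AnnotationParseError(path, lineno, f"gene {gene_id} has zero exons")
    exons = sorted(exons)
    try:
        span = GenomicInterval(chrom, exons[0][0], exons[-1][1], strand)
        return GeneModel(
            gene_id,
            span,
            tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        )
    except ValueError as exc:
        raise AnnotationParseError(path, lineno, str(exc)) from None


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path: str | Path) -> list[GeneModel]:
    # keyed by (gene_id, transcript_id); longest-span transcript kept per gene
    transcripts: dict[tuple[str, str], dict] = {}
    for lineno, f in _data_lines(path):
        if len(f) < 9:
            raise AnnotationParseError(path, lineno, "GTF needs 9 fields")
        if f[2] != "exon":
            continue
        start = _int_field(path, lineno, f, 3, "start") - 1  # 1-based -> 0-based
        end = _int_field(path, lineno, f, 4, "end")
        attrs = dict(_GTF_ATTR.findall(f[8]))
        gene_id = attrs.get("gene_id")
        if gene_id is None:
            raise AnnotationParseError(path, lineno, "missing gene_id attribute")
        tx = attrs.get("transcript_id", gene_id)
        rec = transcripts.setdefault(
            (gene_id, tx),
            {"chrom": f[0], "strand": f[6], "exons": [], "lineno": lineno},
        )
        if rec["chrom"] != f[0] or rec["strand"] != f[6]:
            raise AnnotationParseError(
                path, lineno, f"transcript {tx} spans chroms/strands"
            )
        rec["exons"].append((start, end))

    best: dict[str, dict] = {}
    for (gene_id, _tx), rec in transcripts.items():
        span = max(e for _, e in rec["exons"]) - min(s for s, _ in rec["exons"])
        if gene_id not in best or span > best[gene_id]["span_len"]:
            best[gene_id] = {**rec, "span_len": span}
    return [
        _build_gene(path, rec["lineno"], gid, rec["chrom"], rec["strand"], rec["exons"])
        for gid, rec in best.items()
    ]


def _read_refflat(path: str | Path) -> list[GeneModel]:
    genes = []
    for lineno, f in _data_lines(path):
        if len(f) < 11:
            raise AnnotationParseError(path, lineno, "refFlat needs 11 fields")
        starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
        ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
        if len(starts) != len(ends):
            raise AnnotationParseError(path, lineno, "exonStarts/exonEnds mismatch")
        genes.append(
            _build_gene(path, lineno, f[0], f[2], f[3], list(zip(starts, ends)))
        )
    return genes


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    for lineno, f in _data_lines(path):
        if len(f) < 12:
            raise AnnotationParseError(path, lineno, "BED12 needs 12 fields")
        chrom_start = _int_field(path, lineno, f, 1, "chromStart")
        n_blocks = _int_field(path, lineno, f, 9, "blockCount")
        sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
        offsets = [int(x) for x in f[11].rstrip(",").split(",") if x]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise AnnotationParseError(path, lineno, "block fields disagree with blockCount")
        exons = [(chrom_start + o, chrom_start + o + s) for o, s in zip(offsets, sizes)]
        genes.append(_build_gene(path, lineno, f[3], f[0], f[5], exons))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path, format: str) -> None:
    writers = {"gtf": _write_gtf, "refflat": _write_refflat, "bed12": _write_bed12}
    writers[format](genes, path)


def _write_gtf(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for ex in g.exons:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write(
                    "\t".join(
                        [
                            ex.chrom,
                            "apashift",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def _write_refflat(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.gene_id,
                        g.span.chrom,
                        g.strand,
                        str(g.span.start),
                        str(g.span.end),
                        str(g.span.start),
                        str(g.span.end),
                        str(len(g.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def _write_bed12(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(len(e)) for e in g.exons) + ","
            offsets = ",".join(str(e.start - g.span.start) for e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.span.chrom,
                        str(g.span.start),
                        str(g.span.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.span.start),
                        str(g.span.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6: probes, peaks, tags


def _read_bed6_rows(path):
    for lineno, f in _data_lines(path):
        if len(f) < 6:
            raise AnnotationParseError(path, lineno, "BED6 needs 6 fields")
        start = _int_field(path, lineno, f, 1, "start")
        end = _int_field(path, lineno, f, 2, "end")
        yield lineno, f, start, end


def read_probes_bed(path: str | Path) -> list[ProbeSet]:
    """BED6 of probe-set target regions; the name field is the probe id."""
    probes = []
    for lineno, f, start, end in _read_bed6_rows(path):
        try:
            iv = GenomicInterval(f[0], start, end, f[5])
        except ValueError as exc:
            raise AnnotationParseError(path, lineno, str(exc)) from None
        probes.append(ProbeSet(probe_id=f[3], gene_id=None, target=iv))
    return probes


def write_probes_bed(probes: Sequence[ProbeSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            t = p.target
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{p.probe_id}\t0\t{t.strand}\n"
            )


def read_peaks_bed(path: str | Path) -> list[Peak]:
    """MACS-style peak BED; an optional 7th column holds the absolute summit."""
    peaks = []
    for lineno, f, start, end in _read_bed6_rows(path):
        summit = None
        if len(f) >= 7 and f[6] not in (".", ""):
            summit = _int_field(path, lineno, f, 6, "summit")
        try:
            score = float(f[4]) if f[4] != "." else 0.0
            peaks.append(Peak(GenomicInterval(f[0], start, end, "."), summit, score))
        except ValueError as exc:
            raise AnnotationParseError(path, lineno, str(exc)) from None
    return peaks


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            summit = "." if p.summit is None else str(p.summit)
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\tpeak_{i}\t{p.score:g}\t.\t{summit}\n"
            )


def read_tags_bed(path: str | Path, sample_id: str, total_mapped: int | None = None) -> TagCollection:
    """BED6 of aligned tags: the 5' end is ``start`` on +, ``end - 1`` on -.

    ``total_mapped`` defaults to the number of records in the file.
    """
    tags = []
    for _lineno, f, start, end in _read_bed6_rows(path):
        strand = f[5] if f[5] in ("+", "-") else "."
        pos5 = start if strand != "-" else end - 1
        tags.append((f[0], pos5, strand))
    return TagCollection(sample_id, tags, total_mapped or len(tags))


def write_tags_bed(tc: TagCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, pos, strand) in enumerate(tc.tags):
            s, e = (pos, pos + 1) if strand != "-" else (pos, pos + 1)
            fh.write(f"{chrom}\t{s}\t{e}\t{tc.sample_id}.{i}\t0\t{strand}\n")


def read_tags_sam(path: str | Path, sample_id: str) -> TagCollection:
    """Extract 5'-end positions of mapped primary alignments from a SAM file."""
    tags = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_reverse:
                tags.append((rec.reference_name, rec.reference_end - 1, "-"))
            else:
                tags.append((rec.reference_name, rec.reference_start, "+"))
    return TagCollection(sample_id, tags, max(len(tags), 1))
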