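"""ChIP-seq downstream statistics: metagene peak profile, promoter RPM/dRPM
scores, and the target-gene-set Z-test.

The metagene profile rescales every gene body to unit length and tallies the
percentage of peak anchors per 0.01-wide bin from TSS (0) to TTS (1).  RPM is
reads-per-million mapped reads whose 5' end falls in a window; dRPM is the
ChIP-minus-input RPM difference over the promoter window (<2 kb from the
TSS).  The gene-set test asks whether a target set's mean dRPM exceeds the
genome-wide distribution, with a one-sided upper-tail normal p-value.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genome_model import (
    GeneModel,
    GenomicInterval,
    Peak,
    TagCollection,
    normalized_position,
    promoter_window,
)


@dataclass
class MetageneProfile:
    """Percentage of peaks per normalized gene-body position bin."""

    bins: np.ndarray  # length round(1 / bin_width)
    bin_width: float = 0.01
    n_peaks_total: int = 0
    n_peaks_assigned: int = 0

    def mass(self, first_bin: int = 0, last_bin: int = 9) -> float:
        """Summed percentage over an inclusive bin range."""
        return float(self.bins[first_bin : last_bin + 1].sum())


def peak_anchor(p: Peak) -> int:
    """The single position a peak contributes: its summit, else midpoint."""
    if p.summit is not None:
        return p.summit
    return (p.interval.start + p.interval.end) // 2


def metagene_peak_profile(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    bin_width: float = 0.01,
    unique_assignment: bool = False,
) -> MetageneProfile:
    """Bin peak anchors over unit-normalized gene bodies.

    Every peak contributes once per gene whose span contains its anchor
    (overlapping genes each receive it; set ``unique_assignment`` to count a
    peak once, for the first containing gene).  Bin values are
    ``100 * count / n_peaks_total``, so peaks falling outside every gene
    dilute the profile rather than being renormalized away.
    """
    if not genes:
        raise ValueError("empty gene list")
    n_bins = round(1.0 / bin_width)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.span.chrom, IntervalTree()).addi(
            g.span.start, g.span.end, g
        )
    counts = np.zeros(n_bins)
    assigned = 0
    for p in peaks:
        anchor = peak_anchor(p)
        hits = trees.get(p.interval.chrom, IntervalTree()).at(anchor)
        for iv in sorted(hits, key=lambda iv: iv.data.gene_id):
            g = iv.data
            b = min(int(normalized_position(g, anchor) / bin_width), n_bins - 1)
            counts[b] += 1
            assigned += 1
            if unique_assignment:
                break
    total = len(peaks)
    bins = 100.0 * counts / total if total else counts
    return MetageneProfile(
        bins=bins,
        bin_width=bin_width,
        n_peaks_total=total,
        n_peaks_assigned=assigned,
    )


def tags_to_point_peaks(tc: TagCollection) -> list[Peak]:
    """View each tag 5' position as a 1-bp peak (diagnostic density profile)."""
    return [
        Peak(GenomicInterval(chrom, pos, pos + 1, "."), summit=pos)
        for chrom, pos, _strand in tc.tags
    ]


class _TagIndex:
    """Per-chromosome sorted position arrays for O(log n) window counts."""

    def __init__(self, tc: TagCollection):
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos, _strand in tc.tags:
            by_chrom.setdefault(chrom, []).append(pos)
        self.positions = {c: sorted(p) for c, p in by_chrom.items()}
        self.total_mapped = tc.total_mapped

    def count(self, w: GenomicInterval) -> int:
        pos = self.positions.get(w.chrom, [])
        return bisect_left(pos, w.end) - bisect_left(pos, w.start)


def rpm_in_window(tags: TagCollection | _TagIndex, w: GenomicInterval) -> float:
    """Reads-per-million whose 5' position lies in ``w`` (strand-blind)."""
    idx = tags if isinstance(tags, _TagIndex) else _TagIndex(tags)
    if idx.total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return 1e6 * idx.count(w) / idx.total_mapped


@dataclass(frozen=True)
class PromoterScore:
    """Promoter-window ChIP signal of one gene: RPM and the input-corrected
    dRPM = rpm_chip - rpm_input."""

    gene_id: str
    rpm_chip: float
    rpm_input: float

    @property
    def drpm(self) -> float:
        return self.rpm_chip - self.rpm_input


def drpm_scores(
    chip: TagCollection,
    input_: TagCollection,
    genes: Iterable[GeneModel],
    radius: int = 2000,
) -> list[PromoterScore]:
    """Per-gene promoter dRPM: ChIP RPM minus input RPM in the symmetric
    promoter window of each gene."""
    chip_idx = _TagIndex(chip)
    input_idx = _TagIndex(input_)
    scores = []
    for g in genes:
        w = promoter_window(g, radius)
        scores.append(
            PromoterScore(
                g.gene_id,
                rpm_in_window(chip_idx, w),
                rpm_in_window(input_idx, w),
            )
        )
    return scores


@dataclass(frozen=True)
class GeneSetZResult:
    """Z statistic of a target set's mean dRPM against the genome-wide dRPM
    distribution, with the one-sided upper-tail normal p-value."""

    z: float
    p: float
    n_targets: int
    n_all: int


def upper_tail_p(z: float) -> float:
    """One-sided upper-tail standard-normal p-value, 1 - Phi(z)."""
    return float(stats.norm.sf(z))


def geneset_ztest(
    target_drpm: Sequence[float], all_drpm: Sequence[float]
) -> GeneSetZResult:
    """Test whether the target genes' mean dRPM is high relative to all genes.

    z = (mean(target) - mean(all)) / (sd(all)/sqrt(n_targets)) with the
    genome-wide sample standard deviation (ddof=1) as the null spread;
    p is the upper-tail normal probability.
    """
    target = np.asarray(target_drpm, float)
    allv = np.asarray(all_drpm, float)
    if len(target) < 2:
        raise ValueError("need at least 2 target genes")
    if len(allv) <= len(target):
        raise ValueError("background must be larger than the target set")
    sd = allv.std(ddof=1)
    if sd == 0:
        raise ValueError("zero genome-wide dRPM standard deviation")
    z = (target.mean() - allv.mean()) / (sd / np.sqrt(len(target)))
    return GeneSetZResult(float(z), upper_tail_p(z), len(target), len(allv))


def profile_delta(
    control: MetageneProfile,
    treated: MetageneProfile,
    first_bin: int = 0,
    last_bin: int = 9,
) -> float:
    """Control-minus-treated peak mass over a bin range (default: the first
    10% of the gene body, the 5' region where the profile peaks)."""
    if control.bin_width != treated.bin_width or len(control.bins) != len(treated.bins):
        raise ValueError("profiles have mismatched binning")
    return control.mass(first_bin, last_bin) - treated.mass(first_bin, last_bin)


def write_profile_tsv(profile: MetageneProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tpercent\n")
        for k, v in enumerate(profile.bins):
            fh.write(f"{k * profile.bin_width:.2f}\t{v:.6g}\n")


def write_promoter_scores_tsv(scores: Sequence[PromoterScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trpm_chip\trpm_input\tdrpm\n")
        for s in scores:
            fh.write(f"{s.gene_id}\t{s.rpm_chip:.6g}\t{s.rpm_input:.6g}\t{s.drpm:.6g}\n")
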