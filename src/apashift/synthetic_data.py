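"""Seeded generator of synthetic inputs for every pipeline stage.

Emulates a 3'-biased expression-array knockdown study (two knockdown
conditions against one control, two independent experiments, MAS5-like
positive signals with present/marginal/absent calls) together with matching
ChIP-seq tag sets and peak calls showing tunable 5'-promoter enrichment.
Ground truth (which genes truly shift polyadenylation-site usage, which are
5'-enriched, the enrichment fraction used) is emitted alongside the data so
recovery can be scored exactly.

Isoform model: the distal probe of a gene sees only the long (distal-site)
isoform, the proximal probe sees all isoforms.  A true target expresses the
long isoform at ``distal_fraction_control`` of total in controls and at
``distal_fraction_kd`` under knockdown, so with no noise its distal/proximal
double ratio is exactly ``distal_fraction_kd / distal_fraction_control``
while the proximal signal stays flat — the signature the array pipeline is
built to detect.  Multiplicative lognormal noise (normal with sd
``log2_noise_sd`` in log2 space) is applied per probe and sample.

All randomness flows from ``SimConfig.seed`` through independent numpy
Generator streams per stage; a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_io
from .apa_array import ExpressionMatrix
from .genome_model import GeneModel, GenomicInterval, Peak, ProbeSet, TagCollection


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulator, with study-like defaults.

    Expression: 200 genes, 20% true targets whose distal-isoform fraction
    drops 0.6 -> 0.2 under knockdown, log2 noise sd 0.15, two experiments.
    ChIP: 1e5 tags per sample; under the control condition 60% of ChIP tags
    fall within +/-1 kb of an enriched (target) gene's TSS, reduced to 30%
    under knockdown; input tags are uniform.
    """

    seed: int = 0
    # genes
    n_genes: int = 200
    n_chromosomes: int = 4
    gene_length_range: tuple[int, int] = (9000, 20000)
    min_last_exon: int = 3000
    gap_range: tuple[int, int] = (2000, 8000)
    # probes / expression
    n_distal_probes_range: tuple[int, int] = (1, 2)
    frac_target_genes: float = 0.2
    distal_fraction_control: float = 0.6
    distal_fraction_kd: float = 0.2
    log2_noise_sd: float = 0.15
    n_experiments: int = 2
    kd_conditions: tuple[str, ...] = ("kd1", "kd2")
    baseline_log2_range: tuple[float, float] = (7.0, 12.0)
    frac_silent_probes: float = 0.0
    call_absent_below: float = 32.0
    call_marginal_below: float = 64.0
    # ChIP
    chip_total_tags: int = 100_000
    input_total_tags: int = 100_000
    five_prime_fraction: float = 0.6
    five_prime_fraction_kd: float = 0.3
    nonspecific_tss_fraction: float = 0.3
    promoter_weight_log2_sd: float = 1.0
    tss_window: int = 1000
    n_background_peaks: int = 20

    def __post_init__(self) -> None:
        for name in (
            "frac_target_genes",
            "distal_fraction_control",
            "distal_fraction_kd",
            "five_prime_fraction",
            "five_prime_fraction_kd",
            "frac_silent_probes",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


@dataclass
class SimTruth:
    """Ground truth emitted next to the simulated data."""

    is_true_target: dict[str, bool] = field(default_factory=dict)
    true_distal_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    five_prime_fraction: dict[str, float] = field(default_factory=dict)
    silent_probes: list[str] = field(default_factory=list)

    @property
    def target_gene_ids(self) -> list[str]:
        return [g for g, t in self.is_true_target.items() if t]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "is_true_target": self.is_true_target,
                    "true_distal_fractions": self.true_distal_fractions,
                    "five_prime_fraction": self.five_prime_fraction,
                    "silent_probes": sorted(self.silent_probes),
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["is_true_target"],
            d["true_distal_fractions"],
            d["five_prime_fraction"],
            d["silent_probes"],
        )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_genes(cfg: SimConfig) -> list[GeneModel]:
    """Non-overlapping multi-exon genes on synthetic chromosomes.

    2-4 exons per gene, mixed strands, and a terminal exon of at least
    ``min_last_exon`` bp (real 3'-shifted genes carry long terminal exons,
    and the probe layout needs the room)."""
    rng = _rng(cfg, 0)
    genes: list[GeneModel] = []
    cursors = {f"chrS{i + 1}": 1000 for i in range(cfg.n_chromosomes)}
    chroms = list(cursors)
    for i in range(cfg.n_genes):
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        terminal = int(rng.integers(cfg.min_last_exon, cfg.min_last_exon + 2000))
        other = [int(rng.integers(200, 1000)) for _ in range(n_exons - 1)]
        introns = [int(rng.integers(500, 3000)) for _ in range(n_exons - 1)]
        # transcript order: other exons then the long terminal exon
        sizes_tx = other + [terminal]
        sizes_genomic = sizes_tx if strand == "+" else sizes_tx[::-1]
        introns_genomic = introns if strand == "+" else introns[::-1]
        start = cursors[chrom]
        exons = []
        pos = start
        for k, size in enumerate(sizes_genomic):
            exons.append(GenomicInterval(chrom, pos, pos + size, strand))
            pos += size
            if k < len(introns_genomic):
                pos += introns_genomic[k]
        span = GenomicInterval(chrom, start, exons[-1].end, strand)
        length = len(span)
        lo, hi = cfg.gene_length_range
        if length < lo:  # pad the intron before the terminal exon
            raise_by = lo - length
            if strand == "+":
                exons[-1] = GenomicInterval(
                    chrom, exons[-1].start + raise_by, exons[-1].end + raise_by, strand
                )
            else:
                exons = [exons[0]] + [
                    GenomicInterval(chrom, e.start + raise_by, e.end + raise_by, strand)
                    for e in exons[1:]
                ]
            span = GenomicInterval(chrom, start, exons[-1].end, strand)
        if len(span) > hi:
            raise ValueError(
                f"infeasible packing: gene length {len(span)} exceeds range {cfg.gene_length_range}"
            )
        genes.append(GeneModel(f"gene{i + 1:04d}", span, tuple(exons)))
        cursors[chrom] = span.end + int(rng.integers(*cfg.gap_range))
    return genes


def chromosome_sizes(genes: list[GeneModel], margin: int = 5000) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.span.chrom] = max(sizes.get(g.span.chrom, 0), g.span.end + margin)
    return sizes


def select_target_genes(genes: list[GeneModel], cfg: SimConfig) -> list[str]:
    """The seeded true-target subset, shared by the expression and ChIP
    stages so that APA-shifted genes are also the 5'-enriched ones."""
    rng = _rng(cfg, 9)
    n = round(cfg.frac_target_genes * len(genes))
    idx = rng.permutation(len(genes))[:n]
    return sorted(genes[i].gene_id for i in idx)


def simulate_probes(genes: list[GeneModel], cfg: SimConfig) -> list[ProbeSet]:
    """One proximal + 1-2 distal probe sets in each gene's terminal exon.

    The proximal probe sits in the most 5' 200 bp of the last exon
    (transcript orientation); distal probes are spaced downstream."""
    from .genome_model import last_exon

    rng = _rng(cfg, 1)
    probes: list[ProbeSet] = []
    for g in genes:
        le = last_exon(g)
        n_distal = int(rng.integers(cfg.n_distal_probes_range[0], cfg.n_distal_probes_range[1] + 1))
        offsets = [50] + [800 + 900 * k for k in range(n_distal)]
        names = [f"{g.gene_id}_prox"] + [f"{g.gene_id}_dist{k + 1}" for k in range(n_distal)]
        for name, off in zip(names, offsets):
            if g.strand == "+":
                iv = GenomicInterval(le.chrom, le.start + off, le.start + off + 200, "+")
            else:
                iv = GenomicInterval(le.chrom, le.end - off - 200, le.end - off, "-")
            probes.append(ProbeSet(name, g.gene_id, iv))
    return probes


def _detection_call(signal: float, cfg: SimConfig) -> str:
    if signal < cfg.call_absent_below:
        return "A"
    if signal < cfg.call_marginal_below:
        return "M"
    return "P"


def simulate_expression(
    genes: list[GeneModel], probes: list[ProbeSet], cfg: SimConfig
) -> tuple[ExpressionMatrix, SimTruth]:
    """Linear-scale MAS5-like signal matrix with detection calls.

    Sample grid: (control + knockdown conditions) x experiments.  A true
    target's distal probes read ``baseline * distal_fraction_kd`` under
    knockdown instead of ``baseline * distal_fraction_control`` — an
    apparent downregulation caused purely by the shift to the proximal
    site — while proximal probes read the (unchanged) total.  A small
    seeded fraction of probes is silent (near-floor signal, absent call)
    to exercise expression filtering and curation.
    """
    rng = _rng(cfg, 2)
    targets = set(select_target_genes(genes, cfg))
    conditions = ["control", *cfg.kd_conditions]
    sample_ids, meta = [], []
    for exp in range(1, cfg.n_experiments + 1):
        for cond in conditions:
            sample_ids.append(f"{cond}_e{exp}")
            meta.append({"condition": cond, "experiment": exp})
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))

    truth = SimTruth()
    baselines = {
        g.gene_id: float(2.0 ** rng.uniform(*cfg.baseline_log2_range)) for g in genes
    }
    for g in genes:
        is_t = g.gene_id in targets
        truth.is_true_target[g.gene_id] = is_t
        truth.true_distal_fractions[g.gene_id] = {
            c: (
                cfg.distal_fraction_kd
                if (is_t and c != "control")
                else cfg.distal_fraction_control
            )
            for c in conditions
        }

    silent = set()
    for p in probes:
        if rng.random() < cfg.frac_silent_probes:
            silent.add(p.probe_id)
    truth.silent_probes = sorted(silent)

    sig = np.empty((len(probes), len(sample_ids)))
    for i, p in enumerate(probes):
        base = baselines[p.gene_id]
        is_distal = not p.probe_id.endswith("_prox")
        for j, sid in enumerate(sample_ids):
            cond = samples.loc[sid, "condition"]
            noise = (
                2.0 ** rng.normal(0.0, cfg.log2_noise_sd)
                if cfg.log2_noise_sd > 0
                else 1.0
            )
            if p.probe_id in silent:
                sig[i, j] = 2.0 ** rng.uniform(2.0, 4.0) * noise
            elif is_distal:
                frac = truth.true_distal_fractions[p.gene_id][cond]
                sig[i, j] = base * frac * noise
            else:
                sig[i, j] = base * noise
    index = pd.Index([p.probe_id for p in probes], name="probe_id")
    signals = pd.DataFrame(sig, index=index, columns=sample_ids)
    calls = signals.map(lambda v: _detection_call(v, cfg))
    calls[signals.index.isin(silent)] = "A"
    return ExpressionMatrix(signals, calls, samples, scale="linear"), truth


def simulate_chip_tags(
    genes: list[GeneModel], cfg: SimConfig, condition: str = "control"
) -> tuple[TagCollection, TagCollection, SimTruth]:
    """ChIP and input tag sets with controllable TSS enrichment.

    ChIP tags fall into three pools:

    * *specific recruitment* — a fraction f of tags
      (``five_prime_fraction`` for control, ``five_prime_fraction_kd``
      otherwise) lands uniformly within +/-``tss_window`` of a target
      gene's TSS.  This is the factor's knockdown-sensitive signal, so a
      promoter dRPM gene-set test on the target set has real signal to
      find and loses it as f drops.
    * *nonspecific promoter background* — a condition-independent fraction
      (``nonspecific_tss_fraction``) lands near the TSS of a random gene,
      any gene, with a fixed per-gene lognormal binding propensity
      (``promoter_weight_log2_sd``).  This puts an f-independent spread
      into the genome-wide dRPM distribution; without it every dRPM would
      scale with f and the gene-set Z statistic, a mean shift over that
      spread, would be blind to the knockdown.
    * the remainder, and all input tags, uniform over the synthetic genome.
    """
    from .genome_model import gene_anchors

    stream = 3 if condition == "control" else 4
    rng = _rng(cfg, stream)
    f = (
        cfg.five_prime_fraction
        if condition == "control"
        else cfg.five_prime_fraction_kd
    )
    if f + cfg.nonspecific_tss_fraction > 1.0:
        raise ValueError("five_prime + nonspecific_tss fractions exceed 1")
    enriched = select_target_genes(genes, cfg)
    tss = {g.gene_id: (g.span.chrom, gene_anchors(g)[0]) for g in genes}
    sizes = chromosome_sizes(genes)
    chroms = sorted(sizes)
    lengths = np.array([sizes[c] for c in chroms], float)
    probs = lengths / lengths.sum()
    # per-gene nonspecific binding propensity, shared by all conditions
    w = 2.0 ** _rng(cfg, 8).normal(0.0, cfg.promoter_weight_log2_sd, len(genes))
    w /= w.sum()

    def uniform_tags(n: int, gen: np.random.Generator):
        chrom_idx = gen.choice(len(chroms), size=n, p=probs)
        frac = gen.random(n)
        strands = np.where(gen.random(n) < 0.5, "+", "-")
        return [
            (chroms[ci], int(frac[i] * sizes[chroms[ci]]), strands[i])
            for i, ci in enumerate(chrom_idx)
        ]

    def tss_tags(n: int, gene_ids: list[str], p, gen: np.random.Generator):
        if n == 0 or not gene_ids:
            return []
        picks = gen.choice(len(gene_ids), size=n, p=p)
        offs = gen.integers(-cfg.tss_window, cfg.tss_window, size=n)
        strands = np.where(gen.random(n) < 0.5, "+", "-")
        out = []
        for i, (gi, off) in enumerate(zip(picks, offs)):
            chrom, t = tss[gene_ids[gi]]
            pos = int(min(max(0, t + off), sizes[chrom] - 1))
            out.append((chrom, pos, strands[i]))
        return out

    n_specific = int(round(f * cfg.chip_total_tags)) if enriched else 0
    n_nonspecific = int(round(cfg.nonspecific_tss_fraction * cfg.chip_total_tags))
    chip_tags = tss_tags(n_specific, enriched, None, rng)
    chip_tags.extend(tss_tags(n_nonspecific, [g.gene_id for g in genes], w, rng))
    chip_tags.extend(
        uniform_tags(cfg.chip_total_tags - n_specific - n_nonspecific, rng)
    )
    input_tags = uniform_tags(cfg.input_total_tags, _rng(cfg, 5))

    truth = SimTruth(
        is_true_target={g.gene_id: g.gene_id in set(enriched) for g in genes},
        five_prime_fraction={condition: f},
    )
    chip = TagCollection(f"chip_{condition}", chip_tags, cfg.chip_total_tags)
    inp = TagCollection("input", input_tags, cfg.input_total_tags)
    return chip, inp, truth


def simulate_peaks(
    genes: list[GeneModel], cfg: SimConfig, condition: str = "control"
) -> list[Peak]:
    """Peak calls emitted directly (peak calling itself is upstream of this
    package): promoter peaks at a deterministic ``round(f * n_enriched)``
    subset of the enriched genes — peak detectability scales with the
    enrichment fraction f, and the detected subset is nested across f so the
    5' profile mass is monotone in f — plus a fixed number of uniform
    background peaks shared by all conditions."""
    f = (
        cfg.five_prime_fraction
        if condition == "control"
        else cfg.five_prime_fraction_kd
    )
    enriched = select_target_genes(genes, cfg)
    order = _rng(cfg, 6).permutation(len(enriched))
    n_detected = int(round(f * len(enriched)))
    by_id = {g.gene_id: g for g in genes}
    peaks = []
    from .genome_model import gene_anchors

    for oi in order[:n_detected]:
        g = by_id[enriched[oi]]
        t, _ = gene_anchors(g)
        summit = t if g.strand == "+" else t - 1  # first transcribed base
        lo = max(0, t - cfg.tss_window)
        peaks.append(Peak(GenomicInterval(g.span.chrom, lo, t + cfg.tss_window, "."), summit))
    sizes = chromosome_sizes(genes)
    chroms = sorted(sizes)
    rng_bg = _rng(cfg, 7)
    for _ in range(cfg.n_background_peaks):
        chrom = chroms[int(rng_bg.integers(0, len(chroms)))]
        center = int(rng_bg.integers(300, sizes[chrom] - 300))
        peaks.append(Peak(GenomicInterval(chrom, center - 300, center + 300, "."), center))
    return peaks


def simulate_dataset(cfg: SimConfig):
    """Convenience: genes, probes, expression matrix and truth in one call."""
    genes = simulate_genes(cfg)
    probes = simulate_probes(genes, cfg)
    expr, truth = simulate_expression(genes, probes, cfg)
    return genes, probes, expr, truth


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit the full synthetic study to ``outdir`` as plain-text files and
    return the path map."""
    from .apa_array import write_expression

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes, probes, expr, truth = simulate_dataset(cfg)
    paths = {
        "genes": out / "genes.bed12",
        "probes": out / "probes.bed",
        "signals": out / "signals.tsv",
        "calls": out / "calls.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
        "config": out / "sim_config.json",
    }
    annotation_io.write_gene_models(genes, paths["genes"], "bed12")
    annotation_io.write_probes_bed(probes, paths["probes"])
    write_expression(expr, paths["signals"], paths["calls"], paths["samples"])
    for condition in ("control", "kd"):
        chip, inp, chip_truth = simulate_chip_tags(genes, cfg, condition)
        truth.five_prime_fraction.update(chip_truth.five_prime_fraction)
        paths[f"chip_tags_{condition}"] = out / f"chip_tags_{condition}.bed"
        annotation_io.write_tags_bed(chip, paths[f"chip_tags_{condition}"])
        peaks = simulate_peaks(genes, cfg, condition)
        paths[f"peaks_{condition}"] = out / f"peaks_{condition}.bed"
        annotation_io.write_peaks_bed(peaks, paths[f"peaks_{condition}"])
    chip, inp, _ = simulate_chip_tags(genes, cfg, "control")
    paths["input_tags"] = out / "input_tags.bed"
    annotation_io.write_tags_bed(inp, paths["input_tags"])
    truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True)
    return paths
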