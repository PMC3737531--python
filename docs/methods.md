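# Methods

## Scope and model

`apashift` quantifies shifts in alternative polyadenylation (APA) site
usage from 3′-biased expression arrays, and the promoter association of a
3′-end processing factor from ChIP-seq, for a knockdown-versus-control
design. The package takes summarized inputs — probe-level signals with
MAS5-style detection calls, gene annotation, probe/peak/tag coordinates —
and implements everything downstream: normalization, screening, the
distal/proximal ratio statistic, metagene profiling, promoter dRPM scoring,
the gene-set Z-test, and validation-assay arithmetic. Array summarization,
read alignment and peak calling are upstream of this package and are
consumed as files.

### Array statistic

The key assumption is the probe geometry of a 3′-biased array: in a gene's
terminal exon, the probe set targeting the most 5′ region (the *proximal*
probe) hybridizes to every isoform, while probe sets downstream of the
proximal polyadenylation site (*distal* probes) hybridize only to
long-3′-UTR isoforms. For distal probe *d* and knockdown condition *k*,

    dp(d, k) = [ s_k(d) / s_k(prox) ] / [ s_ctrl(d) / s_ctrl(prox) ]

where the signals are linear-scale means over the condition's samples
(both experiments). The inner divisions cancel per-sample scale, the outer
division cancels probe affinity, so dp is a pure usage ratio: dp < 1 means
the knockdown reduced usage of the distal site adjacent to *d*. A gene is
called `distal_selective` when every retained distal probe satisfies
dp < 1 − margin while the proximal probe's own knockdown/control ratio is
≥ 1 − margin (proximal-site output unaffected or increased — the signature
of a usage shift rather than plain downregulation).

**Margin.** The default margin is 0.2. A literal strict reading (dp < 1,
proximal ≥ 1, margin 0) makes the proximal gate a coin flip: the proximal
ratio of a true APA-shifted gene is centred on exactly 1, so any noise
fails half of them. Under multiplicative noise of sd 0.15 in log2 (typical
inter-replicate array noise, and the generator's default), the log2 of a
per-gene condition ratio has sd ≈ 0.15, and 1 − 2^(−2·0.15) ≈ 0.19;
margin 0.2 therefore treats deviations within about two noise standard
deviations of 1 as "unchanged". Set `margin=0` to recover the strict rule.

**Candidate screen.** Downregulation is screened per probe on the
normalized (log2, 75-percentile-shifted) scale: mean(kd) − mean(control)
≤ −1 (at least 2-fold, inclusive) with a two-sided equal-variance Student
*t*-test *p* < 0.2 across the experiments' values; a gene is a candidate if
any of its probes passes. With two experiments per group the *t*-test is
deliberately coarse — the permissive 0.2 cutoff reflects that this is a
screen, not an inference. Zero-variance probes give t = ±∞, p = 0 and are
kept if the fold criterion holds. Note that percentile-shift normalization
partially absorbs broad downregulation: if a large fraction of probes is
truly down, each knockdown sample's 75th percentile drops and measured
fold-changes shrink toward 0. The screen's contract therefore starts from
normalized data, and the dp ratio itself is immune (per-sample shifts
cancel).

**Expression filter and curation.** "Insignificantly expressed" probes are
removed by a deterministic, logged rule — detection call `present` in at
least half of the control samples (fraction configurable) — replacing
manual curation. Curation then drops unexpressed probe entries, keeps the
proximal→distal ordering, removes genes left without a proximal and at
least one distal probe, and reports every count in a JSON log, so the
step is auditable.

### ChIP statistics

The metagene profile rescales every gene body to [0, 1] (TSS = 0, TTS = 1,
strand-aware) and tallies the percentage of peak *anchors* per 0.01-wide
bin. The anchor is the peak summit when present, else the interval
midpoint. A peak whose anchor falls inside several overlapping genes
contributes to each (a `unique_assignment` switch counts it once); the
denominator is always the total number of peaks, so peaks outside genes
dilute the profile rather than vanish.

Promoter occupancy is RPM — 10⁶ × (tags whose 5′ end falls in the window)
/ (total mapped reads) — in a symmetric ±2 kb window around the TSS
(clipped at coordinate 0). The window is symmetric because "within 2 kb of
the TSS" does not specify a direction and occupancy, not transcription, is
being measured; tag strand is ignored for the same reason. Reads are
counted at their 5′ position with no fragment-shift or extension. dRPM is
RPM(ChIP) − RPM(input).

The gene-set test uses z = (mean(target dRPM) − mean(all dRPM)) /
(sd(all)/√n_targets) with the genome-wide sample sd (ddof = 1) and targets
included in the background, and reports the one-sided upper-tail normal
p-value 1 − Φ(z). The tail convention is pinned by test: the two published
(z, P) reference pairs (1.660419 → 0.04841509, 1.103570 → 0.13488977)
reproduce to 1e−6 only under the upper-tail reading. Alternative Z
constructions (population sd, target-excluded background) change z by
O(1/n) factors and are not distinguishable from the printed pairs alone.

### Validation-assay arithmetic

ChIP-PCR efficiency is (V_ChIP − V_control)/V_input (may legitimately be
negative). Band quantification converts per-replicate distal/proximal
intensity ratios to percent of the control group's mean ratio, per assay,
so the control group averages 100 by construction. The shared two-sample
Student *t*-test is equal-variance with df = n₁ + n₂ − 2; zero pooled
variance degenerates to p = 1 (equal means) or p = 0 (flagged).

## Coordinate and I/O conventions

All internal coordinates are 0-based, half-open; GTF (1-based inclusive)
is converted at the reader boundary. When a GTF holds several transcripts
per gene, the longest-spanning transcript represents the gene. On the
minus strand the TSS anchor is `span.end` (the first transcribed base is
`span.end − 1`), so |TSS − TTS| equals gene length on both strands, and
`normalized_position` uses (end − 1 − pos)/length so positions map into
[0, 1) symmetrically with the plus strand. Probe-to-gene assignment is by
strand-aware span overlap; multi-gene overlaps are resolved to the unique
gene whose last exon the probe hits, otherwise the probe is excluded and
counted. Parsers raise errors naming the offending line number; the small
BED/refFlat/GTF-exon readers are written in-package so this diagnostic
contract holds and write→read round-trips are exact.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: three
conditions (one control, two knockdowns) × two independent experiments on
a 3′ array, plus ChIP/input tag sets and peak calls per condition. All
randomness flows from a single seed through fixed, independent generator
streams, so a given configuration is byte-reproducible.

Defaults (the simulated study conditions): 200 non-overlapping genes on 4
chromosomes, 2–4 exons, terminal exon ≥ 3 kb (APA-regulated genes carry
long terminal exons, and the probe layout needs the room), gene length
9–20 kb; one proximal + 1–2 distal probes per gene; 20% true target genes
whose distal-isoform fraction drops 0.6 → 0.2 under both knockdowns;
linear baseline 2^U(7,12) per gene; multiplicative lognormal noise with
log2 sd 0.15 per probe×sample; detection calls absent < 32, marginal < 64.
Distal probes read baseline × distal fraction (long isoform only);
proximal probes read the baseline (all isoforms). A true target thus shows
*apparent* downregulation at its distal probes — fold 0.2/0.6 = 3× — with
an unchanged proximal probe, which is exactly the footprint the pipeline
detects, and with zero noise every downstream statistic is analytically
exact (dp = 1 for non-targets; dp = fraction ratio for targets). An
optional `frac_silent_probes` (default 0) injects near-floor, absent-called
probes to exercise the expression filter and curation.

ChIP tags (10⁵ per sample by default) fall into three pools: a
knockdown-sensitive *specific* fraction f (0.6 control, 0.3 knockdown)
placed uniformly within ±1 kb of target-gene TSSs; a condition-independent
*nonspecific promoter background* (fraction 0.3) placed near the TSS of
any gene with a fixed per-gene lognormal propensity (log2 sd 1); and a
uniform genomic remainder. Input tags are uniform. The nonspecific pool is
load-bearing: if every promoter count scaled with f, the gene-set Z — a
mean shift measured against the genome-wide spread — would be invariant to
f (numerator and denominator scale together). The fixed background gives
the dRPM distribution an f-independent component, so z rises strictly with
f and falls under knockdown, as a real antibody background does. Peak
calls are emitted directly (peak calling is upstream of this package):
promoter peaks at a deterministic round(f × n_targets) subset of target
TSSs — detectability scales with enrichment, and the subset is nested
across f so the 5′ profile mass is strictly monotone in f — plus a fixed
set of background peaks shared by conditions.

What the generator does **not** model: probe sequence affinity and
cross-hybridization, intensity-dependent (heteroscedastic) array noise,
partial isoform overlap of probes, fragment-length effects and chromatin
accessibility bias in ChIP, read mappability, and overlapping genes.
Passing recovery tests therefore demonstrates that the statistics are
implemented correctly and behave as designed under controlled conditions —
not that the pipeline's operating characteristics transfer quantitatively
to any particular real dataset.

## Numerical choices and problem sizes

Percentile-shift normalization uses linear-interpolation quantiles; ties
and degenerate inputs follow numpy conventions. Ratios are computed on the
linear scale (log2 matrices are exponentiated first); nonpositive linear
signals are rejected at construction. Metagene bin indices are
floor(position/0.01) clipped to bin 99. Window tag counting uses sorted
per-chromosome arrays with binary search; overlap queries use interval
trees. The test suite and the acceptance script run on 200-gene, 10⁵-tag
simulations — large enough for stable recovery statistics (binomial sd of
a 0.95 rate over 40 targets ≈ 0.03) while the full suite completes in a
few seconds.

## Known limitations

- The per-gene APA call is a threshold rule, not a formal test; no
  multiple-testing control is applied (mirroring the screen-then-curate
  design it implements).
- The gene-set Z-test treats genes as independent and the genome-wide dRPM
  spread as the null scale; correlated promoter occupancy would make the
  printed p-values anti-conservative.
- `two_sample_ttest`'s one-sided variant is oriented toward
  mean(a) > mean(b).
- Published headline counts from the original screen depend on
  manually curated probe annotations and the underlying raw datasets, and
  are not recomputable from code alone; the acceptance script instead
  reports exact-oracle, recovery and determinism quantities computed from
  generated data.
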