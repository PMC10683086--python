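# Methods

## Scope and data model

`ecckit` operates on called eccDNA records: genomic intervals
(0-based, half-open, BED convention) with per-sample read counts. It
does not process reads; trimming, alignment, and circle calling are
upstream concerns. Display identifiers ("chr1: 48305638-48307008") are
1-based inclusive, the convention used when naming individual circles;
conversion is `display_start = start + 1`, `display_end = end`.
Duplicate intervals within one sample are merged by summing counts: a
circle's identity is its coordinate pair. Records on chromosomes
absent from the supplied genome are dropped with a warning rather than
failing, so partial/toy genomes work.

## Characterization

**GC content** is computed on the reference span of each record with N
bases excluded from numerator and denominator; the circle consists of
the same bases as its span (the junction only reorders them), so span
GC equals circle GC. An all-N span yields NaN and is excluded from
summaries.

**Size statistics**: median and p75 use linear interpolation between
order statistics (the type-7 quantile convention) so values are
reproducible bit for bit. The length histogram uses 10 bp bins by
default; peaks are local maxima of the Gaussian-smoothed histogram
(sd = 2 bins) with prominence ≥ 5% of the global maximum, reported as
bin centers. The histogram is zero-padded so a single-bin distribution
still yields its maximum. Binning, smoothing, and prominence are
config-exposed; peak positions are therefore resolved to one bin
(±10 bp at defaults).

**Two-group comparisons** use the two-sided Wilcoxon rank-sum test on
per-record values pooled within group: exact enumeration of rank
assignments when n₁+n₂ ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections. Degenerate inputs
(identical pooled values) return p = 1. The implementation is
cross-checked in the test suite against an independent reference to
1e-8.

## Chromosomal density and correlation

Density is circles per megabase per chromosome (1 Mb = 1e6 bp);
chromosomes with zero records are kept with density 0, and nothing is
excluded by default (an exclusion list, e.g. for chrM, is
config-exposed). Feature density counts annotation *intervals*, not
covered bases, and does not merge overlaps — one annotation record is
one element. Pearson R is the sample correlation with the two-sided
p-value from t = R·√((n−2)/(1−R²)) on n−2 df; zero variance is an
error, not a silent NaN.

## Normalized genomic coverage

Membership of a circle in an element class is decided by its **start
position only**, with half-open logic (a start on a merged-interval
boundary `[s, e)` is inside iff `s ≤ start < e`). The denominator is
the percent of genome bases covered by the **merged** class. Classes
are evaluated independently, with no precedence hierarchy — a start
can count for every class covering it, so per-class values are not
forced to sum to anything. Repeat classes instead attribute each
record's full read count to every class its interval overlaps by
≥ 1 bp; percentages may therefore sum to more than 100. This
eccDNA-count-based read attribution approximates read-level repeat
mapping and is documented as such.

## Junction motif analysis

Flanks of half-width w = 10 bp are taken at both the start and the end
coordinate from the reference plus strand only (interval callers emit
unstranded circles); records whose windows would cross a chromosome
edge are excluded and counted. Offsets are relative to the junction
coordinate (−w … w−1 for nucleotides, −w … w−3 for trinucleotide
window starts). The expected trinucleotide frequency is the
genome-wide overlapping 3-mer frequency with N-containing windows
skipped — the simplest defensible background; a floor of 1e-6 guards
division for trinucleotides absent from small toy genomes. Start, end,
and pooled profiles are all reported. The spacer scan scores a
trinucleotide t at offsets (i, i+3+s) as
min(enrichment(i,t), enrichment(i+3+s,t)) — both copies must be
enriched — and reports the best pair per spacer s in 0…8 and overall.

## Differential analysis

Counts are pooled within each group (one library per group), and each
eccDNA is tested with the pooled two-proportion z-test:
p̂ = (k₁+k₂)/(n₁+n₂), z = (k₁/n₁ − k₂/n₂)/√(p̂(1−p̂)(1/n₁+1/n₂)).
This targets the same binomial sampling null as MA-plot
random-sampling tests applied to grouped libraries. A degenerate p̂
(0 or 1) yields z = 0, p = 1. The log2 fold change is computed on
normalized proportions with a pseudocount of 0.5 applied to the counts
only in the fold change, never in the test statistic. Multiplicity is
handled by Benjamini–Hochberg step-up (the "q value"); Storey-style
estimation is a possible alternative but BH is the default and the
only implemented method. Significance requires both |log2FC| ≥ 1
(fold ≥ 2 or ≤ −2, i.e. reciprocal folds) and q < 0.001; "up" means a
higher normalized proportion in the first group of the sample sheet's
group order (young, by convention).

Because replicates are pooled, biological overdispersion between
replicates is **not** modeled: under negative-binomial replicate noise
the test is anti-conservative. This is a known property of this family
of tests and the reason the null-calibration checks in the acceptance
suite use Poisson (dispersion-0) counts — the sampling model the test
assumes — while power checks use overdispersed counts
(dispersion 0.1). A per-replicate NB GLM is out of scope; the test
function is pluggable should one be added.

## Conjoint analysis

A differential eccDNA maps to every gene whose body extended by 2 kb
flanks overlaps its interval by ≥ 1 bp (consistent with the
Gene2KbU/D annotation classes); this interval rule replaces
database-driven host-gene annotation and is an explicit, documented
choice. A (eccDNA, gene) pair is "shared" iff both sides are
significant and change in the same direction; distinct eccDNAs and
distinct genes are counted separately, and a gene hosting circles of
both directions counts once per matching side. The join is validated
end to end against the hypergeometric expectation under
direction-permutation nulls.

## Synthetic data generator

The generator is the testing backbone: it emulates the statistical
structure of an eccDNA study, not its molecular mechanism.

- **Genome**: per-chromosome i.i.d. nucleotides at a configured GC
  fraction (default 0.38–0.45 across four chromosomes of 0.8–1.2 Mb).
  Gene bodies (4 kb: 200 bp UTRs, alternating 200/400 bp
  exons/introns) and repeat elements (Alu 300 bp, CpG 500 bp,
  satellite 1 kb, LINE 800 bp, SINE 300 bp, LTR 500 bp, DNA 400 bp,
  simple repeat 150 bp) are placed uniformly without within-class
  overlap at configured per-Mb densities; Gene2KbU/D are the 2 kb gene
  flanks and may overlap neighboring genes (as in real genomes).
  Densities span a chr19-like (gene/Alu dense) to chr13-like (sparse)
  gradient.
- **Population**: lengths from a Gaussian mixture truncated at ≥ 50 bp
  (well above 2 × 10 bp flanks). The default four modes
  150/240/400/800 bp (weights 0.30/0.12/0.10/0.48, the last broad)
  give a dominant sharp peak at 150 bp, four detectable peaks, a
  median near 420 bp and essentially all circles < 1 kb. Chromosome
  choice is proportional to length × (1 + 0.05 × genes per Mb),
  inducing the positive density–gene-density correlation; start
  positions are drawn by rejection sampling with a per-class
  calibrated weight (below). Circles that would cross a chromosome end
  or the 50 bp edge margin are resampled, never emitted.
- **Enrichment calibration**: the estimand of normalized coverage for
  a class of mass q under a raw in-class weight f is f/(1+(f−1)q),
  not f. The generator therefore uses the calibrated weight
  w = f(1−q)/(1−fq), which makes the realized normalized coverage
  equal the requested fold exactly for a single class and to first
  order for overlapping classes (requires fq < 1; violations raise).
  With the default multi-class configuration (both gene flanks at 3,
  CpG at 0.5, plus gene-density chromosome weighting), interactions
  push the realized flank ratios slightly above 3 — visible in the
  demo report — which is expected and documented rather than
  corrected.
- **Junction motif**: for a configured fraction of records the genome
  is rewritten so the trinucleotide (default CCG) appears at offsets
  −(3+spacer) and 0 relative to both the start and the end coordinate
  (two copies separated by a `spacer`-bp gap, default 3). Rewrites
  colliding with earlier planted bases are skipped with a warning and
  the truth flag stays unset.
- **Counts**: negative binomial parameterized by (mean, dispersion)
  with variance = mean + dispersion·mean² (dispersion 0 → Poisson),
  default mean 50 and dispersion 0.1, per-sample library factors
  default 1.0 — the dispersion and factors are stated as arbitrary
  defaults since count noise structure varies by protocol. Planted
  fold changes split the log2FC symmetrically between groups
  (±lfc/2), 300 of 2000 records by default, 80% "up" in the first
  group, mirroring the strong up-skew such comparisons show.
- **Differential-gene table**: host genes of 60% of the planted
  differential circles are echoed with the same direction, plus 40
  noise genes with random directions, so the conjoint join has a
  known, partially overlapping target.

One integer seed determines everything; all artifacts (FASTA, BEDs,
TSVs, report.json) are byte-identical across runs. What the generator
does **not** emulate: sequence-dependent circle formation, chimeric or
multi-fragment circles, read-level amplification noise, mappability
structure, and between-group differences in size/GC composition (the
two groups share one population and differ only in counts; group
contrasts of composition require two separate simulations, as the
acceptance suite does for the motif presence/absence contrast).
Passing tests therefore demonstrate correctness of the estimators and
calibration under the stated sampling models, not biological validity
on real libraries.

## Problem sizes and numerical choices

The test and acceptance workloads use 10 kb oracle instances,
5000-record populations for calibration/recovery (binomial SE of the
coverage ratio ~0.10 at 5% class mass, making ±0.3 a ≈3σ band),
20 × 5000 null replicates for FDR/uniformity, 2000 records with 300
planted effects for power, and 500 junctions for motif recovery —
sizes at which the statistical tolerances quoted in the tests are
meaningful. Ties in rank tests are handled by midranks with the
standard tie-corrected variance; quantiles are type-7; BH restores the
original order after the step-up pass; JSON reports contain no
timestamps so determinism is byte-level.

## Known limitations

- Pooled differential testing ignores replicate overdispersion (see
  above); calls on real, biologically variable libraries will be
  anti-conservative relative to a per-replicate NB model.
- Repeat read fractions are computed from eccDNA-level counts, an
  approximation to read-level mapping.
- Host-gene assignment is purely interval-based (body ± 2 kb), with no
  transcript-model awareness.
- Flanks use the reference plus strand only; strand-symmetric motifs
  are not collapsed with their reverse complements.
- GO/KEGG enrichment and read-level processing are out of scope.
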