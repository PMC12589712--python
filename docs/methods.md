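# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the places where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Binned DMR calling

The caller compares two *pooled* methylomes (one sample per condition,
no replicates — matching a design in which DNA from several plants is
pooled before sequencing). The genome is tiled into fixed, consecutive
`bin_bp` = 150 bp bins; the final partial bin is kept. Per bin and
sequence context, read counts are pooled across cytosines and the 2×2
table (methylated/unmethylated × condition) is tested.

**Test.** Two-sided Fisher exact: the sum of hypergeometric
probabilities, at fixed margins, of every table no more probable than
the one observed. Implemented via `scipy.special.gammaln` log-pmfs; the
"no more probable" comparison uses a relative guard of 1e-7 so exact
ties (and the observed table itself) are never lost to floating-point
rounding. The unit and acceptance tests compare this against an
independent exact-integer enumeration (binomial-coefficient numerators
over the common denominator C(N, n₁)) on every table with row sums ≤ 30.
A two-proportion z (score) test is available as `method="score"` for
comparison; Fisher is the default because it is exact at the low
per-bin counts the filters admit.

**Filters.** A bin must hold ≥ `min_cytosines` = 4 context cytosines in
*both* samples; its mean coverage per cytosine must be ≥
`min_reads_per_cytosine` = 4 in both samples (the mean-over-bin reading,
which composes sensibly with the cytosine-count filter rather than
dropping individual low-coverage cytosines); the test must give
p ≤ 0.01 (raw — no multiple-testing adjustment by default, with BH
available behind `adjust_p`); and the pooled proportion difference must
reach 0.2 (CpG, CpHpG) or 0.1 (CpHpH). The laxer CpHpH threshold
reflects the low baseline of that context in plants.

**Merging.** Maximal runs of adjacent (gap-0) surviving bins with the
same direction merge into one DMR with re-pooled counts and a
re-computed p-value; merged DMRs are re-checked against the proportion
and p thresholds so that every reported DMR satisfies the full contract
re-assertably from its stored counts. Direction is condition B relative
to A: "gain" means B is more methylated.

**Calibration.** On null methylomes the fraction of count-filtered bins
at p ≤ 0.01 sits slightly *below* 0.01 (Fisher is conservative at
discrete counts); the proportion-difference filter then removes
essentially all remaining null bins at 20× coverage, which is what makes
the caller's false-positive count low despite the raw p threshold.

## Coordinates and I/O

Cytosine reports are the Bismark-style 7-column CX dialect (1-based
positions; contexts CG/CHG/CHH on disk, CpG/CpHpG/CpHpH in memory).
All internal intervals and all BED outputs are 0-based half-open.
Zero-coverage cytosines are retained; profile windows and bins
distinguish "no data" from "0 % methylated". Symmetric-site strand
collapsing is available (`collapse_symmetric_strands`) but off by
default: the bins method pools counts anyway, and collapsing would
halve the cytosine count seen by the min-cytosine filter. GFF3 and BED
are read through pyranges; because pyranges regroups rows by strand,
the TE reader restores coordinate order before assigning stable
synthetic ids.

## Enrichment

Observed counts come from single-label assignment: the feature kind
with the largest overlap wins, ties broken by the fixed precedence
TE > promoter > 5′UTR > 3′UTR > exon > intron, no overlap → intergenic.
TE outranks gene parts because TE enrichment is the scientific signal
of interest. Expected counts are analytic: total DMRs × the fraction of
genomic bp each kind occupies, where occupancy is computed under the
*same* precedence (each base assigned to its highest-ranked covering
kind, remainder intergenic). This makes the categories partition the
genome, so expected counts sum to the observed total exactly.

Assignment and expectation can disagree systematically where features
of different kinds overlap (promoters of downstream genes frequently
cover upstream 3′UTRs in a compact genome): a DMR straddling the
boundary is assigned by its overhang, while the projection credits the
higher-ranked kind. The calibration null therefore places intervals
*proportionally to projected bp, inside single-kind territory*
(`sample_null_dmrs`), under which observed counts are exactly
multinomial around the expectation; a uniform-shuffle Monte-Carlo
(`permutation_expected`) is provided as the cross-check for the
full-genome null. TE superfamily enrichment applies the same
observed/expected logic within each direction of change, with
expectations proportional to superfamily bp within all TE bp. For
class-level groupings, LTR = Gypsy ∪ Copia.

## Differential expression

A deliberately transparent approximation of the standard NB pipeline,
chosen so that every stage is verifiable against closed forms:
median-of-ratios size factors (geometric-mean reference over genes
positive in all samples; upper-quartile fallback); per-gene moment
dispersion α = max(0, (s² − m)/m²) with s² the pooled within-group
variance of normalised counts and m their grand mean, clipped at 5.0 so
a handful of low-count genes cannot distort the shrinkage target, then
shrunk with weight 0.5 toward the mean dispersion over genes; a Wald
test of log₂FC using Var(log₂ mean) ≈ (m + αm²)/(n m² ln²2) per group;
BH adjustment over genes with defined p (all-zero genes are excluded
from the family); DEG rule padj ≤ 0.05 ∧ |log₂FC| ≥ 0.5, two-sided.
A 0.5 pseudocount enters the fold change only when a group mean is zero,
so identical groups report exactly log₂FC = 0, p = 1.

The Wald-plus-moments combination is anti-conservative at n = 3; the
validation suite measures the null p ≤ 0.05 fraction at ≈ 0.06–0.07
rather than asserting nominal 0.05. This stage approximates — and is
cross-checked in one test against, but never implemented by — DESeq2.

## Integration

All signs follow one convention: in comparison "X vs Y", both Δm and
log₂FC are Y relative to X. Set classification over the four
comparisons A = SQHvFLH, B = SQLvFLL, C = SQHvSQL, D = FLHvFLL:
constitutive = A∩B∩C∩D, frequency = (A∩B)∖(C∪D), intensity =
(C∩D)∖(A∪B), plus per-comparison unique sets; a feature differentially
methylated in several contexts counts once. The DMR×DEG association is
the textbook Σ(O−E)²/E on the 2×2 table over all tested genes, df = 1,
no Yates correction (the hand-computable statistic; the correction is
immaterial at these counts), flagged unreliable when an expected cell
is < 1. TE–gene distance is the minimal interval gap (0 on overlap),
not midpoint or TSS distance; a TE's methylation change aggregates its
overlapping DMRs by overlap-length-weighted mean. Correlations are
Pearson (the relationship plotted is linear in Δm and log₂FC), Spearman
behind a flag; strata with n < 3 or zero variance are reported as not
computable rather than silently dropped.

## Synthetic-data generator

The generator emulates the study design, not the organism's sequence:

- **Genome/annotation.** One 2 Mb chromosome by default; 450
  non-overlapping genes (0.8–4 kb, 1–5 exons, strand-aware UTRs and
  1 kb promoters — the common Arabidopsis convention) and 300 TEs
  (log-normal lengths 150–5000 bp) placed with multinomially distributed
  gaps; TE superfamilies drawn from {Gypsy, Copia, LINE, SINE, RathE,
  Helitron, DNA, Unassigned} with retro/DNA class labels. Chromatin
  states partition every base: TEs → constitutive heterochromatin, a
  random 15 % of genes → facultative, other genes → euchromatin,
  remainder → intergenic state.
- **Methylomes.** Cytosines at density 0.35/bp (≈ the both-strand
  cytosine fraction of a ~36 % GC genome), context probabilities
  CpG 0.2 / CpHpG 0.2 / CpHpH 0.6, i.i.d.; baselines CpG 0.25 /
  CpHpG 0.10 / CpHpH 0.05 outside TEs and 0.80/0.50/0.25 inside
  (TE bodies are heavily methylated in all contexts). Coverage is
  i.i.d. Poisson(20) per cytosine — the analysis consumes count tables,
  so no read-level simulation — and methylated counts are Binomial.
- **Planted truth.** Per comparison, 50 DMRs of length 600 bp and
  effect ±0.4 (sign flipped when infeasible against the local baseline),
  70 % in TEs / 20 % in genes / 10 % intergenic — matching the
  enrichment direction the method should detect — with contexts drawn
  CpG-biased; 60 DEGs at |log₂FC| = 1 under NB dispersion 0.05 and
  log-normal library factors; half of each comparison's TE DMRs are
  placed on TEs with a gene within 5 kb, and that gene is planted with
  the opposite-signed fold change (a concordant pair). Each comparison
  perturbs its second condition; with four conditions in four
  comparisons a perturbed condition is necessarily shared by two
  comparisons (FLL here), as in the real design where every condition
  sits in two comparisons. Recovery studies that need clean separation
  restrict the config to one comparison.
- **Determinism.** Every stage draws from its own
  `SeedSequence([seed, stage])` stream; identical configs produce
  byte-identical files, which the pipeline verifies by checksum.

What the generator does *not* model — and hence what passing tests do
not establish about real data: sequence-determined context spacing and
symmetric-site structure, bisulfite conversion error, coverage biases
(mappability, PCR), replicate-level methylome variability (the design
is pooled), TE insertion polymorphism, and any mechanistic coupling
between methylation and expression beyond the planted monotone pairs.

## Validation-study sizes

Desk-scale sizes were chosen so each study estimates its quantity with
sampling error well inside the asserted bound: the Fisher sweep covers
all ≈ 246,000 tables with margins ≤ 30; null DMR calibration uses the
full ≈ 13,300-bin genome; enrichment nulls place 20,000 intervals so
the smallest category still expects > 600 hits; the DE power study uses
12,000 genes with 2,800 planted DEGs — the ≈ 23 % DE fraction mirroring
the headline comparison's share of tested genes, which sets a realistic
BH severity, at a size where the sample median of the |log₂FC| error is
stable to ±0.004; the end-to-end study runs the default 2 Mb genome
twice to confirm byte-identical reruns.

## Known limitations

- One pooled sample per condition: the caller inherits the design's
  inability to separate biological from technical variance; p-values
  describe read-sampling noise only.
- The DE stage's Wald test is anti-conservative at three replicates;
  adjusted p-values near the threshold should be read accordingly.
- Enrichment expectations are analytic bp shares; for questions where
  the largest-overlap boundary behaviour matters, use the permutation
  cross-check.
- The intergenic category is computed as the complement of annotated
  features, so unannotated genome inflates it.
- Chromosome-level profiles use a configurable window (default 100 kb)
  with no smoothing; centromere-like structure appears only insofar as
  TE placement creates it.
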