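# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `srna_transgen`, in the spirit of a statistical
methods appendix.

## Coordinates and formats

All in-memory coordinates are 0-based, half-open.  GFF3 (1-based,
end-inclusive) is converted at the file boundary only; BED is passed
through unchanged.  The DMR table dialect is declared 0-based half-open —
upstream methylation callers differ on this, so the convention is fixed
here and documented rather than guessed per file.  Strand is carried on
every interval but ignored by overlap and distance computations; the only
strand-aware operation is tRNA-fragment side classification.  Distance is
always the edge-to-edge gap (0 for any shared base), so "within 5 kb"
means a gap of at most 5,000 bp, consistent with the interval semantics of
"overlapping".

## Locus calling

Reads from all libraries are pooled before locus definition, so one locus
set serves every sample; per-sample counts are then computed against the
fixed loci.  Merging is transitive with a gap threshold `pad` (default
75 bp) and a weight threshold `min_reads` (default 5).  Both defaults are
exposed because de-novo sRNA cluster callers do not agree on them and the
minimum observed locus size in real surveys (15 bp, a single read) implies
some pipelines keep single-read loci; `min_reads` is therefore a
configurable filter, not a hard-coded rule.  Locus ids are
`chrom:start-end`, deterministic given the input.

## Classification

* Dicer fraction = weight at 20–24 nt / total weight.  The published rule
  is "greater than 80%"; a closed boundary must be chosen for the
  measure-zero tie case, and a fraction of exactly 0.8 is classified
  siRNA (≥).  This is tested explicitly.
* The siRNA size class is the modal dicer length, ties broken toward the
  longer length — biasing toward the 24-nt RdDM-associated class, which is
  the conservative direction for the downstream DMR models.
* miRNA labels are input annotations (a flag column): de-novo miRNA
  discovery involves hairpin-structure criteria that are out of scope, so
  the flag takes precedence over the size rule.
* Analysis strata pool the 20–23 nt classes: {miRNA, siRNA20–23, siRNA24,
  nd-sRNA}.  Per-size labels are kept for reporting.
* tRF side calls are per locus, by weight-majority vote over the reads on
  the tRNA (a per-read call would leave most loci with mixed labels);
  ties, and reads crossing the anticodon, give `anticodon_spanning`.
  5′/3′ is oriented by the tRNA's strand.

## Differential abundance

Counts at locus *i*, sample *j* are modelled NB(μ_ij, α_i) with
log μ_ij = offset_j + x_jᵀβ_i, offset_j = log size factor.  Size factors
are plain median-of-ratios over loci with all-positive counts (falling
back to library-size/mean when no such locus exists).  The treatment
effect is tested by a likelihood-ratio test with 1 df: the full model adds
a wounded/control indicator to the reduced model.  The reported LFC is the
MLE (log2), with no shrinkage — raw LFCs are what downstream correlation
and regression analyses consume.

**Offspring design.**  Offspring libraries are siblings from maternal
lines nested within parental treatment.  Lines are re-indexed 1..k within
their treatment and same-index lines share an indicator column across
treatments; both models carry these blocks and only the full model carries
treatment.  This is the standard fixed-effect device for individuals
nested within groups: sibling correlation loads onto the line blocks while
the average treatment effect stays identifiable with 1 df.  (Putting a
separate indicator per actual line in both models instead makes the full
model saturated in line means, and the "treatment" test degenerates into a
contrast between the two reference lines — we verified this failure mode
directly, which is why the shared-index encoding is used.)

**Dispersion.**  Per-locus α is a method-of-moments estimate from
size-factor-normalized counts using the pooled within-design-cell
variance (so planted or real treatment effects do not inflate it):
α̂ = (v − q̄·mean(1/s)) / q̄², truncated at 0.  Loci are then binned by mean
abundance into 20 quantile bins within each class stratum, and each
estimate is shrunk toward its bin mean with weight 0.85.  The weight was
set by calibration: with 3 replicates per group the per-locus estimate has
4 residual df and is noise-dominated; at shrinkage 0.5 the LRT's type-I
error at p < 0.05 measured 0.064 on 10,000 null loci, while 0.85 gives
0.053 — essentially the known-dispersion floor of the χ²(1) approximation
at n = 6 (0.0535).  Separate strata are used because the class groups show
different mean–variance relationships.

**Filtering and FDR.**  The RPM ≥ 2 filter (mean RPM across all samples)
is applied once, globally, before any contrast — the published locus
counts are consistent with a global filter and a per-contrast filter would
make the tested sets incomparable across contrasts.  BH step-up runs
within each (contrast, stratum) cell.

**Numerics.**  Fitting is Fisher-scoring IRLS with fixed dispersion, at
most 100 iterations, relative log-likelihood tolerance 1e-8; zeros need no
pseudocounts (the NB likelihood handles them); all-zero loci return
p = 1, LFC = 0; non-convergence is flagged with p = NA rather than raised.
The implementation is checked in the test suite against an independent
negative-binomial GLM implementation (statsmodels) on random designs.

## Association models

* Pearson LFC correlations use the closed-form t = r√(n−2)/√(1−r²).
* The DMR overlap logistic model uses log locus length, the O/N/F distance
  class and a binary dicer/non-dicer factor; each term's test is a
  likelihood-ratio chi-square from a drop-one refit.  A constant response
  (all or no loci overlapping) is returned as a flagged degenerate result.
* "Within 20 kb of a DMR" uses edge-to-edge distance, and when several
  DMRs qualify the *nearest* DMR's direction is used — the alternative
  (all DMRs in the window) creates one-to-many rows with no published
  precedent to follow.
* DMR direction proportions condition on the *realized* overlap group of
  each DMR (siRNA / nd-sRNA / none, with siRNA taking precedence when a
  DMR touches both).
* The DEG direction model regresses up-vs-down on log mean expression and
  the sRNA overlap class; genes that are not differentially expressed
  carry no direction and are excluded from this model (only up/down are
  modelled), which also matches the factorial model's df structure.  A
  gene's overlap class is the class of the *nearest* sRNA locus within
  5 kb.
* The factorial LFC model (mRNA change × locus type) reports partial
  (Type-II) sums of squares by default; sequential (Type-I) SS is
  available via `ss_type=1`.  The published analysis does not name its
  software or SS type; Type II is the conventional choice for unbalanced
  factorials without a principled term ordering.
* LFC-tail outlier enrichment is a hypergeometric test of annotation
  membership among the loci in the upper (or lower) `tail_q` quantile
  (default 5%, one-sided).  This is a hypergeometric surrogate for
  rank-based enrichment recipes and is labelled as such in output.
* Expression "low/moderate/high" groupings, where needed, are global
  terciles of log mean expression.

## Synthetic data generator

The generator emulates the study conditions: a 34-library design (three
replicate wounded/control pairs per parental cell at 1 h and 72 h in the
wounded second leaf and 72 h in the unwounded third leaf; sixteen
offspring libraries, two siblings from each of four maternal lines per
parental treatment); seven locus classes mixed at the published survey's
per-class locus counts; class-median locus lengths 227/409/774 bp
(miRNA/siRNA/nd-sRNA, log-normal, log-sd 0.5); class-mean abundances
log10 RPM 1.4/0.37/0.66 (sd 0.4); NB dispersion 0.1; mean library size
2 × 10⁶ (tiny profile) or 5.2 × 10⁶ (survey-shaped profile).

Planted structure:

* 24-nt siRNA loci are placed inside TEs at rate 0.90 and nd-sRNA loci
  over coding sequence at rate 0.627; twelve nd-sRNA loci sit exactly on
  tRNA genes from a 12-isoacceptor catalogue (Leu-CAA, Gly-CCC, Ala-GGC
  and nine further valid anticodons) with a planted 5′/3′ side drawn at
  23:11 odds.
* Wound LFCs concentrate in nd-sRNA loci at the 72 h wounded-leaf
  contrast: 10% of nd loci are responsive, |LFC| ~ N(2.0, 0.5) with
  87% increases; the 1 h response is a 14% subset at half magnitude; the
  unwounded third leaf is quiet.  Offspring LFCs are drawn with population
  correlation −0.2 against the parental 72 h response (offspring sd 0.3).
  Maternal-line random effects are N(0, 0.2) on the natural-log scale —
  the magnitude is not published, and 0.2 was chosen as a plausible
  between-family scale that the nested model must absorb.
* DMRs are preferentially dropped into 24-nt siRNA loci (35%) and nd-sRNA
  loci (15%); the methylation direction is drawn from the configured
  up-probability of the DMR's realized overlap group (0.659 siRNA, 0.418
  nd-sRNA, 0.488 none), so realized proportions match the configuration in
  expectation.  Genes become DEGs at rate 0.132 when within 5 kb of an
  sRNA locus and 0.084 otherwise, with a logistic expression-dependent
  direction bias (slope −1 per log10 unit) and class-specific direction
  log-odds (+0.8 nd-sRNA, −0.8 siRNA).

Two named profiles exist: `tiny` (160 loci, 2 × 0.5 Mb chromosomes,
4,000 reads per library — every stage in seconds, all classes
represented, class mix flattened so the rare classes appear) and
`paper-shaped` (15,000 loci at the survey's class mix, 4 × 12 Mb
chromosomes, 3,731 DMRs, counts only).  Loci keep a mutual gap above the
default `pad` so island calling can separate them.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequence content (no hairpins, no real
tRNA cloverleafs, no mappability structure), multi-mapping ambiguity,
positional read biases within loci, dispersion trends beyond a single α,
batch effects, and any coupling between a locus's own abundance change and
its methylation outcome beyond the planted group-level probabilities.

## Problem sizes in the test and acceptance runs

Calibration and recovery checks run at sizes chosen to make Monte-Carlo
error small relative to the tolerance being asserted: 10,000 null loci for
type-I calibration; 500 planted loci on a 10,000-locus background for LFC
recovery (a ~5% responsive fraction, matching the study's scale — planting
an effect at *all* loci is unidentifiable because median-of-ratios
normalization absorbs a global shift); 2,000 loci for the parent–offspring
correlation; 500 replicates for the uniform-p null checks (KS at
α = 0.01); 25 replicates for the power checks, whose true power at the
configured effect sizes is near 1.

## Known limitations

* The NB machinery is deliberately simpler than a full DESeq2 clone: no
  Cox-Reid adjustment, no dispersion-outlier handling, no LFC shrinkage,
  no Cook's-distance sample outlier replacement.  Bit-compatibility with
  DESeq2 is a non-goal; statistical calibration is tested instead.
* The maternal-line blocks are fixed effects; a random-effects or
  quasi-likelihood treatment would propagate line-level uncertainty into
  the treatment test more faithfully when line variance is large.
* Multi-mapper placement is out of scope; fractional read weights are
  accepted as input for pre-resolved alignments.
* The tRF side classifier resolves 5′/3′/anticodon-spanning only — no
  D-loop/T-loop sub-structure.
* With all-identical group means the chi-square and KS-based tests rely on
  asymptotic approximations; very small tables should use the permutation
  route demonstrated in the test suite.
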