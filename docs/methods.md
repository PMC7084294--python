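# Methods

`lincpipe` re-implements, as a tested pipeline over synthetic data with
planted ground truth, a workflow for identifying long intergenic non-coding
RNAs (lincRNAs) from a merged RNA-seq transcriptome and characterising their
regulatory potential: a six-stage filter cascade, two-group differential
expression, QTL co-localization, cis/trans target prediction by expression
correlation, and a signed lincRNA–target co-expression network. The study
design it emulates is a two-breed pig muscle comparison (fat-type vs
lean-type, three RNA-seq samples per breed), where intramuscular fat (IMF)
content is the trait of interest.

## The identification cascade

Candidate transcripts from a merged assembly pass six filters in a fixed
order; each stage sees only the survivors of the previous one and every
removal is attributed to exactly one stage:

1. **intergenic** — the candidate's genomic span shares no position with
   any reference *gene span* on the same chromosome, strand-agnostically.
   Gene spans (not exon unions) define occupied loci, so intronic and
   antisense candidates are rejected: a lincRNA must lie *between* genes.
2. **structure** — exon count ≥ 2 and spliced length ≥ 200 nt (both
   inclusive). Mono-exonic fragments are indistinguishable from assembly
   noise; 200 nt is the conventional long-non-coding floor.
3. **coding potential** — upstream CPC-style scores must be < 0 (strictly)
   on **both** strands by default. The alternative reading, "non-coding on
   at least one strand", is exposed as `cpc_rule="any"`, but the default is
   `both`: a transcript coding on either strand is not non-coding.
4. **protein domains** — any domain hit with E-value < 1e-5 (strict)
   removes the candidate; E = 1e-5 exactly is *not* a significant hit.
5. **protein databases** — same rule against each configured protein
   database (e.g. NR, UniRef90); a significant hit in any one removes.
6. **expression** — retained only if FPKM ≥ 0.5 in at least one sample
   (equivalently: removed when FPKM < 0.5 in *all* samples).

Evidence or expression missing for a candidate that survived the intergenic
stage is an error, never an implicit pass — silent passes would inflate
lincRNA calls.

Survivors are labelled **known** when some database lincRNA on the same
chromosome shares at least `min_overlap_fraction` (default 0.5) of the
candidate's exonic positions, else **novel**. This is a deterministic
coordinate criterion standing in for a sequence search; it needs no
sequence data and no database version pinning. Class characterization
reports mean transcript length, mean exon length (pooled over all exons of
the class, so mean exon length x mean exon number need not equal mean
transcript length), mean exon number, and mean FPKM.

## Differential expression

A feature is differentially expressed when |log2FC| > 1 (strict) **and**
BH-adjusted p < 0.05 (strict). "Fold change greater than 1" is read on the
log2 scale: a raw fold-change cutoff of 1 would call every unequal feature.
The engine behind the criterion is deliberately transparent rather than a
negative-binomial GLM:

- size factors: library size / median library size (deterministic on
  sparse synthetic data, unlike median-of-ratios);
- log2FC = log2((mean_A + 1)/(mean_B + 1)) on normalized group means — the
  pseudocount stabilises zeros;
- p-values from a two-sided Welch (unequal-variance) t test on
  log2(normalized + 1) per feature, BH-adjusted over all tested features;
  all-zero features are excluded from testing and from the BH family;
- groups exactly constant on the log scale make the Welch statistic 0/0;
  the limit is defined as p = 1 for equal means and p = 0 otherwise, which
  keeps constructed worked examples deterministic.

The substitution is isolated behind `test_differential_expression` so a
stricter engine can be swapped in; every output labels the engine. With
n = 3 per group the test is low-powered; the planted-effect sensitivity the
suite requires (≥ 0.9 at |log2FC| = 3, low dispersion) reflects that.

## QTL co-localization

DE lincRNA loci (transcript spans — QTL intervals are megabase-scale, so
span vs exon-union is immaterial) are intersected with trait-labelled QTL
intervals read from BED (0-based half-open, converted to the internal
1-based inclusive convention at the boundary). Counting is per
(lincRNA, QTL) pair: one QTL hit by two lincRNAs contributes twice.
Trait classes are assigned from configurable lower-cased keyword lists,
IMF before other fat traits (defaults: imf = ["intramuscular fat", "imf"],
fat = ["fat", "backfat", "leaf fat"]); no authoritative trait-name-to-class
mapping exists, so the mapping is declared configuration, not inferred
truth. Summaries report fat-deposition and IMF shares, per-chromosome fat
counts and per-trait tallies; percentages over an empty denominator print
as NA.

## Target prediction and the signed network

All correlations are Pearson across all samples of both groups (n = 6 in
the emulated design), with the exact two-sided test
t = r·sqrt((n-2)/(1-r^2)) ~ t(n-2). Two-sidedness is not an assumption: the
published neighbour-pair table contains a significant negative correlation,
and the package's tests verify every printed p-value in that table is
reproduced from its printed r at n = 6 to printed precision.

- **cis**: protein-coding genes with boundary gap < 100 kb (strict; gap = 0
  when spans overlap) of a DE lincRNA on the same chromosome. *All*
  neighbour pairs are reported with r and p, whatever the p — proximity is
  the cis criterion, correlation is annotation. Pairs with an undefined
  correlation (constant vector) carry NaN and sit outside the FDR family.
- **trans**: every remaining (DE lincRNA, gene) pair, with cis-eligible
  genes excluded so the modes stay disjoint; retained iff |r| ≥ 0.95
  (inclusive) and BH-FDR < 0.05 (strict) over the full tested family of the
  run, which makes selection invariant to input order. Gene partners use
  gene-level expression; lincRNAs transcript-level.

A target that is itself differentially expressed is a DEPTG; per-lincRNA
tallies split DEPTGs by edge sign, where **sign is the sign of r** —
positive = "upregulates", negative = "downregulates" (the conventional
reading of signed co-expression edges; no mechanistic claim). Up + down =
total by construction. The network exports as SIF plus edge/node attribute
tables; duplicate edges are dropped with a warning.

A generic Fisher/hypergeometric enrichment (one-sided upper tail, odds
ratio with Haldane 0.5 correction on zero cells, GMT input) substitutes for
web-service annotation enrichment. The 2^-ddCt helper implements the
standard qPCR relative-quantification arithmetic.

## The synthetic generator

`generate_dataset` emulates the two-breed design and plants every signal
the pipeline is supposed to find, so that recovery is exact and auditable:

- **geometry** — features are laid out one per 1 Mb block along 18
  autosomes of 40 Mb: spatial relations are planted, never accidental.
  Planted cis partners share their lincRNA's block at a drawn gap of
  5–95 kb; all other genes are ≥ several hundred kb from every lincRNA.
  QTLs either cover a designated DE lincRNA's span or sit in the
  guaranteed-empty upper half of a gene block.
- **decoys** — one cohort per filter stage, each failing exactly that
  stage: gene-overlapping; mono-exonic or < 200 nt; CPC ≥ 0 on one strand;
  domain hit E < 1e-5; protein-database hit E < 1e-5; FPKM < 0.5
  everywhere. True lincRNAs pass every stage by construction (and ~30%
  carry deliberately insignificant hits, E > 1e-5, so the threshold
  direction is exercised).
- **counts** — negative-binomial per group (mean lognormal around
  exp(5.5) ≈ 245, size 50), the standard bulk RNA-seq noise model; the
  design emulated states none, so this is the generator's declared
  assumption. Planted DE features split |log2FC| = 3 symmetrically across
  groups.
- **correlations** — planted pairs are constructed with an *exact sample*
  correlation (y = r·u + sqrt(1-r^2)·w on the centered, normalized draw u
  of x and an orthogonalized residual w). At n = 6 the |r| ≥ 0.95 cutoff
  leaves no room for in-expectation planting: trans pairs are planted at
  |r| = 0.99, cis pairs at 0.9. DE lincRNA profiles are drawn mutually
  |r| ≤ 0.5 so a planted partner cannot cross the trans threshold against
  the wrong lincRNA, and unplanted ("null") profiles are redrawn until
  |r| < 0.8 against every DE lincRNA profile — an unconstrained null draw
  at n = 6 crosses |r| = 0.95 with probability ≈ 0.004 per pair, which
  would make exact planted-set recovery seed-dependent.
- **known/novel planting** — known lincRNAs are copied into the database
  stand-in with jittered outer boundaries (overlap fraction stays > 0.5);
  novel ones are absent from it.

The FPKM matrix carries the planted correlation structure and the counts
matrix the planted DE structure; they are separate outputs, not transforms
of one another, because exact sample correlations and negative-binomial
counts cannot be planted simultaneously. Class-specific FPKM baselines
(coding 12 > known lincRNA 6 > novel lincRNA 4) mirror the field's observed
expression ordering; affine scaling leaves correlations untouched.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (alignment, assembly
fragmentation, multi-mapping), batch effects, overdispersion heterogeneity,
correlated gene–gene co-expression structure beyond the planted pairs,
genuine linkage between QTL intervals and expression, and the scale of a
real transcriptome (hundreds of features, not tens of thousands). Recovery
at precision = recall = 1 demonstrates the *decision rules* are implemented
exactly, not that the pipeline would be error-free on real assemblies.

## Numerical choices and conventions

- Internal coordinates are 1-based inclusive throughout; BED converts at
  the I/O boundary. Touching intervals (end = start) overlap; end =
  start − 1 does not.
- Pearson r is clamped to [-1, 1] against rounding; |r| = 1 maps to p = 0.
- BH adjustment uses the standard cumulative-minimum step-up formulation
  (statsmodels); ties need no special casing.
- Unstranded transcripts are allowed and match either strand in overlap
  tests (merged assemblies may lack strand).
- Duplicate transcript ids, duplicate exons, non-integer counts, negative
  expression, E-values ≤ 0 and empty trait names are hard errors at parse
  or construction time.
- Default problem sizes (560 genes, 28 lincRNAs, 30 decoys, 50 trans and
  6 cis pairs, 60 QTLs, 3 + 3 samples) keep a full run around a second
  while leaving every family (BH over ~5,500 trans pairs) statistically
  non-trivial.

## Known limitations

- The Welch-on-log-counts engine has no dispersion shrinkage; on real
  3 vs 3 data it is conservative for low counts and anti-conservative for
  near-zero variance features compared to a negative-binomial GLM.
- Known/novel assignment by coordinate overlap cannot recognise a known
  lincRNA assembled on a different locus (e.g. a paralog).
- Pair-counting of QTL overlaps double-counts QTLs hit by multiple
  lincRNAs; `summarize_qtl` operates on whatever overlap list it is given,
  so deduplication, if wanted, is a one-line filter upstream.
- The trans criterion (|r| ≥ 0.95, FDR < 0.05 at n = 6) is extremely
  permissive about effect size and extremely restrictive about noise; this
  is a property of the emulated design, not of the implementation.
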