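# Methods

## Study design being modelled

An eight-founder synthetic population of recombinant inbred lines (RILs):
each line's genome is a homozygous mosaic of founder haplotypes A1–A8,
summarized at every grid locus *j* by probabilities G<sub>ij</sub> that RIL
*i* carries founder *i*'s haplotype there (the output of haplotype-HMM
genotyping in real panels).  Each RIL is assayed by bulk RNA-seq once per
rearing condition — control versus a chemical exposure such as dietary
lead — giving a paired 2 × n<sub>RIL</sub> sample design, nominally
79 RILs and 158 samples.  The scientific question is which loci change
*splicing* (exon usage, isoform dosage) in a founder-specific,
exposure-conditional way: genotype-by-environment (G×E) splicing QTLs.

## Splicing phenotypes

**Exon fraction.**  For exon *e* of gene *g* in sample *n*:
reads(e, n) / Σ<sub>t ∈ g</sub> reads(t, n).  The denominator is the sum
over *all* transcripts of the host gene, which remains well defined for
exons shared between isoforms.  Cells with a zero denominator are treated
as missing (`zero_policy="drop"`, default) and phenotypes missing in more
than `max_missing_frac` = 0.2 of samples are removed; a pseudocount mode
(+1 to numerator and denominator) is available for sparse designs.
Missingness is handled pairwise in every downstream fit.

**Isoform dosage.**  Genes with ≥ 2 expressed isoforms (row present with
any reads) contribute their isoform × sample block of log2(count + 1)
expression as a multivariate trait.  Single-isoform genes carry no usage
information and are excluded.

Each phenotype is anchored at the midpoint of its host gene's span; the
anchor feeds cis/trans classification and the sQTL-map axes.

## Normalization

Divide → quantile-normalize → remove principal components, in that order.
Quantile normalization forces every sample column onto the cross-sample
mean order-statistic vector (ties receive the mean of their tied targets;
columns with missing cells are mapped through interpolation of the mean
quantile function).  PCA confounder removal centres each phenotype and
regresses out the top sample-space components — 3 for exon fractions, 4
for isoform dosages by default.  Because the downstream test is about
G×E, the treatment vector is protected: every component is
orthogonalized against it before removal (disable with
`protect_environment: false`).

Two practical caveats, both consequences of PCA rather than bugs:

* The mean-order-statistic target depends on the pooled values, so
  quantile normalization is invariant to monotone transforms only at the
  level of rank assignment, not of output values.
* Sequential PC removal is not idempotent (a second pass removes the
  *next* components).  What is guaranteed — and tested — is that removed
  components stay removed: residuals are orthogonal to them to 1e-8 and a
  matrix of rank ≤ n_pc is annihilated.
* On miniature panels (≲ a few hundred genes) the leading PCs chase the
  strongest individual signals, including planted true effects; the
  generator plants no technical confounders, so small demonstration
  configurations run with `n_pc = 0`.  At a realistic transcriptome size
  an individual cis effect is a vanishing variance fraction and removal
  is harmless — but a *hotspot* affecting a macroscopic share of genes is
  exactly the coordinated pattern PCA removes first, which is why the
  hotspot benchmark also runs without PC removal (see below).

## The nested G×E models

At every (phenotype, locus) pair a partial F-test compares nested OLS
fits.  Univariate (exon-fraction) trait:

* H0: intercept + environment.
* HA: adds founder-probability main effects and founder × environment
  interactions, with one founder column dropped as reference (default the
  last).  Only the column span matters, so the statistic is invariant to
  the reference choice; all-zero founder columns are pruned first, and if
  the reference itself carried no mass another column takes over as
  reference — padding with dummy founders cannot change F.

Long-format (isoform-dosage) trait, response Y<sub>nk</sub> stacked over
isoforms *k*: per-isoform intercepts μ<sub>k</sub> and per-isoform
environment terms in both models; under the default `as_printed` block
structure the null carries genotype main effects shared across isoforms
and the alternative adds genotype × isoform and genotype × environment ×
isoform blocks (a joint test of isoform-differential genotype and G×E
effects); under `gxe_only` the genotype × isoform block moves into the
null and only the three-way block is tested.

**Per-sample intercepts (design deviation).**  Isoform measurements of
one gene within one sample share noise — residual library-size effects,
the gene's overall expression, and the negative correlation induced by
proportion normalization.  A long-format OLS without sample effects
assumes independent cells and is measurably anti-conservative under the
null (KS statistic 0.066 against uniform, 7.3% of null p-values below
0.05 in a 2,000-fit calibration run).  Both nested models therefore carry
one intercept per sample by default, absorbed by within-sample demeaning
(the Frisch–Waugh projection; ranks and residual df account for the
absorbed columns).  This restores calibration (KS p ≈ 0.3) and focuses
the tested blocks on pure usage contrasts.  `sample_intercepts=False`
reproduces the bare design.

Degrees of freedom come from design ranks (`lstsq`), so expected
collinearities cost nothing and genuine rank deficiencies beyond the
planned reference drop flag the record with a missing p-value rather than
a fabricated one.  A constant response returns F = 0, p = 1.  The exon
scan batches all phenotypes sharing a missingness pattern into one
multi-RHS QR solve per locus; the batched and per-fit paths are verified
equal to 1e-8.

Efficiency note: the full cross-product size (n_phenotypes × n_loci) is
reported as metadata and never materialized as a precondition of the
scan; association tables stream to disk per phenotype.

## Differential expression

Per transcript, log2 counts-per-million (+1) are contrasted between
conditions with the RIL as covariate; in the balanced paired design the
OLS fit of expression ~ treatment + RIL reduces exactly to the paired
t-contrast, which is how it is computed.  M = log2 of the ratio of mean
Pb to mean control expression (with pseudocount), A = the mean of the two
log2 means; unpaired RILs are excluded with a warning; FDR by
Benjamini–Hochberg.

## FDR, classification, hotspots

Storey q-values: π₀(λ) = #{p > λ} / (m(1 − λ)) on λ = 0.05…0.95 (step
0.05), smoothed by a cubic polynomial and evaluated at λ = 0.95, clipped
to (0, 1]; q = cummin of π₀ m p<sub>(i)</sub>/i.  Forcing π₀ = 1
reproduces Benjamini–Hochberg exactly.  Significance requires p ≤ 1e-4
and q ≤ 0.39 (both configurable); q-values are computed per method, and
the two methods' calls are combined on gene × locus keys with the union
identity nUnion = nA + nB − nShared.

cis/trans: cis iff same chromosome and |anchor − locus| ≤ 1 Mb (closed
bound, configurable).  The 1 Mb window is a conventional choice; nothing
downstream is sensitive to it at desk scale.

Hotspots: bin the locus axis (default 100 kb), count distinct significant
trans-target genes per bin.  Because linkage replicates one QTL across
neighbouring grid loci, calls are first collapsed to each gene's best
locus per chromosome.  The empirical null rescatters the collapsed calls
uniformly over the grid's loci (bins weighted by how many grid loci they
contain — equal-bin weighting is measurably anti-conservative); per-bin
empirical p-values are Bonferroni-corrected over bins, and adjacent
significant bins merge into one hotspot reported with its peak count.  A
label-shuffling null that permutes gene assignments among calls was
rejected: when linkage concentrates every call into the hotspot's own
region, that null reproduces the observed counts and has no power.  The
empirical-null construction is this package's interpretation; the
original band-plot observation it models came with no stated test.
Condition specificity can be assessed by running the detector on calls
from exposure-interaction fits versus control-only refits.

## AS event classification

Transcript pairs of one gene are compared within their overlapping span
through their intron chains: an intron of one transcript contained in an
exon of the other → intron retention; an internal exon of one absent
between two introns of the other that share its flanking splice sites →
exon skipping; intron pairs sharing one boundary and differing at the
other → alternative donor or acceptor, strand-aware (donor = 5′ splice
site = intron start on the plus strand), with a guard that the differing
region is purely exonic in the shorter-intron transcript (otherwise the
difference is a skipped exon, not a shifted site).  Identical chains give
the empty set; differences outside these categories (alternative
first/last exons) are `other`.  The full ASTALAVISTA-style event-code
algebra is deliberately not reproduced — only the four canonical local
events are reported, tallied both per transcript pair and per gene.

## Synthetic data generator

The generator defines the conditions every statistical claim is tested
under; it emulates structure, not sequence.

* **Genotypes** — founder labels follow a Markov chain along each
  chromosome: switch probability `breakpoint_rate` per grid step (default
  0.02 per 10 kb, giving LD decay over a few hundred kb, the order
  observed in multiparental RIL panels), new label uniform among the
  other founders, chromosomes independent.  Labels are softened to
  probabilities as (1 − blur)·onehot + blur·Dirichlet(1) with blur = 0.05,
  mimicking genotyping uncertainty.  The real HMM genotyping is not
  re-implemented: the pipeline consumes probabilities regardless of their
  origin.
* **Annotation** — per gene, a base transcript of 3–8 exons (80–400 bp,
  introns 0.2–2 kb); additional isoforms apply one random splicing move
  (skip an internal exon, retain an intron, shift a donor or acceptor),
  so isoform differences are concrete AS events the classifier can
  rediscover.  Default isoform-count distribution: {1: 0.45, 2: 0.30,
  3: 0.15, 4: 0.10}.
* **Counts** — gene relative expression lognormal (σ = 1, normalized);
  isoform baseline log-proportions Normal(0, 0.8); per-sample, per-isoform
  biological noise Normal(0, 0.2) on the log scale (samples are pools of
  ~50 fly heads, so ~20% biological CV); negative-binomial observation
  with variance μ + 0.05 μ² (a single global dispersion, the simplest
  overdispersed layer the fraction phenotype must tolerate); mean library
  depth 2 × 10⁵ over ~100 genes, i.e. a few hundred reads per isoform,
  matching the per-transcript coverage of a ~23 M-read fly-head library.
  Exon counts partition each transcript's reads across its exons by a
  length-proportional multinomial, so exon and transcript tables are
  consistent and gene-level reads are conserved exactly.
* **Planted effects** — a cis G×E effect multiplies the target isoform's
  mean count by exp(δ · G<sub>fj</sub> · E<sub>n</sub>): δ is an exact
  shift on the natural-log count scale, recoverable by a group-mean
  contrast without any model code.  (An earlier logit-scale formulation
  was rejected because softmax saturation compressed the realized effect
  unpredictably.)  Defaults δ = 1.5; a trans hotspot applies the same
  shift to one isoform of each of many genes from a single locus.
  All effects are registered in a `SimTruth` object.

What the generator does **not** simulate: batch/technical confounders
(hence PC removal at small scale removes only signal and noise), RIL
random effects beyond genotype (line-level shared variation would violate
the exon model's independence assumption exactly as it would on real
data), sequence content, reads, annotation errors, and 75 generations of
breeding realism.  Passing benchmarks therefore demonstrate correctness
and calibration of the machinery under clean conditions, not robustness
to every artefact of real RNA-seq.

## Benchmark problem sizes

Chosen so the full battery runs in ~1 minute on one CPU:

* Null calibration: one effect-free 79-RIL panel, 120 genes, loci drawn
  at `breakpoint_rate` 0.5 so sampled tests are nearly independent; 2,000
  fits per model; KS uniformity at α = 0.01.
* Recovery: 20 panels, 100 RILs, 100 genes, one planted cis G×E effect at
  the generator default δ = 1.5; success = p < 1e-4 at the planted locus
  by either trait; observed rate ≈ 90%.
* FDR: 20 panels, 79 RILs, 200 genes with 5% planted; mean realized FDP
  among calls at q ≤ 0.39, truth window 500 kb around the planted locus;
  observed ≈ 0.38–0.42 — at the nominal level plus the dependence/tail
  slack expected for F-tests on non-Gaussian fractions under linkage.
* Hotspot: one 79-RIL, 150-gene panel (all genes multi-isoform) with a
  50-gene hotspot at δ = 1.5, isoform scan on quantile-normalized data
  without PC removal (rationale above), 200 kb bins, 500 permutations;
  plus 20 uniformly-scattered null call tables (measured family-wise
  false-positive rate ≈ 1.5% at the 0.05 Bonferroni cutoff).

## Known limitations

* No kinship/relatedness correction and no per-phenotype permutation
  p-values (out of scope by design).
* The F-test's tail is mildly inflated on bounded fraction phenotypes
  (~1.3× at p = 1e-4 in null panels); q ≤ 0.39 calls inherit a
  correspondingly higher realized FDP under linkage.
* Isoform groups must be complete blocks; genes with partially missing
  isoform rows are excluded rather than imputed.
* Hotspot detection assumes a locus grid dense relative to the bin size.
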