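# Methods

This note documents the models and procedures implemented in `mirnome`, the
assumptions behind them, and the design decisions taken where the underlying
methods are conventionally underspecified. Nothing here reports an empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Read-level quality control

Reads are cleaned in a fixed cascade: 3′-adapter trimming, size selection,
base-quality filtering, collapsing.

* **Adapter trimming** is a semi-global search for the adapter prefix at
  every start position with ≥ 5 nt of overlap and ≤ 10 % mismatches. Among
  acceptable occurrences the one matching the most adapter bases wins, then
  the lowest error rate, then the leftmost start. Preferring matched bases
  (rather than the leftmost acceptable hit) is what score-based trimmers do
  in practice and prevents a chance internal 5-mer from truncating an
  insert: a true full-length adapter occurrence always outranks it. Reads
  with no acceptable occurrence are returned unchanged; a 50-bp untrimmed
  read can never pass the 18–25 nt size selection, so the surviving set is
  identical either way.
* **Size selection** keeps trimmed inserts of 18–25 nt inclusive. The
  bounds are inclusive because mature miRNA length distributions peak at
  22 nt and populate both endpoints.
* **Quality filtering** rejects reads containing N and keeps reads in which
  at least 80 % of bases have Phred ≥ 30. "Q30 or better" is interpreted
  inclusively (≥ 30), the usual convention; a strict mode (`> 30`) is
  exposed as a flag. Length and quality filters are per-read predicates on
  the trimmed read, so their order does not change the surviving set (this
  is property-tested).
* **Collapsing** compresses identical clean reads into unique tags whose
  FASTA headers carry the frequency (`>{tag}_x{count}`); the count sum
  equals the number of collapsed reads by construction. Candidate matures
  with a tag count below 5 are discarded as unreliable.

## Short-sequence homology

The aligner is an exact end-free (overlap) dynamic program over the DNA
alphabet (U is normalized to T on input): match +1, mismatch −1, gap −2,
terminal gaps free. Among score-optimal alignments it prefers fewer
substitutions + indels, then a smaller 5′ overhang, making the reported
summary deterministic and symmetric in the two sequences. Per side, the
reported overhang is the larger of the two sequences' unaligned lengths,
because the match categories constrain *both* sequences' ends. The DP core
is JIT-compiled with numba (a pure-Python fallback keeps the package
importable without it).

Match categories: *entire match* requires a substitution- and indel-free
core with ≤ 2 nt overhang at each end (per end, not summed); *mismatch*
tolerates one substitution or indel with ≤ 1 nt overhang per end;
everything else is *no hit*. A BLAST-style heuristic was deliberately not
used: at catalogue scale (thousands of ≤ 25-nt sequences) the exact DP is
fast, deterministic, and reports the exact mismatch/overhang quantities the
categories are defined on.

Seeds are bases 2–7 (1-based) of the mature sequence, reported lower-case in
the RNA alphabet as catalogues conventionally print them. Novel-seed
discovery compares normalized representations, so RNA/DNA case conventions
cannot split identical seeds, and reports seeds in their original spelling.

## Paralog and ortholog grouping

Clustering is greedy representative clustering in the style of CD-HIT:
records are visited longest-first (ties broken lexicographically for
determinism); each joins the first cluster whose *representative* (founder)
aligns at ≥ 90 % identity over the aligned region with the alignment
covering ≥ 90 % of the longer sequence (the `-aL` convention), else founds a
new cluster. Paralog groups are then refined: members with > 2
substitutions/indels or > 1 nt overhang per end against the representative
are split out as singleton groups rather than dropped — single-copy miRNAs
count as groups of one.

Ortholog (conserved) groups apply the same joining rule *plus* exact seed
identity, over the merged records of all libraries, and keep only groups
with at least one member in every required library. Expression per library
is the geometric mean of member tag counts; a zero count propagates to a
zero group expression (the formula carries no pseudocount; adding one would
invent expression for an undetected paralog). Raw tag counts, not
normalized values, feed the geometric mean; normalization happens
downstream on the group-level matrix. The computed mean is clamped into
[min, max] of the member counts so the mathematical bound survives
floating-point rounding.

Because greedy assignment is first-match, a record can never appear in two
groups; when two valid groups could claim a member, the earlier-founded
group wins and the conflict is visible in the clustering order.

## Genomic placement and species specificity

Mapping is ungapped on both strands: every placement with at most the
allowed number of substitutions is reported (equivalent to a short-read
mapper's ungapped mode, implemented as a vectorized sliding-window scan —
FM-indexing would be pointless at the desk-scale genome sizes this package
targets). Multi-mapping precursors are classified by their best hit
(fewest mismatches, then lowest coordinate).

Locus classification is strand-aware: a hit entirely inside the exon union
is exonic; a hit overlapping an exon and an adjacent intron of the same
gene is an exon–intron boundary; a hit entirely inside introns is intronic;
a hit touching no gene feature is intergenic. When isoforms disagree the
priority is exonic > boundary > intronic. A hit partially overlapping a
gene edge has no class in this scheme; it falls back to the touched feature
type (exonic preferred) and is logged. Coordinates are 0-based half-open
internally; BED is native and GFF-style inputs are converted on read.

A precursor is species-specific when it has no acceptable placement
(≤ 3 substitutions, either strand) in *any* foreign genome. Raising the
allowance can only shrink the specific set (tested as a monotonicity
property).

## Normalization

* **Quantile normalization** forces every column onto the cross-column mean
  of order statistics. Tied values within a column receive the mean of the
  reference values over the ranks they occupy, which preserves the identity
  of column sums exactly. With ties the columns' sorted vectors can differ
  slightly (the tie rule replaces several reference values by their mean);
  on tie-free data the transform is exact and idempotent.
* **TMM** follows the trimmed-mean-of-M-values construction: for each
  library against a reference, M and A values over features nonzero in
  both, double trimming (30 % of M, 5 % of A, both tails, by rank),
  inverse-asymptotic-variance weights, and an exponentiated weighted mean;
  factors are re-centred to geometric mean 1. When no reference is named,
  the library whose scaled upper quartile is closest to the mean upper
  quartile is used.
* **Median-of-ratios size factors**: over features with nonzero counts in
  every library, each library's factor is the median ratio of its count to
  the feature's geometric mean.

## Differential expression

The DE engine is a two-group negative-binomial model in the NB2
parameterization, Var = μ + αμ², exposed statsmodels-style
(`NBDifferentialExpression(...).fit()` → results object with a `summary()`).

1. Median-of-ratios size factors are computed on the two groups' libraries
   and enter the GLM as a log offset (counts stay raw).
2. Per-feature dispersions are estimated by method of moments from the
   within-group variances of depth-corrected counts. These estimates are
   extremely noisy at the study's group sizes (3 vs 3), so the working
   dispersion is a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ; features
   whose moment estimate exceeds four times the trend keep their own
   estimate, so genuinely overdispersed outliers are not squeezed onto the
   curve and tested anticonservatively. (Taking the pointwise maximum of
   moment estimate and trend — the obvious alternative — upward-biases the
   dispersion by construction and makes the test visibly conservative.)
3. The group effect is a Wald test on the group coefficient of a log-link
   NB GLM with the dispersion fixed at the working value. If the IRLS fit
   fails or degenerates (perfect separation at all-zero groups), the
   feature is refit with a 0.5 pseudo-observation; if that also fails its
   p-value is 1.
4. The reported log2 fold change is log2((mean_B + 0.5)/(mean_A + 0.5)) on
   depth-corrected group means; the 0.5 pseudocount only guards the zero
   case and is not a shrinkage estimator.
5. BH correction is applied per comparison over tested features only;
   features with zero counts in both groups are reported as NA.
6. A feature is called when |log2FC| strictly exceeds the threshold (2 by
   default) **and** the adjusted p-value is strictly below α (0.01 for
   miRNA comparisons, 0.05 for mRNA, both configurable). Up/down calls are
   intersected across species pairs; a feature missing from any comparison
   or called in conflicting directions is excluded from both common sets.

The engine is validated by simulation, not against any particular DE
package's output: on null NB data (2000 features, 3 vs 3, α-dispersion
0.05) the raw-p false-positive rate at nominal 0.05 must fall in
[0.03, 0.07], and planted 16-fold effects at mean 200 must reach adjusted
p < 0.01 in ≥ 90 % of replicates.

## Expression-pattern analyses

Hierarchical clustering uses 1 − correlation as distance with complete
linkage. The correlation flavour is gated on normality: each vector gets a
Shapiro–Wilk test and the axis uses Pearson when the median p-value exceeds
0.05, Spearman otherwise (one method per axis; the median is the
aggregation rule chosen here, as the per-axis decision is otherwise
underdetermined). Constant vectors have undefined correlations; they are
assigned the maximal distance 2 and logged. PCA treats libraries as
observations of feature-centred expression via SVD; variance proportions
sum to 1. Accumulated GO expression averages each gene over a species'
libraries and sums the averages over the genes annotated to each term — a
linear functional of the expression matrix; a selected term with no
annotated gene in the matrix is reported as 0 with a warning.

## Targets and enrichment

Target prediction is canonical seed matching: every exact sense-strand
occurrence of the reverse complement of the 6-nt seed in a 3′-UTR (UTRs
shorter than 20 nt are discarded first). No thermodynamic or
conservation scoring is attempted; the `match_class` field is reserved for
7mer/8mer extensions. The miRNA–mRNA network deduplicates to unique
(miRNA, gene) edges restricted to the DE miRNA set.

GO enrichment is a one-sided (over-representation) Fisher exact test per
term on the in-set × annotated 2 × 2 table, BH-corrected across tested
terms — consistent with the BH use elsewhere in the package.

## The synthetic-data generator

`SimConfig` defines a whole study; one seed makes every output
byte-reproducible. Defaults describe a desk-scale four-species blood
small-RNA comparison: 3 libraries per species, 37 conserved families (the
scale of a conserved blood miRNome), 2 paralogs per family, 20
species-specific miRNAs per species, 20–24 nt matures, 50-bp reads carrying
the standard TruSeq small-RNA 3′ adapter, NB2 counts with α = 0.05 and
means log-uniform on [20, 200], a 10 % planted-effect fraction at 16-fold
(log2FC = 4, comfortably above the |log2FC| > 2 call threshold), and 60-kb
toy genomes.

Construction rules that make the truth tables exact:

* Each conserved family fixes two mutable non-seed positions; every
  paralog/species variant mutates only there, so all members stay within 2
  substitutions of the family base *and* of each other, share the seed, and
  are recoverable as one group. The canonical variant per species stays
  within 1 substitution of the base so that precursors of different species
  remain within the 3-mismatch cross-genome budget.
* Precursors are mature + loop + star, the star being the reverse
  complement of the mature with a 2-nt 3′ offset — a minimal hairpin
  stand-in; no secondary-structure folding is modelled.
* Reads are insert + adapter, padded with random bases or truncated to the
  read length, with two-state (Q38/Q20) per-base qualities; a configurable
  fraction of reads is drawn from a low-quality state so the Q30/80 %
  filter has both passing and failing reads, a fraction carries a planted
  N, and junk reads (no adapter, too-short and too-long inserts) exercise
  the size selection. Per-read truth records the insert actually present
  in the read and the Q30 fraction of the insert portion.
* Genomes plant shared precursors in every species within the shared
  mismatch budget, own-species-specific precursors likewise, and foreign
  specific precursors either not at all or at exactly one substitution more
  than the specificity allowance. Plant sites cycle through intergenic /
  exonic / intronic / boundary loci, inheriting the host gene's strand, and
  every plant's Hamming distance is re-verifiable from the emitted FASTA.
* The mRNA matrix draws NB2 counts with per-library depth factors and
  planted ±16-fold effects in the focal species (alternating direction);
  one GO term annotates ≥ 80 % of planted genes by construction; UTRs are
  30–80 nt with a 10 % short-decoy fraction.

What the generator does **not** emulate — sequencing errors inside the
insert, 5′ adapters, isomiR heterogeneity, RNA editing, hairpin folding,
multi-chromosome genomes, GC or mappability biases, and library-preparation
batch effects. Passing tests therefore demonstrate the correctness of the
pipeline's logic and calibration of its statistics under the stated model,
not robustness to every artefact of real libraries.

## Problem sizes used in the checks

The shipped verification runs use desk-scale sizes chosen so the whole
suite executes quickly on one CPU: 8–20 conserved families across 12
libraries (~10⁴ reads), 50-sequence clustering instances over 20 seeds,
2000-feature null and 100-replicate power simulations for the DE engine,
500-feature depth-recovery matrices, and 100 random enrichment tables.

## Known limitations

* The aligner is exact but O(nm) per pair; it is meant for mature-miRNA
  catalogues, not genome-scale search.
* Genome mapping is ungapped by design; an indel-bearing precursor copy
  will count as diverged.
* The DE model is two-group only (no covariates, no multi-factor designs)
  and does not shrink fold changes.
* Greedy clustering is order-dependent by construction; determinism is
  guaranteed by the fixed visiting order, and equivalence with all-pairs
  single-linkage holds when families are tight cliques under the joining
  rule, which the generator and the oracle tests both respect.
* Quantile normalization with heavily tied counts equalizes column sums
  exactly but sorted vectors only approximately (see above).
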