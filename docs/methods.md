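# Methods

## Local co-expressed pairs (COPs)

For a gene *g* with TSS *t(g)*, the cis candidates are all genes *h* on
the same chromosome with |t(g) − t(h)| ≤ *W* (window *W* = 1 Mb,
boundary inclusive). The statistic is the Pearson correlation ρ of the
two genes' expression vectors across cells (single-cell mode) or samples
(bulk mode); after rank inverse-normal preprocessing Pearson is
effectively rank-based, and on binarized matrices it equals the phi
coefficient.

**Null model.** The number of cis candidates varies strongly along the
genome, so the null for gene *g* is the distribution of the *maximum*
correlation over all of *g*'s candidates when *g*'s expression vector is
permuted across cells (*B* = 1000 permutations). Each observed pair
correlation is compared against its focal gene's max-null with the
add-one estimator p = (1 + #{null ≥ ρ})/(B + 1), which cannot return
zero. The max statistic makes p-values comparable between genes with 2
and with 20 neighbours and is conservative for individual pairs, which
is the intended direction for an error-controlled screen.

Each unordered pair is tested twice (once per focal gene);
Benjamini–Hochberg runs over all tests of a run jointly, and a pair is
significant when either direction has q < 0.05. Calls additionally
require ρ > 0, ρ ≤ 0.99 (near-perfect correlations are treated as
technical duplicates/mapping artifacts), a cross-mappability score ≤ 10
when a score table is supplied (missing scores pass), and, in the binary
regime only, ρ ≥ 0.2 — in very sparse binarized data tiny but highly
significant phi coefficients are otherwise abundant.

**A floor-vs-BH interaction worth knowing.** With *B* permutations the
smallest attainable p is 1/(B+1). BH at level α over *m* tests can then
only reject when at least ⌈m/(α(B+1))⌉ tests sit at the floor — about
2% of tests at B = 1000, α = 0.05. Detection therefore requires either
enough genuinely co-expressed pairs or more permutations; demo and test
configurations are sized with this in mind, as any permutation-FDR
analysis must be.

**Per-experiment hygiene.** Experiments whose COPs-per-cell ratio
exceeds Q75 + 3·IQR of all experiments (type-7 quantiles) are dropped;
COP sets from experiments of one individual are combined as their union,
keeping each pair's most significant statistics.

## Distance-matched controls (non-COPs)

The control pool contains tested pairs with q > 0.05 (continuous mode)
or q > 0.05 and ρ < 0.2 (binary mode), minus anything called a COP.
COPs are processed in a seeded random order; each receives a uniformly
drawn pool pair whose TSS distance differs by ≤ 100 bp, without
replacement. The random processing order avoids systematic exhaustion
bias in dense distance strata. The tolerance is never widened: a COP
without a candidate is reported as unmatched rather than silently
matched farther away.

## Enrichment

A pair is "labeled" when both genes co-occur in ≥ 1 gene set (pathways,
complexes) or the pair is in an explicit reference set. Enrichment of a
query pair list against a background (the union of all tested pairs) is
a Fisher's exact test on the 2×2 table. The reported odds ratio is the
sample cross-product (ad)/(bc) with a Haldane 0.5 correction when a cell
is zero, with a Woolf 95% CI on the log-OR; this differs from the
conditional maximum-likelihood OR printed by some statistical packages,
typically only in the second decimal. The p-value itself is the exact
hypergeometric tail (one-sided "greater" by default).

## Gene–enhancer linking and sharing

Enhancer-state intervals (labels EnhG1/EnhG2/EnhA1/EnhA2 by default) are
merged whenever they overlap or are book-ended (no gap); accessibility
peaks are assigned to every region covering ≥ 50% of the peak, and a
region is active in a cell when any assigned peak is open. Each gene is
tested against every region whose midpoint is within ±1 Mb of its TSS by
Spearman correlation across the shared cells. The null shuffles the
gene's expression vector 1000 times, re-using each shuffle against all
of that gene's regions but counting exceedances per test — there is no
max statistic here; the per-test empirical p matches the screening
design, and BH over all gene–region tests controls the table-wide FDR.
A test is significant when q < 0.05 *and* ρ > 0.05; the floor is applied
as a conjunction on the final call (whether it is applied before or
after BH changes nothing for the calls themselves, only for the exact q
values of the excluded tests, and we keep all tests in the BH family).
An enhancer significant for both genes of a pair is a shared enhancer;
alongside the shared count, the number of enhancers *tested* for both
genes is reported so sharing differences can be checked against testing
opportunity. The "all peaks within ±100 kb" variant is the same code
path with peaks as regions and a smaller window.

## Hi-C support

Contacts are looked up for the bins (floor(pos/resolution)) containing
the gene TSS and the enhancer midpoint and transformed as log2(1 + x).
The plain log2 of a sub-unity normalized contact would be negative and
collide with the "missing contact = 0" rule, so the 1+x form keeps
"no contact" and "missing" at the same end of the scale; with boosted
real contacts the choice only shifts the threshold monotonically. When
TSS and midpoint share a bin the diagonal value is used as-is. Each
association gets a mirrored control — the enhancer position reflected
through the TSS (2·t − m, floored at 0) — which preserves genomic
distance exactly and therefore controls for distance decay. An
association is supported when its contact exceeds the 75th percentile
(linear interpolation) of contacts over *all* tested associations; a
gene pair is supported when at least one shared enhancer has
above-threshold contact with both TSSs simultaneously.

## Concordance readouts

TSS signal: per gene, the strand-matched track value covering the
0-based TSS base (half-open intervals; a TSS at an interval's end is not
covered). Proteomics: isoform intensities are summed per gene and
sample; a gene-sample whose isoforms are all missing stays missing and
drops the pair. The concordance statistic correlates (value of gene 1,
value of gene 2) across pairs (Spearman), computed only when > 10 usable
pairs remain. The negative control shuffles second-position genes across
pairs under a pair-level derangement (no shuffled pair may equal an
original pair), preserving the gene multiset.

## Synthetic data: what it emulates and what it does not

* `simulate_expression` — a Gaussian copula: planted pairs share a
  latent factor with weight √ρ; counts are the negative-binomial
  quantile transform (var = μ + αμ², default α = 0.5) of the latent
  normal CDF, with independent Bernoulli dropout (default 0.3) and
  per-gene log-normal mean heterogeneity (σ = 0.5 around mean-log 1.0).
  The copula preserves marginal count distributions exactly while
  controlling the latent correlation; the observable rank correlation is
  attenuated by zero-ties and dropout (latent ρ = 0.6 typically yields
  count-scale Spearman ≈ 0.2–0.35 at these defaults — the regime in
  which detection power is measured). Planted pairs are gene-disjoint so
  "true pair" is unambiguous in FDP accounting; chained correlations
  would create true-but-unplanted pairs. Pair members also share their
  base mean, which is the cross-pair signal the proteomics and TSS-track
  generators inherit.
* `simulate_multiome` — enhancers open per cell with probability 0.2;
  a linked gene's on-probability rises by `effect` when its enhancer is
  open (baseline 0.3). A shared entry drives two genes from one
  enhancer, inducing gene–gene co-expression: at effect 0.4 the induced
  pair phi is ≈ 0.11 (below the 0.2 binary COP floor — a realistic
  "co-regulated but weakly co-expressed" case), at 0.6 it is ≈ 0.24
  (detectable); the pipeline demo plants shared enhancers at 0.6 so the
  binary branch has callable COPs, while gene–enhancer links use 0.4.
  Decoy enhancers carry activity but no target; decoy peaks overlap no
  enhancer state and must be discarded by region assignment.
* `simulate_hic` — contact(i,j) = c·(1+|i−j|)^(−1)·lognormal, boosted
  ×4 on bin pairs joining a planted link's TSS and enhancer.
* `simulate_proteomics` / `simulate_groseq` — per-gene intensities /
  Poisson TSS reads tracking the expression truth, with isoform
  splitting, missingness and opposite-strand decoys.

Not emulated: batch and library-size structure beyond a global scaling,
cell-cycle covariation, doublets, mappability artifacts (cross-map
scores are an input), genomic sequence context, and trans effects.
Passing tests therefore demonstrate the statistical machinery — error
control, power under planted effects, correct plumbing — not robustness
to every failure mode of real single-cell data.

## Problem sizes and defaults

The acceptance-style experiments use 220 genes / 100 planted pairs / 500
cells / 20 replicates (COP branch) and 55 genes / 50 links / 2000 cells /
10 replicates (multiome branch), with 1000 permutations everywhere —
small enough to run on a laptop CPU in minutes while keeping ≥ 500 null
tests per replicate for stable FDP estimates. The pipeline demo uses 200
genes at 150 kb spacing. Under these conditions COP detection shows mean
FDP ≪ 5% (the max-null is conservative for single pairs) and the
gene–enhancer screen shows mean FDP ≈ 5%, i.e. at its nominal level,
with replicate-to-replicate Monte-Carlo spread of a few percentage
points.

## Scope notes

Size-factor normalization is a simple counts-per-median-library scaling:
downstream statistics are rank-driven (rank-INT, Spearman), which makes
the size-factor estimator nearly irrelevant, and pre-normalized matrices
are accepted directly. Cell-cycle phase labels are an input
(`subset_cells_by_phase`), not predicted. Term-level gene-list
enrichment, peak calling, chromatin-state learning, Hi-C normalization
and binary genomics formats (.hic/cooler/bigWig/BAM) are out of scope;
Hi-C is consumed as position- or bin-keyed plain-text triplets.
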