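# Methods

This note documents the models implemented in `epidiff`, the assumptions
they make, the defaults they ship with, and what the synthetic-cohort
generator does and does not emulate.

## Cytosine contexts and strand handling

Every cytosine is labelled by its three-letter (CNN) context, read 5′→3′
on the cytosine's own strand: the plus-strand context is the reference
triplet at `pos..pos+2`; the minus-strand context is the reverse
complement of the triplet ending at `pos`. Sixteen contexts exist. CG
dinucleotides are strand-symmetric, so the counts of the plus-strand C at
position *i* and the minus-strand C at *i+1* are summed and assigned to
*i* before differential analysis; a dyad covered on only one strand keeps
that strand's counts rather than being discarded — this preserves coverage
at the cost of slightly noisier estimates at asymmetrically covered
dyads. CAC is strand-asymmetric and analysed per strand. Coordinates are
0-based half-open everywhere inside the package; 1-based numbers appear
only in formatted output.

Sites are retained for differential analysis when they carry ≥4 reads in
≥10 samples of *each* group; a second preset (cohort-wide mean coverage
≥5) serves descriptive summaries. Genome-wide context means are unweighted
across sites — every covered site contributes equally regardless of depth —
which is robust to depth variation; a read-weighted mean would shift the
estimate toward deeply covered regions. Sites with zero coverage in a
sample have an undefined (not zero) fraction and drop out of that sample's
means.

## Differential methylation model

Per sample and chromosome, methylation fractions are smoothed by
tricube-weighted local-linear regression with a ±500 bp window widened
symmetrically (in sites) until it holds ≥20 covered sites; smoothed values
are clipped to [0, 1]. Chromosomes with fewer than 20 sites fall back to
raw fractions with a warning. These defaults mirror the documented
contract of the standard smoothing-based WGBS tools and are applied
identically in both contexts.

Each site is tested with an unpaired Welch t test on the smoothed
per-sample values (Welch–Satterthwaite degrees of freedom, two-sided p).
Degenerate sites are resolved deterministically: zero variance in both
groups with equal means gives t = 0, p = 1; zero variance with unequal
means gives p = 1e−300 with an infinite statistic, flagged by its sign.

DMRs are maximal runs of consecutive individually significant sites
(p < 0.001) with a consistent difference sign and inter-site gaps ≤300 bp;
a run must contain ≥5 sites and show an absolute group difference of mean
**raw** methylation ≥1% (smoothed values drive the per-site tests only —
applying the 1% rule to smoothed means would double-count the smoothing).
The region spans its member sites; boundaries are not extended beyond
them. `areaStat`, the sum of member t statistics, is additive under any
split of a region and measures region-level evidence.

Retention under covariates: per DMR, ordinary least squares of per-sample
mean raw methylation on group + age + sex; the DMR is kept iff the group
coefficient's p < 0.05, recorded as `covar_p`. This is the simplest
reading of "adjusting for age and sex" for a fraction-valued response
averaged over a region; constant covariates (e.g. a single-sex cohort) are
dropped with a warning rather than producing a rank-deficient design. Note
the model is only identifiable when the groups overlap in age — with
completely disjoint age ranges, group and age are collinear and genuine
group effects are absorbed into the age term.

Two-sided tests are used throughout; a DMR's direction (HYPER/HYPO with
respect to the case group) is taken from the sign of the difference.

## Chromatin-state maps and transitions

Per-sample segmentations are rasterised onto a 200-bp bin grid
(majority-bp per bin; uncovered bins are MISSING). The cohort consensus
keeps a bin's modal state when its count reaches the threshold (6 of 11
for the reference design), counting only non-missing labels; ties at the
threshold are conservative (AMBIGUOUS) — impossible when the threshold
exceeds half the samples, and for the small group maps determinism beats a
forced call. Group maps use threshold ⌈0.70 × n⌉, i.e. 3/4 and 5/7 for a
4 + 7 design.

Transitions are bins confidently labelled in both group maps but with
different labels; adjacent bins sharing the same (from, to) pair merge
into regions with no minimum length (single-bin transitions are allowed).
The K × K transition table is reported both region-weighted (the default
unit for percentages) and bin-weighted, since either convention is
defensible; row/column totals and the observed-vs-possible type counts
(K(K−1) = 90 for K = 10) accompany it.

Regions are annotated to genomic features by their midpoint with the
precedence promoter (≤1 kb upstream of a TSS, then 1–3 kb) > gene body >
immediate downstream (≤1 kb past the TES) > intergenic (gene desert beyond
1 Mb of any gene, configurable). State-vs-feature fold enrichment is plain
bp accounting: observed joint fraction over the product of marginal
fractions.

## Region enrichment

Regulatory domains follow the basal-plus-extension rule: basal = TSS
−5 kb/+1 kb (strand-aware); each side extends to the nearest neighbouring
basal-domain boundary, capped at 1 Mb from the TSS and clipped at
chromosome ends, never shrinking below the gene's own basal domain.
A region hits a gene iff its midpoint lies in the gene's extended domain
(deterministic, and the natural analogue of the cited association rule);
multi-gene hits are allowed.

Per term: the binomial test compares the count of regions whose midpoints
fall in the union of the term genes' domains against the union's fraction
of the background genome (the total unmasked genome length); the
hypergeometric test compares term-gene hits among all genes hit, within
the universe of all genes with domains. Benjamini–Hochberg runs within
each test family separately. A term passes only with fold ≥1.5 and q ≤0.1
in *both* families and ≥5 term genes hit. The co-occurrence score sums
−log10 of the **raw** binomial p over the transition types in which the
term passes (adjusted p would double-count the filtering). Keyword-based
category grouping is a configurable first-match substring map, shipped
empty — it is a reporting convenience, not hard-coded biology.

## Rank-rank overlap

Gene tables are restricted to their shared universe and ranked by
−log10(p) × sign(log2FC), ties broken by gene id for determinism, p floored
at 1e−300. The grid is stratified into four quadrants at the metric's
sign (concordant up-up and down-down; two discordant pairings); within a
quadrant, the overlap of the top-*i* genes of one list with the top-*j* of
the other is tested by upper-tail hypergeometric against the shared
universe, at rank step 140 (shrunk to ~N/10 when the universe holds fewer
than 280 genes). Benjamini–Yekutieli adjustment runs jointly over all
cells, as the cells are strongly dependent. The reported gene lists come
from the cell with the best adjusted p in each concordant quadrant.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline consumes,
not the raw sequencing process. Its defaults are the reference study
design: 17 reference vs 21 case methylomes, 4 + 7 state tracks, a
10-state model, two 1-Mb chromosomes.

* **Genome.** I.i.d. sequence at GC 0.40 with 85% of CpG dyads depleted,
  reproducing mammalian CpG sparsity (~1 CG dyad per ~170 bp, ~1 CAC per
  ~45 bp). This density matters: it sets how much an 8-site spike is
  attenuated inside the smoother's ≥20-site window. Genes (5–30 kb) are
  placed uniformly without overlap constraints.
* **Methylomes.** Coverage is negative-binomial (mean 10, shape 8).
  A site's per-sample methylation probability is Beta-distributed around
  its mean with overdispersion ρ = 0.02 (a typical between-individual
  scale for bisulfite data); counts are binomial. CG sites sit at 0.81;
  CAC is a mixture with mass near ~2% plus a minority fraction (15%)
  uniform in [0.10, 0.20], balanced so the genome-wide CAC mean equals
  0.041. Other contexts get fixed small baselines (CTC 1.8% … others
  0.3%) when requested.
* **Spikes.** DMR spikes shift the case-group mean by ±10 points over 8
  consecutive same-context sites, alternating sign; CAC hypo spikes are
  placed on minority-component sites so the loss has headroom. A
  configurable fraction (default 75%) of spikes cluster inside a few
  designated 100-kb target windows — real differential regions concentrate
  near functionally related genes, and this co-placement is what makes a
  "designed-enriched" gene set genuinely enriched rather than a label.
  Designed terms are the genes whose domains intersect a window;
  background terms sample genes uniformly.
* **Confounds.** Ages are uniform on [15, 70]; an optional group age gap
  (20 y in the covariate studies — large enough for a strong age-driven
  difference at slope 0.008/y, small enough that the groups' age ranges
  overlap and the OLS stays identifiable) plus an age slope on designated
  regions creates group differences fully attributable to age.
* **State tracks.** A latent segment map (geometric segment lengths, mean
  10 bins) per chromosome; case samples use a variant map with spiked
  5-bin segments switched to a different state; every sample's track is
  its group's map with independent per-bin mislabelling at rate ε = 0.1.
* **Rankings.** Latent bivariate-normal signed metrics at the requested
  correlation; p and log2FC are back-filled so the signed metric
  recomputes exactly.
* **Reproducibility.** One named RNG stream per output class (genome,
  methylomes, tracks, lists, gene sets), so adding an output class never
  perturbs another; identical configs give bit-identical outputs.

What the generator does **not** emulate: read-level artefacts (bisulfite
conversion failure, mapping bias, PCR duplicates), linkage disequilibrium
of methylation with genotype, realistic gene annotation structure, any
coupling between methylation and chromatin state beyond optional
co-placement of spikes, or cell-type heterogeneity. Passing tests
therefore demonstrate correctness of the analytical chain and its
operating characteristics under the stated generative model — not
robustness to those real-data artefacts.

## Problem sizes and numerical choices

The shipped verification runs use two 1-Mb chromosomes (≈62k retained
sites) for spike recovery, 600-kb single-chromosome cohorts for the
covariate studies, 2-Mb/200-gene cohorts for enrichment calibration and
700-gene rankings for the overlap null — sizes at which every measured
property is stable while a full run of the suite plus the acceptance
script stays around a minute. Stochastic checks fix their seeds and were
chosen to be representative; the acceptance script re-measures everything
under whatever seed it is given.

Degenerate inputs are handled explicitly rather than by exception where a
sensible value exists: empty tables produce empty (not erroneous)
results, k = 0 gives a binomial upper tail of 1, empty gene sets are
excluded with a warning, and a consensus threshold above the sample count
is an error. Smoothing falls back to raw values on sparse chromosomes.
Known limitations: the DMR caller's run-based definition fragments a true
region when an interior site misses the p threshold (mitigated but not
eliminated by smoothing); `overlap_dmrs` and `associate_regions` use
quadratic sweeps that are fine at these scales but would want interval
indexes for genome-scale region sets; and the covariate model tests only
linear age effects.
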