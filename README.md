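# epidiff

Context-aware differential epigenomics for two-group postmortem-brain-style
cohorts: DNA methylation analysed separately in the strand-symmetric CG and
the brain-enriched non-CG (CAC) contexts, chromatin-state maps compared
between groups, region-based gene-set enrichment, and rank-rank overlap of
transcriptome rankings. A seeded synthetic-cohort generator with recorded
ground truth makes every stage of the chain benchmarkable.

## Who this is for

Groups analysing whole-genome bisulfite (WGBS) and ChIP-seq-derived
chromatin-state data from small two-group human cohorts (cases vs
controls), who need a differential pipeline whose operating
characteristics — sensitivity, false-call rate, confound handling — can be
measured on data with known truth before being trusted on real samples.

## The methods at the core

**Differential methylation.** Per-cytosine methylation fractions are
smoothed per sample by tricube-weighted local-linear regression (window
±500 bp, widened to cover ≥20 sites). Each site gets an unpaired Welch
t test between groups on the smoothed values (Welch–Satterthwaite df,
two-sided p). A DMR is a maximal run of ≥5 consecutive significant sites
(P < 0.001) with a consistent sign, inter-site gaps ≤300 bp, and an
absolute raw group difference ≥1%; its `areaStat` is the sum of member t
statistics. Each DMR is then re-tested by OLS of per-sample region-mean
methylation on group + age + sex and retained only if the group term stays
significant (p < 0.05). CG dyads are strand-merged (counts of the plus
C at *i* and the minus C at *i+1* summed at position *i*) before analysis;
CAC sites are strand-specific by nature.

**Chromatin states.** Per-sample 200-bp state tracks (a 10-state alphabet)
form a cohort consensus map (modal state where ≥6/11 samples agree) and
per-group maps at 70% within-group agreement (3/4 and 5/7 for the
reference 4 + 7 design). Bins where both group maps are confidently
labelled but differ are state transitions (ST); among K = 10 states there
are K(K−1) = 90 possible ordered ST types.

**Enrichment.** Regions are associated to genes GREAT-style: a basal
regulatory domain (5 kb upstream / 1 kb downstream of the TSS,
strand-aware) extended to the nearest neighbouring basal domain, at most
1 Mb. Each gene-set term is tested two ways — an upper-tail binomial on
regions landing in the term's domain union, and an upper-tail
hypergeometric on the genes hit — and passes only with fold ≥1.5 and BH
FDR q ≤0.1 on *both* tests plus ≥5 term genes hit. A term's co-occurrence
score across ST types is Σ −log10(binomial P) over the types in which it
passes.

**Rank-rank overlap (RRHO).** Two gene rankings by the signed metric
−log10(p) × sign(log2FC) are stratified at the metric's sign; overlaps of
top-*i* vs top-*j* genes (default rank step 140) are tested by upper-tail
hypergeometric per grid cell and corrected jointly with
Benjamini–Yekutieli.

## Worked example

```python
import numpy as np
from epidiff import SimConfig, DifferentialMethylation
from epidiff.simulate import make_genome, make_methylomes
from epidiff.methylome import filter_coverage, merge_cg

cfg = SimConfig(seed=1)          # 17 vs 21 samples, 50 spiked DMRs/context
genome = make_genome(cfg)
table, meta, truth = make_methylomes(cfg, genome)

table = filter_coverage(table, meta)   # >=4 reads in >=10 samples per group
merged = merge_cg(table)

result = DifferentialMethylation(merged, meta, context="CG").fit()
print(result.summary())
```

prints

```
Differential methylation (CG context)
  sites tested:          11887
  DMRs called:           47
  dropped by covariates: 4
  hyper / hypo:          23 / 24
  mean |diff| (%):       6.63
  mean n_sites:          9.2
  p_thresh = 0.001
  min_sites = 5
  max_gap_bp = 300
  min_diff = 0.01
  halfwidth_bp = 500
  alpha = 0.05
```

Of the 50 CG-context spikes in `truth.true_dmrs` (Δ = 10 percentage
points over 8 consecutive dyads), the 47 called regions recover 42 with at
least 1 bp of overlap; the near-even split between hyper- and
hypomethylated calls mirrors the alternating spike signs, the mean
|difference| of ~6.6% reflects smoothing attenuation of the 10% spikes,
and four called regions were discarded because their group effect did not
survive age/sex adjustment. The same `fit()` interface drives the chromatin-state
(`StateTransitionModel`), enrichment (`RegionEnrichment`) and RRHO
(`RankRankOverlap`) models; a thin `epidiff` CLI wraps the same calls for
shell use (`epidiff simulate`, `epidiff call-dmrs`, `epidiff states
transitions`, `epidiff enrich`, `epidiff rrho`, ...).

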