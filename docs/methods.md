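# Methods

This note documents the models, statistics and numerical choices behind
`phosphonet`, and what the synthetic benchmarks do and do not establish
about real data.

## Landscape statistics

A protein is *phosphorylated* iff it carries ≥ 1 site; *homologous* iff its
HID groups it with at least one protein of another species. The seven
summary categories (all; non-phosphorylated and phosphorylated, each split
by homology) are exact partitions: counts are conserved at every level and
percentages are printed at two decimals with half-up rounding, matching the
convention of published proteome summary tables.

**Mean density** is the mean of per-protein ratios (1000·sites/length),
not 1000·(mean sites)/(mean length). The two differ whenever site count
and length covary; published per-category values are consistent with the
mean-of-ratios reading, which is also the statistically natural summary of
a per-protein quantity. Proteins lacking length/mass (seen only in a site
table) are excluded from density and regression stages but retained for
count-only stages (binning, networks), maximising usable data per stage.

**Density distribution.** Densities are rounded half-away-from-zero to
integer bins; the OLS of log10(frequency) on log10(bin) runs over bins ≥ 1
with nonzero frequency (log of the zero bin is undefined). With fewer than
two such bins the slope is undefined and flagged as `None` rather than
extrapolated.

## Homolog correlation

Within a species and HID, paralogs are aggregated by the arithmetic mean of
the metric before pairing — the simplest symmetric treatment, since
homology groupings carry no within-group weighting. Spearman's ρ is the
Pearson correlation of average (midrank) ranks, delegated to
`scipy.stats.spearmanr`; fewer than 10 pairs are refused (the estimate
would be dominated by noise) and zero-variance margins return NaN.
The default metric is the site count per protein; density is available as
an option. Strength bands assign boundary values to the lower band
(0.6 → moderate, 0.4 → weak): the conventional banding leaves the
endpoints open, and the downward assignment is the conservative reading.

The mass–site regression uses strict filters (mass < 500 000 Da,
sites < 500) on phosphorylated proteins only, limiting the leverage of
giant proteins and extreme site counts on the fitted slope.

## Binning with ties

For a k-quantile scheme over N proteins sorted by site count, the ideal
i-th boundary sits at rank i·N/k; a boundary landing inside a run of equal
counts moves **right** to the end of the run, so tied counts are never
split and bin sizes are only approximately N/k. When a run swallows an
entire ideal bin the partition simply has fewer bins. The
zero-plus-quartile scheme (for proteomes where most proteins carry no
site) first isolates the count-0 proteins, then quartiles the remainder.
A proteome with all counts equal yields a single bin with a warning.

**Network statistics.** The mean degree is 2E/N over *all* bin members,
isolated ones included: recomputation of the published per-bin tables shows
the printed values satisfy 2E/N exactly (18 of 20 cells to the printed
digit; two differ by one unit in the last digit, a display artifact).
Connected components are counted only at size ≥ 2 — isolated nodes are
reported separately as the singleton percentage, and counting them as
components would double-book them. The confidence threshold is strict
(score > 0.7) on the normalised [0, 1] scale.

## Enrichment

One-sided upper-tail hypergeometric p-values (via
`scipy.stats.hypergeom.sf`), validated in the tests against exact
combinatorial enumeration for every universe up to N = 12. The BH step-up
adjustment is `statsmodels`' `fdr_bh`. The FDR family is the set of terms
tested within one query label, matching the per-column structure of
enrichment heatmaps; the universe defaults to the accessions of the
annotation map and is configurable, since annotation tools differ on this
convention. Heatmap cells store log10(FDR) for significant cells
(FDR strictly < 0.05) and 0 otherwise, so all cells are ≤ 0.

## Kinase-group overlap

Euler regions are computed by direct membership enumeration: each distinct
target belongs to the region of exactly the groups containing it, so region
cardinalities always sum to the number of distinct targets — an invariant
checked before and after merging. The prominence filter keeps groups
targeting strictly more than 2 % of the distinct targets across all groups
(the dataset union, the denominator published alongside such analyses);
the denominator is configurable since a species-proteome reading is also
defensible. Merging collapses groups with set-equal targets under a
sorted composite label and is idempotent.

## Time-course modules

Variation counts apply the inclusive two-fold rule: a site counts at a time
point when its log2 fold-change versus control is ≤ −1 or ≥ +1. Counts are
monotone non-increasing in the threshold by construction.

The active-module search is a seeded greedy expansion of the standardised
mean-weight statistic z(M) = (mean weight in M − μ)/(σ/√|M|), with μ and σ
taken over all graph nodes (missing weights 0). Seeds are visited in
descending weight; growth adds the neighbour maximising z and stops when no
addition improves it; nodes claimed by a higher-seeded module are
unavailable to later ones, making modules connected and pairwise disjoint;
modules below a configurable z floor (default 2.0) are discarded and the
rest ranked by z. This is an Ideker-style node-weighted search chosen for
reproducibility and auditability: the embedding-based searcher used in the
original analysis is not re-implemented, but the contract (nonnegative node
weights in, ranked connected modules out) is identical, so another searcher
can be substituted. Greedy expansion is not globally optimal in general;
on planted instances with clear weight separation it matches exhaustive
connected-subgraph enumeration (verified on small graphs) and recovers
planted modules exactly in the benchmarks below. The number of modules per
time point is emergent, never a parameter.

Status tracking is relative to the *previous* time point only: new
(differential now, not before), persistent, reverted, unaffected, with
"differential" meaning variation count ≥ 1 by default — the weakest
reading consistent with the counting rule, and configurable.

## Synthetic data: what it emulates

* **Site counts**: zero-inflated discrete power law, P(k) ∝ k^−α on
  1..cap conditional on non-zero. Defaults: zero fraction 0.06
  (a heavily phosphorylated, human-like proteome), α = 1.5, cap 100.
  The power law is the simplest family consistent with a near-linear
  log–log density-frequency plot; α is a knob, not an inference.
  The cap may not exceed the minimum protein length because site positions
  are drawn uniformly without replacement along the protein.
* **Lengths/masses**: log-normal lengths (median ≈ 450 aa, floor 100 aa),
  mass ≈ 110 Da per residue with mild scatter.
* **Homolog pairs**: Gaussian copula on ranks. Discrete margins tie
  heavily, which attenuates tied-rank Spearman below the latent level, so
  the latent correlation is calibrated by Monte-Carlo bisection (fixed
  internal stream, 20 000 draws, 12 iterations) until the *empirical*
  Spearman converges to the planted value; |ρ| = 1 bypasses the copula and
  is exact. Recovery at n = 2000 is within ±0.05.
* **Interactions**: Chung–Lu edge probabilities with node weights
  exp(coupling · standardised log(1+sites)); coupling 0 degenerates to an
  Erdős–Rényi graph. Default base density 0.005 (≈ 10 expected partners at
  n = 2000). Edge confidence scores are drawn above the 0.7 cut so the
  thresholded graph equals the generated one.
* **Kinase maps**: exact set construction per planted region signature —
  region recounting is deterministic and noise-free by design.
* **Time courses**: six time points (1, 5, 10, 15, 20, 30 min), five
  measured sites per protein; planted-module proteins receive a scheduled
  number of exceeding sites per time point (magnitudes 1 + |N(0.8, 0.4)|,
  random sign; schedule peaking at 15 min), background sites exceed at
  rate 0.01.

Determinism: one global seed expands into fixed per-generator streams
(`numpy` SeedSequence spawn keys), so outputs are bit-identical under a
fixed seed and adding a generator never perturbs another's stream.

**What passing benchmarks do not show.** The generators reproduce the
*statistical couplings* the analyses consume, not biology: no sequences or
kinase motifs, no mass-spectrometry missingness or measurement error, no
correlated annotation structure, and module activation follows a clean
schedule. Recovery results therefore validate the estimation code paths,
not the biological conclusions reachable from any particular database
snapshot; quantities that depend on live database content (specific
correlation values, enrichment term lists, the published kinase-overlap
cardinalities) are treated as inputs, not reproduction targets.

## Problem sizes

The benchmark sizes are chosen so every stage runs comfortably on a
laptop-scale machine while keeping sampling error well inside the
acceptance bands: 2000 homolog pairs (Spearman null sd ≈ 0.022),
2000-protein proteomes for binning trends, 500-node graphs with 10-node
planted modules over 20 seeds for module recovery, and 5000 proteins for
the landscape summaries in the acceptance script.
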