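# Methods

## Overview

`helmscan` tests, SNP by SNP, whether population allele frequencies track an
environmental variable across a worldwide panel, using Kendall rank
correlation with a two-gate significance call, and then asks whether the
resulting gene list is enriched for a target gene set under a
SNP-count-matched resampling null.  The canonical environment is helminth
diversity — the number of parasitic-worm species/genera transmitted per
country — used as a proxy for long-term pathogen-driven selective pressure;
any per-country covariate (temperature, radiation flux, precipitation) can
be run through the same machinery, which is how the climate confounder
re-test works.

## Environmental variables

Diversity is a per-country count over a curated species × country
presence/absence matrix; every species transmitted in a country counts once
regardless of prevalence.  A `common_only` variant first removes species
flagged rare (or lacking any prevalence estimate) in *every* country where
they occur, giving a rarity-robustness check on the proxy.  Prevalence
surveys are averaged per (country, species) after dropping HIV-seropositive
cohorts (HIV modulates helminth susceptibility); species combine into group
values by unweighted mean over members with data — the combiner is
configurable (`max`, `sum`) because the right pooling of heterogeneous
surveys is genuinely open, and the mean is the symmetric, scale-preserving
default.

Environments are defined per country but the scan runs per population, so
country values are broadcast to populations; climate covariates, natively
per population, are averaged back to countries first.  Both directions exist
to keep one invariant: **every correlation in a run sees the same tie
structure** (all populations of a country share a value).  Ties are
therefore structural, and everything downstream is built tie-aware.

The packaged presence matrix is a synthetic stand-in curation (the original
source for such curations is a proprietary epidemiology database): 60 real
helminth species/genera across 21 countries with a tropical-skewed richness
pattern, each species transmitted somewhere, with per-cell rarity flags.  It
exercises the full curation surface — counts, rarity filtering, the
all-vs-common comparison — but its country values are not real epidemiology.

## Kendall τ_b and inference

τ_b = S/√((n₀−n₁)(n₀−n₂)) with S = C − D from pair enumeration and n₁, n₂
the tied-pair counts per margin.  The two-sided p uses the standard
tie-adjusted variance of S,

var S = [n(n−1)(2n+5) − Σt(t−1)(2t+5) − Σu(u−1)(2u+5)]/18
      + [Σt(t−1)][Σu(u−1)]/[2n(n−1)]
      + [Σt(t−1)(t−2)][Σu(u−1)(u−2)]/[9n(n−1)(n−2)],

summing over tie blocks of sizes t (first margin) and u (second).  No
continuity correction is applied by default (configurable); p-values are
two-sided throughout, with sign handled by allele orientation downstream.
Constant margins yield a flagged degenerate record (τ = NaN, p = 1) rather
than an exception so genome scans proceed past monomorphic SNPs.

The normal approximation is treated as valid for n ≥ 11.  Below that the
API warns and substitutes an exact permutation p where enumerable (n ≤ 9;
the tie pattern of the permuted margin is permutation-invariant, so the test
reduces to |S| and all n! values are evaluated vectorially); at n = 10
enumeration (3.6 M permutations) is not worth its cost and the normal
approximation is retained with the warning.  Measured behaviour at n = 9
under heavy ties: the normal p tracks the exact p to ≈0.05 on average, with
single instances off by up to ≈0.1 (one discreteness step); at n = 50 the
rejection rate at nominal 5% is 0.050 ± 0.002, and in the far tail
(p ≈ 10⁻⁴…10⁻⁶) the approximation is mildly conservative (≈0.5–0.7× the
nominal rate).

## The scan and its gates

Per SNP, MAF is the fold of the unweighted across-population mean reference
frequency, min(f̄, 1−f̄) — folding after averaging, matching a panel-level
MAF definition.  Missing frequencies are handled by pairwise deletion;
SNPs with fewer than 11 complete pairs are flagged untested and excluded
from all gates.  The scan is vectorised: one pairwise sign-matrix
contraction yields S for every SNP at once, tied-pair counts come from the
same sign matrix, and higher tie moments are computed per row only for the
rare rows containing ties, so 20,000 SNPs × 50 populations scan in roughly
a second.

Significance is the conjunction of two gates:

* **Bonferroni** — p < α/m with α = 0.05 and m = the number of SNPs
  *attempted* (degenerate and untested rows included), the convention that
  reproduces a printed panel-wide threshold from the panel size.
* **MAF-matched percentile** — |τ| strictly greater than the nearest-rank
  95th percentile of |τ| among all tested SNPs within ±0.01 MAF (window
  includes the focal SNP; a SNP alone in its window, or tied with all of
  it, cannot pass).  The gate operates on |τ| because per-SNP allele
  labelling makes the sign arbitrary.  Sorted by MAF the windows are
  contiguous with monotone ends, so a sliding Fenwick tree over discretised
  |τ| answers both the quantile and the percentile rank in O(m log m).

The percentile gate exists because population structure inflates
environmental correlations as a function of allele frequency: under shared
country-level drift the per-SNP p distribution is stochastically much
smaller than uniform (measured on the default synthetic null: >10% of
neutral SNPs reach p < 0.05 against the 5% nominal).  **What the gate does
and does not do** deserves emphasis.  It bounds the per-window call rate at
5% and removes any MAF-dependence of the implied |τ| threshold; it does not
recalibrate p.  Both gates are monotone in |τ| at fixed MAF, so they are
nearly nested: a drift-driven Bonferroni survivor usually also tops its MAF
window.  On the default synthetic panel (10 countries × 5 populations,
F_country = 0.05, F_pop = 0.01, β = 8, 50 planted / 20,050 SNPs) the scan
recovers essentially all planted SNPs (sensitivity ≈ 1.0 over 20 seeds) but
calls a few hundred neutral SNPs alongside them (truth-FDR ≈ 0.9).  That is
a property of the method under realistic clustered drift, not an
implementation artifact: honest error control at the country-cluster
resolution would require cluster-aware inference, which is outside this
method's definition.  Scan hits are candidate loci to be triaged by the
confounder re-test, gene context and enrichment — not a calibrated
discovery set.  With independent populations (no shared country effects)
the call is well behaved: zero significant SNPs in ≈97% of null runs,
consistent with the Bonferroni FWER bound.

The climate re-test correlates each significant SNP against each climate
covariate (broadcast per country) and applies Bonferroni within that
analysis (m = number of significant SNPs, per variable); hits explained by
climate would survive here, and the expectation for a genuine
pathogen-diversity signal is that none do.

## Gene mapping

Coordinates are 0-based half-open (BED).  A SNP belongs to a gene when it
falls in [tx_start − u, tx_end) on + genes or [tx_start, tx_end + u) on −
genes: u = 500 bp for scan reporting, 25 kb for gene-set analyses.  The
upstream window is strand-aware — "upstream of the TSS" is biologically
strand-defined even where a source convention is silent — with the TSS at
tx_start (+) or tx_end (−).  One transcript per gene; overlapping
transcripts are the data producer's job to merge.  Nearest-gene distance is
0 inside the transcript, otherwise the gap to the nearer boundary;
equidistant genes resolve to the lexicographically smaller gene_id.

## Enrichment

Genes covered by ≥1 SNP form the universe, quantile-binned into 24
intervals of typed-SNP count (interior edges use the "higher" quantile so
bins split at count gaps; duplicate edges merge, so the effective bin count
can be lower).  Each resample replaces every target gene with a uniform
draw from its bin, without replacement within the resample (a sampled gene
*set* is read as distinct genes; with-replacement is a flag for small
bins), and target genes remain in the pool (exclusion is a flag).  The
gene-level empirical p is upper-tailed, (1 + k)/(1 + R) to avoid zero
p-values; the SNP-count comparison is two-sided (2·min(tails), capped at
1), since either deviation is interpretable.  R defaults to 10,000;
calibration and power checks in the test-suite and acceptance script use
R = 999, which the (1+k)/(1+R) estimator supports without bias at the 5%
level, to fit single-CPU runtimes.

The genic χ² draws, per significant SNP, one uniform control among
non-significant SNPs within ±0.01 MAF, builds the 2×2 significant/control ×
genic/intergenic table and applies Pearson's χ² (1 df, two-sided, no
continuity correction by default).  Measured null calibration (significance
independent of genic status): rejection ≈ 5% at nominal 5%.

## Synthetic data

The generator emulates the features the scan depends on: populations nested
in countries; a country-level integer environmental gradient (default
1..n_countries) broadcast with ties; hierarchical Balding–Nichols drift
(ancestral p₀ ~ U(0.05, 0.95); country ~ Beta(p₀(1−F_c)/F_c,
(1−p₀)(1−F_c)/F_c); population likewise around the country value with
F_pop); planted SNPs with country mean logistic(a + βz), a ~ U(−1, 1), z
the standardised environment.  Defaults — 10 countries × 5 populations,
20,000 neutral + 50 planted SNPs, F_country = 0.05, F_pop = 0.01, β = 8 —
give worldwide-human-scale differentiation (F_ST ≈ 0.05 between countries)
at a desk-scale SNP count.  Annotation places non-overlapping genes
uniformly on one chromosome (order statistics of uniform gaps), SNP
positions uniform, and a target gene set sampled with configurable odds of
attracting planted SNPs, which plants the enrichment signal.

It does **not** emulate: linkage disequilibrium between SNPs (independent
given structure), realistic demography or admixture, genotype-level
sampling noise, SNP ascertainment bias, or correlated environments.
Passing tests therefore demonstrate the statistical machinery — tie
handling, gate behaviour, matching, calibration — under a clean drift
model; they do not certify performance on real panels, where LD clusters
hits and admixture adds structure the Balding–Nichols hierarchy lacks.

## Numerical and design notes

* One seeded `numpy` Generator drives each simulation; identical config +
  seed gives byte-identical output files.  Pipeline manifests record input
  checksums, configuration and seed.
* Nearest-rank percentile (ceil(q·w)-th order statistic) with strict
  inequality: on a window of 10,000 distinct |τ| values exactly 5% pass,
  and ties can only reduce the pass rate.
* erfc is used for the normal tail to keep precision at large |z|; p is
  floored at the smallest positive double rather than 0.
* Degenerate inputs: constant SNPs and constant climate vectors produce
  flagged records with p = 1 everywhere; empty windows and exhausted bins
  raise errors naming the offending SNPs/bins.
* Problem sizes in the acceptance script (5 recovery seeds, 20 null runs,
  100 calibration replicates, R = 999) are chosen to estimate each rate to
  the precision its comparison needs on a single CPU.
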