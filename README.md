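# helmscan

Environmental-correlation selection scans on population SNP panels, with
pathogen (helminth) diversity as the environmental variable.

## The problem

Parasitic worms chronically infect about a quarter of humanity and have done
so for far longer than our species has existed, which makes them one of the
strongest and most stable selective pressures on human immune genes.  Where
direct phenotypes are unavailable, a signature of that pressure can be
sought in allele-frequency geography: a SNP under helminth-driven selection
should have population allele frequencies that track the intensity of the
pressure across regions.  `helmscan` implements that scan for researchers in
population genetics and genetic epidemiology:

1. **Environment construction** — helminth diversity per country (the count
   of worm species/genera transmitted there, from a curated
   presence/absence matrix), prevalence-survey aggregation with HIV-cohort
   exclusion, and broadcast of country values onto populations (which
   deliberately creates tied blocks).
2. **Genome scan** — per-SNP Kendall rank correlation τ_b between
   reference-allele frequency and the environment, with a two-gate
   significance call:
   Bonferroni (two-sided *p* < α/*m*) **and** a MAF-matched empirical gate
   (|τ| strictly above the 95th percentile of |τ| among all SNPs whose MAF
   lies within ±0.01), plus a climate-covariate re-test of the hits.
3. **Gene context** — strand-aware SNP-to-gene assignment (transcribed
   region + 500 bp upstream for reporting, 25 kb for gene-set analyses),
   nearest-gene distances, and genic/intergenic classification.
4. **Enrichment** — SNP-count-matched resampling: the gene universe is cut
   into 24 quantile intervals of typed-SNP count, each target gene is
   replaced by a random same-interval gene in each of *R* resamples, and the
   empirical *p* is (1 + *k*)/(1 + *R*).  A companion χ² contrasts the
   genic fraction of significant SNPs against MAF-matched controls.
5. **Synthetic data** — a seeded generator producing the whole input suite
   with known truth: populations nested in countries, Balding–Nichols drift
   (country frequencies ~ Beta around an ancestral *p₀* with dispersion
   *F*_country, population frequencies likewise with *F*_pop), and planted
   SNPs whose country frequency is logistic(a + βz) in the standardised
   environment.

## The core statistic

For frequency vector *x* and environment *y* over *n* populations,

τ_b = S / √((n₀ − n₁)(n₀ − n₂)),  S = C − D,  n₀ = n(n−1)/2,

with n₁, n₂ the tied-pair counts of each margin.  Inference uses the
tie-adjusted variance of S (z = S/√var S, two-sided normal tail), valid for
n > 10 even under heavy ties; an exact n!-permutation p is available for
n ≤ 9 and serves as the test oracle.  Because several populations share a
country, ties are structural, not incidental — every stage preserves them so
all correlations in a run see comparable tie patterns.

## Worked example

`examples/` contains one narrative script per capability.
`python examples/03_selection_scan.py` simulates a 10-country × 5-population
panel (5,000 neutral + 25 planted SNPs, β = 8) and prints:

```
Bonferroni threshold: 9.950e-06
pass Bonferroni:      174
pass 95th percentile: 235
significant (both):   154

planted SNPs recovered: 21/25 (sensitivity 0.84)
neutral SNPs called:    133
```

All planted signals recovered here sit near the τ ceiling allowed by the tie
structure (≈0.96), but note the 133 neutral SNPs called alongside them:
shared country-level drift inflates neutral correlations, and the percentile
gate bounds the per-window call rate at 5% rather than restoring p-value
calibration.  A scan hit is a candidate for selection, not proof of it — see
`docs/methods.md` for the quantitative discussion.

The pipeline is also scriptable from a shell:

```
helmscan simulate --out-dir data/ --seed 1
helmscan all --frequencies data/frequencies.tsv --populations data/populations.tsv \
  --env data/env.tsv --genes data/genes.bed --snp-loci data/snp_loci.tsv \
  --gene-set data/geneset_target.txt --truth data/truth.tsv --out-dir results/
```

Every output directory carries a JSON manifest with input checksums, the
full configuration and the seed; identical config + seed reproduces results
byte for byte.

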