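# coevo

Phylogenetic comparative detection of gene-expression coevolution across
species.

## The problem

Genes whose expression rises and falls together across species are
candidates for shared function — but species are not independent samples.
Two yeasts that diverged ten million years ago inherit most of their
expression profile from a common ancestor, so an ordinary Pearson
correlation across species over-counts degrees of freedom and calls
"coevolution" where there is only shared ancestry. `coevo` is for
evolutionary genomicists who want to quantify expression coevolution of
gene (protein) pairs across a clade — e.g. RNA-seq panels spanning a fungal
phylogeny — while accounting for that non-independence, and to understand
how the common non-phylogenetic shortcuts behave.

## The model

Let C be the n×n species covariance matrix implied by a time-calibrated
tree (C_ij = depth of the most recent common ancestor of species i and j).
Two expression traits evolving by multivariate Brownian Motion with
evolutionary rate matrix

    R = [ r11  r12 ]
        [ r12  r22 ]

have tip values distributed as a 2n-variate normal with covariance
R ⊗ C plus per-observation measurement-error variance. The evolutionary
correlation

    ρ_C = r12 / √(r11 · r22)

measures how strongly the two traits' evolutionary *changes* are coupled,
and a likelihood-ratio test of the full model against a null with r12 = 0
(χ²₁) tests for coevolution. The package also implements:

- standard-lognormal cross-species normalization of TPM replicates with
  per-gene standard errors (and a proxy-SE rule for unreplicated species);
- the independent-contrasts screen for departures from Brownian Motion;
- the uncorrected correlation ρ_U and two empirical-null procedures built
  on it (histogram-crossover cutoff; per-pair randomization p-values with
  an FDR-calibrated cutoff);
- weighted Spearman correlations (weight = ½(1/N₁ + 1/N₂)) with bootstrap
  CIs, group t-tests, BH correction, membership-controlled resampling;
- Markov clustering of weighted interaction networks and a
  phylogenetically-corrected Covariance Ratio modularity test;
- a seeded synthetic-data generator and a benchmarking harness that scores
  all four detection methods by TPR/FPR/FDR/accuracy on labeled
  simulations.

## Worked example

```python
import numpy as np
from coevo import PhyloPairBM, fit_pair, lrt, vcv
from coevo.synthetic import SimConfig, generate_pair_sets

tree, panel, pairs = generate_pair_sets(SimConfig(n_binding=2, n_control=1, seed=4))
cov = vcv(tree)

rec = pairs[0]                       # a "binding" pair simulated with coevolution
x, se = panel.traits(rec.gene1, rec.gene2, species_order=cov.species)
est = PhyloPairBM(cov).fit(x.T, se=se.T)
test = est.test()
print(f"true rho = {rec.rho_true:.3f}")
print(f"rho_C    = {est.rho_c_:.3f}")
print(f"LRT stat = {est.lrt_stat_:.3f}, p = {est.p_value_:.4f}")
```

prints

```
true rho = 0.453
rho_C    = 0.438
LRT stat = 3.826, p = 0.0505
```

The fitted evolutionary correlation (0.438) recovers the simulated value
(0.453); with only 18 species even a moderately coupled pair sits right at
the significance boundary (p ≈ 0.05), which is exactly the power
limitation the benchmarking harness quantifies. A full end-to-end run (normalize → filter
→ fit → group tests → modules) is available as `coevo run`, and
`coevo benchmark` reproduces the method-comparison table on synthetic data;
see `coevo --help` for all subcommands.

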