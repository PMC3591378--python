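# gsikit

Bayesian genetic stock identification (GSI) and body-condition analysis
for mixed-stock samples of SNP-genotyped fish.

Fisheries studies often sample a mixture of individuals — say, juvenile
sockeye salmon netted in a nursery lake — whose populations of origin are
unknown but whose candidate source populations ("the baseline") have been
genotyped at the same markers. `gsikit` answers the two questions such
studies turn on:

1. **What fraction of the mixture comes from each stock?** A Gibbs sampler
   over the classic conditional Dirichlet mixture model yields posterior
   distributions of stock proportions and per-fish origin probabilities,
   with multi-chain Gelman–Rubin convergence checking, threshold-based
   individual assignment, and holdout calibration of assignment error
   rates against known-origin test mixtures.
2. **Do the identified groups differ in body condition?** Four nested
   grouped length–mass regressions are compared by small-sample AIC (AICc)
   and Akaike weights, alongside Bartlett-gated ANOVA / Kruskal–Wallis
   length comparisons.

A synthetic-data module generates baselines, mixtures, and length–mass
data with the statistical structure the analysis assumes (Balding–Nichols
population differentiation, Hardy–Weinberg genotypes, group-specific
allometries), so the whole pipeline is testable end to end without any
proprietary genotype data.

## The model

A mixture of N fish is drawn from K baseline populations with unknown
proportions **θ** ~ Dirichlet(α), default α_k = 1/K. Fish *i* has a latent
origin z_i ~ Categorical(**θ**), and its multilocus genotype g_i arises
from the origin's allele frequencies p_k: Hardy–Weinberg probabilities
(p², 2pq) at diploid SNPs, plain category frequencies at composite haploid
(mtDNA haplotype) and phenotype (joint MHC genotype class) loci, missing
calls contributing nothing. Allele frequencies carry per-locus Dirichlet
priors (1/A pseudocounts for an A-allele locus) updated by the baseline
counts. The Gibbs sweep alternates

    z_i | θ, p   ~  Categorical( θ_k · L(g_i | p_k) )
    θ  | z       ~  Dirichlet( α + origin counts )
    p_kl | z     ~  Dirichlet( prior + baseline counts + assigned mixture counts )

with the third step optional (`update_allele_freqs=False` conditions on the
baseline posterior-mean frequencies instead). Stock groups are reporting
units: group proportions are sums of member-population θ, and a fish is
assigned to a group when its posterior group probability meets the chosen
threshold (conventionally 80%), else left unassigned.

Body condition is compared on the log scale, log₁₀ m = β₀ + β₁ log₁₀ ℓ,
with the four candidate models sharing or splitting β₀ and β₁ between two
groups, ranked by

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1),   w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2).

## Worked example

`examples/01_mixture_analysis.py` simulates the default study structure —
13 baseline populations in three stock groups (5 Black Lake, 7 Chignik
Lake, 1 Chignik River), 92 SNPs plus composite mtDNA and MHC loci — draws
a 200-fish mixture at true proportions 25% / 75% / 0%, and runs three
chains:

```
group            true  sample    mean            95% CI      GR
Black Lake       0.25   0.275   0.282   [0.213, 0.354]   1.000
Chignik Lake     0.75   0.725   0.718   [0.645, 0.786]   1.000
Chignik River    0.00   0.000   0.001   [0.000, 0.006]   1.000
```

Each posterior mean sits next to the realized sample fraction, the 95%
credibility interval brackets the generating proportion, and Gelman–Rubin
statistics at 1.000 say the chains agree. The other examples demonstrate
holdout calibration and threshold choice (`02`), condition-model ranking
and length tests (`03`), and SNP panel preprocessing with composite-locus
construction (`04`).

A thin CLI wraps the same pipeline for shell use:

```bash
gsi run-all --config config.yaml --out run1 --seed 42 --thresholds 0.7,0.8,0.9
```

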