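# Methods

## The mixture model and its assumptions

`gsikit` implements the conditional Dirichlet mixture model that underlies
classical genetic stock identification. The assumptions, stated plainly:

* every mixture fish originates from one of the K baseline populations
  (the baseline is exhaustive);
* loci are independent within an individual (linkage-disequilibrium pairs
  are expected to be pruned in preprocessing, and jointly inherited
  markers combined into composite loci);
* diploid genotypes follow Hardy–Weinberg proportions within populations;
* composite haploid loci (e.g. a multi-SNP mitochondrial haplotype) and
  composite "phenotype" loci (a joint two-locus genotype class, used for
  tightly linked MHC loci) are modelled by their empirical category
  frequencies, with no Hardy–Weinberg expansion of the phenotype classes.

The Gibbs sampler alternates origin assignments z, mixture proportions θ,
and (optionally) allele frequencies p. Two variants are provided because
both are in common use:

* **full model** (`update_allele_freqs=True`, the default): mixture fish
  currently assigned to a population contribute to its allele-frequency
  conditional, so a large mixture can sharpen a small baseline;
* **conditional variant** (`update_allele_freqs=False`): frequencies stay
  fixed at their baseline posterior means. The genotype log-likelihood
  matrix is then computed once, which makes long chains roughly two orders
  of magnitude cheaper. With baselines of ~100 fish per population the two
  variants give near-identical posteriors; the package's own study-scale
  checks (coverage, calibration) use the conditional variant for runtime,
  and that choice is recorded in the calibration report.

All likelihood arithmetic is in log space. Categorical draws use a
max-shifted exponential and inverse-CDF step; a fish whose genotype is
impossible in every population (all −∞ rows, only possible with exactly
zero frequencies) falls back to the prior with a warning, as does a fish
with no genotype calls at all.

## Priors and defaults

| parameter | default | rationale |
|---|---|---|
| mixture prior α | 1/K per population | equal weight per pooled baseline population, total mass 1 |
| allele prior | 1/A per allele at an A-allele locus | flat total mass of one per locus (the convention of the Bayesian GSI family); `"unit"` (1 per allele) available |
| chains | 3 × 140,000 iterations, thin 7 | the literature configuration this package mirrors: 20,000 retained per chain |
| burn-in | 10,000 **retained** draws per chain | "burn-in 10,000" is interpreted on the thinned scale, i.e. half of the 20,000 retained draws; configurable |
| start scheme | 0.3 to each of 3 random populations, 0.1 split among the rest | distinct overdispersed starts per chain; K < 4 falls back to uniform |
| Gelman–Rubin threshold | 1.2 | a conventional pass level; the statistic is always reported so stricter users can re-gate. B = 0 (duplicated/constant chains) is defined as exactly 1 |
| assignment threshold | 0.80 report level, grid 0.50–0.90 | thresholds ≥ 0.5 guarantee at most one qualifying group (a tie at exactly 0.5 resolves to the maximal group); the 80% level is the conventional yield/error compromise |
| missing-fish exclusion | ≥ 15% of loci missing | inclusive comparison ("at least 15%") |
| error ceiling in `choose_threshold` | 0.15 | per-group mean error must stay below it; the smallest qualifying threshold maximizes yield |

Seeding: every random stream derives from `numpy.random.default_rng([seed,
tag])`; chain c uses `[seed, c]`, calibration replicate r uses
`[seed, 7919, r]` for the holdout draw and a derived integer for its
chains. Identical inputs and seed reproduce draw sequences bit for bit.

## Preprocessing semantics

* Monomorphism is judged on the **baseline only**: a locus with a single
  observed allele across all baseline populations is dropped even if the
  mixture shows variation (the baseline provides no discriminating
  information either way).
* A composite call is MISSING whenever any member call is MISSING —
  partial haplotypes are never invented.
* Composite construction requires individual-level baseline genotypes:
  joint haplotype counts cannot be derived from per-locus marginal counts,
  so counts-only baselines must ship composites pre-formed.
* Preprocessing is idempotent; a second pass reports nothing. A composite
  that itself comes out monomorphic is dropped in the same pass.
* Diploid calls are unordered and canonicalized lexicographically on read
  ("C/A" ≡ "A/C").

## Holdout calibration

Per replicate, `mixture_size` fish are drawn from the baseline with group
totals fixed by largest-remainder rounding of the target proportions and,
within a group, populations weighted by their baseline sample sizes (again
largest-remainder, ties broken by population order). The baseline is
rebuilt without the held-out fish — count conservation is exact and
tested — and the full MCMC + assignment is rerun. The error rate for a
group is 1 − precision: among fish assigned to the group, the fraction
whose true group differs. Replicates in which nobody is assigned to a
group leave that group's error undefined; such replicates are excluded
from the mean/SD and counted in `n_replicates_defined`. Groups designed at
0% (here Chignik River) contribute no holdout fish but remain assignable,
so spurious assignments to them would be visible. Calibration chains may
be shorter than production chains; the configuration used is attached to
the report.

## Condition models

The four candidate models regress log₁₀(mass in g) on log₁₀(fork length in
mm) — the standard allometric scale for the regression approach to fish
condition; `ln` and untransformed variants are exposed behind a
`transform` option since the choice moves coefficients but not the
comparison machinery. The parameter count k includes the residual variance
(k = 3, 4, 4, 5); a `count_sigma=False` flag drops it, which shifts every
AICc by a constant at fixed model but not uniformly across models at small
n, so the flag is part of the reported fit. Weights are presented at two
decimals with half-up rounding, matching how such tables are printed.
Degenerate inputs fail loudly: fewer than 3 fish per group, zero length
variance under a slope-varying model, or n ≤ k + 1 for the AICc
correction. With a single group label all four models collapse to the
shared line (k = 3).

Length comparisons gate on Bartlett's test at α = 0.05 (the gate level is
an argument): homoscedastic → one-way ANOVA with both between- and
residual-df reported, plus Tukey HSD pairwise comparisons when more than
two groups; heteroscedastic → Kruskal–Wallis. A zero-variance group makes
Bartlett undefined and falls through to Kruskal–Wallis with a note.

## Synthetic data: what it does and does not emulate

`simulate_baseline` draws ancestral diploid allele frequencies uniform on
(0.05, 0.95) (Dirichlet-uniform for composite categories) and population
frequencies from the Balding–Nichols Beta/Dirichlet with concentration
(1 − F)/F, so `differentiation` F acts like a fixation index relating
among-population spread to the ancestral frequency. Genotypes are
Hardy–Weinberg draws; mixtures draw group, then population uniformly
within group, then genotype; missingness is independent per call. The
default design mirrors the emulated study: 13 populations in 5/7/1 groups,
92 SNPs plus one 5-category haploid and one 6-category phenotype
composite, F = 0.05, 100 fish per baseline population, mixtures of 200 at
25/75/0. Condition data use group-specific log₁₀ allometries with normal
residuals (defaults near juvenile-sockeye values: intercept ≈ −5.1, slope
≈ 3.0, residual SD 0.035–0.045, lengths ~N(65–70, 5–8) mm truncated
positive).

Not emulated — so green tests say nothing about these features of real
data: linkage disequilibrium between simulated loci, genotyping error,
population structure beyond the single-F island-like model, age
structure, non-exhaustive baselines, and informative missingness.

## Numerical and testing choices

* Problem sizes in the study-scale checks are chosen to make the suite a
  few minutes long: coverage uses 20 replicates at the full default design
  with 3 × 20,000-iteration chains (thinned by 5, first 2,000 retained
  draws discarded); calibration checks use 10 replicates at two
  differentiation levels with single shorter chains; the
  exact-enumeration check uses 200,000 post-burn-in draws on a 4-fish
  instance, with the enumeration done by an independent
  Dirichlet-integral oracle.
* Interval coverage of a boundary-true value: posterior Dirichlet draws
  are strictly positive, so the equal-tailed interval for a group whose
  true proportion is exactly 0 has a positive (if astronomically small)
  lower limit. Coverage is therefore evaluated with an absolute tolerance
  of 1e-6 on the interval ends — the same convention under which such an
  interval is printed as "0–0.05".
* Empirical quantiles use linear interpolation (`numpy.quantile`
  defaults), cross-checked against an independent sort-and-interpolate
  oracle.
* Underflow guard: a Dirichlet row whose gamma draws all underflow to zero
  (possible only at tiny concentrations) is replaced by a uniform draw.

## Known limitations

* The full-model sampler recomputes the likelihood matrix every sweep;
  at the default 3 × 140,000 configuration it is only practical for
  mixtures of a few hundred fish. The conditional variant is the
  recommended setting for calibration sweeps.
* GenePop input supports diploid loci only and 2/3-digit numeric allele
  codes with `00`/`000` missing; it is a reading convenience, not the
  native format.
* The pipeline's condition stage needs exactly two assigned groups with
  length/mass data (or an explicit simulated design); three-group length
  comparisons are available through the library API.
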