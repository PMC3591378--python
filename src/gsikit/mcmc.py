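"""Bayesian mixed-stock analysis by Gibbs sampling.

The model is the classic conditional Dirichlet mixture for genetic stock
identification.  A mixture of N individuals is assumed to be drawn from K
baseline populations with unknown proportions theta ~ Dirichlet(alpha).
Each fish i carries a latent origin z_i ~ Categorical(theta), and its
multilocus genotype g_i is generated from the origin population's allele
frequencies p_k: Hardy–Weinberg genotype probabilities (p^2, 2pq) at
diploid loci and plain category frequencies at composite haploid or
phenotype loci.  Allele frequencies get per-locus Dirichlet priors whose
pseudocounts default to 1/A_l per allele (flat total mass of one per
locus), combined with the observed baseline counts.

The Gibbs sweep alternates

1. z_i | theta, p  ~  Categorical( theta_k * L(g_i | p_k) ),
2. theta | z       ~  Dirichlet( alpha + origin counts ),
3. optionally p_kl | z  ~  Dirichlet( prior + baseline counts + allele
   counts of mixture fish currently assigned to population k ).

Step 3 is the full model, in which mixture fish inform the baseline allele
frequencies; with ``update_allele_freqs=False`` frequencies stay fixed at
their baseline posterior means (the conditional variant), which lets the
genotype likelihood matrix be computed once and makes long chains cheap.

All likelihood arithmetic is in log space; categorical draws use a
normalized-cumulative-sum inverse-CDF step.  Runs are reproducible: every
random draw derives from ``(seed, chain_index)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .loci import MISSING, BaselineSet, GenotypeRecord, LocusDefinition

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorDraws",
    "MixtureSummary",
    "genotype_log_likelihood",
    "initial_theta",
    "run_chain",
    "run_chains",
    "summarize_groups",
    "gelman_rubin",
    "export_draws",
]

LOG2 = np.log(2.0)


@dataclass
class PriorSpec:
    """Priors for the mixture proportions and the allele frequencies.

    ``mixture_prior`` defaults to the uniform Dirichlet with total mass one:
    each of the K baseline populations gets parameter 1/K ("equal weight and
    the probabilities summing to one").  ``allele_prior_scheme`` is either
    ``"flat_total"`` (1/A_l per allele at a locus with A_l alleles) or
    ``"unit"`` (1 per allele).
    """

    mixture_prior: Optional[np.ndarray] = None
    allele_prior_scheme: str = "flat_total"

    def mixture_alpha(self, n_populations: int) -> np.ndarray:
        if self.mixture_prior is None:
            return np.full(n_populations, 1.0 / n_populations)
        alpha = np.asarray(self.mixture_prior, dtype=float)
        if alpha.shape != (n_populations,) or (alpha <= 0).any():
            raise ValueError("mixture_prior must be a positive K-vector")
        return alpha

    def allele_alpha(self, locus: LocusDefinition) -> np.ndarray:
        n = len(locus.alleles)
        if self.allele_prior_scheme == "flat_total":
            return np.full(n, 1.0 / n)
        if self.allele_prior_scheme == "unit":
            return np.ones(n)
        raise ValueError(f"unknown allele_prior_scheme {self.allele_prior_scheme!r}")


@dataclass
class ChainConfig:
    """MCMC run configuration.

    ``iterations`` raw Gibbs sweeps per chain with every ``thin``-th draw
    retained; ``burn_in`` counts *retained* draws discarded per chain before
    pooling.  The literature default mirrored here is 3 chains of 140,000
    iterations thinned by 7 (20,000 retained, the first 10,000 discarded).
    """

    n_chains: int = 3
    iterations: int = 140_000
    thin: int = 7
    burn_in: int = 10_000
    seed: int = 0
    start_scheme: str = "random_triple"
    update_allele_freqs: bool = True
    gr_threshold: float = 1.2

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.iterations % self.thin != 0:
            raise ValueError("iterations must be a multiple of thin")
        if self.iterations // self.thin < self.burn_in:
            raise ValueError("retained draws (iterations/thin) must be >= burn_in")

    @property
    def n_retained(self) -> int:
        return self.iterations // self.thin


@dataclass
class PosteriorDraws:
    """Retained draws from all chains plus per-individual origin tallies."""

    theta_draws: np.ndarray  # (n_chains, n_retained, K)
    burn_in: int
    z_counts: np.ndarray  # (N, K), tallies over post-burn-in retained draws
    populations: list
    groups: tuple
    group_indicator: np.ndarray  # (K, n_groups)
    individual_ids: list

    @property
    def n_chains(self) -> int:
        return self.theta_draws.shape[0]

    @property
    def pooled_theta(self) -> np.ndarray:
        """Post-burn-in draws pooled over chains, shape (n_draws, K)."""
        kept = self.theta_draws[:, self.burn_in:, :]
        return kept.reshape(-1, kept.shape[-1])

    @property
    def z_probs(self) -> np.ndarray:
        """Per-individual posterior population frequencies, rows sum to 1."""
        totals = self.z_counts.sum(axis=1, keepdims=True)
        return self.z_counts / totals

    @property
    def group_draws(self) -> np.ndarray:
        """Stock-group proportions per chain/draw: sums of member-population theta."""
        return self.theta_draws @ self.group_indicator

    def group_z_probs(self) -> np.ndarray:
        """Per-individual posterior stock-group probabilities, shape (N, n_groups)."""
        return self.z_probs @ self.group_indicator


@dataclass
class MixtureSummary:
    """Posterior summary of stock-group proportions over pooled chains."""

    groups: tuple
    mean: np.ndarray
    median: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    gelman_rubin: np.ndarray  # nan when < 2 chains
    gr_threshold: float

    @property
    def converged(self):
        """Per-group pass flags; None when the diagnostic is not computable."""
        if np.isnan(self.gelman_rubin).all():
            return None
        return self.gelman_rubin < self.gr_threshold

    def to_dict(self) -> dict:
        out = {}
        for j, g in enumerate(self.groups):
            gr = self.gelman_rubin[j]
            out[g] = {
                "mean": float(self.mean[j]),
                "median": float(self.median[j]),
                "ci95_low": float(self.q025[j]),
                "ci95_high": float(self.q975[j]),
                "gelman_rubin": None if np.isnan(gr) else float(gr),
                "converged": None if self.converged is None else bool(self.converged[j]),
            }
        return out


def genotype_log_likelihood(
    record: GenotypeRecord,
    pop_freqs: Mapping[str, np.ndarray],
    loci: Sequence[LocusDefinition],
) -> float:
    """Log-probability of one multilocus genotype given population frequencies.

    Diploid loci contribute Hardy–Weinberg terms log(p^2) or log(2pq);
    composite loci contribute the log category frequency; MISSING calls
    contribute zero.  An observed allele with zero frequency yields ``-inf``.
    """
    total = 0.0
    for loc in loci:
        call = record.calls.get(loc.name)
        if call is MISSING:
            continue
        freqs = np.asarray(pop_freqs[loc.name], dtype=float)
        idx = loc.allele_index()
        with np.errstate(divide="ignore"):
            if loc.is_diploid:
                a, b = call
                term = np.log(freqs[idx[a]]) + np.log(freqs[idx[b]])
                if a != b:
                    term += LOG2
            else:
                term = np.log(freqs[idx[call]])
        total += float(term)
    return total


def initial_theta(K: int, scheme: str, rng: np.random.Generator) -> np.ndarray:
    """Starting stock proportions for one chain.

    The ``random_triple`` scheme assigns 0.3 to each of three randomly
    chosen populations and splits the remaining 0.1 equally among the
    others; it needs K >= 4 and falls back to a uniform start (with a
    warning) otherwise.
    """
    if scheme == "uniform":
        return np.full(K, 1.0 / K)
    if scheme != "random_triple":
        raise ValueError(f"unknown start scheme {scheme!r}")
    if K < 4:
        warnings.warn(
            f"random_triple start needs K >= 4 (got {K}); using a uniform start"
        )
        return np.full(K, 1.0 / K)
    theta = np.full(K, 0.1 / (K - 3))
    triple = rng.choice(K, size=3, replace=False)
    theta[triple] = 0.3
    return theta


# ---------------------------------------------------------------------------
# internal numeric encoding


class _Encoded:
    """Baseline and mixture recoded to integer arrays for the sampler."""

    def __init__(self, baseline: BaselineSet, mixture, prior: PriorSpec):
        self.K = len(baseline.populations)
        self.N = len(mixture)
        self.loci = baseline.loci
        self.diploid = []  # (a1, a2, counts, alpha) per diploid locus
        self.categorical = []  # (cat, counts, alpha) per composite locus
        self.het_const = np.zeros(self.N)  # sum of log 2 over het calls per fish
        for loc in self.loci:
            idx = loc.allele_index()
            counts = baseline.count_matrix(loc).astype(float)
            alpha = prior.allele_alpha(loc)
            if loc.is_diploid:
                a1 = np.full(self.N, -1, dtype=np.int64)
                a2 = np.full(self.N, -1, dtype=np.int64)
                for i, rec in enumerate(mixture):
                    call = rec.calls.get(loc.name)
                    if call is MISSING:
                        continue
                    a1[i], a2[i] = idx[call[0]], idx[call[1]]
                    if call[0] != call[1]:
                        self.het_const[i] += LOG2
                self.diploid.append((a1, a2, counts, alpha))
            else:
                cat = np.full(self.N, -1, dtype=np.int64)
                for i, rec in enumerate(mixture):
                    call = rec.calls.get(loc.name)
                    if call is not MISSING:
                        cat[i] = idx[call]
                self.categorical.append((cat, counts, alpha))

    def posterior_mean_freqs(self):
        """Baseline posterior-mean frequency matrices, one per locus term."""
        dip = [
            (counts + alpha) / (counts + alpha).sum(axis=1, keepdims=True)
            for _, _, counts, alpha in self.diploid
        ]
        cat = [
            (counts + alpha) / (counts + alpha).sum(axis=1, keepdims=True)
            for _, counts, alpha in self.categorical
        ]
        return dip, cat

    def log_likelihood_matrix(self, dip_freqs, cat_freqs) -> np.ndarray:
        """(N, K) log L(g_i | p_k) for the given frequency matrices."""
        logL = np.tile(self.het_const[:, None], (1, self.K))
        with np.errstate(divide="ignore"):
            for (a1, a2, _, _), p in zip(self.diploid, dip_freqs):
                lp = np.log(p)  # (K, A)
                obs = a1 >= 0
                if obs.any():
                    logL[obs] += lp[:, a1[obs]].T + lp[:, a2[obs]].T
            for (cat, _, _), p in zip(self.categorical, cat_freqs):
                lp = np.log(p)
                obs = cat >= 0
                if obs.any():
                    logL[obs] += lp[:, cat[obs]].T
        return logL

    def sample_freqs(self, z: np.ndarray, rng: np.random.Generator):
        """Draw p from its full conditional given current origins z."""
        dip_out, cat_out = [], []
        for a1, a2, counts, alpha in self.diploid:
            conc = counts + alpha
            obs = a1 >= 0
            np.add.at(conc, (z[obs], a1[obs]), 1.0)
            np.add.at(conc, (z[obs], a2[obs]), 1.0)
            dip_out.append(_dirichlet_rows(conc, rng))
        for cat, counts, alpha in self.categorical:
            conc = counts + alpha
            obs = cat >= 0
            np.add.at(conc, (z[obs], cat[obs]), 1.0)
            cat_out.append(_dirichlet_rows(conc, rng))
        return dip_out, cat_out


def _dirichlet_rows(conc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    g = rng.standard_gamma(conc)
    s = g.sum(axis=1, keepdims=True)
    # tiny concentrations can underflow every gamma in a row; fall back to uniform
    bad = s[:, 0] == 0.0
    if bad.any():
        g[bad] = 1.0
        s = g.sum(axis=1, keepdims=True)
    return g / s


def _sample_categorical_rows(logw: np.ndarray, log_theta: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of logw (unnormalized log weights)."""
    m = logw.max(axis=1)
    dead = ~np.isfinite(m)
    if dead.any():
        # genotype impossible in every population: fall back to the prior
        logw = logw.copy()
        logw[dead] = log_theta
        m = logw.max(axis=1)
    w = np.exp(logw - m[:, None])
    c = np.cumsum(w, axis=1)
    u = rng.random(logw.shape[0]) * c[:, -1]
    z = np.sum(c < u[:, None], axis=1)
    return np.minimum(z, logw.shape[1] - 1)


def run_chain(
    baseline: BaselineSet,
    mixture: Sequence[GenotypeRecord],
    prior: PriorSpec,
    config: ChainConfig,
    chain_index: int,
    _encoded: Optional[_Encoded] = None,
):
    """Run one Gibbs chain; returns ``(theta draws, post-burn-in z tallies)``.

    ``theta draws`` has shape (n_retained, K); tallies have shape (N, K).
    The random stream is a pure function of ``(config.seed, chain_index)``.
    """
    enc = _encoded if _encoded is not None else _Encoded(baseline, mixture, prior)
    rng = np.random.default_rng([config.seed, chain_index])
    K, N = enc.K, enc.N
    alpha = prior.mixture_alpha(K)

    all_missing = np.ones(N, dtype=bool)
    for a1, _, _, _ in enc.diploid:
        all_missing &= a1 < 0
    for cat, _, _ in enc.categorical:
        all_missing &= cat < 0
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} mixture individual(s) have no genotype "
            "calls and are allocated by the prior alone"
        )

    theta = initial_theta(K, config.start_scheme, rng)
    dip_freqs, cat_freqs = enc.posterior_mean_freqs()
    logL = enc.log_likelihood_matrix(dip_freqs, cat_freqs)

    n_ret = config.n_retained
    theta_out = np.empty((n_ret, K))
    z_tally = np.zeros((N, K))
    burn_iter = config.burn_in * config.thin
    kept = 0
    for it in range(1, config.iterations + 1):
        log_theta = np.log(theta)
        z = _sample_categorical_rows(logL + log_theta, log_theta, rng)
        counts = np.bincount(z, minlength=K)
        theta = rng.dirichlet(alpha + counts)
        if config.update_allele_freqs:
            dip_freqs, cat_freqs = enc.sample_freqs(z, rng)
            logL = enc.log_likelihood_matrix(dip_freqs, cat_freqs)
        if it % config.thin == 0:
            theta_out[kept] = theta
            kept += 1
            if it > burn_iter:
                z_onehot_tally(z_tally, z)
    return theta_out, z_tally


def z_onehot_tally(tally: np.ndarray, z: np.ndarray) -> None:
    np.add.at(tally, (np.arange(z.shape[0]), z), 1.0)


def run_chains(
    baseline: BaselineSet,
    mixture: Sequence[GenotypeRecord],
    prior: Optional[PriorSpec] = None,
    config: Optional[ChainConfig] = None,
) -> PosteriorDraws:
    """Run ``config.n_chains`` independent chains and pool them."""
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    enc = _Encoded(baseline, mixture, prior)
    theta_all = np.empty((config.n_chains, config.n_retained, enc.K))
    z_counts = np.zeros((enc.N, enc.K))
    for c in range(config.n_chains):
        theta_all[c], tally = run_chain(
            baseline, mixture, prior, config, chain_index=c, _encoded=enc
        )
        z_counts += tally
    return PosteriorDraws(
        theta_draws=theta_all,
        burn_in=config.burn_in,
        z_counts=z_counts,
        populations=list(baseline.populations),
        groups=baseline.groups,
        group_indicator=baseline.group_indicator(),
        individual_ids=[rec.individual_id for rec in mixture],
    )


def gelman_rubin(per_chain_series: np.ndarray) -> float:
    """Potential scale reduction factor over >= 2 equal-length chains.

    With within-chain variance W (mean of per-chain sample variances) and
    between-chain variance B (n times the variance of chain means), returns
    sqrt( ((n-1)/n * W + B/n) / W ).  Identical constant chains give 1.0.
    """
    series = np.asarray(per_chain_series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2 or series.shape[1] < 2:
        raise ValueError("need >= 2 chains each of length >= 2")
    m, n = series.shape
    W = series.var(axis=1, ddof=1).mean()
    B = n * series.mean(axis=1).var(ddof=1)
    if B == 0.0:
        # indistinguishable chains (duplicated or all constant): converged
        return 1.0
    if W == 0.0:
        return np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def summarize_groups(
    draws: PosteriorDraws, gr_threshold: float = 1.2
) -> MixtureSummary:
    """Mean, median, and equal-tailed 95% interval of group proportions.

    Summaries use draws pooled over chains after burn-in; the Gelman–Rubin
    statistic is computed per group across chains (nan with one chain).
    """
    gd = draws.group_draws[:, draws.burn_in:, :]  # (chains, kept, G)
    if gd.size == 0:
        raise ValueError("no post-burn-in draws to summarize")
    pooled = gd.reshape(-1, gd.shape[-1])
    q025, med, q975 = np.quantile(pooled, [0.025, 0.5, 0.975], axis=0)
    n_groups = gd.shape[-1]
    gr = np.full(n_groups, np.nan)
    if draws.n_chains >= 2 and gd.shape[1] >= 2:
        gr = np.array([gelman_rubin(gd[:, :, j]) for j in range(n_groups)])
    return MixtureSummary(
        groups=draws.groups,
        mean=pooled.mean(axis=0),
        median=med,
        q025=q025,
        q975=q975,
        gelman_rubin=gr,
        gr_threshold=gr_threshold,
    )


def export_draws(draws: PosteriorDraws, theta_path, group_path) -> None:
    """Write retained draws as TSV: chain, draw, then one column per unit."""
    import pandas as pd

    n_chains, n_ret, K = draws.theta_draws.shape
    chain_col = np.repeat(np.arange(n_chains), n_ret)
    draw_col = np.tile(np.arange(n_ret), n_chains)
    theta_flat = draws.theta_draws.reshape(-1, K)
    df = pd.DataFrame(theta_flat, columns=draws.populations)
    df.insert(0, "draw", draw_col)
    df.insert(0, "chain", chain_col)
    df.to_csv(theta_path, sep="\t", index=False, float_format="%.8g")

    gd = draws.group_draws.reshape(-1, len(draws.groups))
    gdf = pd.DataFrame(gd, columns=list(draws.groups))
    gdf.insert(0, "draw", draw_col)
    gdf.insert(0, "chain", chain_col)
    gdf.to_csv(group_path, sep="\t", index=False, float_format="%.8g")
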