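"""Gibbs sampler: likelihoods, starts, draws, convergence diagnostics."""

import numpy as np
import pytest

from gsikit.loci import DIPLOID, HAPLOID_COMPOSITE, MISSING, LocusDefinition
from gsikit.mcmc import (
    ChainConfig,
    PriorSpec,
    gelman_rubin,
    genotype_log_likelihood,
    initial_theta,
    run_chain,
    run_chains,
    summarize_groups,
)
from gsikit.mcmc import _sample_categorical_rows

from conftest import make_baseline, make_record
from oracles import brute_genotype_loglik, exact_mixture_posterior, quantile_linear


# ------------------------------------------------------------------ likelihood


def test_certain_homozygote_has_zero_loglik():
    loci = [LocusDefinition("L1", DIPLOID, ("A", "C"))]
    rec = make_record("f", {"L1": ("A", "A")})
    assert genotype_log_likelihood(rec, {"L1": [1.0, 0.0]}, loci) == 0.0


def test_heterozygote_probability_is_2pq():
    loci = [LocusDefinition("L1", DIPLOID, ("A", "C"))]
    rec = make_record("f", {"L1": ("A", "C")})
    ll = genotype_log_likelihood(rec, {"L1": [0.5, 0.5]}, loci)
    assert np.isclose(np.exp(ll), 0.5)


def test_zero_frequency_gives_minus_inf_not_exception():
    loci = [LocusDefinition("L1", DIPLOID, ("A", "C"))]
    rec = make_record("f", {"L1": ("C", "C")})
    assert genotype_log_likelihood(rec, {"L1": [1.0, 0.0]}, loci) == -np.inf


def test_missing_loci_contribute_nothing():
    loci = [
        LocusDefinition("L1", DIPLOID, ("A", "C")),
        LocusDefinition("L2", DIPLOID, ("G", "T")),
    ]
    freqs = {"L1": [0.25, 0.75], "L2": [0.6, 0.4]}
    full = make_record("f", {"L1": ("A", "C"), "L2": MISSING})
    only = make_record("g", {"L1": ("A", "C")})
    assert genotype_log_likelihood(full, freqs, loci) == pytest.approx(
        genotype_log_likelihood(only, freqs, [loci[0]])
    )


def test_multilocus_loglik_matches_per_locus_brute_force():
    rng = np.random.default_rng(5)
    loci = [
        LocusDefinition("L1", DIPLOID, ("A", "C")),
        LocusDefinition("L2", DIPLOID, ("G", "T")),
        LocusDefinition("L3", DIPLOID, ("A", "G", "T")),
        LocusDefinition("mt", HAPLOID_COMPOSITE, ("H1", "H2", "H3")),
        LocusDefinition("L5", DIPLOID, ("C", "T")),
    ]
    for _ in range(20):
        freqs = {}
        for loc in loci:
            p = rng.dirichlet(np.ones(len(loc.alleles)))
            freqs[loc.name] = p
        calls = {}
        for loc in loci:
            if loc.is_diploid:
                a, b = rng.choice(loc.alleles, size=2)
                calls[loc.name] = tuple(sorted((a, b)))
            else:
                calls[loc.name] = rng.choice(loc.alleles)
        rec = make_record("f", calls)
        assert genotype_log_likelihood(rec, freqs, loci) == pytest.approx(
            brute_genotype_loglik(rec, loci, freqs), rel=1e-12
        )


# ------------------------------------------------------------------ starts


def test_random_triple_start_scheme_k13():
    theta = initial_theta(13, "random_triple", np.random.default_rng(0))
    vals = np.sort(theta)[::-1]
    assert np.allclose(vals[:3], 0.3)
    assert np.allclose(vals[3:], 0.01)
    assert theta.sum() == pytest.approx(1.0)


def test_start_scheme_k4_forced_pattern():
    theta = initial_theta(4, "random_triple", np.random.default_rng(1))
    assert sorted(np.round(theta, 10)) == [0.1, 0.3, 0.3, 0.3]


def test_start_scheme_small_k_falls_back_to_uniform():
    with pytest.warns(UserWarning, match="uniform"):
        theta = initial_theta(3, "random_triple", np.random.default_rng(2))
    assert np.allclose(theta, 1 / 3)


def test_high_triple_selection_frequency():
    """Over many seeded draws each population lands in the 0.3-triple about
    3/13 of the time (binomial check, 4 sigma)."""
    rng = np.random.default_rng(42)
    K, n = 13, 1000
    hits = np.zeros(K)
    for _ in range(n):
        hits += initial_theta(K, "random_triple", rng) > 0.2
    freq = hits / n
    se = np.sqrt((3 / 13) * (10 / 13) / n)
    assert (np.abs(freq - 3 / 13) < 4 * se).all()


# ------------------------------------------------------------------ chains


def test_retained_draw_count_arithmetic(two_pop_one_locus_baseline):
    mix = [make_record("f1", {"L1": ("A", "C")})]
    config = ChainConfig(
        n_chains=1, iterations=1400, thin=7, burn_in=100, seed=0,
        update_allele_freqs=False,
    )
    assert config.n_retained == 200
    theta, _ = run_chain(two_pop_one_locus_baseline, mix, PriorSpec(), config, 0)
    assert theta.shape == (200, 2)


def test_pooled_draws_and_single_chain_diagnostic(two_pop_one_locus_baseline):
    mix = [make_record("f1", {"L1": ("A", "A")})]
    config = ChainConfig(
        n_chains=3, iterations=400, thin=2, burn_in=100, seed=3,
        update_allele_freqs=False,
    )
    draws = run_chains(two_pop_one_locus_baseline, mix, PriorSpec(), config)
    assert draws.pooled_theta.shape == (3 * 100, 2)
    # pooled mean equals the average of per-chain post-burn-in means
    per_chain = draws.theta_draws[:, 100:, :].mean(axis=1)
    np.testing.assert_allclose(draws.pooled_theta.mean(axis=0), per_chain.mean(axis=0))

    single = ChainConfig(
        n_chains=1, iterations=400, thin=2, burn_in=100, seed=3,
        update_allele_freqs=False,
    )
    sdraws = run_chains(two_pop_one_locus_baseline, mix, PriorSpec(), single)
    summary = summarize_groups(sdraws)
    assert np.isnan(summary.gelman_rubin).all()
    assert summary.converged is None


def test_theta_and_zprobs_normalization(two_pop_one_locus_baseline):
    rng = np.random.default_rng(7)
    mix = [
        make_record(f"f{i}", {"L1": tuple(sorted(rng.choice(["A", "C"], 2)))})
        for i in range(8)
    ]
    config = ChainConfig(
        n_chains=2, iterations=600, thin=3, burn_in=50, seed=1,
        update_allele_freqs=True,
    )
    draws = run_chains(two_pop_one_locus_baseline, mix, PriorSpec(), config)
    np.testing.assert_allclose(draws.theta_draws.sum(axis=2), 1.0, atol=1e-9)
    np.testing.assert_allclose(draws.z_probs.sum(axis=1), 1.0, atol=1e-9)


def test_determinism_bit_identical(two_pop_one_locus_baseline):
    mix = [make_record("f1", {"L1": ("A", "C")}), make_record("f2", {"L1": ("C", "C")})]
    config = ChainConfig(
        n_chains=2, iterations=300, thin=3, burn_in=20, seed=9,
        update_allele_freqs=True,
    )
    d1 = run_chains(two_pop_one_locus_baseline, mix, PriorSpec(), config)
    d2 = run_chains(two_pop_one_locus_baseline, mix, PriorSpec(), config)
    assert np.array_equal(d1.theta_draws, d2.theta_draws)
    assert np.array_equal(d1.z_counts, d2.z_counts)


def test_single_admissible_origin_takes_all_draws():
    """A fish with -inf likelihood in all populations but one is assigned
    there every time."""
    rng = np.random.default_rng(0)
    logw = np.array([[-np.inf, -2.0, -np.inf]] * 500)
    z = _sample_categorical_rows(logw, np.log([1 / 3, 1 / 3, 1 / 3]), rng)
    assert (z == 1).all()


def test_impossible_everywhere_falls_back_to_prior():
    rng = np.random.default_rng(0)
    theta = np.array([0.9, 0.1])
    logw = np.full((2000, 2), -np.inf)
    z = _sample_categorical_rows(logw, np.log(theta), rng)
    assert np.mean(z == 0) == pytest.approx(0.9, abs=0.03)


def test_prior_dominance_with_all_missing_genotypes(two_pop_one_locus_baseline):
    """Zero-information genotypes leave the Dirichlet prior untouched:
    sum over origins of prod theta_{z_i} is 1, so theta's marginal posterior
    is its prior.  Checked against closed-form Dirichlet moments."""
    mix = [make_record(f"f{i}", {"L1": MISSING}) for i in range(4)]
    config = ChainConfig(
        n_chains=1, iterations=60_000, thin=2, burn_in=1000, seed=21,
        update_allele_freqs=False,
    )
    with pytest.warns(UserWarning, match="prior alone"):
        draws = run_chains(two_pop_one_locus_baseline, mix, PriorSpec(), config)
    pooled = draws.pooled_theta[:, 0]
    # theta_1 ~ Beta(1/2, 1/2): mean 1/2, var = (1/4)/(2) = 1/8
    assert pooled.mean() == pytest.approx(0.5, abs=0.02)
    assert pooled.var() == pytest.approx(1 / 8, abs=0.02)


def test_gibbs_matches_exhaustive_enumeration(two_pop_one_locus_baseline):
    """Small-instance oracle equivalence at modest draw count (the strict
    200k-draw version runs with the acceptance checks)."""
    mix = [
        make_record("f1", {"L1": ("A", "A")}),
        make_record("f2", {"L1": ("C", "C")}),
        make_record("f3", {"L1": ("A", "C")}),
    ]
    freqs = {"p1": [0.7, 0.3], "p2": [0.3, 0.7]}
    L = [
        [freqs[p][0] ** 2 for p in ("p1", "p2")],
        [freqs[p][1] ** 2 for p in ("p1", "p2")],
        [2 * freqs[p][0] * freqs[p][1] for p in ("p1", "p2")],
    ]
    theta_exact, z_exact = exact_mixture_posterior(L, [0.5, 0.5])
    config = ChainConfig(
        n_chains=1, iterations=80_000, thin=1, burn_in=5_000, seed=13,
        update_allele_freqs=False, start_scheme="uniform",
    )
    draws = run_chains(two_pop_one_locus_baseline, mix, PriorSpec(), config)
    np.testing.assert_allclose(
        draws.pooled_theta.mean(axis=0), theta_exact, atol=0.02
    )
    np.testing.assert_allclose(draws.z_probs, z_exact, atol=0.02)


# ------------------------------------------------------------------ summaries


def test_group_draws_sum_to_one_for_5_7_1_structure():
    rng = np.random.default_rng(3)
    pops = [f"p{i}" for i in range(13)]
    groups = ("Black Lake", "Chignik Lake", "Chignik River")
    gmap = {p: groups[0] if i < 5 else groups[1] if i < 12 else groups[2]
            for i, p in enumerate(pops)}
    loci = [LocusDefinition("L1", DIPLOID, ("A", "C"))]
    base = make_baseline(
        {p: {"L1": rng.integers(1, 20, size=2).tolist()} for p in pops},
        loci, gmap, groups,
    )
    mix = [make_record("f1", {"L1": ("A", "C")})]
    config = ChainConfig(
        n_chains=2, iterations=200, thin=2, burn_in=10, seed=4,
        update_allele_freqs=False,
    )
    draws = run_chains(base, mix, PriorSpec(), config)
    assert draws.group_draws.shape[-1] == 3
    np.testing.assert_allclose(draws.group_draws.sum(axis=2), 1.0, atol=1e-9)


def test_degenerate_summary_and_quantile_oracle():
    rng = np.random.default_rng(8)

    # all draws identical -> mean = median, zero-width interval
    from gsikit.mcmc import PosteriorDraws

    const = np.tile(np.array([0.2, 0.8]), (2, 50, 1))
    draws = PosteriorDraws(
        theta_draws=const, burn_in=10, z_counts=np.ones((1, 2)),
        populations=["a", "b"], groups=("Ga", "Gb"),
        group_indicator=np.eye(2), individual_ids=["f1"],
    )
    s = summarize_groups(draws)
    np.testing.assert_allclose(s.mean, s.median)
    np.testing.assert_allclose(s.q975 - s.q025, 0.0)
    assert s.gelman_rubin[0] == 1.0  # duplicated chains

    # empirical quantiles against an independent sort-and-interpolate oracle
    x = rng.random(1000)
    theta = np.stack([x, 1 - x], axis=1)[None, :, :]
    draws2 = PosteriorDraws(
        theta_draws=theta, burn_in=0, z_counts=np.ones((1, 2)),
        populations=["a", "b"], groups=("Ga", "Gb"),
        group_indicator=np.eye(2), individual_ids=["f1"],
    )
    s2 = summarize_groups(draws2)
    assert s2.q025[0] == pytest.approx(quantile_linear(x, 0.025), rel=1e-12)
    assert s2.q975[0] == pytest.approx(quantile_linear(x, 0.975), rel=1e-12)
    assert s2.median[0] == pytest.approx(quantile_linear(x, 0.5), rel=1e-12)


# ------------------------------------------------------------------ diagnostics


def test_gelman_rubin_identical_chains_is_one():
    chain = np.sin(np.arange(100.0))
    assert gelman_rubin(np.stack([chain, chain])) == pytest.approx(1.0)


def test_gelman_rubin_same_distribution_near_one():
    rng = np.random.default_rng(17)
    chains = rng.normal(size=(3, 10_000))
    assert gelman_rubin(chains) < 1.05


def test_gelman_rubin_separated_chains_blows_up():
    rng = np.random.default_rng(18)
    c1 = 0.2 + 1e-4 * rng.normal(size=5000)
    c2 = 0.8 + 1e-4 * rng.normal(size=5000)
    assert gelman_rubin(np.stack([c1, c2])) > 100


def test_gelman_rubin_constant_chains_defined_as_one():
    assert gelman_rubin(np.zeros((2, 10))) == 1.0


def test_gelman_rubin_rejects_single_chain():
    with pytest.raises(ValueError):
        gelman_rubin(np.zeros((1, 10)))
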