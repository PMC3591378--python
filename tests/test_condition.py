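"""Length–mass condition models, AICc ranking, and length comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsikit.condition import (
    MODEL_IDS,
    ConditionDataset,
    aicc,
    akaike_weights,
    compare_condition,
    compare_lengths,
    fit_condition_model,
    round_half_up,
)
from gsikit.synthetic import ConditionDesign, GroupConditionParams, simulate_condition

from oracles import aicc_formula, normal_equations_fit


def _two_group_data(b1, b2, s1, s2, noise=0.0, n=40, seed=0):
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(50, 90, size=2 * n)
    groups = np.array(["g1"] * n + ["g2"] * n)
    logm = np.where(
        groups == "g1",
        b1 + s1 * np.log10(lengths),
        b2 + s2 * np.log10(lengths),
    )
    logm = logm + noise * rng.normal(size=2 * n)
    return ConditionDataset(groups, lengths, 10.0 ** logm)


def test_shared_model_recovers_single_line_exactly():
    data = _two_group_data(-5.0, -5.0, 3.0, 3.0)
    fit = fit_condition_model(data, "M_shared")
    assert fit.coefficients["B0"] == pytest.approx(-5.0, abs=1e-8)
    assert fit.coefficients["B1"] == pytest.approx(3.0, abs=1e-8)
    assert fit.rss == pytest.approx(0.0, abs=1e-12)
    assert (fit.n, fit.k) == (80, 3)


def test_intercepts_model_recovers_parallel_lines():
    data = _two_group_data(-5.2, -4.9, 3.0, 3.0)
    fit = fit_condition_model(data, "M_intercepts")
    assert fit.coefficients["B01"] == pytest.approx(-5.2, abs=1e-8)
    assert fit.coefficients["B02"] == pytest.approx(-4.9, abs=1e-8)
    assert fit.coefficients["B1"] == pytest.approx(3.0, abs=1e-8)
    assert fit.k == 4


def test_full_model_recovers_two_lines():
    data = _two_group_data(-5.2, -4.8, 3.1, 2.9)
    fit = fit_condition_model(data, "M_full")
    assert fit.coefficients["B01"] == pytest.approx(-5.2, abs=1e-8)
    assert fit.coefficients["B12"] == pytest.approx(2.9, abs=1e-8)
    assert fit.k == 5


def test_coefficients_match_normal_equations_oracle():
    """12-fish fixture solved independently via (X'X)^-1 X'y."""
    data = _two_group_data(-5.1, -4.95, 3.05, 2.95, noise=0.05, n=6, seed=4)
    x = np.log10(data.length_mm)
    y = np.log10(data.mass_g)
    i1 = (data.group == "g1").astype(float)
    i2 = (data.group == "g2").astype(float)
    designs = {
        "M_shared": np.column_stack([np.ones_like(x), x]),
        "M_intercepts": np.column_stack([i1, i2, x]),
        "M_slopes": np.column_stack([np.ones_like(x), x * i1, x * i2]),
        "M_full": np.column_stack([i1, i2, x * i1, x * i2]),
    }
    for mid, X in designs.items():
        beta, rss = normal_equations_fit(X, y)
        fit = fit_condition_model(data, mid)
        np.testing.assert_allclose(
            list(fit.coefficients.values()), beta, rtol=1e-8
        )
        assert fit.rss == pytest.approx(rss, rel=1e-8)


def test_group_with_too_few_fish_errors():
    data = ConditionDataset(
        np.array(["a", "a", "a", "b", "b"]),
        np.array([60, 61, 62, 63, 64.0]),
        np.array([2, 2.1, 2.2, 2.3, 2.4]),
    )
    with pytest.raises(ValueError, match="fewer than 3"):
        fit_condition_model(data, "M_shared")


def test_zero_length_variance_blocks_slope_models():
    data = ConditionDataset(
        np.array(["a"] * 4 + ["b"] * 4),
        np.array([60.0] * 4 + [60, 62, 64, 66]),
        np.linspace(2, 3, 8),
    )
    with pytest.raises(ValueError, match="zero length variance"):
        fit_condition_model(data, "M_full")


def test_relabelling_to_one_group_collapses_to_shared_fit():
    data = _two_group_data(-5.1, -4.9, 3.0, 3.1, noise=0.03, seed=9)
    shared = fit_condition_model(data, "M_shared")
    merged = ConditionDataset(
        np.full(len(data.group), "all"), data.length_mm, data.mass_g
    )
    for mid in ("M_intercepts", "M_slopes", "M_full"):
        fit = fit_condition_model(merged, mid)
        assert fit.rss == pytest.approx(shared.rss, rel=1e-12)
        assert fit.coefficients["B0"] == pytest.approx(
            shared.coefficients["B0"], rel=1e-10
        )
        assert fit.coefficients["B1"] == pytest.approx(
            shared.coefficients["B1"], rel=1e-10
        )
        assert fit.k == 3  # degenerate grouping leaves two coefficients + sigma


# ------------------------------------------------------------------ AICc


def test_aicc_matches_formula_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = int(rng.integers(8, 500))
        k = int(rng.integers(2, 6))
        rss = float(rng.uniform(0.01, 50))
        assert aicc(rss, n, k) == pytest.approx(aicc_formula(rss, n, k), rel=1e-12)


def test_aicc_correction_vanishes_for_large_n():
    n, k, rss = 10**6, 3, 1.0
    aic = n * np.log(rss / n) + 2 * k
    assert abs(aicc(rss, n, k) - aic) < 1e-4


def test_aicc_undefined_for_tiny_samples():
    with pytest.raises(ValueError, match="n > k"):
        aicc(1.0, 4, 3)


def test_equal_rss_equal_k_equal_aicc():
    assert aicc(2.5, 30, 4) == aicc(2.5, 30, 4)


# ------------------------------------------------------------------ weights


TABLE2 = {
    # comparison/year -> (delta AICc vector, printed weights)
    "natal_2010": ((278.86, 26.49, 30.29, 0.00), (0.00, 0.00, 0.00, 1.00)),
    "natal_2011": ((249.35, 0.00, 0.98, 1.68), (0.00, 0.49, 0.30, 0.21)),
    "emigrant_2010": ((72.30, 3.05, 4.44, 0.00), (0.00, 0.16, 0.08, 0.75)),
    "emigrant_2011": ((85.92, 0.78, 0.00, 0.56), (0.00, 0.28, 0.41, 0.31)),
    "shared_lake_2010": ((7.96, 4.71, 5.15, 0.00), (0.02, 0.08, 0.06, 0.84)),
    "shared_lake_2011": ((0.93, 2.91, 2.95, 0.00), (0.30, 0.11, 0.11, 0.48)),
}


@pytest.mark.parametrize("case", sorted(TABLE2))
def test_published_weight_columns_reproduce_from_delta_aicc(case):
    """Every printed weight column follows from its printed dAICc column
    under w_i = exp(-d_i/2)/sum_j exp(-d_j/2), at 2-dp half-up rounding."""
    deltas, printed = TABLE2[case]
    _, weights = akaike_weights(np.array(deltas))
    assert tuple(round_half_up(w, 2) for w in weights) == printed


def test_single_model_weight_is_one():
    delta, w = akaike_weights([123.4])
    assert delta.tolist() == [0.0] and w.tolist() == [1.0]


@settings(max_examples=50, deadline=None)
@given(
    vals=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
    shift=st.floats(-1000, 1000),
)
def test_weights_sum_to_one_and_shift_invariant(vals, shift):
    _, w = akaike_weights(vals)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    _, w_shift = akaike_weights([v + shift for v in vals])
    np.testing.assert_allclose(w, w_shift, atol=1e-9)


# ------------------------------------------------------------------ comparison


def test_rss_nesting_on_noisy_data():
    data = _two_group_data(-5.1, -4.9, 3.0, 3.2, noise=0.05, seed=5)
    fits = {f.model_id: f for f in compare_condition(data)}
    assert fits["M_full"].rss <= fits["M_intercepts"].rss + 1e-12
    assert fits["M_full"].rss <= fits["M_slopes"].rss + 1e-12
    assert fits["M_intercepts"].rss <= fits["M_shared"].rss + 1e-12
    assert fits["M_slopes"].rss <= fits["M_shared"].rss + 1e-12
    assert sum(f.weight for f in fits.values()) == pytest.approx(1.0, abs=1e-12)
    assert sorted(f.delta_aicc for f in fits.values())[0] == 0.0


def test_generating_model_recovery_full():
    """Strongly separated groups at n=500: the full model dominates."""
    data = _two_group_data(-5.4, -4.7, 3.3, 2.8, noise=0.04, n=250, seed=6)
    ranked = compare_condition(data)
    assert ranked[0].model_id == "M_full"
    assert ranked[0].weight > 0.9


def test_parsimonious_model_wins_under_shared_generation():
    """Data from one line: the shared model is the modal AICc winner over
    seeded replicates (richer models pay their parameter penalty)."""
    wins = 0
    for seed in range(20):
        data = _two_group_data(-5.0, -5.0, 3.0, 3.0, noise=0.05, n=100, seed=seed)
        if compare_condition(data)[0].model_id == "M_shared":
            wins += 1
    assert wins >= 11


# ------------------------------------------------------------------ lengths


def test_homoscedastic_branch_anova_p_uniformity():
    """Same-distribution groups: ANOVA branch, p-values roughly uniform."""
    pvals = []
    for seed in range(50):
        rng = np.random.default_rng(100 + seed)
        data = ConditionDataset(
            np.repeat(["a", "b"], 200),
            np.abs(rng.normal(65, 6, size=400)) + 1,
            np.full(400, 2.5),
        )
        cmp = compare_lengths(data)
        if cmp.chosen_test == "ANOVA":
            pvals.append(cmp.p_value)
    assert len(pvals) >= 45  # Bartlett false-positive rate ~ alpha
    pvals = np.array(pvals)
    # coarse uniformity: quartile occupancy within binomial noise
    for lo, hi in ((0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0)):
        frac = np.mean((pvals >= lo) & (pvals < hi + 1e-12))
        assert 0.05 <= frac <= 0.55


def test_heteroscedastic_branch_detected():
    taken = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        data = ConditionDataset(
            np.repeat(["a", "b"], 200),
            np.concatenate([
                rng.normal(65, 1, 200),
                rng.normal(65, 5, 200),
            ]),
            np.full(400, 2.5),
        )
        if compare_lengths(data).chosen_test == "Kruskal-Wallis":
            taken += 1
    assert taken >= 38  # variance ratio 25: detected in >= 95% of seeds


def test_identical_groups_give_null_result():
    x = np.linspace(60, 70, 50)
    data = ConditionDataset(
        np.repeat(["a", "b"], 50), np.concatenate([x, x]), np.full(100, 2.0)
    )
    cmp = compare_lengths(data)
    assert cmp.statistic == pytest.approx(0.0, abs=1e-9)
    assert cmp.p_value > 0.99


def test_three_group_anova_reports_tukey_and_both_dfs():
    rng = np.random.default_rng(77)
    data = ConditionDataset(
        np.repeat(["a", "b", "c"], 80),
        rng.normal([65, 66, 70], 5, size=(80, 3)).T.ravel(),
        np.full(240, 2.5),
    )
    cmp = compare_lengths(data)
    if cmp.chosen_test == "ANOVA":
        assert cmp.df == (2, 237)
        assert cmp.pairwise is not None and len(cmp.pairwise) == 3
    else:  # unlucky Bartlett false positive: rank test with k-1 df
        assert cmp.df == (2,)


def test_zero_variance_group_falls_through_to_kruskal():
    data = ConditionDataset(
        np.repeat(["a", "b"], 10),
        np.concatenate([np.full(10, 65.0), np.linspace(60, 70, 10)]),
        np.full(20, 2.0),
    )
    cmp = compare_lengths(data)
    assert cmp.chosen_test == "Kruskal-Wallis"
    assert cmp.bartlett_stat is None and cmp.note is not None


# ------------------------------------------------------------------ synthetic link


def test_noiseless_simulated_condition_data_recovers_parameters():
    design = ConditionDesign(
        groups={
            "g1": GroupConditionParams(-5.2, 3.1, 0.0, 65, 5, 50),
            "g2": GroupConditionParams(-4.9, 2.9, 0.0, 70, 6, 50),
        },
        seed=8,
    )
    data = simulate_condition(design)
    fit = fit_condition_model(data, "M_full")
    assert fit.coefficients["B01"] == pytest.approx(-5.2, abs=1e-9)
    assert fit.coefficients["B02"] == pytest.approx(-4.9, abs=1e-9)
    assert fit.coefficients["B11"] == pytest.approx(3.1, abs=1e-9)
    assert fit.coefficients["B12"] == pytest.approx(2.9, abs=1e-9)
    assert fit.rss == pytest.approx(0.0, abs=1e-12)
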