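"""Independent oracles used to check the package's numerics.

These deliberately avoid the library's own code paths: plain-Python
enumeration, naive formulas via ``math``, and explicit linear algebra.
"""

import itertools
import math

import numpy as np


def brute_genotype_loglik(record, loci, freqs):
    """Naive per-locus Hardy–Weinberg product, term by term."""
    total = 0.0
    for loc in loci:
        call = record.calls.get(loc.name)
        if call is None:
            continue
        f = {a: float(p) for a, p in zip(loc.alleles, freqs[loc.name])}
        if loc.mode == "diploid_nuclear":
            a, b = call
            prob = f[a] * f[a] if a == b else 2.0 * f[a] * f[b]
        else:
            prob = f[call]
        total += math.log(prob) if prob > 0 else float("-inf")
    return total


def exact_mixture_posterior(likelihood, alpha):
    """Exact posterior by enumerating every origin configuration.

    ``likelihood[i][k]`` is L(g_i | population k); ``alpha`` the Dirichlet
    prior on mixture proportions.  Integrating theta out of
    p(z, theta) = Dir(theta; alpha) * prod_i theta_{z_i} L_i(z_i) gives
    p(z) proportional to prod_i L_i(z_i) * prod_k Gamma(alpha_k + n_k(z)),
    and E[theta_k | z] = (alpha_k + n_k) / (sum(alpha) + N).

    Returns (posterior mean of theta, per-fish origin marginals).
    """
    L = [[float(v) for v in row] for row in likelihood]
    alpha = [float(a) for a in alpha]
    N, K = len(L), len(alpha)
    a0 = sum(alpha)
    theta_mean = [0.0] * K
    z_marg = [[0.0] * K for _ in range(N)]
    total = 0.0
    for z in itertools.product(range(K), repeat=N):
        counts = [0] * K
        w = 1.0
        for i, k in enumerate(z):
            counts[k] += 1
            w *= L[i][k]
        for k in range(K):
            w *= math.gamma(alpha[k] + counts[k]) / math.gamma(alpha[k])
        total += w
        for k in range(K):
            theta_mean[k] += w * (alpha[k] + counts[k]) / (a0 + N)
        for i, k in enumerate(z):
            z_marg[i][k] += w
    theta_mean = [t / total for t in theta_mean]
    z_marg = [[v / total for v in row] for row in z_marg]
    return np.array(theta_mean), np.array(z_marg)


def normal_equations_fit(X, y):
    """OLS via the normal equations with an explicit inverse."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.inv(X.T @ X) @ (X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def aicc_formula(rss, n, k):
    """Straight evaluation of n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)."""
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def quantile_linear(values, q):
    """Sort-and-index empirical quantile with linear interpolation."""
    s = sorted(float(v) for v in values)
    h = (len(s) - 1) * q
    lo = int(math.floor(h))
    if lo == len(s) - 1:
        return s[lo]
    return s[lo] + (h - lo) * (s[lo + 1] - s[lo])
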