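"""Independent oracles for the test suite.

Everything here is computed straight from definitions (brute-force sums,
recursions, enumerations) and never calls the code paths it is used to
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

LN2 = math.log(2.0)


def division_stats(divisions, n0, mode="tree"):
    """Selection statistics of the division count by direct substitution.

    Returns a dict with tau_lambda, landscape per d, S_KL1/S_KL2/S_JF,
    mean/variance of h under both measures.
    """
    d = np.asarray(divisions, dtype=float)
    if mode == "tree":
        n_tau = d.size
        p_cl = 2.0 ** (-d) / n0
        p_rs = np.full(d.size, 1.0 / n_tau)
    else:
        n_tau = float(np.sum(2.0 ** d))
        p_cl = np.full(d.size, 1.0 / n0)
        p_rs = 2.0 ** d / np.sum(2.0 ** d)
    tau_lambda = math.log(n_tau / n0)
    support = np.unique(d)
    q_cl = np.array([p_cl[d == v].sum() for v in support])
    q_rs = np.array([p_rs[d == v].sum() for v in support])
    h = tau_lambda + np.log(q_rs / q_cl)
    m_cl, m_rs = float(h @ q_cl), float(h @ q_rs)
    return {
        "tau_lambda": tau_lambda,
        "support": support,
        "q_cl": q_cl,
        "q_rs": q_rs,
        "h": h,
        "mean_cl": m_cl,
        "mean_rs": m_rs,
        "var_cl": float((h - m_cl) ** 2 @ q_cl),
        "var_rs": float((h - m_rs) ** 2 @ q_rs),
        "s_kl1": float(q_cl @ np.log(q_cl / q_rs)),
        "s_kl2": float(q_rs @ np.log(q_rs / q_cl)),
    }


def raw_moments(values, weights, n_max):
    return np.array([float(np.sum(weights * values ** n)) for n in range(n_max + 1)])


def moments_to_cumulants(m):
    """κ_n from raw moments by the classic recursion
    κ_n = m_n − Σ_{k=1}^{n−1} C(n−1, k−1) κ_k m_{n−k}."""
    n_max = len(m) - 1
    kappa = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        s = sum(math.comb(n - 1, k - 1) * kappa[k] * m[n - k] for k in range(1, n))
        kappa[n] = m[n] - s
    return kappa[1:]


def central_moment_cumulants(values, weights):
    """κ1..κ4 via central-moment formulas: κ3 = m3c, κ4 = m4c − 3 m2c²."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    mean = float(w @ v)
    c = v - mean
    m2 = float(w @ c ** 2)
    m3 = float(w @ c ** 3)
    m4 = float(w @ c ** 4)
    return np.array([mean, m2, m3, m4 - 3.0 * m2 ** 2])


def euler_lotka_gamma(shape, scale):
    """Growth rate solving 2(1+Λθ)^(−k) = 1 for gamma generation times."""
    return (2.0 ** (1.0 / shape) - 1.0) / scale


def enumerate_colony_bootstrap(divisions, statistic):
    """Exhaustive colony-scheme resample distribution for a tiny tree.

    Every one of n^n equally likely index draws (uniform = retrospective
    weights) is enumerated; returns the sorted array of statistic values.
    """
    d = list(divisions)
    n = len(d)
    values = []
    for idx in itertools.product(range(n), repeat=n):
        sample = [d[i] for i in idx]
        values.append(statistic(sample))
    return np.sort(np.array(values, dtype=float))


def enumerate_chronological_bootstrap(divisions, statistic):
    """Exhaustive chronological-scheme resample distribution (n^n draws)."""
    return enumerate_colony_bootstrap(divisions, statistic)


def tau_lambda_colony(sample):
    """Replicate statistic: ln(Nτ / N̂0) with N̂0 = Σ 2^(−D)."""
    n_tau = len(sample)
    n0_hat = sum(2.0 ** (-di) for di in sample)
    return math.log(n_tau / n0_hat)


def n_tau_chronological(sample):
    """Replicate statistic: N̂τ = Σ 2^D."""
    return float(sum(2.0 ** di for di in sample))
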