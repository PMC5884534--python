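"""Independent oracles for the likelihood tests.

The brute-force dynamic-occupancy likelihood enumerates every latent
configuration z in {0,1}^(sites x seasons) and sums the exact joint
probability — tractable only for toy sizes, and deliberately written
without the forward recursion it checks.
"""

from itertools import product

import numpy as np
from scipy.special import expit


def brute_force_loglik(theta_blocks, x_psi, x_gamma, x_eps, x_p, y):
    """Enumerate all z configurations for a (sites, seasons, surveys) array.

    ``theta_blocks`` is a dict with psi1/gamma/eps/p coefficient vectors;
    design matrices include the intercept column. ``y`` may contain NaN
    (missing surveys). Detection probability is site-level.
    """
    n, n_seasons, _ = y.shape
    psi = expit(x_psi @ theta_blocks["psi1"])
    p = expit(x_p @ theta_blocks["p"])
    if n_seasons > 1:
        gamma = expit(x_gamma @ theta_blocks["gamma"])
        eps = expit(x_eps @ theta_blocks["eps"])
    obs = ~np.isnan(y)
    s1 = np.nansum(y, axis=2)
    s0 = (obs & (np.nan_to_num(y) == 0)).sum(axis=2)
    total = 0.0
    for i in range(n):
        site_sum = 0.0
        for zs in product((0, 1), repeat=n_seasons):
            pr = psi[i] if zs[0] else 1 - psi[i]
            for t in range(1, n_seasons):
                if zs[t - 1]:
                    pr *= (1 - eps[i]) if zs[t] else eps[i]
                else:
                    pr *= gamma[i] if zs[t] else 1 - gamma[i]
            for t in range(n_seasons):
                if zs[t]:
                    pr *= p[i] ** s1[i, t] * (1 - p[i]) ** s0[i, t]
                elif s1[i, t] > 0:
                    pr = 0.0
            site_sum += pr
        total += np.log(site_sum)
    return total


def random_toy(rng, max_sites=4, max_seasons=3, n_surveys=4, missing_rate=0.15):
    """A random toy instance: design matrices, coefficients and history."""
    n = int(rng.integers(1, max_sites + 1))
    n_seasons = int(rng.integers(1, max_seasons + 1))
    x_cov = rng.normal(0, 1, (n, 1))
    ones = np.ones((n, 1))
    x_psi = np.hstack([ones, x_cov])
    x_gamma = ones
    x_eps = ones
    x_p = np.hstack([ones, x_cov])
    theta = {
        "psi1": rng.normal(0, 1.2, 2),
        "gamma": rng.normal(0, 1.2, 1),
        "eps": rng.normal(0, 1.2, 1),
        "p": rng.normal(0, 1.2, 2),
    }
    y = rng.integers(0, 2, (n, n_seasons, n_surveys)).astype(float)
    y[rng.random(y.shape) < missing_rate] = np.nan
    return n, n_seasons, x_cov, theta, y, (x_psi, x_gamma, x_eps, x_p)
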