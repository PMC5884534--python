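"""Adaptive random-walk Metropolis machinery shared by the model fitters.

Three independent chains with Haario-style adaptation during burn-in: the
proposal scale tracks a target acceptance rate and the proposal covariance
is re-estimated from the chain history halfway through and at the end of
burn-in. Adaptation stops when sampling starts, so the kept draws come from
a fixed-kernel Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults are test-scale (3 chains, 2,000 kept draws each after 500
    burn-in); ``paper_scale()`` returns the field study's settings of
    100,000 kept after 20,000 burn-in.
    """

    n_chains: int = 3
    n_burn: int = 500
    n_keep: int = 2000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.35
    n_z_draws: int = 900
    rhat_threshold: float = 1.1
    prior_sd: float = 31.6

    @classmethod
    def paper_scale(cls, **kwargs) -> "MCMCConfig":
        kwargs.setdefault("n_burn", 20_000)
        kwargs.setdefault("n_keep", 100_000)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=seed)


def run_chain(
    logpost,
    x0: np.ndarray,
    n_burn: int,
    n_keep: int,
    thin: int,
    rng: np.random.Generator,
    target_accept: float = 0.35,
    sweep=None,
):
    """One adaptive RW-Metropolis chain.

    ``sweep(x, kept_index)`` runs after every Metropolis step (kept_index is
    None during burn-in/thinned steps) and returns the new log-posterior; the
    latent-state sampler uses it to interleave Gibbs updates of z. Returns
    draws ``(n_keep, dim)`` and log-posterior values ``(n_keep,)``.
    """
    x = np.asarray(x0, float).copy()
    d = x.size
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-posterior")
    scale = 2.38 / np.sqrt(d)
    chol = np.eye(d) * 0.3
    draws = np.empty((n_keep, d))
    lps = np.empty(n_keep)
    history = []
    window_acc = 0
    total = n_burn + n_keep * thin
    recompute_at = {n_burn // 2, n_burn} if n_burn >= 100 else set()
    for it in range(total):
        prop = x + scale * (chol @ rng.standard_normal(d))
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            window_acc += 1
        in_burn = it < n_burn
        j = it - n_burn
        kept_index = None if in_burn or j % thin else j // thin
        if sweep is not None:
            lp = sweep(x, kept_index)
        if in_burn:
            history.append(x.copy())
            if (it + 1) % 25 == 0:
                rate = window_acc / 25.0
                window_acc = 0
                scale *= np.exp((rate - target_accept) * 0.6)
            if (it + 1) in recompute_at:
                h = np.asarray(history[len(history) // 2 :])
                cov = np.atleast_2d(np.cov(h.T)) + 1e-8 * np.eye(d)
                chol = np.linalg.cholesky(cov)
                scale = 2.38 / np.sqrt(d)
        elif kept_index is not None:
            draws[kept_index] = x
            lps[kept_index] = lp
    return draws, lps


def find_mode(logpost, dim: int, x0: np.ndarray | None = None) -> np.ndarray:
    """Posterior mode via derivative-free optimization, for chain starts."""
    from scipy import optimize

    x0 = np.zeros(dim) if x0 is None else np.asarray(x0, float)
    res = optimize.minimize(lambda v: -logpost(v), x0, method="Nelder-Mead",
                            options={"maxiter": 400 * dim, "xatol": 1e-4, "fatol": 1e-4})
    res2 = optimize.minimize(lambda v: -logpost(v), res.x, method="BFGS",
                             options={"maxiter": 200})
    return res2.x if res2.fun <= res.fun else res.x


def split_rhat(chains: np.ndarray) -> float:
    """Classic split Gelman-Rubin potential-scale-reduction factor.

    ``chains`` has shape (n_chains, n_draws). Each chain is split in half,
    and R-hat is sqrt(((n-1)/n W + B/n) / W) over the resulting half-chains.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains for the Gelman-Rubin diagnostic")
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    n = half
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))
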