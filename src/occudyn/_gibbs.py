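"""Compiled single-site Gibbs sweep for the explicit latent-state sampler.

The full conditional of z(i, t) combines the site's own emission, its
transition from t-1 and into t+1, and — when the auto-covariate is active —
the t -> t+1 transitions of every neighbor j (whose D depends on z(i, t)).
The sweep is written as a numba kernel over a CSR adjacency; a pure-Python
fallback keeps the package importable without numba.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _log(x):
    return np.log(max(x, 1e-300))


@njit(cache=True)
def _neighbor_mean(z, t, i, indptr, indices):
    lo, hi = indptr[i], indptr[i + 1]
    if hi == lo:
        return 0.0
    s = 0.0
    for k in range(lo, hi):
        s += z[indices[k], t]
    return s / (hi - lo)


@njit(cache=True)
def _log_trans(z_from, z_to, eta_g, c_g, eta_e, c_e, d):
    if z_from == 1:
        e = _logistic(eta_e + c_e * d)
        return _log(1.0 - e) if z_to == 1 else _log(e)
    g = _logistic(eta_g + c_g * d)
    return _log(g) if z_to == 1 else _log(1.0 - g)


@njit(cache=True)
def gibbs_sweep(
    z, forced, s0, log1mp, logpsi, log1mpsi,
    eta_g, c_g, eta_e, c_e, indptr, indices, u,
):
    n, n_seasons = z.shape
    has_auto = (c_g != 0.0) or (c_e != 0.0)
    for t in range(n_seasons):
        for i in range(n):
            if forced[i, t]:
                continue
            logit1 = s0[i, t] * log1mp[i]
            logit0 = 0.0
            if t == 0:
                logit1 += logpsi[i]
                logit0 += log1mpsi[i]
            else:
                d = _neighbor_mean(z, t - 1, i, indptr, indices)
                logit1 += _log_trans(z[i, t - 1], 1, eta_g[i], c_g, eta_e[i], c_e, d)
                logit0 += _log_trans(z[i, t - 1], 0, eta_g[i], c_g, eta_e[i], c_e, d)
            if t < n_seasons - 1:
                for a in range(2):
                    z[i, t] = a
                    acc = 0.0
                    d = _neighbor_mean(z, t, i, indptr, indices)
                    acc += _log_trans(a, z[i, t + 1], eta_g[i], c_g, eta_e[i], c_e, d)
                    if has_auto:
                        for k in range(indptr[i], indptr[i + 1]):
                            j = indices[k]
                            dj = _neighbor_mean(z, t, j, indptr, indices)
                            acc += _log_trans(
                                z[j, t], z[j, t + 1], eta_g[j], c_g, eta_e[j], c_e, dj
                            )
                    if a == 1:
                        logit1 += acc
                    else:
                        logit0 += acc
            pr1 = _logistic(logit1 - logit0)
            z[i, t] = 1 if u[t, i] < pr1 else 0
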