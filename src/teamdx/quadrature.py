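"""Brute-force Gauss-Hermite marginal likelihood for small crossed designs.

Independent oracle for :mod:`teamdx.glmm`: the marginal likelihood is
integrated exactly (up to quadrature error) over the full product grid of all
rater and lesion random intercepts.  The summation exploits that, with the
lesion intercepts held at a grid point, the rater intercepts are
conditionally independent -- the result is identical to the dense
(n_raters + n_lesions)-dimensional product-grid sum, evaluated without
materializing it.

Only feasible for a handful of lesions (grid is n_nodes ** n_lesions).
"""

from __future__ import annotations

import itertools
import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .glmm import _prepare

__all__ = ["gh_loglik", "gh_fit"]

_MAX_GRID = 2_000_000


def gh_loglik(
    rows,
    beta: np.ndarray,
    sigma_rater: float,
    sigma_lesion: float,
    n_nodes: int = 9,
) -> float:
    """Gauss-Hermite product-grid marginal log-likelihood.

    ``rows`` as in :func:`teamdx.glmm.fit_crossed_logistic`.  Uses
    ``n_nodes`` Hermite nodes per latent dimension.
    """
    y, s, r, l, r_levels, l_levels = _prepare(rows)
    qr, ql = len(r_levels), len(l_levels)
    if n_nodes**ql > _MAX_GRID:
        raise ValueError(
            f"{n_nodes} nodes over {ql} lesions exceeds the grid budget"
        )
    x, wts = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(wts) - 0.5 * math.log(math.pi)
    u_nodes = math.sqrt(2.0) * sigma_rater * x      # (K,)
    v_nodes = math.sqrt(2.0) * sigma_lesion * x     # (K,)

    combos = np.array(list(itertools.product(range(n_nodes), repeat=ql)), dtype=np.intp)
    vgrid = v_nodes[combos]          # (G, ql)
    logw_v = logw[combos].sum(axis=1)  # (G,)

    b0, b1 = float(beta[0]), float(beta[1])
    total = logw_v.copy()
    for i in range(qr):
        m = r == i
        yi, si, li = y[m], s[m], l[m]
        off = b0 + b1 * si                                  # (ni,)
        eta = off[None, None, :] + u_nodes[None, :, None] + vgrid[:, li][:, None, :]
        ll = (yi[None, None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=2)  # (G, K)
        total += logsumexp(ll + logw[None, :], axis=1)
    return float(logsumexp(total))


def gh_fit(
    rows,
    n_nodes: int = 9,
    x0: Optional[np.ndarray] = None,
) -> dict:
    """Maximize the Gauss-Hermite marginal likelihood over (beta, sigmas).

    Returns a dict with ``beta``, ``sigma_rater``, ``sigma_lesion`` and
    ``loglik``.  Slow; intended only as a small-instance oracle.
    """
    if x0 is None:
        x0 = np.array([0.0, 0.0, math.log(0.5), math.log(0.5)])

    def nll(par):
        b = par[:2]
        sr = math.exp(np.clip(par[2], -8.0, 2.0))
        sl = math.exp(np.clip(par[3], -8.0, 2.0))
        return -gh_loglik(rows, b, sr, sl, n_nodes=n_nodes)

    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "fatol": 1e-8, "xatol": 1e-5},
    )
    par = res.x
    return {
        "beta": np.array(par[:2]),
        "sigma_rater": math.exp(np.clip(par[2], -8.0, 2.0)),
        "sigma_lesion": math.exp(np.clip(par[3], -8.0, 2.0)),
        "loglik": -float(res.fun),
        "converged": bool(res.success),
    }
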