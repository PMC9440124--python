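"""Logistic regression with crossed rater- and lesion-level random intercepts.

Marginal maximum likelihood via the Laplace approximation: an inner penalized
iteratively-reweighted least-squares (PIRLS) solve finds the joint mode of the
fixed effects and both random-intercept vectors for given variance
components; the marginal log-likelihood adds the log-determinant correction
of the random-effects Hessian; an outer bounded Nelder-Mead search maximizes
it over (log sd_rater, log sd_lesion).

The model is

    logit P(y_ij = 1) = b0 + b1 * session + u_rater(i) + v_lesion(j)

with u ~ N(0, sigma_rater^2), v ~ N(0, sigma_lesion^2), crossed (every
observation carries one u and one v).  Crossed factors do not factorize, so
adaptive quadrature is unavailable; a brute-force Gauss-Hermite oracle for
small instances lives in :mod:`teamdx.quadrature`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy.special import expit, ndtr

__all__ = [
    "GlmmSettings",
    "GlmmFit",
    "SeparationError",
    "NotConvergedError",
    "fit_crossed_logistic",
    "wald_interval",
    "test_one_sided",
]

_LOG_SD_FLOOR = -12.0


class SeparationError(ValueError):
    """Complete (or quasi-complete) separation: the ML estimate is infinite."""


class NotConvergedError(RuntimeError):
    """An inferential operation was requested on a non-converged fit."""


@dataclass(frozen=True)
class GlmmSettings:
    """Tolerances and iteration limits; all overridable."""

    outer_tol: float = 1e-6       # absolute tolerance on the Laplace loglik
    inner_tol: float = 1e-8       # tolerance on the penalized deviance
    max_outer: int = 200
    max_inner: int = 80
    log_sd_floor: float = _LOG_SD_FLOOR
    log_sd_ceiling: float = 3.0
    log_sd_start: float = math.log(0.5)


@dataclass
class GlmmFit:
    """Fixed effects and variance components of the crossed-intercepts model."""

    beta: np.ndarray                 # (intercept, session) on the log-odds scale
    se_beta: np.ndarray
    sigma_rater: float
    sigma_lesion: float
    loglik: float
    converged: bool
    boundary: bool                   # a variance component hit the floor
    n_obs: int
    n_raters: int
    n_lesions: int
    n_outer_evals: int = 0
    rater_levels: Sequence[str] = field(default_factory=list)
    lesion_levels: Sequence[str] = field(default_factory=list)
    ranef_rater: Optional[np.ndarray] = None
    ranef_lesion: Optional[np.ndarray] = None

    @property
    def log_or(self) -> float:
        return float(self.beta[1])

    @property
    def se_log_or(self) -> float:
        return float(self.se_beta[1])

    def to_dict(self) -> dict:
        return {
            "beta": [float(b) for b in self.beta],
            "se_beta": [float(s) for s in self.se_beta],
            "sigma_rater": float(self.sigma_rater),
            "sigma_lesion": float(self.sigma_lesion),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "n_obs": int(self.n_obs),
            "n_raters": int(self.n_raters),
            "n_lesions": int(self.n_lesions),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _prepare(rows: Union[pd.DataFrame, dict]) -> tuple:
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    for col in ("y", "session", "rater_id", "lesion_id"):
        if col not in rows.columns:
            raise ValueError(f"rows must contain column {col!r}")
    y = np.asarray(rows["y"], dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    s = np.asarray(rows["session"], dtype=float)
    if not np.isin(s, (0.0, 1.0)).all():
        raise ValueError("session must be coded 0/1")
    r_codes, r_levels = pd.factorize(rows["rater_id"], sort=True)
    l_codes, l_levels = pd.factorize(rows["lesion_id"], sort=True)
    return y, s, r_codes.astype(np.intp), l_codes.astype(np.intp), list(r_levels), list(l_levels)


def _check_separation(y: np.ndarray, s: np.ndarray) -> None:
    if y.min() == y.max():
        raise SeparationError(
            f"response is constant (all y = {int(y[0])}); the session effect is not identifiable"
        )
    for level in (0.0, 1.0):
        ys = y[s == level]
        if ys.size and ys.min() == ys.max():
            other = y[s != level]
            if other.size and other.min() == other.max() and other[0] != ys[0]:
                raise SeparationError(
                    "complete separation: y is constant within each session level"
                )


class _LaplaceProblem:
    """Shared state for the inner PIRLS solve and the Laplace objective."""

    def __init__(self, y, s, r, l, qr, ql, settings: GlmmSettings):
        self.y, self.s, self.r, self.l = y, s, r, l
        self.qr, self.ql = qr, ql
        self.n = y.size
        self.settings = settings
        # warm starts carried across outer evaluations
        self.beta = np.zeros(2)
        p = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        self.beta[0] = math.log(p / (1 - p))
        self.u = np.zeros(qr)
        self.v = np.zeros(ql)
        self.n_evals = 0

    # -- linear algebra helpers -------------------------------------------

    def _weighted_blocks(self, w):
        """Cross-product blocks of the penalized Newton system."""
        s, r, l, qr, ql = self.s, self.r, self.l, self.qr, self.ql
        sw = w.sum()
        ws = w * s
        XtWX = np.array([[sw, ws.sum()], [ws.sum(), (ws * s).sum()]])
        wr = np.bincount(r, weights=w, minlength=qr)
        wl = np.bincount(l, weights=w, minlength=ql)
        wrs = np.bincount(r, weights=ws, minlength=qr)
        wls = np.bincount(l, weights=ws, minlength=ql)
        C = sparse.coo_matrix((w, (r, l)), shape=(qr, ql)).toarray()
        return XtWX, wr, wl, wrs, wls, C

    def _assemble(self, XtWX, wr, wl, wrs, wls, C, sig_r, sig_l):
        qr, ql = self.qr, self.ql
        d = 2 + qr + ql
        A = np.zeros((d, d))
        A[:2, :2] = XtWX
        A[0, 2 : 2 + qr] = wr
        A[1, 2 : 2 + qr] = wrs
        A[0, 2 + qr :] = wl
        A[1, 2 + qr :] = wls
        A[2 : 2 + qr, :2] = A[:2, 2 : 2 + qr].T
        A[2 + qr :, :2] = A[:2, 2 + qr :].T
        idx = np.arange(qr)
        A[2 + idx, 2 + idx] = wr + 1.0 / sig_r**2
        jdx = np.arange(ql)
        A[2 + qr + jdx, 2 + qr + jdx] = wl + 1.0 / sig_l**2
        A[2 : 2 + qr, 2 + qr :] = C
        A[2 + qr :, 2 : 2 + qr] = C.T
        return A

    def _penalized_nll(self, beta, u, v, sig_r, sig_l):
        eta = beta[0] + beta[1] * self.s + u[self.r] + v[self.l]
        ll = float(self.y @ eta - np.logaddexp(0.0, eta).sum())
        pen = 0.5 * (u @ u / sig_r**2 + v @ v / sig_l**2)
        return -(ll - pen), eta

    def pirls(self, sig_r, sig_l):
        """Joint mode of (beta, u, v) by damped Newton on the penalized deviance."""
        st = self.settings
        beta, u, v = self.beta.copy(), self.u.copy(), self.v.copy()
        obj, eta = self._penalized_nll(beta, u, v, sig_r, sig_l)
        converged = False
        for _ in range(st.max_inner):
            mu = expit(eta)
            w = np.maximum(mu * (1.0 - mu), 1e-12)
            res = self.y - mu
            g = np.concatenate(
                [
                    [res.sum(), (res * self.s).sum()],
                    np.bincount(self.r, weights=res, minlength=self.qr) - u / sig_r**2,
                    np.bincount(self.l, weights=res, minlength=self.ql) - v / sig_l**2,
                ]
            )
            blocks = self._weighted_blocks(w)
            A = self._assemble(*blocks, sig_r, sig_l)
            try:
                cf = linalg.cho_factor(A, lower=True, check_finite=False)
                step = linalg.cho_solve(cf, g, check_finite=False)
            except linalg.LinAlgError:
                step = np.linalg.lstsq(A, g, rcond=None)[0]
            # step halving
            t = 1.0
            for _ in range(30):
                nb = beta + t * step[:2]
                nu = u + t * step[2 : 2 + self.qr]
                nv = v + t * step[2 + self.qr :]
                nobj, neta = self._penalized_nll(nb, nu, nv, sig_r, sig_l)
                if nobj <= obj + 1e-14:
                    break
                t *= 0.5
            delta = obj - nobj
            beta, u, v, eta = nb, nu, nv, neta
            obj = nobj
            if abs(delta) < st.inner_tol * (1.0 + abs(obj)):
                converged = True
                break
        self.beta, self.u, self.v = beta, u, v
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        return beta, u, v, eta, w, obj, converged

    def laplace_loglik(self, sig_r, sig_l):
        """Laplace-approximate marginal loglik profiled over (beta, u, v)."""
        self.n_evals += 1
        beta, u, v, eta, w, obj, _ = self.pirls(sig_r, sig_l)
        # logdet(I + S Z'WZ S) with S = diag(sigma); stable as sigma -> 0
        wr = np.bincount(self.r, weights=w, minlength=self.qr)
        wl = np.bincount(self.l, weights=w, minlength=self.ql)
        C = sparse.coo_matrix((w, (self.r, self.l)), shape=(self.qr, self.ql)).toarray()
        q = self.qr + self.ql
        M = np.empty((q, q))
        M[: self.qr, : self.qr] = np.diag(sig_r**2 * wr)
        M[self.qr :, self.qr :] = np.diag(sig_l**2 * wl)
        M[: self.qr, self.qr :] = sig_r * sig_l * C
        M[self.qr :, : self.qr] = sig_r * sig_l * C.T
        M[np.arange(q), np.arange(q)] += 1.0
        try:
            L = linalg.cholesky(M, lower=True, check_finite=False)
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
        except linalg.LinAlgError:
            sign, logdet = np.linalg.slogdet(M)
            if sign <= 0:
                return -np.inf
        return -obj - 0.5 * logdet


def fit_crossed_logistic(
    rows: Union[pd.DataFrame, dict],
    settings: Optional[GlmmSettings] = None,
    fix_sigma_rater: Optional[float] = None,
    fix_sigma_lesion: Optional[float] = None,
) -> GlmmFit:
    """Fit the crossed random-intercepts logistic model by Laplace ML.

    ``rows`` must provide columns ``y`` (0/1), ``session`` (0/1), ``rater_id``
    and ``lesion_id``.  Variance components may be fixed (e.g. at 0 to reduce
    to ordinary logistic regression).  Deterministic given data and settings.

    Raises :class:`SeparationError` on a constant response or a response fully
    determined by session; boundary variance estimates are returned as 0 with
    ``boundary=True``.
    """
    st = settings or GlmmSettings()
    y, s, r, l, r_levels, l_levels = _prepare(rows)
    qr, ql = len(r_levels), len(l_levels)
    if qr < 2 or ql < 2:
        raise ValueError(f"need >=2 raters and >=2 lesions (got {qr}, {ql})")
    if len(np.unique(s)) < 2:
        raise ValueError("both session levels must be present")
    _check_separation(y, s)

    prob = _LaplaceProblem(y, s, r, l, qr, ql, st)

    def theta_to_sigma(th, fixed, i):
        if fixed is not None:
            return max(float(fixed), 0.0) or math.exp(st.log_sd_floor)
        return math.exp(th[i])

    free = [fix_sigma_rater is None, fix_sigma_lesion is None]

    def negloglik(theta_free):
        th = iter(theta_free)
        tr = next(th) if free[0] else None
        tl = next(th) if free[1] else None
        sig_r = math.exp(np.clip(tr, st.log_sd_floor, st.log_sd_ceiling)) if free[0] \
            else theta_to_sigma(None, fix_sigma_rater, 0)
        sig_l = math.exp(np.clip(tl, st.log_sd_floor, st.log_sd_ceiling)) if free[1] \
            else theta_to_sigma(None, fix_sigma_lesion, 1)
        return -prob.laplace_loglik(sig_r, sig_l)

    n_free = sum(free)
    converged = True
    if n_free == 0:
        theta_opt = np.array([])
        nll = negloglik(theta_opt)
    else:
        x0 = np.full(n_free, st.log_sd_start)
        res = optimize.minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": st.max_outer * (n_free + 1),
                "fatol": st.outer_tol,
                "xatol": 1e-4,
            },
        )
        theta_opt = np.clip(res.x, st.log_sd_floor, st.log_sd_ceiling)
        nll = negloglik(theta_opt)
        converged = bool(res.success) or abs(res.fun - nll) < 10 * st.outer_tol

    it = iter(theta_opt)
    sig_r = math.exp(next(it)) if free[0] else max(float(fix_sigma_rater), 0.0) or math.exp(st.log_sd_floor)
    sig_l = math.exp(next(it)) if free[1] else max(float(fix_sigma_lesion), 0.0) or math.exp(st.log_sd_floor)

    beta, u, v, eta, w, _, inner_ok = prob.pirls(sig_r, sig_l)
    converged = converged and inner_ok

    # Wald SEs from the beta block of the inverse penalized information
    blocks = prob._weighted_blocks(w)
    A = prob._assemble(*blocks, sig_r, sig_l)
    try:
        cf = linalg.cho_factor(A, lower=True, check_finite=False)
        e = np.zeros((A.shape[0], 2))
        e[0, 0] = 1.0
        e[1, 1] = 1.0
        cov = linalg.cho_solve(cf, e, check_finite=False)[:2, :2]
    except linalg.LinAlgError:
        cov = np.linalg.pinv(A)[:2, :2]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    if np.abs(beta).max() > 15.0 or (se > 50).any():
        raise SeparationError(
            f"fitted effects are unbounded (beta={beta}); data are separated"
        )

    floor_sd = math.exp(st.log_sd_floor + 0.5)
    boundary = (free[0] and sig_r <= floor_sd) or (free[1] and sig_l <= floor_sd)
    return GlmmFit(
        beta=beta.copy(),
        se_beta=se,
        sigma_rater=0.0 if sig_r <= floor_sd else float(sig_r),
        sigma_lesion=0.0 if sig_l <= floor_sd else float(sig_l),
        loglik=float(-nll),
        converged=converged,
        boundary=boundary,
        n_obs=int(y.size),
        n_raters=qr,
        n_lesions=ql,
        n_outer_evals=prob.n_evals,
        rater_levels=r_levels,
        lesion_levels=l_levels,
        ranef_rater=u.copy(),
        ranef_lesion=v.copy(),
    )


def wald_interval(fit: GlmmFit, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for the session odds ratio.

    Computed on the log scale and exponentiated; monotone (nested) in
    ``level``.  Refuses non-converged fits.
    """
    if not fit.converged:
        raise NotConvergedError("refusing a Wald interval on a non-converged fit")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    lo = math.exp(fit.log_or - z * fit.se_log_or)
    hi = math.exp(fit.log_or + z * fit.se_log_or)
    return lo, hi


def test_one_sided(
    fit: GlmmFit, bound: float = 1.0, direction: str = "greater"
) -> tuple[float, float]:
    """One-sided Wald test of the session odds ratio against ``bound``.

    Returns ``(z, p)`` where ``z = (log_or - log(bound)) / se`` and ``p`` is
    the one-sided tail probability in the stated direction.
    """
    if not fit.converged:
        raise NotConvergedError("refusing a Wald test on a non-converged fit")
    if bound <= 0:
        raise ValueError(f"bound must be positive, got {bound}")
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    if fit.se_log_or == 0:
        z = math.inf * np.sign(fit.log_or - math.log(bound)) if fit.log_or != math.log(bound) else 0.0
    else:
        z = (fit.log_or - math.log(bound)) / fit.se_log_or
    p = float(1.0 - ndtr(z)) if direction == "greater" else float(ndtr(z))
    return float(z), p
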