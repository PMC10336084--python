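"""Penalized-spline Gaussian mixed models fit by exact marginal ML.

The trajectory models are additive mixed models: fixed covariates, one or two
penalized cubic-spline smooths of age (basis dimension k = 4), and a subject
random intercept for the repeated scans. Each smooth is reparametrized into
an unpenalized null-space part (absorbed into the fixed effects) and an
isotropic penalized part treated as a Gaussian random effect; the smoothing
parameter is then a variance ratio. All variance parameters are estimated by
maximizing the exact marginal Gaussian log-likelihood (beta and the residual
variance profiled out; bounded quasi-Newton over log variance ratios from
five deterministic starts), so the reported log-likelihood can be reproduced
by direct evaluation of the marginal density.

Likelihood-ratio degrees of freedom count every identifiable basis column of
a smooth (k - 1 after the sum-to-zero constraint), a conservative upper bound
for penalized terms. AIC = -2 loglik + 2 (n_fixed + n_varpar) with the same
column counting plus one per free variance parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.stats import chi2

__all__ = [
    "SmoothSpec",
    "SplineBasis",
    "SmoothTerm",
    "ModelFit",
    "spline_basis",
    "fit_gamm",
    "lrt",
    "select_model",
    "bh_fdr",
]

log = logging.getLogger(__name__)

#: deterministic multi-start grid for log10 variance ratios
_STARTS = (-4.0, -2.0, -1.0, 0.0, 1.0)
_LOG10_BOUNDS = (-8.0, 6.0)


@dataclass(frozen=True)
class SmoothSpec:
    """Penalized-spline smooth: cubic B-splines, difference penalty.

    k is the basis dimension (>= 3); penalty_order the difference order (2 =
    second differences, null space {constant, linear}); knots are placed at
    quantiles of the observed ages; a sum-to-zero constraint over the observed
    data removes the constant, leaving k - 1 identifiable columns.
    """

    k: int = 4
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")
        if not 1 <= self.penalty_order < self.k:
            raise ValueError("penalty order must be in [1, k)")


@dataclass
class SplineBasis:
    """Constructed smooth basis: raw design, penalty, and the constraint /
    reparametrization transforms needed to evaluate the smooth anywhere."""

    spec: SmoothSpec
    knots: np.ndarray  # full knot vector (degree-3, clamped)
    penalty: np.ndarray  # (k, k) = D'D, second-order difference penalty
    constraint: np.ndarray  # (k, k-1) null-space basis of the centering constraint
    null_transform: np.ndarray  # (k-1, n_null): constrained coefs -> null cols
    pen_transform: np.ndarray  # (k-1, n_pen): constrained coefs -> penalized cols

    @property
    def n_null(self) -> int:
        return self.null_transform.shape[1]

    @property
    def n_pen(self) -> int:
        return self.pen_transform.shape[1]

    def raw(self, x: np.ndarray) -> np.ndarray:
        """Raw k-column B-spline design at points x (clamped to the knot range)."""
        x = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[-1])
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    def terms(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(X_null, Z_pen) evaluated at x: the unpenalized columns and the
        isotropic penalized columns of the constrained, reparametrized smooth."""
        bt = self.raw(x) @ self.constraint
        return bt @ self.null_transform, bt @ self.pen_transform


def spline_basis(ages: np.ndarray, spec: SmoothSpec = SmoothSpec()) -> SplineBasis:
    """Build the constrained penalized cubic-spline basis on observed ages.

    Interior knots (k - 4 of them, none when k = 4) sit at age quantiles;
    boundary knots are clamped at the age range. The sum-to-zero constraint is
    taken over the observed ages; the penalty is eigendecomposed so penalized
    directions become iid random-effect columns.
    """
    ages = np.asarray(ages, dtype=float)
    k = spec.k
    if np.unique(ages).size < k:
        raise ValueError(f"need >= {k} distinct ages, got {np.unique(ages).size}")
    lo, hi = ages.min(), ages.max()
    n_interior = k - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(ages, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    d = np.eye(k)
    for _ in range(spec.penalty_order):
        d = np.diff(d, axis=0)
    penalty = d.T @ d
    b = BSpline.design_matrix(ages, knots, 3).toarray()
    # sum-to-zero constraint over observed data: C beta = 0, C = column means
    c = b.mean(axis=0, keepdims=True)
    constraint = sla.null_space(c)  # (k, k-1)
    s_t = constraint.T @ penalty @ constraint
    evals, evecs = np.linalg.eigh(s_t)
    tol = max(evals.max(), 1.0) * 1e-10
    pos = evals > tol
    null_transform = evecs[:, ~pos]
    pen_transform = evecs[:, pos] / np.sqrt(evals[pos])
    return SplineBasis(spec=spec, knots=knots, penalty=penalty,
                       constraint=constraint, null_transform=null_transform,
                       pen_transform=pen_transform)


@dataclass
class SmoothTerm:
    """One smooth's contribution to a model: unpenalized null-space columns
    (joined to the fixed effects) and penalized columns with an iid Gaussian
    prior whose variance ratio is estimated (or fixed via ``fixed_ratio``)."""

    name: str
    x_null: np.ndarray
    z_pen: np.ndarray
    fixed_ratio: float | None = None  # variance ratio = 1/lambda, if frozen


@dataclass
class ModelFit:
    """One fitted model: coefficients, variance parameters, ML log-likelihood
    and the df bookkeeping used by LRT/AIC."""

    model_id: str
    beta: np.ndarray
    coef_names: list[str]
    sigma2: float
    sigma_b2: float
    lambdas: dict[str, float]
    loglik: float
    n_fixed: int  # fixed columns + penalized smooth columns (LRT/AIC df count)
    n_varpar: int  # free variance parameters incl. sigma^2
    aic: float
    edf: float
    fitted: np.ndarray
    n_obs: int
    converged: bool
    b: np.ndarray = field(default_factory=lambda: np.zeros(0))  # random coefs
    block_slices: dict[str, slice] = field(default_factory=dict)

    def smooth_coefs(self, name: str) -> np.ndarray:
        return self.b[self.block_slices[name]]


def _check_design(x: np.ndarray, names: list[str]) -> None:
    if x.size == 0:
        raise ValueError("empty fixed design")
    _, r, piv = sla.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diagonal(r))
    bad = diag < max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if bad.any():
        cols = [names[piv[i]] for i in np.flatnonzero(bad)]
        raise ValueError(f"singular fixed design; collinear column(s): {', '.join(cols)}")


def fit_gamm(
    y: np.ndarray,
    fixed: np.ndarray,
    smooths: list[SmoothTerm] | None = None,
    subject_ids: np.ndarray | None = None,
    method: str = "ML",
    model_id: str = "",
    coef_names: list[str] | None = None,
    subject_ratio: float | None = None,
) -> ModelFit:
    """Fit a Gaussian additive mixed model by exact marginal ML.

    Parameters
    ----------
    y : (m,) response (rows with missing response must be dropped beforehand).
    fixed : (m, p) fixed-effect design (include the intercept column).
    smooths : penalized smooth terms; their null-space columns are appended to
        the fixed design internally.
    subject_ids : per-row subject labels for the random intercept, or None.
    subject_ratio : freeze the subject variance ratio (testing hook).
    """
    if method != "ML":
        raise ValueError("only ML fitting is supported")
    y = np.asarray(y, dtype=float)
    x = np.asarray(fixed, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("rows of y and fixed design must align")
    m = y.size
    smooths = smooths or []
    names = list(coef_names) if coef_names else [f"x{j}" for j in range(x.shape[1])]
    n_pen_cols = 0
    for sm in smooths:
        x = np.hstack([x, sm.x_null])
        names += [f"{sm.name}_null{j}" for j in range(sm.x_null.shape[1])]
        n_pen_cols += sm.z_pen.shape[1]
    _check_design(x, names)
    p = x.shape[1]

    # rows are sorted by subject so the subject random-intercept part of the
    # covariance is block diagonal and invertible in closed form; the few
    # penalized smooth columns are handled by a small Woodbury correction.
    has_subject = subject_ids is not None
    if has_subject:
        subject_ids = np.asarray(subject_ids)
        if subject_ids.shape[0] != m:
            raise ValueError("subject_ids must align with y")
        order = np.argsort(subject_ids, kind="stable")
    else:
        order = np.arange(m)
    xs = x[order]
    ys = y[order]
    if has_subject:
        _, starts_idx, counts = np.unique(subject_ids[order],
                                          return_index=True, return_counts=True)
        n_subj = counts.size
    else:
        starts_idx = counts = None
        n_subj = 0
    u_blocks = [np.asarray(sm.z_pen, dtype=float)[order] for sm in smooths]
    u = np.hstack(u_blocks) if u_blocks else np.zeros((m, 0))
    r_pen = u.shape[1]
    slices, start = {}, 0
    if has_subject:
        slices["subject"] = slice(0, n_subj)
        start = n_subj
    for sm in smooths:
        slices[sm.name] = slice(start, start + sm.z_pen.shape[1])
        start += sm.z_pen.shape[1]

    blocks: list[tuple[str, float | None]] = []
    if has_subject:
        blocks.append(("subject", subject_ratio))
    for sm in smooths:
        blocks.append((sm.name, sm.fixed_ratio))
    free = [i for i, (_, fr) in enumerate(blocks) if fr is None]
    n_free = len(free)

    big = np.hstack([xs, u, ys[:, None]])  # (m, p + r + 1)
    mtm = big.T @ big
    if has_subject:
        gsum = np.add.reduceat(big, starts_idx, axis=0)  # per-subject sums
    else:
        gsum = None

    def ratios_from(theta: np.ndarray) -> np.ndarray:
        g = np.empty(len(blocks))
        it = iter(theta)
        for i, (_, fr) in enumerate(blocks):
            g[i] = fr if fr is not None else 10.0 ** next(it)
        return g

    def pen_ratios(gam: np.ndarray) -> np.ndarray:
        """Per-column variance ratio for the penalized smooth columns."""
        off = 1 if has_subject else 0
        return np.concatenate([
            np.full(sm.z_pen.shape[1], gam[off + j])
            for j, sm in enumerate(smooths)
        ]) if smooths else np.zeros(0)

    def profile(theta: np.ndarray):
        """Profiled loglik, beta, sigma2 at given log10 variance ratios."""
        gam = ratios_from(theta)
        if has_subject:
            gb = gam[0]
            w = gb / (1.0 + gb * counts)  # A^{-1} = I - Zs diag(w) Zs'
            pmat = mtm - (gsum * w[:, None]).T @ gsum
            logdet_a = float(np.log1p(gb * counts).sum())
        else:
            pmat = mtm
            logdet_a = 0.0
        pxx = pmat[:p, :p]
        pxy = pmat[:p, -1]
        pyy = pmat[-1, -1]
        if r_pen:
            du = pen_ratios(gam)
            pxu = pmat[:p, p:p + r_pen]
            puu = pmat[p:p + r_pen, p:p + r_pen]
            puy = pmat[p:p + r_pen, -1]
            kmat = puu + np.diag(1.0 / du)
            ck = sla.cho_factor(kmat, lower=True)
            logdet_v0 = (logdet_a + 2.0 * np.log(np.diagonal(ck[0])).sum()
                         + np.log(du).sum())
            kin_ux = sla.cho_solve(ck, pxu.T)
            kin_uy = sla.cho_solve(ck, puy)
            a = pxx - pxu @ kin_ux
            bvec = pxy - pxu @ kin_uy
            cquad = pyy - puy @ kin_uy
        else:
            ck = None
            logdet_v0 = logdet_a
            a, bvec, cquad = pxx, pxy, pyy
        beta = sla.solve(a, bvec, assume_a="pos")
        rss = max(cquad - beta @ bvec, 1e-300)
        sigma2 = rss / m
        ll = -0.5 * (m * np.log(2 * np.pi * sigma2) + logdet_v0 + m)
        return ll, beta, sigma2, ck

    def nll(theta: np.ndarray) -> float:
        try:
            return -profile(theta)[0]
        except np.linalg.LinAlgError:
            return 1e10

    converged = True
    if n_free:
        # score the deterministic starts, then bounded quasi-Newton from the
        # two most promising, then a tight simplex polish of the winner
        start_vals = [(nll(np.full(n_free, s)), s) for s in _STARTS]
        start_vals.sort(key=lambda t: t[0])
        best, any_success = None, False
        for _, s in start_vals[:2]:
            res = minimize(nll, np.full(n_free, s), method="L-BFGS-B",
                           bounds=[_LOG10_BOUNDS] * n_free,
                           options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 150})
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        polish = minimize(nll, best.x, method="Nelder-Mead",
                          options={"xatol": 1e-7, "fatol": 1e-13, "maxiter": 300})
        theta_hat = polish.x if polish.fun <= best.fun else best.x
        theta_hat = np.clip(theta_hat, *_LOG10_BOUNDS)
        # a flat plateau (variance ratio at its bound) can exhaust the simplex
        # budget without moving the optimum; that is convergence, not failure
        converged = bool(any_success or polish.success
                         or best.fun - polish.fun < 1e-6)
        if not converged:
            log.warning("model %s: optimizer did not report convergence", model_id)
    else:
        theta_hat = np.zeros(0)

    ll, beta, sigma2, _ = profile(theta_hat)
    gam = ratios_from(theta_hat) if blocks else np.zeros(0)

    # random coefficients b_hat = D Z' V0^{-1} (y - X beta), fitted values, edf
    resid = ys - xs @ beta
    if has_subject:
        gb = gam[0]
        w = gb / (1.0 + gb * counts)
        rsum = np.add.reduceat(resid, starts_idx)
        ainv_r = resid - np.repeat(w * rsum, counts)
        if r_pen:
            gu = np.add.reduceat(u, starts_idx, axis=0)
            ainv_u = u - np.repeat(w[:, None] * gu, counts, axis=0)
    else:
        ainv_r = resid
        ainv_u = u
    edf = float(p)
    if r_pen:
        du = pen_ratios(gam)
        puu_a = u.T @ ainv_u
        kmat = puu_a + np.diag(1.0 / du)
        ck = sla.cho_factor(kmat, lower=True)
        v0inv_r = ainv_r - ainv_u @ sla.cho_solve(ck, ainv_u.T @ resid)
        b_u = du * (u.T @ v0inv_r)
        uvu = puu_a - puu_a @ sla.cho_solve(ck, puu_a)
        edf += float(np.sum(du * np.diagonal(uvu)))
    else:
        v0inv_r = ainv_r
        b_u = np.zeros(0)
    if has_subject:
        b_subj = gam[0] * np.add.reduceat(v0inv_r, starts_idx)
        fitted_sorted = xs @ beta + np.repeat(b_subj, counts)
        diag_zvz = counts / (1.0 + gam[0] * counts)
        if r_pen:
            fitted_sorted = fitted_sorted + u @ b_u
            e = gu / (1.0 + gam[0] * counts)[:, None]
            diag_zvz = diag_zvz - np.sum(e * sla.cho_solve(ck, e.T).T, axis=1)
        edf += float(gam[0] * diag_zvz.sum())
        b_hat = np.concatenate([b_subj, b_u])
    else:
        fitted_sorted = xs @ beta + (u @ b_u if r_pen else 0.0)
        b_hat = b_u
    fitted = np.empty(m)
    fitted[order] = fitted_sorted

    sigma_b2 = float(sigma2 * gam[0]) if has_subject else 0.0
    lambdas = {}
    off = 1 if has_subject else 0
    for j, sm in enumerate(smooths):
        g = gam[off + j]
        lambdas[sm.name] = float(1.0 / g) if g > 0 else np.inf
    n_fixed = p + n_pen_cols
    n_varpar = 1 + n_free
    aic = -2.0 * ll + 2.0 * (n_fixed + n_varpar)
    return ModelFit(
        model_id=model_id, beta=beta, coef_names=names, sigma2=float(sigma2),
        sigma_b2=sigma_b2, lambdas=lambdas, loglik=float(ll), n_fixed=n_fixed,
        n_varpar=n_varpar, aic=float(aic), edf=edf, fitted=fitted, n_obs=m,
        converged=converged, b=b_hat, block_slices=slices,
    )


def marginal_loglik_dense(
    y: np.ndarray,
    fixed: np.ndarray,
    smooths: list[SmoothTerm] | None,
    subject_ids: np.ndarray | None,
    fit: ModelFit,
) -> float:
    """Independent dense evaluation of the marginal Gaussian log-density at a
    fit's estimates — the oracle the optimizer's reported loglik must match."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(fixed, dtype=float)
    cols = [x]
    smooths = smooths or []
    for sm in smooths:
        cols.append(sm.x_null)
    xf = np.hstack(cols)
    m = y.size
    cov = fit.sigma2 * np.eye(m)
    if subject_ids is not None:
        _, inv = np.unique(np.asarray(subject_ids), return_inverse=True)
        zs = np.zeros((m, inv.max() + 1))
        zs[np.arange(m), inv] = 1.0
        cov += fit.sigma_b2 * (zs @ zs.T)
    for sm in smooths:
        lam = fit.lambdas[sm.name] if sm.fixed_ratio is None else 1.0 / sm.fixed_ratio
        var = fit.sigma2 / lam
        cov += var * (sm.z_pen @ sm.z_pen.T)
    r = y - xf @ fit.beta
    chol = sla.cho_factor(cov, lower=True)
    quad = float(r @ sla.cho_solve(chol, r))
    logdet = 2.0 * float(np.log(np.diagonal(chol[0])).sum())
    return -0.5 * (m * np.log(2.0 * np.pi) + logdet + quad)


def lrt(simple: ModelFit, complex: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits on identical rows.

    Returns (deviance, df, p). Deviance is clipped at zero (optimizer noise
    can leave the complex fit marginally lower); df is the difference in
    column counts, penalized smooth columns included.
    """
    if simple.n_obs != complex.n_obs:
        raise ValueError("fits must use identical rows")
    df = complex.n_fixed - simple.n_fixed
    if df <= 0:
        raise ValueError(
            f"models not nested: df = {df} ({complex.model_id} vs {simple.model_id})"
        )
    dev = max(0.0, 2.0 * (complex.loglik - simple.loglik))
    p = float(chi2.sf(dev, df)) if dev > 0 else 1.0
    return dev, df, p


def select_model(
    fits: list[ModelFit], alpha: float = 0.05, aic_margin: float = 2.0
) -> str:
    """Sequential forward walk up the ladder.

    Advance from the current model to the next iff the LRT is significant
    (p < alpha) AND the complex model improves AIC by at least ``aic_margin``;
    stop at the first failure and return the last accepted model's id.
    """
    current = fits[0]
    for nxt in fits[1:]:
        if not nxt.converged:
            break
        _, _, p = lrt(current, nxt)
        if p < alpha and nxt.aic <= current.aic - aic_margin:
            current = nxt
        else:
            break
    return current.model_id


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (qvals, rejected). NaN entries pass through as NaN / not rejected
    and do not count toward the number of tests. q_i = min_{j: p_j >= p_i}
    m p_(j) / j, capped at 1; rejected iff q <= alpha.
    """
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    pv = p[ok]
    mtests = pv.size
    if mtests:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * mtests / np.arange(1, mtests + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.minimum(qv, 1.0)
        qs = np.empty(mtests)
        qs[order] = qv
        q[ok] = qs
        rej[ok] = qs <= alpha
    return q, rej
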