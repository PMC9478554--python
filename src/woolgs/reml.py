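"""REML variance-component estimation and GBLUP prediction.

Two model families are fit against a genomic relationship matrix G:

* univariate: y = Xb + Zu + e with u ~ N(0, G * sigma2_u), e ~ N(0, I * sigma2_e).
  The phenotyped submatrix of G is eigendecomposed once, y and X are rotated
  into the eigenbasis, sigma2_e is profiled out and the restricted likelihood
  is maximized over the single ratio lambda = sigma2_u / sigma2_e by bounded
  1-D search — deterministic and free of starting-value sensitivity.

* multivariate (three ages treated as distinct traits): vec(U) ~ N(0, Su (x) G),
  vec(E) ~ N(0, Se (x) I) with 3x3 covariance matrices Su, Se.  Records may be
  missing per (individual, age) cell; each age enters through its own
  incidence mapping.  Estimation runs a few EM iterations for stability and
  then switches to average-information (AI) updates, falling back to an EM
  step whenever an AI step would decrease the restricted likelihood.  A
  complete-record dataset takes a fast path in the eigenbasis of G where the
  likelihood factorizes over individuals into 3x3 blocks.

GEBVs are computed for every individual in G, phenotyped or not — the
unphenotyped ones are predicted purely through their genomic relationships.

REML log-likelihood convention used throughout (and by the test oracles):
ll = -1/2 [ log|V| + log|X'V^-1 X| + y'Py + (N - rank X) log 2*pi ].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .genio import PhenotypeTable
from .grm import GRM, stabilize

logger = logging.getLogger(__name__)

__all__ = ["FixedDesign", "UvFit", "MvFit", "build_fixed_design", "fit_uvlmm", "fit_mvlmm", "predict_gebv"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FixedDesign:
    """Treatment-coded intercept + sex + batch design matrix."""

    X: np.ndarray
    labels: list[str]
    dropped: list[str]


def build_fixed_design(sex: np.ndarray, batch: np.ndarray) -> FixedDesign:
    """Intercept + sex + batch with treatment contrasts (first level reference).

    Aliased (rank-deficient) columns are dropped with a logged warning, as
    happens when e.g. only one batch level is present.
    """
    n = len(sex)
    cols = [np.ones(n)]
    labels = ["intercept"]
    for name, values in (("sex", np.asarray(sex)), ("batch", np.asarray(batch))):
        levels = pd.unique(pd.Series(values))
        for lev in levels[1:]:
            cols.append((values == lev).astype(float))
            labels.append(f"{name}[{lev}]")
    X = np.column_stack(cols)
    keep = _independent_columns(X)
    dropped = [labels[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropping aliased fixed-effect columns: %s", dropped)
    return FixedDesign(X=X[:, keep], labels=[labels[j] for j in keep], dropped=dropped)


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    if X.size == 0:
        return []
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    return sorted(piv[:rank].tolist())


def _align_covars(covars: PhenotypeTable, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lookup = {v: i for i, v in enumerate(covars.individual_ids)}
    idx = np.array([lookup[i] for i in ids], dtype=int)
    return np.asarray(covars.sex, dtype=object)[idx], np.asarray(covars.batch, dtype=object)[idx]


def _bend(M: np.ndarray, rel_floor: float = 1e-6) -> np.ndarray:
    """Symmetrize and floor eigenvalues at rel_floor * trace/dim."""
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    floor = rel_floor * max(np.trace(M) / M.shape[0], rel_floor)
    if vals[0] >= floor:
        return M
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------

@dataclass
class UvFit:
    sigma2_u: float
    sigma2_e: float
    h2: float
    se_h2: float
    beta_hat: np.ndarray
    beta_labels: list[str]
    gebv: np.ndarray
    loglik_reml: float
    n_iterations: int
    converged: bool
    boundary: bool
    individual_ids: np.ndarray
    phenotyped_ids: np.ndarray = field(repr=False, default=None)


def _uv_profile(log10_lam: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profiled REML pieces at a given log10(lambda). Returns (ll, sigma2_e, beta)."""
    lam = 10.0 ** log10_lam
    d = lam * s + 1.0
    Xw = Xt / d[:, None]
    A = Xt.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yt)
    r = yt - Xt @ beta
    nobs, p = yt.size, Xt.shape[1]
    quad = float(r @ (r / d))
    s2e = quad / (nobs - p)
    sign, logdetA = np.linalg.slogdet(A)
    ll = -0.5 * (
        (nobs - p) * np.log(s2e)
        + np.sum(np.log(d))
        + logdetA
        + (nobs - p)
        + (nobs - p) * _LOG2PI
    )
    return ll, s2e, beta


def _uv_loglik(s2u: float, s2e: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """Un-profiled rotated REML log-likelihood at (sigma2_u, sigma2_e)."""
    d = s2u * s + s2e
    Xw = Xt / d[:, None]
    A = Xt.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yt)
    r = yt - Xt @ beta
    nobs, p = yt.size, Xt.shape[1]
    _, logdetA = np.linalg.slogdet(A)
    return float(
        -0.5 * (np.sum(np.log(d)) + logdetA + r @ (r / d) + (nobs - p) * _LOG2PI)
    )


def fit_uvlmm(
    y,
    covars: PhenotypeTable,
    grm: GRM,
    log10_lambda_bounds: tuple[float, float] = (-6.0, 6.0),
    min_records: int = 30,
) -> UvFit:
    """Univariate REML-GBLUP fit.

    ``y`` is aligned with ``grm.individual_ids`` (NaN = unphenotyped) or a
    pandas Series indexed by individual id.  Fixed effects (intercept, sex,
    batch) are taken from ``covars``.  GEBVs are returned for every
    individual in the GRM.
    """
    ids = grm.individual_ids
    if isinstance(y, pd.Series):
        y = y.reindex(ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != (grm.n,):
        raise ValueError("y must align with the GRM individuals")
    obs = np.flatnonzero(np.isfinite(y))
    if obs.size < min_records:
        raise ValueError(f"only {obs.size} phenotyped individuals (< {min_records})")
    sex, batch = _align_covars(covars, ids[obs])
    design = build_fixed_design(sex, batch)
    X = design.X
    Goo = grm.matrix[np.ix_(obs, obs)]
    s, U = eigh(Goo)
    if s[0] < -1e-8 * max(1.0, s[-1]):
        Goo = stabilize(GRM(Goo, ids[obs], grm.n_markers_used, grm.denom)).matrix
        s, U = eigh(Goo)
    s = np.clip(s, 0.0, None)
    yo = y[obs]
    yt, Xt = U.T @ yo, U.T @ X

    res = minimize_scalar(
        lambda t: -_uv_profile(t, s, yt, Xt)[0],
        bounds=log10_lambda_bounds,
        method="bounded",
        options={"xatol": 1e-10},
    )
    log10_lam = float(res.x)
    ll, s2e, beta = _uv_profile(log10_lam, s, yt, Xt)
    lam = 10.0 ** log10_lam
    s2u = lam * s2e
    boundary = (
        log10_lam < log10_lambda_bounds[0] + 1e-3
        or log10_lam > log10_lambda_bounds[1] - 1e-3
    )
    var_p = float(np.var(yo, ddof=1))
    h2 = s2u / (s2u + s2e)
    if s2u < 1e-8 * var_p:
        h2 = 0.0

    se_h2 = float("nan")
    if not boundary:
        se_h2 = _uv_se_h2(s2u, s2e, s, yt, Xt)

    # GEBV for everyone: u_hat = s2u * G[:, obs] V^-1 (y - X beta)
    r = yo - X @ beta
    vinv_r = U @ ((U.T @ r) / (s2u * s + s2e))
    gebv = s2u * (grm.matrix[:, obs] @ vinv_r)

    return UvFit(
        sigma2_u=float(s2u),
        sigma2_e=float(s2e),
        h2=float(h2),
        se_h2=se_h2,
        beta_hat=beta,
        beta_labels=design.labels,
        gebv=gebv,
        loglik_reml=float(ll),
        n_iterations=int(res.nfev),
        converged=bool(res.success),
        boundary=boundary,
        individual_ids=ids,
        phenotyped_ids=ids[obs],
    )


def _uv_se_h2(s2u, s2e, s, yt, Xt) -> float:
    """Delta-method SE of h2 from a numeric observed-information matrix."""
    theta = np.array([s2u, s2e])
    step = np.maximum(1e-4 * np.abs(theta), 1e-10)

    def f(t):
        return _uv_loglik(max(t[0], 1e-12), max(t[1], 1e-12), s, yt, Xt)

    H = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * step[i]
            ej = np.eye(2)[j] * step[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * step[i] * step[j])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return float("nan")
    tot = s2u + s2e
    g = np.array([s2e, -s2u]) / tot**2
    v = float(g @ cov @ g)
    return float(np.sqrt(v)) if v > 0 else float("nan")


# ---------------------------------------------------------------------------
# multivariate
# ---------------------------------------------------------------------------

@dataclass
class MvFit:
    Sigma_u: np.ndarray
    Sigma_e: np.ndarray
    genetic_corr: np.ndarray
    h2: np.ndarray
    beta_hat: list[np.ndarray]
    gebv: np.ndarray
    loglik_reml: float
    n_iterations: int
    converged: bool
    loglik_trace: list[tuple[str, float]]
    individual_ids: np.ndarray
    observed_records: list[tuple[object, int]] = field(repr=False, default=None)
    missing_summary: dict = field(default_factory=dict)


class _MvEngineGeneral:
    """Direct-V REML machinery for arbitrary per-cell missing patterns.

    Records are stacked age-major; V (records x records) is assembled from
    Su (x) G blocks plus Se on same-individual overlaps and factorized
    densely each iteration.
    """

    def __init__(self, Yp: np.ndarray, X0: np.ndarray, Gpp: np.ndarray):
        self.m, self.T = Yp.shape
        self.Gpp = Gpp
        self.obs = [np.flatnonzero(np.isfinite(Yp[:, t])) for t in range(self.T)]
        self.sizes = [o.size for o in self.obs]
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)]).astype(int)
        self.N = int(self.offsets[-1])
        self.y = np.concatenate([Yp[self.obs[t], t] for t in range(self.T)])
        # per-age design, aliased columns re-dropped on the age's records
        self.Xb, self.keep = [], []
        for t in range(self.T):
            Xt = X0[self.obs[t]]
            keep = _independent_columns(Xt)
            self.Xb.append(Xt[:, keep])
            self.keep.append(keep)
        self.p_tot = sum(x.shape[1] for x in self.Xb)
        self.X = np.zeros((self.N, self.p_tot))
        c0 = 0
        for t in range(self.T):
            r0, r1 = self.offsets[t], self.offsets[t + 1]
            self.X[r0:r1, c0 : c0 + self.Xb[t].shape[1]] = self.Xb[t]
            c0 += self.Xb[t].shape[1]
        # overlap positions for residual covariance blocks
        self.Gblocks = [[Gpp[np.ix_(self.obs[t], self.obs[u])] for u in range(self.T)] for t in range(self.T)]
        self.overlap = {}
        for t in range(self.T):
            for u in range(self.T):
                common, it, iu = np.intersect1d(self.obs[t], self.obs[u], return_indices=True)
                self.overlap[(t, u)] = (it, iu)

    def rows(self, t):
        return slice(self.offsets[t], self.offsets[t + 1])

    def evaluate(self, Su: np.ndarray, Se: np.ndarray) -> dict:
        T, N = self.T, self.N
        V = np.zeros((N, N))
        for t in range(T):
            for u in range(T):
                blk = Su[t, u] * self.Gblocks[t][u]
                it, iu = self.overlap[(t, u)]
                if it.size:
                    blk = blk.copy()
                    blk[it, iu] += Se[t, u]
                V[self.rows(t), self.rows(u)] = blk
        c, low = cho_factor(V, lower=True)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = cho_solve((c, low), np.eye(N))
        VinvX = Vinv @ self.X
        A = self.X.T @ VinvX
        cA, lowA = cho_factor(A)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cA))))
        Ainv = cho_solve((cA, lowA), np.eye(self.p_tot))
        beta = Ainv @ (VinvX.T @ self.y)
        P = Vinv - VinvX @ Ainv @ VinvX.T
        w = P @ self.y
        ll = -0.5 * (logdetV + logdetA + float(self.y @ w) + (N - self.p_tot) * _LOG2PI)

        wfull = np.zeros((self.m, T))
        for t in range(T):
            wfull[self.obs[t], t] = w[self.rows(t)]
        Gw = self.Gpp @ wfull  # m x T
        Q = wfull.T @ Gw
        Qe = wfull.T @ wfull
        S = np.empty((T, T))
        Str = np.empty((T, T))
        for t in range(T):
            for u in range(T):
                Pblk = P[self.rows(t), self.rows(u)]
                S[t, u] = float(np.sum(Pblk * self.Gblocks[t][u]))
                it, iu = self.overlap[(t, u)]
                Str[t, u] = float(Pblk[it, iu].sum()) if it.size else 0.0

        grad, F = self._grad_and_F(Su, Se, Q, S, Qe, Str, wfull, Gw)
        PF = P @ F
        AI = 0.5 * (F.T @ PF)
        return {
            "ll": ll, "Q": Q, "S": S, "Qe": Qe, "Str": Str, "grad": grad, "AI": AI,
            "Du": -0.5 * (S - Q), "De": -0.5 * (Str - Qe),
            "beta": beta, "wfull": wfull, "n_u": self.m, "n_e": self.m,
        }

    def _grad_and_F(self, Su, Se, Q, S, Qe, Str, wfull, Gw):
        T, N = self.T, self.N
        params = _vech_indices(T)
        grad = np.empty(2 * len(params))
        F = np.zeros((N, 2 * len(params)))
        for j, (k, l) in enumerate(params):
            mult = 1.0 if k == l else 2.0
            grad[j] = -0.5 * mult * (S[k, l] - Q[k, l])
            grad[len(params) + j] = -0.5 * mult * (Str[k, l] - Qe[k, l])
            # F for Su(k,l): dV w
            f = np.zeros(N)
            f[self.rows(k)] += Gw[self.obs[k], l]
            if k != l:
                f[self.rows(l)] += Gw[self.obs[l], k]
            F[:, j] = f
            f = np.zeros(N)
            f[self.rows(k)] += wfull[self.obs[k], l]
            if k != l:
                f[self.rows(l)] += wfull[self.obs[l], k]
            F[:, len(params) + j] = f
        return grad, F

    def predict(self, G_all_p: np.ndarray, wfull: np.ndarray, Su: np.ndarray) -> np.ndarray:
        return (G_all_p @ wfull) @ Su


class _MvEngineComplete:
    """Eigen-rotated REML machinery when every phenotyped individual has all ages.

    In the eigenbasis of G the likelihood factorizes over individuals into
    independent 3x3 problems V_i = s_i Su + Se — each iteration is O(m).
    """

    def __init__(self, Yp: np.ndarray, X0: np.ndarray, Gpp: np.ndarray):
        self.m, self.T = Yp.shape
        s, U = eigh(Gpp)
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.Yt = U.T @ Yp
        self.Xt = U.T @ X0
        self.p = X0.shape[1]
        self.p_tot = self.T * self.p
        self.N = self.m * self.T

    def evaluate(self, Su: np.ndarray, Se: np.ndarray) -> dict:
        m, T, p = self.m, self.T, self.p
        V = self.s[:, None, None] * Su + Se  # (m,3,3)
        sign, logdets = np.linalg.slogdet(V)
        Vinv = np.linalg.inv(V)
        A = np.einsum("ikl,ia,ib->kalb", Vinv, self.Xt, self.Xt).reshape(self.p_tot, self.p_tot)
        rhs = np.einsum("ikl,il,ia->ka", Vinv, self.Yt, self.Xt).reshape(self.p_tot)
        cA, lowA = cho_factor(A)
        Ainv = cho_solve((cA, lowA), np.eye(self.p_tot))
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cA))))
        beta = Ainv @ rhs
        Beta = beta.reshape(T, p).T  # p x T
        R = self.Yt - self.Xt @ Beta
        wt = np.einsum("ikl,il->ik", Vinv, R)  # m x T
        quad = float(np.sum(R * wt))
        ll = -0.5 * (float(logdets.sum()) + logdetA + quad + (self.N - self.p_tot) * _LOG2PI)

        Q = (wt * self.s[:, None]).T @ wt
        Qe = wt.T @ wt
        # C_i = H_i Ainv H_i', H_i = Vinv_i (x) x_i'
        H = np.einsum("ikl,ia->ikla", Vinv, self.Xt).reshape(m, T, self.p_tot)
        HA = np.einsum("ikq,qr->ikr", H, Ainv)
        C = np.einsum("ikr,ilr->ikl", HA, H)
        PiD = Vinv - C  # per-individual diagonal blocks of P
        S = np.einsum("i,ikl->kl", self.s, PiD)
        Str = PiD.sum(axis=0)

        params = _vech_indices(T)
        nprm = len(params)
        grad = np.empty(2 * nprm)
        Fi = np.zeros((m, T, 2 * nprm))
        for j, (k, l) in enumerate(params):
            mult = 1.0 if k == l else 2.0
            grad[j] = -0.5 * mult * (S[k, l] - Q[k, l])
            grad[nprm + j] = -0.5 * mult * (Str[k, l] - Qe[k, l])
            Fi[:, k, j] += self.s * wt[:, l]
            if k != l:
                Fi[:, l, j] += self.s * wt[:, k]
            Fi[:, k, nprm + j] += wt[:, l]
            if k != l:
                Fi[:, l, nprm + j] += wt[:, k]
        PF = self._apply_P(Fi, Vinv, Ainv)
        AI = 0.5 * np.einsum("ikj,ikh->jh", Fi, PF)
        return {
            "ll": ll, "Q": Q, "S": S, "Qe": Qe, "Str": Str, "grad": grad, "AI": AI,
            "Du": -0.5 * (S - Q), "De": -0.5 * (Str - Qe),
            "beta": beta, "wt": wt, "Vinv": Vinv, "n_u": m, "n_e": m,
        }

    def _apply_P(self, v: np.ndarray, Vinv: np.ndarray, Ainv: np.ndarray) -> np.ndarray:
        """P applied to stacked record-space vectors v of shape (m, T, nv)."""
        t1 = np.einsum("ikl,ilv->ikv", Vinv, v)
        xv = np.einsum("ikv,ia->kav", t1, self.Xt).reshape(self.p_tot, -1)
        c = (Ainv @ xv).reshape(self.T, self.p, -1)
        xc = np.einsum("ia,kav->ikv", self.Xt, c)
        return t1 - np.einsum("ikl,ilv->ikv", Vinv, xc)

    def wfull(self, wt: np.ndarray) -> np.ndarray:
        return self.U @ wt

    def predict(self, G_all_p: np.ndarray, wfull: np.ndarray, Su: np.ndarray) -> np.ndarray:
        return (G_all_p @ wfull) @ Su


def _polish_cholesky(engine, Su: np.ndarray, Se: np.ndarray, max_nfev: int = 200):
    """Final refinement of (Su, Se) by L-BFGS-B in log-Cholesky coordinates.

    The Cholesky parametrization is smooth up to the positive-semidefinite
    boundary, where AI-REML steps tend to crawl; the analytic gradient with
    respect to a factor L (Sigma = L L') is 2 * (dl/dSigma) L.
    """
    from scipy.optimize import minimize

    T = Su.shape[0]
    tril = [(k, l) for k in range(T) for l in range(k)]
    scale = float(np.sqrt(max(np.trace(Su) + np.trace(Se), 1e-12) / T))
    lo, hi = np.log(1e-6 * scale), np.log(1e3 * scale)

    def pack(A: np.ndarray) -> np.ndarray:
        L = np.linalg.cholesky(_bend(A, rel_floor=1e-10) + 1e-12 * scale**2 * np.eye(T))
        return np.concatenate([np.clip(np.log(np.diag(L)), lo, hi), [L[k, l] for k, l in tril]])

    def unpack(x: np.ndarray) -> np.ndarray:
        L = np.zeros((T, T))
        L[np.diag_indices(T)] = np.exp(x[:T])
        for j, (k, l) in enumerate(tril):
            L[k, l] = x[T + j]
        return L

    def fun(x):
        Lu, Le = unpack(x[: T + len(tril)]), unpack(x[T + len(tril) :])
        try:
            st = engine.evaluate(Lu @ Lu.T, Le @ Le.T)
        except np.linalg.LinAlgError:
            return 1e15, np.zeros_like(x)  # barrier: line search backs off
        g = np.empty_like(x)
        for off, (D, L) in enumerate(((st["Du"], Lu), (st["De"], Le))):
            GL = 2.0 * D @ L
            base = off * (T + len(tril))
            g[base : base + T] = np.diag(GL) * np.diag(L)
            for j, (k, l) in enumerate(tril):
                g[base + T + j] = GL[k, l]
        return -st["ll"], -g

    x0 = np.concatenate([pack(Su), pack(Se)])
    bounds = ([(lo, hi)] * T + [(None, None)] * len(tril)) * 2
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxfun": max_nfev, "ftol": 1e-13, "gtol": 1e-7})
    Lu, Le = unpack(res.x[: T + len(tril)]), unpack(res.x[T + len(tril) :])
    return Lu @ Lu.T, Le @ Le.T, int(res.nfev), bool(res.success)


def _vech_indices(T: int) -> list[tuple[int, int]]:
    return [(k, l) for k in range(T) for l in range(k + 1)]


def _vech_to_mats(theta: np.ndarray, T: int) -> tuple[np.ndarray, np.ndarray]:
    params = _vech_indices(T)
    Su = np.zeros((T, T))
    Se = np.zeros((T, T))
    for j, (k, l) in enumerate(params):
        Su[k, l] = Su[l, k] = theta[j]
        Se[k, l] = Se[l, k] = theta[len(params) + j]
    return Su, Se


def _mats_to_vech(Su: np.ndarray, Se: np.ndarray) -> np.ndarray:
    params = _vech_indices(Su.shape[0])
    return np.array([Su[k, l] for k, l in params] + [Se[k, l] for k, l in params])


def fit_mvlmm(
    Y,
    covars: PhenotypeTable,
    grm: GRM,
    em_burnin: int = 5,
    max_iter: int = 200,
    tol: float = 1e-8,
    force_general: bool = False,
    em_only: bool = False,
    min_records: int = 30,
    start: tuple[np.ndarray, np.ndarray] | None = None,
) -> MvFit:
    """Multivariate (3-age) REML-GBLUP fit with per-cell missing records.

    ``Y`` is an (n, 3) array aligned with ``grm.individual_ids`` (NaN =
    missing record) or a DataFrame indexed by individual id.  Individuals
    with no record at all still receive GEBVs through G.  ``em_only`` runs
    pure EM (used to check the EM monotonicity property); the default is
    ``em_burnin`` EM steps followed by AI updates with EM fallback.
    """
    ids = grm.individual_ids
    if isinstance(Y, pd.DataFrame):
        Y = Y.reindex(ids).to_numpy(dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (grm.n, 3):
        raise ValueError("Y must be n x 3 aligned with the GRM individuals")
    counts = np.isfinite(Y).sum(axis=0)
    if (counts < min_records).any():
        raise ValueError(f"each age needs >= {min_records} records, got {counts.tolist()}")
    pset = np.flatnonzero(np.isfinite(Y).any(axis=1))
    Yp = Y[pset]
    sex, batch = _align_covars(covars, ids[pset])
    design = build_fixed_design(sex, batch)
    Gpp = grm.matrix[np.ix_(pset, pset)]
    if np.linalg.eigvalsh(Gpp)[0] < 1e-10:
        Gpp = Gpp + 1e-6 * np.eye(Gpp.shape[0])

    complete = bool(np.isfinite(Yp).all()) and not force_general
    engine = _MvEngineComplete(Yp, design.X, Gpp) if complete else _MvEngineGeneral(Yp, design.X, Gpp)

    if start is not None:
        Su, Se = _bend(np.asarray(start[0], dtype=float)), _bend(np.asarray(start[1], dtype=float))
        em_burnin = min(em_burnin, 1)  # a supplied start replaces the EM warm-up
    else:
        # half the per-age phenotypic variance to each component, no covariance
        varp = np.nanvar(Yp, axis=0, ddof=1)
        Su = np.diag(0.5 * varp)
        Se = np.diag(0.5 * varp)
    trace: list[tuple[str, float]] = []
    state = engine.evaluate(Su, Se)
    trace.append(("init", state["ll"]))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        use_em = em_only or it <= em_burnin
        if use_em:
            Su_n = _bend(Su + Su @ ((state["Q"] - state["S"]) / state["n_u"]) @ Su)
            Se_n = _bend(Se + Se @ ((state["Qe"] - state["Str"]) / state["n_e"]) @ Se)
            try:
                new = engine.evaluate(Su_n, Se_n)
            except np.linalg.LinAlgError:
                # severely ill-conditioned proposal: bend harder and retry
                Su_n, Se_n = _bend(Su_n, rel_floor=1e-4), _bend(Se_n, rel_floor=1e-4)
                new = engine.evaluate(Su_n, Se_n)
            kind = "em"
        else:
            theta = _mats_to_vech(Su, Se)
            AI, grad = state["AI"], state["grad"]
            scale = np.maximum(np.abs(np.diag(AI)), 1e-12 * np.abs(np.diag(AI)).max() + 1e-300)
            kind = "ai"
            new = None
            # damped AI: interpolate towards steepest ascent when the raw
            # Newton-like step overshoots (typical near a singular Sigma_u)
            for mu in (0.0, 1e-4, 1e-2, 1.0, 1e2, 1e4):
                try:
                    step = np.linalg.solve(AI + mu * np.diag(scale), grad)
                except np.linalg.LinAlgError:
                    continue
                Su_n, Se_n = _vech_to_mats(theta + step, 3)
                Su_n, Se_n = _bend(Su_n), _bend(Se_n)
                try:
                    cand = engine.evaluate(Su_n, Se_n)
                except np.linalg.LinAlgError:
                    continue
                if cand["ll"] >= state["ll"] - 1e-10:
                    new = cand
                    break
            if new is None:  # AI failed outright: EM safeguard step
                Su_n = _bend(Su + Su @ ((state["Q"] - state["S"]) / state["n_u"]) @ Su)
                Se_n = _bend(Se + Se @ ((state["Qe"] - state["Str"]) / state["n_e"]) @ Se)
                new = engine.evaluate(Su_n, Se_n)
                kind = "em-fallback"
        delta = new["ll"] - state["ll"]
        Su, Se, state = Su_n, Se_n, new
        trace.append((kind, state["ll"]))
        if abs(delta) / (1.0 + abs(state["ll"])) < tol and it > em_burnin:
            converged = True
            break
        lls = [v for _, v in trace]
        if not em_only and len(lls) > 10 and lls[-1] - lls[-9] < 1e4 * tol * (1.0 + abs(lls[-1])):
            break  # stalled: hand over to the Cholesky polish

    if not em_only:
        # near-singular Sigma_u (strong genetic correlations) makes AI crawl
        # along the PSD boundary; a log-Cholesky refinement finishes the job
        Su_p, Se_p, nfev, ok = _polish_cholesky(engine, Su, Se)
        it += nfev
        try:
            cand = engine.evaluate(Su_p, Se_p)
            if cand["ll"] >= state["ll"]:
                Su, Se, state = Su_p, Se_p, cand
                converged = converged or ok
        except np.linalg.LinAlgError:
            pass
        trace.append(("polish", state["ll"]))

    wfull = state["wfull"] if "wfull" in state else engine.wfull(state["wt"])
    G_all_p = grm.matrix[:, pset]
    gebv = engine.predict(G_all_p, wfull, Su)

    du = np.sqrt(np.clip(np.diag(Su), 1e-30, None))
    gcorr = Su / np.outer(du, du)
    np.fill_diagonal(gcorr, 1.0)
    h2 = np.diag(Su) / (np.diag(Su) + np.diag(Se))
    observed = [
        (ids[pset[i]], t) for t in range(3) for i in np.flatnonzero(np.isfinite(Yp[:, t]))
    ]
    beta_list: list[np.ndarray] = []
    if complete:
        beta_list = list(state["beta"].reshape(3, -1))
    else:
        c0 = 0
        for t in range(3):
            pt = engine.Xb[t].shape[1]
            beta_list.append(state["beta"][c0 : c0 + pt])
            c0 += pt
    return MvFit(
        Sigma_u=Su,
        Sigma_e=Se,
        genetic_corr=gcorr,
        h2=h2,
        beta_hat=beta_list,
        gebv=gebv,
        loglik_reml=float(state["ll"]),
        n_iterations=it,
        converged=converged,
        loglik_trace=trace,
        individual_ids=ids,
        observed_records=observed,
        missing_summary={
            "n_individuals": int(grm.n),
            "n_phenotyped": int(pset.size),
            "records_per_age": np.isfinite(Y).sum(axis=0).tolist(),
            "complete_path": complete,
        },
    )


def predict_gebv(fit: UvFit | MvFit, grm: GRM, target_ids) -> np.ndarray:
    """BLUP breeding values for the requested individuals.

    The fit already carries GEBVs for every individual of the GRM it was
    estimated against (unphenotyped ones predicted purely through G); this
    selects and orders them, raising on unknown ids.
    """
    lookup = {v: i for i, v in enumerate(fit.individual_ids)}
    try:
        idx = np.array([lookup[i] for i in target_ids], dtype=int)
    except KeyError as exc:
        raise KeyError(f"id {exc.args[0]!r} was not part of the fitted GRM") from exc
    return fit.gebv[idx]
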