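"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles — exact
rational enumeration, dense-matrix likelihoods, textbook formulas — and
shares no code path with woolgs itself.
"""

from fractions import Fraction
from math import factorial

import numpy as np
from scipy.linalg import cho_factor, cho_solve

_LOG2PI = float(np.log(2.0 * np.pi))


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    hs = range(n_A % 2, min(n_A, 2 * n - n_A) + 1, 2)

    def ways(h: int) -> int:
        n_hom_A = (n_A - h) // 2
        n_hom_a = n - n_hom_A - h
        return factorial(n) // (factorial(n_hom_A) * factorial(h) * factorial(n_hom_a)) * 2**h

    total = sum(ways(h) for h in hs)
    probs = {h: Fraction(ways(h), total) for h in hs}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def direct_reml_loglik(y: np.ndarray, X: np.ndarray, G: np.ndarray, s2u: float, s2e: float) -> float:
    """Univariate REML log-likelihood from the dense covariance V = s2u G + s2e I."""
    n, p = y.size, X.shape[1]
    V = s2u * G + s2e * np.eye(n)
    c = cho_factor(V)
    logdetV = 2.0 * np.log(np.diag(c[0])).sum()
    VinvX = cho_solve(c, X)
    A = X.T @ VinvX
    _, logdetA = np.linalg.slogdet(A)
    beta = np.linalg.solve(A, VinvX.T @ y)
    r = y - X @ beta
    quad = float(r @ cho_solve(c, r))
    return float(-0.5 * (logdetV + logdetA + quad + (n - p) * _LOG2PI))


def ridge_snp_blup_gebv(dosages: np.ndarray, freqs: np.ndarray, y: np.ndarray,
                        X_obs: np.ndarray, obs: np.ndarray,
                        s2u: float, s2e: float, denom: float) -> np.ndarray:
    """GEBVs from the marker-effects ridge model matched to a GBLUP fit.

    Effects a ~ N(0, (s2u/denom) I); solves the joint (b, a) mixed model
    equations on the phenotyped records and returns W a for all individuals.
    """
    keep = (freqs > 0) & (freqs < 1)
    W = np.where(np.isnan(dosages), 0.0, dosages - 2.0 * freqs)[:, keep]
    Wo = W[obs]
    lam = s2e / (s2u / denom)
    p = X_obs.shape[1]
    m = W.shape[1]
    A = np.block([
        [X_obs.T @ X_obs, X_obs.T @ Wo],
        [Wo.T @ X_obs, Wo.T @ Wo + lam * np.eye(m)],
    ])
    rhs = np.concatenate([X_obs.T @ y[obs], Wo.T @ y[obs]])
    sol = np.linalg.solve(A, rhs)
    return W @ sol[p:]


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Textbook Welch t statistic and two-sided p via Satterthwaite df."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return float(t), float(p)


def ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals from the normal equations, solved with a pseudo-inverse."""
    beta = np.linalg.pinv(X.T @ X) @ (X.T @ y)
    return y - X @ beta
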