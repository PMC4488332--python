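"""Variance-component inference for the one-GRM linear mixed model
``y = X a + g + e`` with ``Var(y) = sigma_g^2 G + sigma_e^2 I``:

* :func:`score_statistic` — the quadratic-form score statistic T² for
  H0: sigma_g^2 = 0, computed from the ML null fit.  As defined here the
  statistic is twice the canonical efficient score, so under H0 its
  distribution is approximately that of 2·chi²(1) rather than chi²(1);
  nominal chi²(1) critical values (3.84) are therefore anti-conservative
  and the Monte-Carlo calibration in :mod:`snpherit.power` is essential.
  When G equals the identity, numerator and denominator both vanish (the
  variance components are unidentifiable) and the statistic is undefined.
* :func:`reml_fit` — exact restricted maximum likelihood via a single
  eigendecomposition of G, profiling the total variance and maximising the
  restricted likelihood over h² = sigma_g²/(sigma_g²+sigma_e²) on [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.stats import chi2

from .grm import GRM

__all__ = [
    "NullFit", "ScoreTestResult", "VarianceComponentFit",
    "UnidentifiableError", "fit_null", "score_statistic", "reml_fit",
    "reml_loglik_naive",
]

#: relative identifiability guard on the score-test denominator
DENOM_GUARD = 1e-8

#: upper bound for h2 during REML optimisation (keeps V positive definite)
H2_MAX = 1.0 - 1e-6


class UnidentifiableError(ValueError):
    """Score test denominator is (numerically) zero: G is too close to I
    for the genetic variance to be identifiable."""


@dataclass
class NullFit:
    """ML fit of the fixed-effects-only model (sigma_g^2 = 0)."""

    beta_hat: np.ndarray
    sigma2_hat: float       # ML estimate: RSS / N
    residuals: np.ndarray
    degenerate: bool = False


@dataclass
class ScoreTestResult:
    T2: float
    S: float                # centered quadratic form r'Gr/sigma2 - tr(G)
    tr_G: float
    tr_GG: float
    denom: float            # N tr(GG) - tr(G)^2
    N: int


@dataclass
class VarianceComponentFit:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik_reml: float
    p_lrt: float
    converged: bool
    boundary: bool
    n_used: int
    M_used: int = 0


def fit_null(y: np.ndarray, X: np.ndarray) -> NullFit:
    """Ordinary least squares with the ML variance divisor N (not N - p)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    q, r_mat, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(r_mat)) > np.abs(r_mat[0, 0]) * n * np.finfo(float).eps))
    if rank < p:
        collinear = sorted(piv[rank:].tolist())
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return NullFit(beta_hat=beta, sigma2_hat=rss / n, residuals=resid,
                   degenerate=rss <= n * np.finfo(float).eps * max(1.0, float(y @ y)))


def score_statistic(y: np.ndarray, X: np.ndarray, G: GRM | np.ndarray,
                    variance_ddof: int = 1) -> ScoreTestResult:
    """Score statistic T² = N S² / (N tr(GG) - tr(G)²) for H0: sigma_g² = 0,
    with S = r'Gr/sigma²_hat - tr(G) from the null (OLS) fit.

    ``variance_ddof`` selects the divisor of the residual variance:
    the default 1 is the unbiased sample-variance convention (divisor
    N - 1), which is what the empirical calibration tables in
    :mod:`snpherit.power` reflect; 0 gives the pure-ML divisor N.  The two
    differ by a shift of roughly tr(G)/N in S — negligible when the signal
    is strong, but material in the near-degenerate regime where G is close
    to I and T² is small.

    Raises :class:`UnidentifiableError` when the denominator falls below
    ``DENOM_GUARD * N²`` — in particular when G = I, where the statistic
    is 0/0.
    """
    Gm = G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)
    n = Gm.shape[0]
    if Gm.shape != (n, n):
        raise ValueError("G must be square")
    null = fit_null(y, X)
    if null.degenerate or null.sigma2_hat <= 0.0:
        raise ValueError("null fit has zero residual variance; score test undefined")
    tr_G = float(np.trace(Gm))
    tr_GG = float(np.sum(Gm * Gm))
    denom = n * tr_GG - tr_G ** 2
    if denom <= DENOM_GUARD * n ** 2:
        raise UnidentifiableError(
            f"N tr(GG) - tr(G)^2 = {denom:.3g} <= {DENOM_GUARD:g} N^2: "
            "G is numerically proportional to I, sigma_g^2 is unidentifiable")
    r = null.residuals
    sigma2 = float(r @ r) / (n - variance_ddof)
    S = float(r @ (Gm @ r)) / sigma2 - tr_G
    T2 = n * S ** 2 / denom
    return ScoreTestResult(T2=T2, S=S, tr_G=tr_G, tr_GG=tr_GG, denom=denom, N=n)


def _profile_reml(lam, yt, Xt, n, p):
    """Restricted log-likelihood profiled over the total variance.

    Returns a function of h2 together with a helper recovering the full
    parameter set.  Uses the rotated model: U'y ~ N(U'X b, s2 D(h2)) with
    D = h2 L + (1 - h2) I on the eigenbasis of G.
    """
    def parts(h2):
        d = h2 * lam + (1.0 - h2)
        w = 1.0 / d
        Xw = Xt * w[:, None]
        XtDX = Xt.T @ Xw
        XtDy = Xw.T @ yt
        beta = np.linalg.solve(XtDX, XtDy)
        r = yt - Xt @ beta
        rss = float(r * w @ r)
        s2 = rss / (n - p)
        sign, logdet_XtDX = np.linalg.slogdet(XtDX)
        return d, s2, beta, logdet_XtDX

    def loglik(h2):
        d, s2, _, logdet_XtDX = parts(h2)
        return -0.5 * ((n - p) * (np.log(2 * np.pi * s2) + 1.0)
                       + np.sum(np.log(d)) + logdet_XtDX)

    return parts, loglik


def reml_loglik_naive(y, X, G, sigma_g2, sigma_e2):
    """Direct-inversion restricted log-likelihood (small-n reference).

    L_R = -1/2 [ log|V| + log|X'V^-1 X| + r' V^-1 r ] - (n-p)/2 log(2 pi),
    with r the GLS residuals.  Uses the same convention as the
    eigendecomposition route (no log|X'X| term), so the two agree exactly.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Gm = G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)
    n, p = X.shape
    V = sigma_g2 * Gm + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    _, logdetXtViX = np.linalg.slogdet(XtViX)
    return float(-0.5 * (logdetV + logdetXtViX + r @ Vi @ r)
                 - 0.5 * (n - p) * np.log(2 * np.pi))


def reml_fit(y: np.ndarray, X: np.ndarray, G: GRM | np.ndarray,
             h2_grid_init: int = 64) -> VarianceComponentFit:
    """Exact REML for Var(y) = sigma_g² G + sigma_e² I.

    One eigendecomposition of G; the restricted likelihood (with total
    variance profiled out) is maximised over h² on [0, 1-1e-6] by a coarse
    grid followed by bounded scalar refinement.  The standard error of h²
    comes from the curvature of the profile restricted log-likelihood at
    the optimum (one-sided at a boundary, flagged); the p-value uses the
    boundary mixture  1/2 chi²(0) + 1/2 chi²(1).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Gm = G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)
    # REML depends on X only through its column space: reduce to an
    # orthonormal basis so redundant (spanned) columns are harmless
    q, r_mat, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    tol = np.abs(r_mat[0, 0]) * X.shape[0] * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(r_mat)) > tol))
    X = q[:, :rank]
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    lam, U = np.linalg.eigh(Gm)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    # constant restoring the log|X'V^-1 X| convention of the original
    # (un-orthonormalised) design, so loglik matches reml_loglik_naive
    ll_const = float(-np.sum(np.log(np.abs(np.diag(r_mat)[:rank]))))
    parts, loglik_raw = _profile_reml(lam, yt, Xt, n, p)
    loglik = lambda h2: loglik_raw(h2) + ll_const

    grid = np.linspace(0.0, H2_MAX, max(8, h2_grid_init))
    ll_grid = np.array([loglik(h) for h in grid])
    i_best = int(np.argmax(ll_grid))
    lo = grid[max(0, i_best - 1)]
    hi = grid[min(len(grid) - 1, i_best + 1)]
    converged = True
    if hi > lo:
        res = scipy.optimize.minimize_scalar(
            lambda h: -loglik(h), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8})
        if res.success and -res.fun >= ll_grid[i_best] - 1e-12:
            h2_hat = float(res.x)
            ll_hat = float(-res.fun)
        else:
            converged = False
            h2_hat = float(grid[i_best])
            ll_hat = float(ll_grid[i_best])
    else:
        h2_hat = float(grid[i_best])
        ll_hat = float(ll_grid[i_best])
    if ll_grid[i_best] > ll_hat:
        h2_hat, ll_hat = float(grid[i_best]), float(ll_grid[i_best])

    boundary = h2_hat <= 1e-8 or h2_hat >= H2_MAX - 1e-8
    step = 1e-4
    if boundary:
        # one-sided curvature from two interior points
        sgn = 1.0 if h2_hat <= 1e-8 else -1.0
        l0, l1, l2 = (loglik(h2_hat), loglik(h2_hat + sgn * step),
                      loglik(h2_hat + 2 * sgn * step))
        d2 = (l2 - 2 * l1 + l0) / step ** 2
    else:
        h = min(step, h2_hat, H2_MAX - h2_hat)
        d2 = (loglik(h2_hat + h) - 2 * ll_hat + loglik(h2_hat - h)) / h ** 2
    se_h2 = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("inf")

    _, s2, _, _ = parts(h2_hat)
    sigma_g2 = h2_hat * s2
    sigma_e2 = (1.0 - h2_hat) * s2
    lr = 2.0 * (ll_hat - loglik(0.0))
    p_lrt = 1.0 if lr <= 0 else float(0.5 * chi2.sf(lr, df=1))
    return VarianceComponentFit(
        sigma_g2=float(sigma_g2), sigma_e2=float(sigma_e2), h2=h2_hat,
        se_h2=se_h2, loglik_reml=ll_hat, p_lrt=p_lrt, converged=converged,
        boundary=boundary, n_used=n,
        M_used=G.n_snps if isinstance(G, GRM) else 0)
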