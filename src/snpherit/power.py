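"""Monte-Carlo calibration and power of the score test T².

The experiment: fix a sample size N, a number of SNPs M and a relatedness
model K (identity, or unit diagonal with uniform(0, 0.05) off-diagonals);
per replicate draw a realised GRM ``G = ZZ'/M`` from Gaussian score columns
with covariance K, draw the phenotype from ``N(0, sigma_g^2 G + sigma_e^2
I)`` (sigma_g^2 = 0 under the null), and evaluate T².  The 95th percentile
of the null replicates is the empirical critical value; power is the
fraction of alternative replicates exceeding it.

Three per-replicate engines produce the *same* distribution of T²:

``direct``
    explicit Z (cost grows with M) — the literal protocol;
``wishart``
    Bartlett draw of M*G ~ Wishart(M, K); cost independent of M, cubic in N;
``spectral``
    K = I only: by orthogonal invariance the eigenvectors of G are Haar
    and independent of the spectrum, so only the Wishart eigenvalue law
    (sampled from the bidiagonal beta ensemble) and the rotated intercept
    direction are needed — cost quadratic in N and independent of M.

The heavy matrix products inside the ``wishart`` engine run in single
precision: the score statistic's ingredients there are far from the
catastrophic-cancellation regime (that regime is K = I, which uses the
float64 spectral engine), and the float32 error is orders of magnitude
below Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import blas as sblas
from statsmodels.stats.proportion import proportion_confint

from .synthetic import KinshipModel, sample_wishart_eigenvalues
from .inference import DENOM_GUARD

__all__ = [
    "PowerCell", "NullCalibration", "simulate_t2", "null_critical_value",
    "power_cell", "run_table1", "TABLE1_GRID",
]

#: nominal chi-square(1) 5% critical value used for the type-I-error tabulation
NOMINAL_CRIT = 3.841458820694124

#: default Table-1-style grid: (N, M, kinship kind)
TABLE1_GRID = [
    (N, M, kind)
    for N in (1000, 4000)
    for kind in ("unrelated", "related")
    for M in (120, 6000, 50000, 100000, 300000)
]


@dataclass
class NullCalibration:
    crit: float
    alpha: float
    typeI_at_nominal: float     # fraction of null T² above 3.84
    n_reps: int
    n_excluded: int
    t2: np.ndarray | None = None


@dataclass
class PowerCell:
    N: int
    M: int
    kinship_kind: str
    mean_T2: float
    sd_T2: float
    crit_empirical: float
    power: float
    power_ci: tuple[float, float]
    typeI_at_nominal: float
    n_null_reps: int
    n_alt_reps: int
    seed: int | None
    n_excluded: int = 0


def _t2_from_parts(N, tr_G, tr_GG, quad, rr):
    """Assemble T² from tr(G), tr(GG), r'Gr and ||r||²; None if unidentifiable.

    The residual variance uses the sample divisor N - 1 (the intercept is
    the only fixed effect here), matching :func:`snpherit.score_statistic`
    with its default ``variance_ddof=1``.
    """
    denom = N * tr_GG - tr_G ** 2
    if denom <= DENOM_GUARD * N ** 2:
        return None
    s2 = rr / (N - 1)
    S = quad / s2 - tr_G
    return N * S ** 2 / denom


def _rep_direct(N, M, L, sg2, se2, rng):
    Z = rng.standard_normal((N, M))
    if L is not None:
        Z = L @ Z
    G = Z @ Z.T / M
    if sg2 > 0:
        Lc = np.linalg.cholesky(sg2 * G + se2 * np.eye(N))
        y = Lc @ rng.standard_normal(N)
    else:
        y = np.sqrt(se2) * rng.standard_normal(N)
    r = y - y.mean()
    return _t2_from_parts(N, float(np.trace(G)), float(np.sum(G * G)),
                          float(r @ (G @ r)), float(r @ r))


def _rep_wishart(N, M, L32, sg2, se2, rng):
    """Bartlett draw; L32 is the float32 Cholesky factor of K (None for I)."""
    A = np.zeros((N, N), dtype=np.float32)
    il = np.tril_indices(N, -1)
    A[il] = rng.standard_normal(len(il[0]))
    A[np.diag_indices(N)] = np.sqrt(rng.chisquare(M - np.arange(N)))
    if L32 is None:
        C = A
    else:
        C = sblas.strmm(1.0, L32, A, lower=1)     # L @ A, triangular matmul
    C /= np.float32(np.sqrt(M))
    tr_G = float(np.sum(C.astype(np.float64) ** 2))
    CtC = sblas.ssyrk(1.0, C, trans=1, lower=1)   # lower triangle of C'C
    ltri = np.tril(CtC, -1)
    tr_GG = float(2.0 * np.sum(ltri.astype(np.float64) ** 2)
                  + np.sum(np.diag(CtC).astype(np.float64) ** 2))
    if sg2 > 0:
        y = (np.sqrt(sg2) * (C @ rng.standard_normal(N).astype(np.float32)).astype(np.float64)
             + np.sqrt(se2) * rng.standard_normal(N))
    else:
        y = np.sqrt(se2) * rng.standard_normal(N)
    r = y - y.mean()
    Ctr = C.T.astype(np.float64) @ r
    return _t2_from_parts(N, tr_G, tr_GG, float(Ctr @ Ctr), float(r @ r))


def _rep_spectral(N, M, sg2, se2, rng):
    """K = I: Wishart spectrum + Haar intercept direction, O(N^2)."""
    lam = sample_wishart_eigenvalues(N, M, rng) / M
    q = rng.standard_normal(N)
    q /= np.linalg.norm(q)
    u = np.sqrt(sg2 * lam + se2) * rng.standard_normal(N)
    w = u - (q @ u) * q          # rotated residuals of the intercept fit
    tr_G = float(lam.sum())
    tr_GG = float((lam ** 2).sum())
    return _t2_from_parts(N, tr_G, tr_GG, float((lam * w ** 2).sum()),
                          float(w @ w))


def _resolve_method(method, N, M, K):
    identity = K is None or K.is_identity
    if method != "auto":
        if method == "spectral" and not identity:
            raise ValueError("spectral engine requires K = I")
        if method == "wishart" and M < N:
            raise ValueError("wishart engine needs M >= N (nonsingular)")
        return method
    if identity:
        return "spectral" if M >= 1000 else "direct"
    return "wishart" if (M >= N and M > 2000) else "direct"


def simulate_t2(N: int, M: int, K: KinshipModel | None = None,
                sigma_g2: float = 1.0, sigma_e2: float = 1.0,
                n_reps: int = 2000, method: str = "auto",
                seed: int | None = None) -> tuple[np.ndarray, int]:
    """Simulate ``n_reps`` draws of T² for one (N, M, K) cell.

    ``sigma_g2 = 0`` gives the null.  K (when given) is held fixed across
    replicates; fresh score columns are drawn every replicate.  Returns the
    array of identifiable T² draws and the count of replicates excluded by
    the identifiability guard.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    eng = _resolve_method(method, N, M, K)
    identity = K is None or K.is_identity
    L = None
    if not identity:
        L = K.cholesky()
    L32 = None if L is None else np.asfortranarray(L, dtype=np.float32)
    out = np.empty(n_reps)
    n_ok = 0
    n_excl = 0
    for _ in range(n_reps):
        if eng == "direct":
            t2 = _rep_direct(N, M, L, sigma_g2, sigma_e2, rng)
        elif eng == "wishart":
            t2 = _rep_wishart(N, M, L32, sigma_g2, sigma_e2, rng)
        else:
            t2 = _rep_spectral(N, M, sigma_g2, sigma_e2, rng)
        if t2 is None:
            n_excl += 1
        else:
            out[n_ok] = t2
            n_ok += 1
    return out[:n_ok], n_excl


def null_critical_value(N: int, M: int, K: KinshipModel | None = None,
                        n_reps: int = 3000, alpha: float = 0.05,
                        method: str = "auto", seed: int | None = None,
                        keep_draws: bool = False) -> NullCalibration:
    """Empirical (1 - alpha) quantile of T² under sigma_g² = 0.

    Also tabulates the fraction of null draws above the nominal chi²(1)
    value 3.84 (the empirical type-I error of the uncalibrated test).
    ``alpha = 1`` returns the sample minimum (quantile contract).
    """
    if n_reps < 100:
        raise ValueError("need at least 100 null replicates")
    t2, n_excl = simulate_t2(N, M, K, sigma_g2=0.0, sigma_e2=1.0,
                             n_reps=n_reps, method=method, seed=seed)
    crit = float(np.quantile(t2, 1.0 - alpha))
    return NullCalibration(crit=crit, alpha=alpha,
                           typeI_at_nominal=float(np.mean(t2 > NOMINAL_CRIT)),
                           n_reps=n_reps, n_excluded=n_excl,
                           t2=t2 if keep_draws else None)


def power_cell(N: int, M: int, K: KinshipModel | None = None,
               h2: float = 0.5, n_alt_reps: int = 2000,
               crit: float | NullCalibration | None = None,
               n_null_reps: int = 3000, method: str = "auto",
               seed: int | None = None) -> PowerCell:
    """Mean, SD and power of T² for one cell at heritability ``h2``.

    sigma_e² is fixed at 1 and sigma_g² = h2/(1-h2) (T² is scale
    invariant, so this is without loss of generality; h2 = 0.5 gives
    sigma_g² = sigma_e² = 1).  ``crit`` may be a precomputed empirical
    critical value; otherwise the null calibration is run here with
    ``n_null_reps`` replicates.  The power CI is a 95% Wilson interval.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must be in (0, 1)")
    seed_seq = (seed if isinstance(seed, np.random.SeedSequence)
                else np.random.SeedSequence(seed))
    s_null, s_alt = seed_seq.spawn(2)
    if crit is None:
        crit = null_critical_value(N, M, K, n_reps=n_null_reps, method=method,
                                   seed=s_null)
    if isinstance(crit, NullCalibration):
        calib = crit
    else:
        calib = NullCalibration(crit=float(crit), alpha=0.05,
                                typeI_at_nominal=float("nan"),
                                n_reps=0, n_excluded=0)
    sg2 = h2 / (1.0 - h2)
    t2, n_excl = simulate_t2(N, M, K, sigma_g2=sg2, sigma_e2=1.0,
                             n_reps=n_alt_reps, method=method, seed=s_alt)
    n_ok = len(t2)
    n_reject = int(np.sum(t2 > calib.crit))
    lo, hi = proportion_confint(n_reject, n_ok, alpha=0.05, method="wilson")
    kind = "unrelated" if (K is None or K.is_identity) else K.kind
    return PowerCell(N=N, M=M, kinship_kind=kind,
                     mean_T2=float(t2.mean()), sd_T2=float(t2.std(ddof=1)),
                     crit_empirical=calib.crit, power=n_reject / n_ok,
                     power_ci=(float(lo), float(hi)),
                     typeI_at_nominal=calib.typeI_at_nominal,
                     n_null_reps=calib.n_reps, n_alt_reps=n_ok,
                     seed=seed, n_excluded=n_excl + calib.n_excluded)


def run_table1(grid=None, h2: float = 0.5, n_alt_reps: int = 2000,
               n_null_reps: int = 3000, kinship_low: float = 0.0,
               kinship_high: float = 0.05, method: str = "auto",
               seed: int | None = None, out_tsv: str | None = None,
               progress: bool = False) -> pd.DataFrame:
    """Run a grid of power cells and tabulate the results.

    ``grid`` is a list of (N, M, kind) with kind in {"unrelated",
    "related"}; default is the full 20-cell layout.  One related K per
    sample size N is drawn from the seed and held fixed for all cells and
    replicates at that N.  Returns a DataFrame (and optionally writes TSV)
    with one row per cell.
    """
    grid = list(grid) if grid is not None else list(TABLE1_GRID)
    seed_seq = np.random.SeedSequence(seed)
    k_seeds = {}
    kmodels = {}
    rows = []
    cell_seeds = seed_seq.spawn(len(grid))
    for (N, M, kind), cs in zip(grid, cell_seeds):
        K = None
        if kind == "related":
            if N not in kmodels:
                k_seeds[N] = np.random.SeedSequence([0 if seed is None else seed, N])
                kmodels[N] = make_related_kinship(N, kinship_low, kinship_high,
                                                 k_seeds[N])
            K = kmodels[N]
        cell = power_cell(N, M, K, h2=h2, n_alt_reps=n_alt_reps,
                          n_null_reps=n_null_reps, method=method, seed=cs)
        if progress:
            print(f"N={N} M={M} {kind}: mean={cell.mean_T2:.1f} "
                  f"crit={cell.crit_empirical:.2f} power={cell.power:.3f}")
        rows.append({
            "N": N, "M": M, "kinship": kind, "mean": cell.mean_T2,
            "sd": cell.sd_T2, "crit": cell.crit_empirical,
            "power": cell.power, "ci_lo": cell.power_ci[0],
            "ci_hi": cell.power_ci[1], "typeI_384": cell.typeI_at_nominal,
            "reps_null": cell.n_null_reps, "reps_alt": cell.n_alt_reps,
            "seed": str(seed), "n_degenerate": cell.n_excluded,
        })
    df = pd.DataFrame(rows)
    if out_tsv:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df


def make_related_kinship(N, low, high, seed_seq) -> KinshipModel:
    """Draw the held-fixed 'moderately related' K for a table cell."""
    from .synthetic import make_kinship
    rng_seed = np.random.default_rng(seed_seq).integers(2 ** 31)
    return make_kinship(N, low, high, seed=int(rng_seed))
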