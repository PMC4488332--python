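"""Synthetic genotype and kinship generators.

Everything downstream (GRM construction, REML, the score test, the power
and masking experiments) is exercised on data produced here, so the
generators are written to have *known* statistical structure:

* ``make_kinship`` builds the population relatedness matrix ``K`` — either
  the identity (no relatedness) or a "moderately related" model whose
  off-diagonal entries are iid uniform on a narrow band such as (0, 0.05).
* ``sample_scores`` draws column-standardised genotype scores ``Z`` whose
  columns are iid zero-mean Gaussians with covariance ``K``, the canonical
  completion of "mean 0, variance K".
* ``sample_dosages`` draws discrete 0/1/2 genotypes, optionally with
  block-LD structure from a latent AR(1) Gaussian per haplotype.
* ``sample_grm_wishart`` exploits that with Gaussian columns
  ``M * G ~ Wishart(M, K)``: a Bartlett-factor draw of the GRM whose cost
  does not grow with the number of SNPs.
* ``sample_wishart_eigenvalues`` samples only the GRM spectrum, using the
  bidiagonal beta-ensemble construction; for ``K = I`` this, together with
  orthogonal invariance, supports score-test simulation at a per-replicate
  cost that is quadratic rather than cubic in sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "KinshipModel", "ScoreMatrix", "DosageGenotypeMatrix",
    "make_kinship", "sample_scores", "sample_dosages", "standardize",
    "sample_grm_wishart", "sample_wishart_eigenvalues",
]

#: eigenvalue floor used when repairing an indefinite kinship matrix
PSD_FLOOR = 1e-8


class DegenerateSNPError(ValueError):
    """Raised when a SNP has allele frequency 0 or 1 and cannot be standardised."""


@dataclass
class KinshipModel:
    """A population relatedness matrix K with unit diagonal.

    ``psd_adjusted`` records the magnitude of the eigenvalue clipping that
    was applied to repair an indefinite draw (0.0 when none was needed).
    """

    n: int
    matrix: np.ndarray
    kind: str = "custom"
    psd_adjusted: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.kind == "identity" or np.array_equal(self.matrix, np.eye(self.n))

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor, falling back to an eigenvalue-clipped
        symmetric square root when K is only semi-definite."""
        try:
            return np.linalg.cholesky(self.matrix)
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(self.matrix)
            w = np.clip(w, 0.0, None)
            return v * np.sqrt(w)


@dataclass
class ScoreMatrix:
    """Column-standardised genotype scores Z (samples x SNPs)."""

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("score matrix must be 2-D with at least one column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains non-finite entries")
        if not self.row_ids:
            self.row_ids = [f"S{i+1}" for i in range(self.values.shape[0])]
        if not self.col_ids:
            self.col_ids = [f"snp{j+1}" for j in range(self.values.shape[1])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]


@dataclass
class DosageGenotypeMatrix:
    """Integer 0/1/2 dosages with per-SNP allele frequencies.

    Missing genotypes are encoded as -1 in ``dosages`` and flagged through
    ``missing_mask``.  ``freqs`` holds the allele frequency ``f_k`` of the
    dosage-counted allele for each SNP.
    """

    dosages: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)
    freqs: np.ndarray | None = None
    block_spec: dict | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        valid = np.isin(self.dosages, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        if not self.sample_ids:
            self.sample_ids = [f"S{i+1}" for i in range(self.dosages.shape[0])]
        if not self.snp_ids:
            self.snp_ids = [f"snp{j+1}" for j in range(self.dosages.shape[1])]
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, dtype=float)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def M(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == -1

    def sample_freqs(self) -> np.ndarray:
        """Allele frequencies estimated from the non-missing dosages."""
        d = np.ma.masked_equal(self.dosages, -1)
        return np.asarray(d.mean(axis=0) / 2.0)

    def subset_snps(self, snp_ids) -> "DosageGenotypeMatrix":
        idx = [self.snp_ids.index(s) if isinstance(s, str) else s for s in snp_ids]
        return DosageGenotypeMatrix(
            self.dosages[:, idx],
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            freqs=None if self.freqs is None else self.freqs[idx],
            block_spec=self.block_spec,
        )

    def subset_samples(self, sample_ids) -> "DosageGenotypeMatrix":
        idx = [self.sample_ids.index(s) if isinstance(s, str) else s for s in sample_ids]
        return DosageGenotypeMatrix(
            self.dosages[idx, :],
            sample_ids=[self.sample_ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            freqs=self.freqs,
            block_spec=self.block_spec,
        )


def make_kinship(n: int, low: float = 0.0, high: float = 0.05,
                 seed: int | None = None) -> KinshipModel:
    """Draw a symmetric unit-diagonal kinship matrix with iid uniform
    off-diagonal entries in [low, high].

    ``low == high == 0`` gives the identity.  An indefinite draw (possible
    for large n because uniform noise pushes eigenvalues below zero) is
    repaired by clipping eigenvalues at ``PSD_FLOOR`` and rescaling the
    diagonal back to one; the applied adjustment magnitude is recorded.
    """
    if n < 2:
        raise ValueError("kinship model needs at least n=2 individuals")
    if not (0.0 <= low <= high < 1.0):
        raise ValueError("need 0 <= low <= high < 1")
    rng = np.random.default_rng(seed)
    K = np.eye(n)
    if high > 0.0:
        iu = np.triu_indices(n, 1)
        offs = rng.uniform(low, high, size=len(iu[0]))
        K[iu] = offs
        K.T[iu] = offs
    kind = "identity" if high == 0.0 and low == 0.0 else "uniform_related"
    adjustment = 0.0
    if high > 0.0:
        w = np.linalg.eigvalsh(K)
        if w[0] < PSD_FLOOR:
            w_full, v = np.linalg.eigh(K)
            adjustment = float(PSD_FLOOR - w_full[0])
            w_clip = np.clip(w_full, PSD_FLOOR, None)
            K = (v * w_clip) @ v.T
            d = np.sqrt(np.diag(K))
            K = K / np.outer(d, d)
            np.fill_diagonal(K, 1.0)
            K = (K + K.T) / 2.0
    return KinshipModel(n=n, matrix=K, kind=kind, psd_adjusted=adjustment)


def sample_scores(n: int, M: int, K: KinshipModel,
                  seed: int | None = None) -> ScoreMatrix:
    """Draw Z with independent columns ~ N(0, K).

    Column ``j`` is reproducible from ``(seed, j)`` alone: the same column
    appears at the same position regardless of the total number of columns
    requested.
    """
    if K.n != n:
        raise ValueError(f"kinship is {K.n}x{K.n}, requested n={n}")
    w_min = np.linalg.eigvalsh(K.matrix)[0] if not K.is_identity else 1.0
    if w_min < -1e-10:
        raise ValueError("kinship matrix is indefinite; repair it first")
    L = None if K.is_identity else K.cholesky()
    cols = np.empty((n, M))
    for j in range(M):
        col_rng = np.random.default_rng(None if seed is None else [seed, j])
        g = col_rng.standard_normal(n)
        cols[:, j] = g if L is None else L @ g
    return ScoreMatrix(cols)


def sample_dosages(n: int, M: int, maf_low: float = 0.01, maf_high: float = 0.5,
                   block_len: int = 1, rho: float = 0.0,
                   seed: int | None = None) -> DosageGenotypeMatrix:
    """Draw discrete 0/1/2 genotypes, optionally with block-LD structure.

    Per SNP the allele frequency is uniform on [maf_low, maf_high].  With
    ``block_len == 1`` dosages are independent Binomial(2, f).  Otherwise
    each haplotype carries a latent AR(1)(rho) Gaussian within blocks of
    ``block_len`` SNPs; thresholding at the f-quantile produces alleles, so
    adjacent SNPs within a block are in LD while blocks are independent.
    """
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if not (0.0 <= rho < 1.0):
        raise ValueError("need 0 <= rho < 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, size=M)
    if block_len <= 1 or rho == 0.0:
        dos = rng.binomial(2, freqs[None, :], size=(n, M)).astype(np.int8)
        spec = None
    else:
        # two haplotypes per person; latent AR(1) chain restarted per block
        z = rng.standard_normal((2 * n, M))
        scale = np.sqrt(1.0 - rho ** 2)
        for j in range(1, M):
            if j % block_len != 0:
                z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
        from scipy.stats import norm
        thresh = norm.ppf(freqs)
        alleles = (z < thresh[None, :]).astype(np.int8)
        dos = alleles[:n] + alleles[n:]
        spec = {"block_len": block_len, "rho": rho}
    return DosageGenotypeMatrix(dos, freqs=freqs, block_spec=spec)


def standardize(g: DosageGenotypeMatrix, freq_mode: str = "sample") -> ScoreMatrix:
    """Centre and scale dosages to genotype scores.

    Entry (i, k) becomes ``(dosage_ik - 2 f_k) / sqrt(2 f_k (1 - f_k))``;
    missing dosages are imputed to ``2 f_k`` (score zero).  ``freq_mode``
    selects sample-estimated or supplied allele frequencies.
    """
    if freq_mode == "sample":
        f = g.sample_freqs()
    elif freq_mode == "supplied":
        if g.freqs is None:
            raise ValueError("no supplied frequencies on this genotype matrix")
        f = g.freqs
    else:
        raise ValueError("freq_mode must be 'sample' or 'supplied'")
    bad = (f <= 0.0) | (f >= 1.0)
    if bad.any():
        names = [g.snp_ids[j] for j in np.flatnonzero(bad)[:10]]
        raise DegenerateSNPError(
            f"SNP(s) with allele frequency 0 or 1 cannot be standardised: {names}")
    d = g.dosages.astype(float)
    d[g.missing_mask] = np.take(2.0 * f, np.where(g.missing_mask)[1])
    Z = (d - 2.0 * f[None, :]) / np.sqrt(2.0 * f * (1.0 - f))[None, :]
    return ScoreMatrix(Z, row_ids=list(g.sample_ids), col_ids=list(g.snp_ids))


def _bartlett_factor(n: int, M: int, rng: np.random.Generator) -> np.ndarray:
    """Lower-triangular A with A A' ~ Wishart(M, I_n); requires M >= n."""
    A = np.zeros((n, n))
    il = np.tril_indices(n, -1)
    A[il] = rng.standard_normal(len(il[0]))
    A[np.diag_indices(n)] = np.sqrt(rng.chisquare(M - np.arange(n)))
    return A


def sample_grm_wishart(n: int, M: int, K: KinshipModel, seed: int | None = None):
    """Draw a GRM G = ZZ'/M directly as (1/M) Wishart(M, K).

    With Gaussian score columns the product ZZ' is Wishart distributed, so
    the Bartlett construction delivers a draw of G whose cost is independent
    of M.  Requires ``M >= n`` (nonsingular case).
    """
    from .grm import GRM
    if M < 1:
        raise ValueError("M must be >= 1")
    if M < n:
        raise ValueError("Bartlett sampling needs M >= n; use sample_scores + build_grm")
    rng = np.random.default_rng(seed)
    A = _bartlett_factor(n, M, rng)
    L = None if K.is_identity else K.cholesky()
    C = A if L is None else L @ A
    G = (C @ C.T) / M
    G = (G + G.T) / 2.0
    return GRM(matrix=G, sample_ids=[f"S{i+1}" for i in range(n)], n_snps=M)


def sample_wishart_eigenvalues(n: int, M: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Sample the eigenvalues of a Wishart(M, I_n) matrix in O(n^2).

    Uses the bidiagonal beta-ensemble construction (beta = 1): B is lower
    bidiagonal with diagonal chi_{d}, chi_{d-1}, ..., chi_{d-p+1} and
    subdiagonal chi_{p-1}, ..., chi_1 where p = min(n, M), d = max(n, M);
    the squared singular values of B follow the Wishart eigenvalue law.
    For M < n the spectrum is padded with the n - M structural zeros.
    Returned ascending.
    """
    p, d = min(n, M), max(n, M)
    diag = np.sqrt(rng.chisquare(d - np.arange(p)))
    if p > 1:
        off = np.sqrt(rng.chisquare(p - 1 - np.arange(p - 1)))
        t_diag = diag ** 2
        t_diag[1:] += off ** 2
        t_off = off * diag[:-1]
        w = scipy.linalg.eigvalsh_tridiagonal(t_diag, t_off)
    else:
        w = diag ** 2
    w = np.clip(w, 0.0, None)
    if n > M:
        w = np.concatenate([np.zeros(n - M), w])
    return w
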