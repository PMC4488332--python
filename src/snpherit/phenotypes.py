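"""Phenotype simulators.

Two generative models:

* :func:`simulate_mvn_phenotype` — the variance-model view: draw
  ``y ~ N(0, sigma_g^2 G + sigma_e^2 I)`` given a realised GRM.  This is
  the model under which the score test's power is studied.
* :func:`simulate_polygenic_phenotype` — the finite-causal view: per-SNP
  effects ``u ~ N(0, 1)`` on a set of causal standardised genotypes, plus
  iid residuals scaled so that the realised heritability matches a target
  ``h²``.  The residual variance uses the *realised* variance of the
  polygenic score g, which makes the realised Var(g)/Var(y) unbiased for
  the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import GRM
from .synthetic import ScoreMatrix

__all__ = ["PhenotypeSet", "simulate_mvn_phenotype", "simulate_polygenic_phenotype"]


@dataclass
class PhenotypeSet:
    """Outcome vector plus fixed-effect design (intercept always included)."""

    y: np.ndarray
    X: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("missing or non-finite phenotype values")
        if not self.sample_ids:
            self.sample_ids = [f"S{i+1}" for i in range(len(self.y))]

    @property
    def n(self) -> int:
        return len(self.y)


def _with_covariates(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        X = np.hstack([X, covariates])
    return X


def simulate_mvn_phenotype(G: GRM, sigma_g2: float, sigma_e2: float,
                           seed: int | None = None,
                           covariates: np.ndarray | None = None,
                           coefficients: np.ndarray | None = None) -> PhenotypeSet:
    """Draw y ~ N(Xa, sigma_g2 * G + sigma_e2 * I).

    The genetic part uses a symmetric factorisation of G; with
    ``sigma_e2 > 0`` the total covariance is positive definite for any PSD
    G.  ``covariates``/``coefficients`` optionally add fixed effects; the
    default design is intercept-only (with zero mean).
    """
    if sigma_g2 < 0 or sigma_e2 <= 0:
        raise ValueError("need sigma_g2 >= 0 and sigma_e2 > 0")
    rng = np.random.default_rng(seed)
    n = G.n
    y = np.sqrt(sigma_e2) * rng.standard_normal(n)
    if sigma_g2 > 0:
        w, v = np.linalg.eigh(G.matrix)
        w = np.clip(w, 0.0, None)
        y += np.sqrt(sigma_g2) * (v @ (np.sqrt(w) * rng.standard_normal(n)))
    X = _with_covariates(n, covariates)
    if coefficients is not None:
        y += X @ np.asarray(coefficients, dtype=float)
    return PhenotypeSet(y=y, X=X, sample_ids=list(G.sample_ids))


def simulate_polygenic_phenotype(Z_causal: ScoreMatrix, h2: float,
                                 seed: int | None = None,
                                 covariates: np.ndarray | None = None,
                                 coefficients: np.ndarray | None = None) -> PhenotypeSet:
    """Finite-causal polygenic trait at target heritability h².

    Effects u ~ N(0, 1) per causal SNP give the polygenic score
    g = Z_causal u; residuals are iid N(0, Var(g) (1 - h²) / h²) with
    Var(g) the realised sample variance of g, so the realised heritability
    is centred on the target.  ``h2 = 1`` returns y = g exactly.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must be in (0, 1]; residual variance undefined at 0")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(Z_causal.M)
    g = Z_causal.values @ u
    var_g = float(np.var(g))
    if h2 < 1.0:
        e = rng.normal(0.0, np.sqrt(var_g * (1.0 - h2) / h2), size=Z_causal.n)
    else:
        e = np.zeros(Z_causal.n)
    y = g + e
    X = _with_covariates(Z_causal.n, covariates)
    if coefficients is not None:
        y += X @ np.asarray(coefficients, dtype=float)
    return PhenotypeSet(y=y, X=X, sample_ids=list(Z_causal.row_ids))
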