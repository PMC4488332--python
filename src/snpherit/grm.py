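"""Genetic relationship matrix: construction, GCTA-format I/O, relatedness
pruning, LD pruning and principal components.

The GRM is ``G = Z Z' / M`` for column-standardised scores Z; its
off-diagonal ``G_ij`` estimates the relationship coefficient (twice the
kinship coefficient) between individuals i and j, and is used directly for
relatedness pruning.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import DosageGenotypeMatrix, ScoreMatrix

__all__ = [
    "GRM", "PrincipalComponents", "build_grm", "write_grm", "read_grm",
    "prune_related", "ld_prune", "principal_components", "GRMFormatError",
]


class GRMFormatError(ValueError):
    """Malformed GCTA-dialect GRM file."""


@dataclass
class GRM:
    """Symmetric n x n genetic relationship matrix with sample IDs."""

    matrix: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    n_snps: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not self.sample_ids:
            self.sample_ids = [f"S{i+1}" for i in range(self.matrix.shape[0])]
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError("sample_ids length does not match matrix")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PrincipalComponents:
    """Leading eigenvectors of a GRM, eigenvalues sorted descending."""

    vectors: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: list[str] = field(default_factory=list)


def build_grm(Z: ScoreMatrix) -> GRM:
    """G = Z Z' / M, symmetrised after the product."""
    if Z.M < 1:
        raise ValueError("empty score matrix")
    G = Z.values @ Z.values.T / Z.M
    G = (G + G.T) / 2.0
    return GRM(matrix=G, sample_ids=list(Z.row_ids), n_snps=Z.M)


def write_grm(grm: GRM, prefix: str) -> None:
    """Write the GCTA text dialect: ``prefix.grm.id`` (FID IID) and
    ``prefix.grm.gz`` with lower-triangle triplet lines
    ``i<TAB>j<TAB>n_snps<TAB>value`` (1-based, j <= i)."""
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")
    m = grm.n_snps if grm.n_snps else 1
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i+1}\t{j+1}\t{m}\t{grm.matrix[i, j]:.6g}\n")


def read_grm(prefix: str) -> GRM:
    """Read the GCTA text dialect written by :func:`write_grm`."""
    ids = []
    with open(f"{prefix}.grm.id") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise GRMFormatError(f"{prefix}.grm.id line {lineno}: need FID and IID")
            ids.append(parts[1])
    n = len(ids)
    G = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    n_snps = 0
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise GRMFormatError(f"{prefix}.grm.gz line {lineno}: expected 4 fields")
            i, j = int(parts[0]), int(parts[1])
            if not (1 <= i <= n and 1 <= j <= n):
                raise GRMFormatError(
                    f"{prefix}.grm.gz line {lineno}: index ({i},{j}) out of range for {n} samples")
            if j > i:
                raise GRMFormatError(
                    f"{prefix}.grm.gz line {lineno}: upper-triangle entry j={j} > i={i}")
            n_snps = int(parts[2])
            G[i - 1, j - 1] = G[j - 1, i - 1] = float(parts[3])
            seen[i - 1, j - 1] = True
    il = np.tril_indices(n)
    if not seen[il].all():
        raise GRMFormatError(f"{prefix}.grm.gz: missing lower-triangle entries")
    return GRM(matrix=G, sample_ids=ids, n_snps=n_snps)


def prune_related(grm: GRM, threshold: float = 0.025) -> list[str]:
    """Greedily remove individuals until no pair has G_ij above threshold.

    While any off-diagonal exceeds the threshold the individual involved in
    the largest number of above-threshold pairs is removed (ties broken by
    removing the smaller file-order index).  Returns the kept sample IDs in
    file order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = grm.n
    adj = grm.matrix > threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    deg = adj.sum(axis=1).astype(int)
    while True:
        if not (deg[alive] > 0).any():
            break
        deg_masked = np.where(alive, deg, -1)
        worst = int(np.argmax(deg_masked))  # argmax takes the first max -> smaller index
        alive[worst] = False
        deg[adj[worst]] -= 1
        deg[worst] = 0
    return [grm.sample_ids[i] for i in range(n) if alive[i]]


def ld_prune(g: DosageGenotypeMatrix, window: int = 50,
             r2_max: float = 0.25) -> list[str]:
    """Greedy pairwise-r² LD pruning in sliding windows.

    Windows of ``window`` SNPs step by ``window // 2``.  Within each window,
    while any kept pair has r² >= ``r2_max``, the member of the worst pair
    with the larger summed r² to the other kept SNPs is dropped (tie: the
    later SNP).  Monomorphic SNPs are dropped first with a warning.
    Deterministic given input order.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    X = g.dosages.astype(float)
    X[g.missing_mask] = np.nan
    sd = np.nanstd(X, axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(f"dropping {int(mono.sum())} monomorphic SNP(s) before LD pruning")
    keep = ~mono
    step = max(1, window // 2)
    M = g.M
    for start in range(0, M, step):
        idx = [j for j in range(start, min(start + window, M)) if keep[j]]
        if len(idx) < 2:
            if start + window >= M:
                break
            continue
        sub = X[:, idx]
        col_mean = np.nanmean(sub, axis=0)
        filled = np.where(np.isnan(sub), col_mean, sub)
        r2 = np.corrcoef(filled, rowvar=False) ** 2
        np.fill_diagonal(r2, 0.0)
        active = list(range(len(idx)))
        while True:
            sub_r2 = r2[np.ix_(active, active)]
            if sub_r2.size == 0 or sub_r2.max() < r2_max:
                break
            a, b = np.unravel_index(np.argmax(sub_r2), sub_r2.shape)
            load_a = sub_r2[a].sum()
            load_b = sub_r2[b].sum()
            drop_local = b if load_b >= load_a else a
            dropped = active.pop(drop_local)
            keep[idx[dropped]] = False
        if start + window >= M:
            break
    return [g.snp_ids[j] for j in range(M) if keep[j]]


def principal_components(grm: GRM, k: int = 10) -> PrincipalComponents:
    """Top-k eigenvectors of G, eigenvalues nonincreasing; each vector's
    sign is fixed so its largest-magnitude entry is positive."""
    if k >= grm.n:
        raise ValueError("k must be smaller than the number of samples")
    w, v = np.linalg.eigh(grm.matrix)
    order = np.argsort(w)[::-1][:k]
    vals = w[order]
    vecs = v[:, order]
    for j in range(k):
        i_max = np.argmax(np.abs(vecs[:, j]))
        if vecs[i_max, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PrincipalComponents(vectors=vecs, eigenvalues=vals,
                               sample_ids=list(grm.sample_ids))
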