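"""Text-format I/O: PLINK .raw-style dosages, phenotype/covariate TSVs and
YAML experiment configs.  Gzip is handled transparently by extension."""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .synthetic import DosageGenotypeMatrix
from .phenotypes import PhenotypeSet

__all__ = [
    "write_raw", "read_raw", "write_dosage_tsv", "write_phenotype_tsv",
    "read_phenotype_tsv", "write_covariates_tsv", "read_covariates_tsv",
    "write_pcs_tsv", "SimulationConfig", "load_config",
]

RAW_FIXED_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _open(path, mode):
    return gzip.open(path, mode + "t") if str(path).endswith(".gz") else open(path, mode)


def write_raw(g: DosageGenotypeMatrix, path, phenotype=None) -> None:
    """PLINK .raw additive dosage dialect: header FID IID PAT MAT SEX
    PHENOTYPE SNP1 ... SNPM, one row per sample, missing dosage as NA."""
    pheno = ["-9"] * g.n if phenotype is None else [f"{v:g}" for v in phenotype]
    with _open(path, "w") as fh:
        fh.write(" ".join(RAW_FIXED_COLS + list(g.snp_ids)) + "\n")
        for i, sid in enumerate(g.sample_ids):
            row = [sid, sid, "0", "0", "0", pheno[i]]
            row += ["NA" if d == -1 else str(int(d)) for d in g.dosages[i]]
            fh.write(" ".join(row) + "\n")


def read_raw(path) -> DosageGenotypeMatrix:
    with _open(path, "r") as fh:
        header = fh.readline().split()
        if header[: len(RAW_FIXED_COLS)] != RAW_FIXED_COLS:
            raise ValueError(f"{path}: not a .raw header (expected {RAW_FIXED_COLS})")
        snp_ids = header[len(RAW_FIXED_COLS):]
        sample_ids, rows = [], []
        for lineno, line in enumerate(fh, 2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                raise ValueError(f"{path} line {lineno}: field count mismatch")
            sample_ids.append(parts[1])
            rows.append([-1 if v == "NA" else int(v) for v in parts[6:]])
    return DosageGenotypeMatrix(np.array(rows, dtype=np.int8),
                                sample_ids=sample_ids, snp_ids=snp_ids)


def write_dosage_tsv(g: DosageGenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.snp_ids)
    df.replace(-1, pd.NA).to_csv(path, sep="\t", index_label="IID")


def write_phenotype_tsv(p: PhenotypeSet, path) -> None:
    """FID IID y, tab separated, no header (mixed-model tool convention)."""
    with _open(path, "w") as fh:
        for sid, v in zip(p.sample_ids, p.y):
            fh.write(f"{sid}\t{sid}\t{v:.10g}\n")


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["FID", "IID", "y"])
    return df


def write_covariates_tsv(sample_ids, covariates, path, names=None) -> None:
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != len(sample_ids):
        covariates = covariates.T
    names = names or [f"cov{i+1}" for i in range(covariates.shape[1])]
    df = pd.DataFrame(covariates, columns=names)
    df.insert(0, "IID", list(sample_ids))
    df.insert(0, "FID", list(sample_ids))
    df.to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pcs_tsv(pcs, path) -> None:
    names = [f"PC{i+1}" for i in range(pcs.vectors.shape[1])]
    write_covariates_tsv(pcs.sample_ids, pcs.vectors, path, names=names)


@dataclass
class SimulationConfig:
    """YAML-backed description of a synthetic cohort."""

    n: int = 1000
    M: int = 5000
    kinship_kind: str = "identity"
    kinship_low: float = 0.0
    kinship_high: float = 0.0
    maf_low: float = 0.01
    maf_high: float = 0.5
    block_len: int = 1
    rho: float = 0.0
    seed: int = 0


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kin = raw.get("kinship", {})
    maf = raw.get("maf", {})
    ld = raw.get("ld", {})
    return SimulationConfig(
        n=int(raw.get("n", 1000)), M=int(raw.get("M", 5000)),
        kinship_kind=str(kin.get("kind", "identity")),
        kinship_low=float(kin.get("low", 0.0)),
        kinship_high=float(kin.get("high", 0.0)),
        maf_low=float(maf.get("low", 0.01)), maf_high=float(maf.get("high", 0.5)),
        block_len=int(ld.get("block_len", 1)), rho=float(ld.get("rho", 0.0)),
        seed=int(raw.get("seed", 0)),
    )
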