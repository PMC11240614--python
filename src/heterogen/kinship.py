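"""Additive and dominance genomic relationship matrices.

VanRaden-style method-1 construction from the centered design pair:

    Ga = Z Z' / sum_j 2 p_j (1 - p_j)
    Gd = W W' / sum_j [2 p_j (1 - p_j)]^2

Centering lives in the design matrices; the denominators absorb the scale,
so the columns are deliberately NOT variance-standardized (doing both would
double-normalize).  The stored matrix is exactly the formula — any ridge
needed for solving is added inside downstream solvers, never here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genotype_io import DesignPair


@dataclass
class GRM:
    """A symmetric n x n genomic relationship matrix."""

    values: np.ndarray
    kind: Literal["additive", "dominance"]
    samples: list[str]
    denominator: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if v.shape[0] != len(self.samples):
            raise ValueError("GRM dimension does not match sample count")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def additive_grm(designs: DesignPair) -> GRM:
    """Ga = ZZ' over the summed expected heterozygosity."""
    denom = float(designs.het_weights().sum())
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: additive GRM denominator is zero")
    values = (designs.Z @ designs.Z.T) / denom
    return GRM(values=values, kind="additive", samples=list(designs.samples), denominator=denom)


def dominance_grm(designs: DesignPair) -> GRM:
    """Gd = WW' over the sum of squared expected heterozygosities."""
    denom = float((designs.het_weights() ** 2).sum())
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: dominance GRM denominator is zero")
    if not np.any(designs.W):
        warnings.warn("W is all zeros (no heterozygotes); dominance GRM is zero")
    values = (designs.W @ designs.W.T) / denom
    return GRM(values=values, kind="dominance", samples=list(designs.samples), denominator=denom)


# ---------------------------------------------------------------------------
# I/O: GCTA binary triple and plain TSV
# ---------------------------------------------------------------------------


def write_grm_gcta(grm: GRM, prefix: str | Path) -> None:
    """Write <prefix>.grm.bin (float32 lower triangle, row-major) + .grm.id."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n
    tri = grm.values[np.tril_indices(n)].astype(np.float32)
    tri.tofile(str(prefix) + ".grm.bin")
    pd.DataFrame({"fid": grm.samples, "iid": grm.samples}).to_csv(
        str(prefix) + ".grm.id", sep="\t", header=False, index=False
    )


def read_grm_gcta(prefix: str | Path, kind: Literal["additive", "dominance"] = "additive") -> GRM:
    prefix = Path(prefix)
    ids = pd.read_csv(str(prefix) + ".grm.id", sep="\t", header=None, dtype=str)
    samples = ids[1].tolist()
    n = len(samples)
    tri = np.fromfile(str(prefix) + ".grm.bin", dtype=np.float32)
    if tri.size != n * (n + 1) // 2:
        raise ValueError(
            f"{prefix}.grm.bin holds {tri.size} values, expected {n*(n+1)//2} for n={n}"
        )
    values = np.zeros((n, n))
    il = np.tril_indices(n)
    values[il] = tri
    values.T[il] = tri
    return GRM(values=values, kind=kind, samples=samples, denominator=np.nan)


def write_grm_tsv(grm: GRM, path: str | Path) -> None:
    pd.DataFrame(grm.values, index=grm.samples, columns=grm.samples).to_csv(path, sep="\t")


def read_grm_tsv(path: str | Path, kind: Literal["additive", "dominance"] = "additive") -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GRM(
        values=df.to_numpy(dtype=np.float64),
        kind=kind,
        samples=[str(s) for s in df.index],
        denominator=np.nan,
    )
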