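"""Signed LD correlation matrices over a named variant set.

The matrix stores the signed correlation r between variant dosages; it is the
r_ij entering the variance-covariance matrix of the LD-aware IVW estimator and
the r^2 used for clumping and proxy lookup.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["LDMatrix", "make_ar1_ld"]


class LDMatrix:
    """Square signed-correlation matrix aligned to an ordered variant-id list.

    Parameters
    ----------
    variant_ids
        Ordered variant identifiers; must be unique.
    r
        Square array of signed correlations, symmetric with unit diagonal.
    validate
        When true (default) the structural invariants are checked:
        symmetry, unit diagonal, |r| <= 1 and positive semi-definiteness
        up to a small numerical tolerance.
    """

    def __init__(self, variant_ids: Sequence[str], r: np.ndarray, validate: bool = True):
        ids = [str(v) for v in variant_ids]
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(ids) != r.shape[0]:
            raise ValueError(
                f"{len(ids)} variant ids for a {r.shape[0]}x{r.shape[1]} matrix"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in LD matrix")
        if validate:
            if not np.allclose(r, r.T, atol=1e-8):
                raise ValueError("LD matrix is not symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-6):
                raise ValueError("LD matrix diagonal is not 1")
            if np.any(np.abs(r) > 1 + 1e-8):
                raise ValueError("|r| > 1 entry in LD matrix")
            w = np.linalg.eigvalsh((r + r.T) / 2.0)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValueError("LD matrix is not positive semi-definite")
        self.variant_ids = ids
        self.r = (r + r.T) / 2.0
        self._index = {v: i for i, v in enumerate(ids)}

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in LD matrix") from None

    def submatrix(self, ids: Sequence[str]) -> "LDMatrix":
        """Restriction to ``ids`` in the given order."""
        idx = [self.index_of(v) for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)], validate=False)

    def r_between(self, a: str, b: str) -> float:
        """Signed correlation between two variants."""
        return float(self.r[self.index_of(a), self.index_of(b)])

    def r2_between(self, a: str, b: str) -> float:
        """Squared correlation (the clumping / proxy-lookup r^2)."""
        return self.r_between(a, b) ** 2

    # -- I/O ------------------------------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        """Write as a tab-delimited matrix with a variant-id header and index."""
        df = pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids)
        df.to_csv(path, sep="\t", index_label="id", float_format="%.10g")

    @classmethod
    def from_file(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def __repr__(self) -> str:  # pragma: no cover
        return f"LDMatrix({len(self)} variants)"


def make_ar1_ld(n_snps: int, rho: float, prefix: str = "snp") -> LDMatrix:
    """AR(1) LD structure: r_ij = rho^|i-j|.

    A first-order autoregressive correlation along the chromosome is the
    standard stand-in for a local LD block when no reference panel is
    available; it is positive definite for any rho in [0, 1).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1); got {rho}")
    lag = np.abs(np.subtract.outer(np.arange(n_snps), np.arange(n_snps)))
    r = rho ** lag if rho > 0 else np.eye(n_snps)
    ids = [f"{prefix}_{i + 1}" for i in range(n_snps)]
    return LDMatrix(ids, np.asarray(r, dtype=float), validate=False)
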