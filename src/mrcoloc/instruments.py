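"""Instrument selection and quality control.

The selection chain mirrors standard summary-data MR practice: keep
genome-wide-significant exposure associations, thin them to quasi-independent
index SNPs by greedy LD clumping, drop weak instruments by the F-statistic
rule (F < 10), and bundle the survivors with their LD submatrix, enforcing a
minimum instrument count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ld import LDMatrix
from .sumstats import HarmonizedPair

logger = logging.getLogger("mrcoloc")

__all__ = [
    "InstrumentSet",
    "gw_filter",
    "clump",
    "strength_filter",
    "assemble_instruments",
    "EmptySelectionError",
    "InsufficientInstrumentsError",
]


class EmptySelectionError(ValueError):
    """No variant survived a selection step."""


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the configured minimum."""

    def __init__(self, count: int, minimum: int, context: str = ""):
        self.count = count
        self.minimum = minimum
        msg = f"{count} instrument(s) remain; minimum is {minimum}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class LDCoverageError(KeyError):
    """A variant required for clumping is absent from the LD matrix."""


@dataclass
class InstrumentSet:
    """Quality-filtered instruments with their aligned LD submatrix.

    ``records`` rows carry the harmonized effects plus ``r2_explained`` and
    ``f_stat``; ``ld.variant_ids`` matches ``records['snp']`` in order.
    ``snp_out`` / ``snp_index`` are the counts before and after clumping.
    """

    records: "object"  # pandas DataFrame
    ld: LDMatrix
    snp_out: int
    snp_index: int
    exposure_trait: str = "exposure"
    outcome_trait: str = "outcome"

    def __post_init__(self) -> None:
        if list(self.records["snp"]) != list(self.ld.variant_ids):
            raise ValueError("LD submatrix order does not match instrument records")
        if self.snp_index > self.snp_out:
            raise ValueError("snp_index cannot exceed snp_out")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, keep_mask: np.ndarray) -> "InstrumentSet":
        recs = self.records.loc[keep_mask].reset_index(drop=True)
        return InstrumentSet(recs, self.ld.submatrix(list(recs["snp"])),
                             self.snp_out, self.snp_index,
                             self.exposure_trait, self.outcome_trait)


def gw_filter(pair: HarmonizedPair, p_threshold: float = 5e-8) -> HarmonizedPair:
    """Retain variants genome-wide significant for the exposure (p_zx < threshold)."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    keep = pair.df["p_zx"] < p_threshold
    if not keep.any():
        raise EmptySelectionError(
            f"no variant passes exposure significance p < {p_threshold:g}")
    out = HarmonizedPair(pair.exposure_trait, pair.outcome_trait,
                         pair.df.loc[keep].reset_index(drop=True))
    out.snp_out = int(keep.sum())
    logger.info("gw_filter: %d/%d variants at p < %g", out.snp_out, len(pair), p_threshold)
    return out


def clump(
    pair: HarmonizedPair,
    ld: LDMatrix,
    r2_threshold: float = 0.05,
    window_bp: int = 1_000_000,
) -> HarmonizedPair:
    """Greedy LD clumping to quasi-independent index SNPs.

    Repeatedly promote the unremoved variant with the smallest exposure
    p-value (ties broken by position, then id) to index SNP, and remove every
    unremoved variant within ``window_bp`` of it on the same chromosome whose
    r^2 with it exceeds ``r2_threshold``.  Cross-chromosome r^2 is defined as
    zero.  The result is the index set in position order.
    """
    df = pair.df
    missing = [s for s in df["snp"] if s not in ld]
    if missing:
        raise LDCoverageError(f"variant(s) absent from LD matrix: {missing[:5]}")

    order = df.sort_values(["p_zx", "pos", "snp"], kind="mergesort").index
    removed = set()
    index_snps = []
    chrom = df["chrom"].to_dict()
    pos = df["pos"].to_dict()
    for i in order:
        if i in removed:
            continue
        index_snps.append(i)
        near = df.index[
            (df["chrom"] == chrom[i])
            & (abs(df["pos"] - pos[i]) <= window_bp)
            & (df.index != i)
        ]
        for j in near:
            if j in removed:
                continue
            if ld.r2_between(df.at[i, "snp"], df.at[j, "snp"]) > r2_threshold:
                removed.add(j)

    out_df = df.loc[sorted(index_snps)].sort_values(
        ["chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    out = HarmonizedPair(pair.exposure_trait, pair.outcome_trait, out_df)
    out.snp_out = pair.snp_out if pair.snp_out is not None else len(pair)
    out.snp_index = len(out_df)
    logger.info("clump: %d index SNP(s) from %d (r2 > %g within %d bp)",
                out.snp_index, len(df), r2_threshold, window_bp)
    return out


def strength_filter(
    pair: HarmonizedPair,
    f_min: float = 10.0,
    method: str = "zstat",
    var_y: float = 1.0,
) -> HarmonizedPair:
    """Annotate per-variant R^2 and F and drop weak instruments (F < f_min).

    The default ``zstat`` method needs no allele frequency:
    R^2 = z^2 / (z^2 + n - 2) and F = (n - 2) R^2 / (1 - R^2), which reduces
    algebraically to F = z^2.  The ``eaf`` alternative uses
    R^2 = 2 p (1 - p) beta^2 / var_y for users with a known phenotype
    variance.  The exclusion is strict: F exactly equal to ``f_min`` is kept.
    """
    df = pair.df.copy()
    n = df["n_x"].to_numpy(dtype=float)
    if np.any(n < 3):
        raise ValueError("strength_filter requires n_x >= 3 per variant")
    if method == "zstat":
        z2 = (df["bzx"] / df["se_zx"]) ** 2
        r2 = z2 / (z2 + n - 2)
    elif method == "eaf":
        r2 = 2.0 * df["freq"] * (1.0 - df["freq"]) * df["bzx"] ** 2 / var_y
    else:
        raise ValueError(f"unknown R^2 method {method!r}")
    f = (n - 2) * r2 / (1.0 - r2)
    df["r2_explained"] = r2
    df["f_stat"] = f
    keep = df["f_stat"] >= f_min
    if (~keep).any():
        logger.info("strength_filter: removed %d weak instrument(s) with F < %g",
                    int((~keep).sum()), f_min)
    out = HarmonizedPair(pair.exposure_trait, pair.outcome_trait,
                         df.loc[keep].reset_index(drop=True))
    out.snp_out = pair.snp_out
    out.snp_index = pair.snp_index
    return out


def assemble_instruments(
    pair: HarmonizedPair,
    ld: LDMatrix,
    min_instruments: int = 10,
) -> InstrumentSet:
    """Bundle a filtered, clumped pair with its LD submatrix.

    Fails with :class:`InsufficientInstrumentsError` when fewer than
    ``min_instruments`` variants remain (the minimum-ten-variants rule by
    default).
    """
    df = pair.df.reset_index(drop=True)
    if len(df) < min_instruments:
        raise InsufficientInstrumentsError(len(df), min_instruments,
                                           context=pair.outcome_trait)
    if "f_stat" not in df.columns:
        df = strength_filter(pair, f_min=0.0).df
    sub = ld.submatrix(list(df["snp"]))
    return InstrumentSet(
        records=df, ld=sub,
        snp_out=pair.snp_out if pair.snp_out is not None else len(df),
        snp_index=pair.snp_index if pair.snp_index is not None else len(df),
        exposure_trait=pair.exposure_trait, outcome_trait=pair.outcome_trait)
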