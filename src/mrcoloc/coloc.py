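"""Bayesian colocalization of two traits over instrument-anchored windows.

Per-SNP evidence is the Wakefield approximate Bayes factor computed from the
marginal (beta, SE) under a N(0, W) effect-size prior:

    log ABF = 1/2 [ log(1 - r) + r z^2 ],   r = W / (W + se^2),  z = beta/se.

Assuming at most one causal variant per trait in the region, the five
hypotheses — no association (H0), trait-1 only (H1), trait-2 only (H2), both
traits with distinct causal variants (H3), both traits sharing one causal
variant (H4) — have unnormalized log posterior weights formed from the
per-SNP log ABFs L1, L2 and per-SNP priors p1, p2, p12; the posterior
probabilities are their softmax.  PP.H4 > 0.9 is the conventional "strong
colocalization" annotation; it is never used as a hard filter here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import SumStatsTable

logger = logging.getLogger("mrcoloc")

__all__ = [
    "ColocPriors",
    "Region",
    "ColocModel",
    "ColocResults",
    "build_regions",
    "log_abf",
    "coloc_pp",
    "coloc_sensitivity",
]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities and the ABF effect-size prior variance.

    Defaults are the conventional quantitative-trait values: p1 = p2 = 1e-4
    (associated with one trait), p12 = 1e-5 (associated with both) and
    W = 0.15^2.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W: float = 0.15 ** 2

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")
        if self.W <= 0:
            raise ValueError("W must be positive")

    def check_region(self, n_snps: int) -> None:
        if n_snps * (self.p1 + self.p2 + self.p12) >= 1:
            raise ValueError(
                f"priors sum to >= 1 over {n_snps} SNPs; reduce p1/p2/p12")


@dataclass
class Region:
    """A 1-based inclusive genomic window seeded by one or more IVs."""

    chrom: str
    start: int
    end: int
    source_ivs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


def build_regions(
    iv_positions: list[tuple[str, int]],
    half_window: int = 500_000,
    merge: bool = True,
) -> list[Region]:
    """One window per IV (pos +- half_window, clipped at 1).

    With ``merge`` (default) overlapping or book-ended same-chromosome
    windows are unioned and their seeding IVs accumulated.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    windows = sorted(
        (str(c), max(1, p - half_window), p + half_window, f"{c}:{p}")
        for c, p in iv_positions)
    regions: list[Region] = []
    for chrom, start, end, iv in windows:
        if (merge and regions and regions[-1].chrom == chrom
                and start <= regions[-1].end + 1):
            regions[-1].end = max(regions[-1].end, end)
            regions[-1].source_ivs.append(iv)
        else:
            regions.append(Region(chrom, start, end, [iv]))
    return regions


def log_abf(beta, se, W: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor of association vs null."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if W < 0:
        raise ValueError("W must be >= 0")
    r = W / (W + se ** 2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z ** 2)


class EmptyRegionError(ValueError):
    """No shared variant between the two traits in the region."""


class ColocModel:
    """Two-trait colocalization model for one region.

    ``t1`` and ``t2`` are region slices of the two traits' summary
    statistics; variants are intersected on id (those present in only one
    trait are dropped with a log message).
    """

    def __init__(
        self,
        t1: SumStatsTable,
        t2: SumStatsTable,
        priors: ColocPriors | None = None,
        region: Region | None = None,
    ):
        self.priors = priors or ColocPriors()
        self.region = region
        shared = t1.df.merge(t2.df, on="snp", suffixes=("_1", "_2"))
        if len(shared) == 0:
            raise EmptyRegionError(
                f"no shared variants between {t1.trait} and {t2.trait}")
        n_dropped = (len(t1) - len(shared)) + (len(t2) - len(shared))
        if n_dropped:
            logger.info("coloc: dropped %d variant(s) present in one trait only", n_dropped)
        self.trait1, self.trait2 = t1.trait, t2.trait
        self.df = shared

    def fit(self) -> "ColocResults":
        pri = self.priors
        df = self.df
        n = len(df)
        pri.check_region(n)
        l1 = log_abf(df["beta_1"], df["se_1"], pri.W)
        l2 = log_abf(df["beta_2"], df["se_2"], pri.W)
        l12 = l1 + l2
        s1 = logsumexp(l1)
        s2 = logsumexp(l2)
        s12 = logsumexp(l12)

        h0 = 0.0
        h1 = np.log(pri.p1) + s1
        h2 = np.log(pri.p2) + s2
        # H3 sums exp(L1_i + L2_j) over i != j = exp(S1 + S2) - exp(S12);
        # evaluated in log space, clamped to -inf on numerical underflow
        a, b = s1 + s2, s12
        if n == 1 or b >= a:
            h3 = -np.inf
        else:
            diff = -np.expm1(b - a)  # 1 - exp(b - a), in (0, 1]
            h3 = np.log(pri.p1) + np.log(pri.p2) + a + np.log(diff) if diff > 0 else -np.inf
        h4 = np.log(pri.p12) + s12

        logw = np.array([h0, h1, h2, h3, h4])
        logz = logsumexp(logw[np.isfinite(logw)])
        pp = np.where(np.isfinite(logw), np.exp(logw - logz), 0.0)

        snp_h4 = np.exp(l12 - s12)
        top = int(np.argmax(l12))
        detail = pd.DataFrame({
            "snp": df["snp"], "chrom": df["chrom_1"], "pos": df["pos_1"],
            "z1": df["beta_1"] / df["se_1"], "z2": df["beta_2"] / df["se_2"],
            "log_abf_1": l1, "log_abf_2": l2, "snp_h4": snp_h4,
        })
        return ColocResults(
            model=self, pp=dict(zip(["H0", "H1", "H2", "H3", "H4"], pp)),
            n_snps=n, top_snp=str(df["snp"].iat[top]),
            top_pos=(str(df["chrom_1"].iat[top]), int(df["pos_1"].iat[top])),
            snp_detail=detail, priors=pri, region=self.region)


@dataclass
class ColocResults:
    """Posterior hypothesis probabilities and per-SNP H4 evidence shares."""

    model: ColocModel
    pp: dict[str, float]
    n_snps: int
    top_snp: str
    top_pos: tuple[str, int]
    snp_detail: pd.DataFrame
    priors: ColocPriors
    region: Region | None = None

    def label(self) -> str:
        """Report annotation for the shared-causal-variant evidence."""
        h4 = self.pp["H4"]
        if h4 >= 0.9:
            return "strong"
        if h4 >= 0.5:
            return "suggestive"
        return "inconclusive"

    def summary(self) -> str:
        reg = (f"{self.region.chrom}:{self.region.start}-{self.region.end}"
               if self.region else "ad hoc region")
        lines = [
            "Bayesian colocalization (single causal variant per trait)",
            "=" * 58,
            f"traits:   {self.model.trait1} vs {self.model.trait2}",
            f"region:   {reg}  ({self.n_snps} shared SNPs)",
            "  ".join(f"PP.{h}={p:.4f}" for h, p in self.pp.items()),
            f"top SNP:  {self.top_snp} at {self.top_pos[0]}:{self.top_pos[1]}"
            f" (H4 share {self.snp_detail['snp_h4'].max():.3f})",
            f"evidence: {self.label()} (strong means PP.H4 >= 0.9)",
        ]
        return "\n".join(lines)


def coloc_pp(
    t1: SumStatsTable,
    t2: SumStatsTable,
    priors: ColocPriors | None = None,
    region: Region | None = None,
) -> ColocResults:
    """Fit the five-hypothesis posterior for one region slice pair."""
    return ColocModel(t1, t2, priors, region).fit()


def coloc_sensitivity(
    t1: SumStatsTable,
    t2: SumStatsTable,
    iv_positions: list[tuple[str, int]],
    half_windows: tuple[int, ...] = (100_000, 250_000, 500_000),
    priors: ColocPriors | None = None,
) -> pd.DataFrame:
    """Window-size sensitivity analysis.

    Re-runs the colocalization for every window half-width and every (merged)
    region; the returned table carries one row per (half_window, region) with
    the posteriors and top SNP, plus ``top_snp_stable``: whether the region
    seeded by the same IVs keeps one identical top SNP across all window
    sizes.
    """
    if any(w <= 0 for w in half_windows):
        raise ValueError("half_windows must be positive")
    rows = []
    for hw in half_windows:
        for region in build_regions(iv_positions, hw, merge=True):
            try:
                res = coloc_pp(t1.slice_region(region.chrom, region.start, region.end),
                               t2.slice_region(region.chrom, region.start, region.end),
                               priors, region)
            except EmptyRegionError:
                continue
            rows.append({
                "half_window": hw, "chrom": region.chrom,
                "start": region.start, "end": region.end,
                "source_ivs": ",".join(region.source_ivs), "n_snps": res.n_snps,
                **{f"pp_{h.lower()}": p for h, p in res.pp.items()},
                "top_snp": res.top_snp,
            })
    out = pd.DataFrame(rows)
    if len(out):
        stable = out.groupby("source_ivs")["top_snp"].transform(lambda s: s.nunique() == 1)
        out["top_snp_stable"] = stable
    return out
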