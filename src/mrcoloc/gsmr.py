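"""LD-aware summary-data Mendelian randomization with pleiotropy filtering.

For each instrument i the causal effect of exposure x on outcome y is
estimated by the ratio of marginal SNP effects, b_xy(i) = b_zy(i) / b_zx(i),
with first-order delta-method variance
var_i = (se_zy_i^2 + b_xy_i^2 se_zx_i^2) / b_zx_i^2.  The per-instrument
ratios are combined by a generalized inverse-variance-weighted estimator

    b_xy = (1' V^-1 1)^-1 1' V^-1 b,    var(b_xy) = (1' V^-1 1)^-1,

where V is the ratio variance-covariance matrix whose off-diagonal entries
carry the LD correlation r_ij between instruments.  Horizontally pleiotropic
instruments — those whose ratio deviates from that of the most strongly
exposure-associated (reference) instrument beyond sampling noise — are
removed beforehand by the HEIDI-outlier test at p < 0.01, iterated until no
further removal.

:class:`GsmrModel` / :class:`GsmrResults` expose the procedure in the usual
model/results idiom; the underlying steps are importable functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .instruments import (InstrumentSet, InsufficientInstrumentsError,
                          assemble_instruments, clump, gw_filter, strength_filter)
from .ld import LDMatrix
from .sumstats import HarmonizedPair, SumStatsTable, harmonize, two_sided_p

logger = logging.getLogger("mrcoloc")

__all__ = [
    "GsmrModel",
    "GsmrResults",
    "HeidiReport",
    "MrStudyResult",
    "ratio_estimates",
    "build_v",
    "ivw_fit",
    "heidi_outlier",
    "run_gsmr",
]

#: relative-eigenvalue threshold below which V is ridge-conditioned
_RIDGE_REL_EIG = 1e-10
_RIDGE_SCALE = 1e-8


class DegenerateInstrumentError(ValueError):
    """A ratio estimate is undefined (exposure effect is zero)."""


class SingularVError(np.linalg.LinAlgError):
    """V not positive definite even after ridge conditioning."""


def ratio_estimates(iset: InstrumentSet) -> pd.DataFrame:
    """Per-instrument ratio estimates and delta-method variances.

    Returns a frame with columns ``snp``, ``b_xy`` and ``var`` aligned to the
    instrument records.  The variance ignores any covariance between the
    exposure and outcome effect estimates (see ``overlap_rho`` in
    :func:`build_v` for the sample-overlap term).
    """
    df = iset.records
    bzx = df["bzx"].to_numpy(dtype=float)
    zero = bzx == 0.0
    if zero.any():
        raise DegenerateInstrumentError(
            f"zero exposure effect for {list(df.loc[zero, 'snp'])[:5]}")
    b_xy = df["bzy"].to_numpy(dtype=float) / bzx
    var = (df["se_zy"].to_numpy(dtype=float) ** 2
           + b_xy ** 2 * df["se_zx"].to_numpy(dtype=float) ** 2) / bzx ** 2
    return pd.DataFrame({"snp": df["snp"].to_numpy(), "b_xy": b_xy, "var": var})


def build_v(
    iset: InstrumentSet,
    ratios: pd.DataFrame,
    overlap_rho: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Variance-covariance matrix of the ratio estimates.

    Diagonal entries are the delta-method variances; off-diagonal entries
    couple instruments i != j through their LD correlation r_ij:

        V_ij = r_ij (se_zy_i se_zy_j + b_xy_i b_xy_j se_zx_i se_zx_j)
               / (b_zx_i b_zx_j).

    A non-zero ``overlap_rho`` (correlation of the exposure and outcome
    estimation errors under sample overlap) subtracts the corresponding
    cross-covariance from every entry.  When the smallest eigenvalue falls
    below 1e-10 times the largest, a ridge of 1e-8 * trace/m is added to the
    diagonal and flagged in the returned info dict.
    """
    df = iset.records
    bzx = df["bzx"].to_numpy(dtype=float)
    se_zx = df["se_zx"].to_numpy(dtype=float)
    se_zy = df["se_zy"].to_numpy(dtype=float)
    b_xy = ratios["b_xy"].to_numpy(dtype=float)
    r = iset.ld.r

    num = (np.outer(se_zy, se_zy) + np.outer(b_xy * se_zx, b_xy * se_zx))
    if overlap_rho != 0.0:
        num = num - overlap_rho * (np.outer(b_xy * se_zx, se_zy)
                                   + np.outer(se_zy, b_xy * se_zx))
    v = r * num / np.outer(bzx, bzx)
    np.fill_diagonal(v, ratios["var"].to_numpy(dtype=float)
                     - (2.0 * overlap_rho * b_xy * se_zx * se_zy) / bzx ** 2)
    if not np.all(np.isfinite(v)):
        i, j = np.argwhere(~np.isfinite(v))[0]
        raise FloatingPointError(
            f"non-finite V entry for pair ({df['snp'].iat[i]}, {df['snp'].iat[j]})")
    v = (v + v.T) / 2.0

    info = {"ridged": False, "ridge": 0.0}
    eig = np.linalg.eigvalsh(v)
    if eig[0] < _RIDGE_REL_EIG * max(eig[-1], 0.0):
        ridge = _RIDGE_SCALE * np.trace(v) / v.shape[0]
        v = v + ridge * np.eye(v.shape[0])
        info = {"ridged": True, "ridge": ridge}
        logger.warning("build_v: near-singular V; ridge %.3e added to diagonal", ridge)
    info["condition"] = float(np.linalg.cond(v))
    return v, info


def ivw_fit(ratios: pd.DataFrame, v: np.ndarray) -> tuple[float, float, float]:
    """Generalized IVW combination of ratio estimates under covariance V.

    Returns (estimate, SE, two-sided p).  Solved through a Cholesky
    factorization of V; a factorization failure raises
    :class:`SingularVError` with the condition number.
    """
    b = ratios["b_xy"].to_numpy(dtype=float)
    if b.shape[0] == 1:
        est = float(b[0])
        se = float(np.sqrt(v[0, 0]))
        return est, se, float(two_sided_p(est / se))
    try:
        cho = linalg.cho_factor(v, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularVError(f"V is singular (cond={np.linalg.cond(v):.3e})") from exc
    ones = np.ones_like(b)
    vinv_1 = linalg.cho_solve(cho, ones)
    vinv_b = linalg.cho_solve(cho, b)
    denom = float(ones @ vinv_1)
    if denom <= 0:
        raise SingularVError(f"V not positive definite (cond={np.linalg.cond(v):.3e})")
    est = float(ones @ vinv_b / denom)
    se = float(1.0 / np.sqrt(denom))
    return est, se, float(two_sided_p(est / se))


@dataclass
class HeidiReport:
    """Record of HEIDI-outlier exclusions (the pleiotropic-variant table).

    ``excluded`` has one row per removed variant with its full effect row and
    HEIDI p-value; ``reference_variant`` is the reference instrument of the
    final pass.
    """

    excluded: pd.DataFrame
    alpha: float
    reference_variant: str
    n_passes: int = 1

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


_HEIDI_COLS = ["snp", "chrom", "pos", "bzx", "se_zx", "p_zx",
               "bzy", "se_zy", "p_zy", "p_heidi"]


def heidi_outlier(
    iset: InstrumentSet,
    alpha: float = 0.01,
    min_instruments: int = 10,
) -> tuple[InstrumentSet, HeidiReport]:
    """Iterative HEIDI-outlier exclusion of horizontally pleiotropic variants.

    Each pass takes the instrument with the largest |b_zx / se_zx| as the
    reference, tests every other instrument's ratio deviation
    d_i = b_xy_i - b_xy_ref against var(d_i) = var_i + var_ref - 2 V_i,ref,
    and removes all instruments with two-sided p < ``alpha`` at once.  Passes
    repeat (re-deriving the reference) until no removal.  If an exclusion
    pass would leave fewer than ``min_instruments`` instruments, an
    :class:`InsufficientInstrumentsError` carrying the report so far is
    raised.
    """
    if len(iset) < 3:
        raise ValueError("HEIDI-outlier requires at least 3 instruments")
    current = iset
    removed_frames: list[pd.DataFrame] = []
    n_passes = 0
    while True:
        n_passes += 1
        df = current.records
        ratios = ratio_estimates(current)
        v, _ = build_v(current, ratios)
        z_x = np.abs(df["bzx"].to_numpy(dtype=float) / df["se_zx"].to_numpy(dtype=float))
        ref = int(np.argmax(z_x))
        b = ratios["b_xy"].to_numpy()
        var = ratios["var"].to_numpy()
        d = b - b[ref]
        var_d = var + var[ref] - 2.0 * v[:, ref]
        var_d = np.maximum(var_d, 1e-12 * (var + var[ref]))
        p = two_sided_p(d / np.sqrt(var_d))
        p[ref] = 1.0
        flag = p < alpha
        if not flag.any():
            report_ref = str(df["snp"].iat[ref])
            break
        out = df.loc[flag, [c for c in _HEIDI_COLS if c != "p_heidi"]].copy()
        out["p_heidi"] = p[flag]
        removed_frames.append(out)
        keep = ~flag
        if int(keep.sum()) < min_instruments:
            report = _make_report(removed_frames, alpha, str(df["snp"].iat[ref]), n_passes)
            err = InsufficientInstrumentsError(int(keep.sum()), min_instruments,
                                               context="HEIDI-outlier")
            err.report = report
            raise err
        current = current.subset(keep.to_numpy() if hasattr(keep, "to_numpy") else keep)
    report = _make_report(removed_frames, alpha, report_ref, n_passes)
    if report.n_excluded:
        logger.info("heidi_outlier: excluded %d variant(s) at p < %g in %d pass(es)",
                    report.n_excluded, alpha, n_passes)
    return current, report


def _make_report(frames: list[pd.DataFrame], alpha: float, ref: str, n_passes: int) -> HeidiReport:
    if frames:
        excluded = pd.concat(frames, ignore_index=True)[_HEIDI_COLS]
    else:
        excluded = pd.DataFrame(columns=_HEIDI_COLS)
    return HeidiReport(excluded=excluded, alpha=alpha,
                       reference_variant=ref, n_passes=n_passes)


class GsmrModel:
    """Causal-effect model for one exposure-outcome pair.

    Parameters
    ----------
    instruments
        Selected and quality-filtered instruments with their LD submatrix.
    heidi_alpha
        HEIDI-outlier exclusion threshold; ``None`` disables the filter.
    min_instruments
        Minimum surviving instrument count (the minimum-ten rule).
    overlap_rho
        Optional correlation of exposure/outcome estimation errors added to
        the ratio covariance (sample overlap); zero by default.
    """

    def __init__(
        self,
        instruments: InstrumentSet,
        heidi_alpha: float | None = 0.01,
        min_instruments: int = 10,
        overlap_rho: float = 0.0,
    ):
        self.instruments = instruments
        self.heidi_alpha = heidi_alpha
        self.min_instruments = min_instruments
        self.overlap_rho = overlap_rho

    def fit(self) -> "GsmrResults":
        iset = self.instruments
        if self.heidi_alpha is not None and len(iset) >= 3:
            iset, report = heidi_outlier(iset, self.heidi_alpha, self.min_instruments)
        else:
            report = _make_report([], self.heidi_alpha or np.nan,
                                  str(iset.records["snp"].iat[0]), 0)
        ratios = ratio_estimates(iset)
        v, info = build_v(iset, ratios, self.overlap_rho)
        est, se, p = ivw_fit(ratios, v)
        return GsmrResults(
            model=self, b_xy=est, se=se, pvalue=p, m_used=len(iset),
            heidi=report, v_condition=info["condition"], ridged=info["ridged"],
            instruments_used=iset, ratios=ratios)


@dataclass
class GsmrResults:
    """Fitted causal estimate with uncertainty and diagnostics."""

    model: GsmrModel
    b_xy: float
    se: float
    pvalue: float
    m_used: int
    heidi: HeidiReport
    v_condition: float
    ridged: bool
    instruments_used: InstrumentSet
    ratios: pd.DataFrame

    @property
    def zvalue(self) -> float:
        return self.b_xy / self.se

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        q = stats.norm.ppf(1.0 - alpha / 2.0)
        return self.b_xy - q * self.se, self.b_xy + q * self.se

    def summary(self) -> str:
        lo, hi = self.conf_int()
        iset = self.instruments_used
        lines = [
            "Generalized summary-data MR (LD-aware IVW)",
            "=" * 46,
            f"exposure:            {iset.exposure_trait}",
            f"outcome:             {iset.outcome_trait}",
            f"instruments used:    {self.m_used}"
            f" (snp_out={iset.snp_out}, snp_index={iset.snp_index})",
            f"HEIDI excluded:      {self.heidi.n_excluded} at p < {self.heidi.alpha:g}",
            f"b_xy (SE):           {self.b_xy:.4g} ({self.se:.4g})",
            f"95% CI:              [{lo:.4g}, {hi:.4g}]",
            f"z, p:                {self.zvalue:.3f}, {self.pvalue:.3g}",
            f"V condition number:  {self.v_condition:.3e}"
            + ("  [ridge-conditioned]" if self.ridged else ""),
        ]
        return "\n".join(lines)


@dataclass
class MrStudyResult:
    """Multi-outcome study: per-outcome fits under a Bonferroni threshold."""

    exposure_trait: str
    fits: dict[str, GsmrResults]
    bonferroni_alpha: float
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def significant(self) -> dict[str, bool]:
        return {t: r.pvalue < self.bonferroni_alpha for t, r in self.fits.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trait, r in self.fits.items():
            iset = r.instruments_used
            rows.append({
                "trait": trait, "snp_out": iset.snp_out, "snp_index": iset.snp_index,
                "b_xy": r.b_xy, "se": r.se, "p": r.pvalue, "n_ivs": r.m_used,
                "significant": r.pvalue < self.bonferroni_alpha,
            })
        return pd.DataFrame(rows)

    def heidi_frame(self) -> pd.DataFrame:
        frames = []
        for trait, r in self.fits.items():
            if r.heidi.n_excluded:
                f = r.heidi.excluded.copy()
                f.insert(0, "outcome", trait)
                frames.append(f)
        if not frames:
            return pd.DataFrame(columns=["outcome"] + _HEIDI_COLS)
        return pd.concat(frames, ignore_index=True)


def run_gsmr(
    exposure: SumStatsTable,
    outcomes: list[SumStatsTable],
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.05,
    clump_window_bp: int = 1_000_000,
    f_min: float = 10.0,
    heidi_alpha: float = 0.01,
    min_instruments: int = 10,
    palindromic_policy: str = "drop_ambiguous",
    family_alpha: float = 0.05,
) -> MrStudyResult:
    """Full per-outcome chain with a Bonferroni-corrected family threshold.

    For each outcome: harmonize -> significance filter -> LD clump ->
    strength filter -> assemble -> HEIDI-outlier -> IVW.  The family
    significance threshold is ``family_alpha / n_outcomes``.  Stage failures
    are recorded per outcome (tagged with the trait) without aborting the
    remaining outcomes.
    """
    fits: dict[str, GsmrResults] = {}
    errors: dict[str, str] = {}
    for outcome in outcomes:
        try:
            pair = harmonize(exposure, outcome, palindromic_policy)
            pair = gw_filter(pair, p_threshold)
            pair = clump(pair, ld, clump_r2, clump_window_bp)
            pair = strength_filter(pair, f_min)
            iset = assemble_instruments(pair, ld, min_instruments)
            fits[outcome.trait] = GsmrModel(
                iset, heidi_alpha, min_instruments).fit()
        except Exception as exc:
            errors[outcome.trait] = f"{type(exc).__name__}: {exc}"
            logger.error("run_gsmr[%s]: %s", outcome.trait, errors[outcome.trait])
    return MrStudyResult(
        exposure_trait=exposure.trait, fits=fits,
        bonferroni_alpha=family_alpha / max(len(outcomes), 1), errors=errors)
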