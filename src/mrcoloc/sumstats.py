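"""GWAS summary statistics: containers, I/O, meta-analysis and harmonization.

A :class:`SumStatsTable` holds per-variant marginal association results for a
single trait (effect and other allele, effect-allele frequency, beta, SE,
p-value, sample size), backed by a pandas DataFrame sorted by genomic
position.  :func:`meta_fixed_ivw` combines per-population tables with
fixed-effect inverse-variance weights; :func:`genomic_control` applies (or
estimates) an inflation-factor correction; :func:`harmonize` aligns an
exposure and an outcome table onto the exposure's effect allele, which is the
form the ratio-based MR estimator consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrcoloc")

__all__ = [
    "SumStatsTable",
    "HarmonizedPair",
    "read_sumstats",
    "write_sumstats",
    "meta_fixed_ivw",
    "genomic_control",
    "harmonize",
]

#: canonical column order of the internal frame
COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "freq", "beta", "se", "p", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumStatsFormatError(ValueError):
    """Malformed summary-statistics input."""


class EmptyInputError(ValueError):
    """An input with no usable rows."""


def _complement(allele: str) -> str | None:
    out = []
    for base in allele:
        c = _COMPLEMENT.get(base.upper())
        if c is None:
            return None
        out.append(c)
    return "".join(out)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _complement(a1) == a2.upper()


def two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal tail probability of a z statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))


def _sort_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)


@dataclass
class SumStatsTable:
    """Summary statistics for one trait.

    ``df`` carries one row per variant with columns ``snp chrom pos a1 a2
    freq beta se p n``; ``a1`` is the effect allele to which ``beta`` refers.
    Rows are kept sorted by (chrom, pos) and variant ids are unique.
    """

    trait: str
    df: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsFormatError(f"missing columns: {missing}")
        df = self.df.loc[:, COLUMNS].copy()
        df["snp"] = df["snp"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        dup = df["snp"].duplicated()
        if dup.any():
            raise SumStatsFormatError(
                f"duplicate variant id(s): {sorted(df.loc[dup, 'snp'].unique())[:5]}"
            )
        self.df = _sort_frame(df)

    def __len__(self) -> int:
        return len(self.df)

    def note(self, msg: str) -> None:
        self.provenance.append(msg)

    def zscores(self) -> np.ndarray:
        return (self.df["beta"] / self.df["se"]).to_numpy()

    def slice_region(self, chrom: str, start: int, end: int) -> "SumStatsTable":
        """Rows with chrom == ``chrom`` and start <= pos <= end (1-based inclusive)."""
        mask = (self.df["chrom"] == str(chrom)) & self.df["pos"].between(start, end)
        return SumStatsTable(self.trait, self.df.loc[mask], list(self.provenance))


@dataclass
class HarmonizedPair:
    """Exposure/outcome effects aligned to the exposure effect allele.

    ``df`` columns: ``snp chrom pos a1 a2 freq bzx se_zx p_zx n_x bzy se_zy
    p_zy n_y`` (plus any QC columns added downstream).  Every outcome beta has
    already been sign-flipped where the allele assignment was swapped.
    """

    exposure_trait: str
    outcome_trait: str
    df: pd.DataFrame
    snp_out: int | None = None
    snp_index: int | None = None

    def __len__(self) -> int:
        return len(self.df)

    def _side(self, which: str, trait: str) -> "SumStatsTable":
        d = self.df
        cols = {"snp": d["snp"], "chrom": d["chrom"], "pos": d["pos"],
                "a1": d["a1"], "a2": d["a2"], "freq": d["freq"]}
        suffix = "zx" if which == "x" else "zy"
        cols["beta"] = d[f"b{suffix}"]
        cols["se"] = d[f"se_{suffix}"]
        cols["p"] = d[f"p_{suffix}"]
        cols["n"] = d[f"n_{which}"]
        return SumStatsTable(trait, pd.DataFrame(cols))

    def exposure_table(self) -> "SumStatsTable":
        return self._side("x", self.exposure_trait)

    def outcome_table(self) -> "SumStatsTable":
        return self._side("y", self.outcome_trait)

    def to_file(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MA_COLUMNS = {"SNP": "snp", "A1": "a1", "A2": "a2", "freq": "freq",
               "b": "beta", "se": "se", "p": "p", "N": "n"}


def _parse_positional_id(snp: str) -> tuple[str, int]:
    """chrom:pos(:...) tokens carry their own coordinates; others do not."""
    parts = str(snp).split(":")
    if len(parts) >= 2:
        try:
            return parts[0].removeprefix("chr"), int(parts[1])
        except ValueError:
            pass
    return "un", 0


def read_sumstats(
    path: str | Path,
    dialect: str = "cojo_ma",
    trait: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> SumStatsTable:
    """Read a summary-statistics file.

    ``cojo_ma`` is the whitespace-delimited COJO format with header
    ``SNP A1 A2 freq b se p N`` (optional ``CHR``/``BP`` columns are used when
    present, otherwise coordinates are parsed from ``chrom:pos`` ids);
    ``generic_tsv`` is tab-delimited with a ``column_map`` from the canonical
    names (snp, chrom, pos, a1, a2, freq, beta, se, p, n) to file columns.

    Rows with non-positive SE or p outside (0, 1] are dropped with a logged
    count; a duplicated variant id raises :class:`SumStatsFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "cojo_ma":
        df = pd.read_csv(path, sep=r"\s+")
        missing = [c for c in _MA_COLUMNS if c not in df.columns]
        if missing:
            raise SumStatsFormatError(f"{path}: missing mandatory column(s) {missing}")
        df = df.rename(columns=_MA_COLUMNS)
        if "CHR" in df.columns and "BP" in df.columns:
            df["chrom"] = df["CHR"].astype(str)
            df["pos"] = df["BP"]
        else:
            coords = [_parse_positional_id(s) for s in df["snp"]]
            df["chrom"] = [c for c, _ in coords]
            df["pos"] = [p for _, p in coords]
    elif dialect == "generic_tsv":
        raw = pd.read_csv(path, sep="\t")
        cmap = dict(column_map or {})
        rename = {}
        for canon in COLUMNS:
            src = cmap.get(canon, canon)
            if src not in raw.columns:
                raise SumStatsFormatError(f"{path}: missing mandatory column {src!r}")
            rename[src] = canon
        df = raw.rename(columns=rename)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    n0 = len(df)
    for col in ("beta", "se", "p", "n", "freq"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = ~(df["se"] > 0) | ~((df["p"] > 0) & (df["p"] <= 1)) | df["beta"].isna()
    if bad.any():
        logger.warning("%s: dropped %d row(s) failing QC (se<=0, p outside (0,1], or missing beta)",
                       path.name, int(bad.sum()))
    df = df.loc[~bad]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no rows left after QC")

    # flag (not drop) p/z inconsistency beyond 10% relative tolerance
    with np.errstate(divide="ignore"):
        p_expected = two_sided_p(df["beta"] / df["se"])
    incons = np.abs(np.log(df["p"].to_numpy()) - np.log(p_expected)) > np.abs(
        np.log(np.maximum(p_expected, 1e-300))) * 0.1 + 0.105
    if incons.any():
        logger.warning("%s: %d row(s) with p inconsistent with beta/se (>10%% rel.)",
                       path.name, int(incons.sum()))

    table = SumStatsTable(trait or path.stem, df)
    table.note(f"read {len(table)}/{n0} rows from {path} ({dialect})")
    return table


def write_sumstats(table: SumStatsTable, path: str | Path) -> None:
    """Write in COJO .ma layout (tab-delimited, with CHR/BP carried along)."""
    df = table.df.rename(columns={v: k for k, v in _MA_COLUMNS.items()})
    df["CHR"] = table.df["chrom"]
    df["BP"] = table.df["pos"]
    cols = ["SNP", "CHR", "BP", "A1", "A2", "freq", "b", "se", "p", "N"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# meta-analysis and genomic control
# ---------------------------------------------------------------------------

def _align_alleles(ref: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Orient ``other`` onto ``ref``'s effect alleles (match on variant id).

    Tries identity, allele swap, strand complement and complement+swap, in
    that order; irreconcilable rows are dropped with a logged count.
    """
    merged = other.merge(ref[["snp", "a1", "a2"]], on="snp", suffixes=("", "_ref"))
    if len(merged) == 0:
        return merged
    a1 = merged["a1"].str.upper()
    a2 = merged["a2"].str.upper()
    r1 = merged["a1_ref"].str.upper()
    r2 = merged["a2_ref"].str.upper()
    c1 = a1.map(lambda a: _complement(a) or "?")
    c2 = a2.map(lambda a: _complement(a) or "?")
    same = (a1 == r1) & (a2 == r2)
    swap = (a1 == r2) & (a2 == r1)
    strand = (c1 == r1) & (c2 == r2) & ~same & ~swap
    strand_swap = (c1 == r2) & (c2 == r1) & ~same & ~swap
    flip = swap | strand_swap
    keep = same | swap | strand | strand_swap
    if (~keep).any():
        logger.warning("meta/harmonize: dropped %d variant(s) with irreconcilable alleles",
                       int((~keep).sum()))
    out = merged.loc[keep].copy()
    fl = flip[keep]
    out.loc[fl, "beta"] = -out.loc[fl, "beta"]
    out.loc[fl, "freq"] = 1.0 - out.loc[fl, "freq"]
    out["a1"] = out["a1_ref"]
    out["a2"] = out["a2_ref"]
    return out.drop(columns=["a1_ref", "a2_ref"])


def meta_fixed_ivw(tables: Sequence[SumStatsTable], trait: str | None = None) -> SumStatsTable:
    """Fixed-effect inverse-variance-weighted meta-analysis across populations.

    Per variant (matched by id, alleles harmonized to the first table in
    which the variant appears): beta = sum(w_i b_i)/sum(w_i) with
    w_i = 1/se_i^2, SE = sum(w_i)^(-1/2), p from a two-sided normal, and
    n = sum(n_i).  Variants present in a single table pass through unchanged.
    Cochran's Q heterogeneity is computed and logged but does not filter.
    """
    tables = [t for t in tables if len(t) > 0]
    if len(tables) == 0:
        raise EmptyInputError("meta_fixed_ivw: no non-empty tables")

    # reference allele orientation: first table where each variant appears
    seen: set[str] = set()
    aligned: list[pd.DataFrame] = []
    ref_frames = []
    for t in tables:
        new = t.df[~t.df["snp"].isin(seen)]
        seen.update(new["snp"])
        ref_frames.append(new[["snp", "chrom", "pos", "a1", "a2"]])
    ref = pd.concat(ref_frames, ignore_index=True)
    for t in tables:
        aligned.append(_align_alleles(ref, t.df))

    stacked = pd.concat(aligned, ignore_index=True)
    w = 1.0 / stacked["se"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["beta"],
                             _wf=w * stacked["freq"], _wb2=w * stacked["beta"] ** 2)
    g = stacked.groupby("snp", sort=False)
    agg = g.agg(chrom=("chrom", "first"), pos=("pos", "first"),
                a1=("a1", "first"), a2=("a2", "first"),
                sw=("_w", "sum"), swb=("_wb", "sum"), swf=("_wf", "sum"),
                swb2=("_wb2", "sum"), n=("n", "sum"), k=("snp", "size"))
    beta = agg["swb"] / agg["sw"]
    se = 1.0 / np.sqrt(agg["sw"])
    out = pd.DataFrame({
        "snp": agg.index, "chrom": agg["chrom"], "pos": agg["pos"],
        "a1": agg["a1"], "a2": agg["a2"], "freq": agg["swf"] / agg["sw"],
        "beta": beta, "se": se, "p": two_sided_p(beta / se), "n": agg["n"],
    }).reset_index(drop=True)

    # Cochran's Q = sum w_i (b_i - b_meta)^2, df = k - 1; logged only
    q = agg["swb2"] - agg["swb"] ** 2 / agg["sw"]
    k = agg["k"].to_numpy()
    with np.errstate(invalid="ignore"):
        q_p = stats.chi2.sf(q.to_numpy(), np.maximum(k - 1, 1))
    het = int(np.sum((k > 1) & (q_p < 0.05)))
    logger.info("meta_fixed_ivw: %d variants, %d with Q heterogeneity p<0.05", len(out), het)

    result = SumStatsTable(trait or tables[0].trait, out)
    result.note(f"fixed-effect IVW meta of {len(tables)} tables")
    return result


def genomic_control(table: SumStatsTable, lambda_gc: float | str = "estimate") -> SumStatsTable:
    """Genomic-control correction of test-statistic inflation.

    With ``lambda_gc="estimate"`` the inflation factor is
    lambda = median(z^2) / 0.4549 (the median of a 1-df chi-square),
    requiring at least 1000 variants.  SEs are multiplied by
    max(1, sqrt(lambda)) — deflation below 1 is never applied — and p-values
    recomputed.
    """
    z = table.zscores()
    if isinstance(lambda_gc, str):
        if lambda_gc != "estimate":
            raise ValueError(f"lambda_gc must be positive or 'estimate', got {lambda_gc!r}")
        if len(table) < 1000:
            raise ValueError("lambda estimation needs >= 1000 variants")
        lam = float(np.median(z ** 2) / stats.chi2.ppf(0.5, 1))
    else:
        lam = float(lambda_gc)
        if lam <= 0:
            raise ValueError(f"lambda_gc must be positive, got {lam}")
    scale = max(1.0, np.sqrt(lam))
    df = table.df.copy()
    df["se"] = df["se"] * scale
    df["p"] = two_sided_p(df["beta"] / df["se"])
    out = SumStatsTable(table.trait, df, list(table.provenance))
    out.note(f"genomic control lambda={lam:.4f} (SE scale {scale:.4f})")
    return out


# ---------------------------------------------------------------------------
# exposure/outcome harmonization
# ---------------------------------------------------------------------------

def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindromic_policy: str = "drop_ambiguous",
) -> HarmonizedPair:
    """Align outcome effects onto the exposure's effect alleles.

    Variants are intersected by id (with a chrom:pos + allele-set fallback
    for ids present in only one table), outcome betas sign-flipped where the
    allele assignment is swapped, and strand flips resolved by complementing.
    Palindromic (A/T, C/G) variants are handled per ``palindromic_policy``:
    ``drop_ambiguous`` (default) removes them when the effect-allele frequency
    lies in [0.4, 0.6] in either table, ``drop_all`` removes all of them and
    ``keep`` retains them.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise EmptyInputError("harmonize: empty input table")
    if palindromic_policy not in ("drop_ambiguous", "keep", "drop_all"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")

    exp = exposure.df
    out = outcome.df.copy()

    # id fallback: positional token chrom:pos:allele-set for unmatched ids
    shared = set(exp["snp"]) & set(out["snp"])
    only_exp = exp.loc[~exp["snp"].isin(shared)]
    only_out = out.loc[~out["snp"].isin(shared)]
    if len(only_exp) and len(only_out):
        def poskey(df: pd.DataFrame) -> pd.Series:
            alleles = [":".join(sorted((a.upper(), b.upper())))
                       for a, b in zip(df["a1"], df["a2"])]
            return df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + alleles
        emap = dict(zip(poskey(only_exp), only_exp["snp"]))
        rename = {s: emap[k] for s, k in zip(only_out["snp"], poskey(only_out)) if k in emap}
        if rename:
            logger.info("harmonize: matched %d variant(s) by position+alleles", len(rename))
            out["snp"] = out["snp"].replace(rename)

    aligned = _align_alleles(exp, out)
    n_flip = int((np.sign(aligned["beta"].to_numpy()) !=
                  np.sign(out.set_index("snp").loc[aligned["snp"], "beta"].to_numpy())).sum())

    merged = exp.merge(aligned[["snp", "freq", "beta", "se", "p", "n"]],
                       on="snp", suffixes=("", "_out"))
    if len(merged) == 0:
        raise EmptyInputError(
            f"harmonize: no shared variants between {exposure.trait} and {outcome.trait}")

    pal = np.array([_is_palindromic(a, b) for a, b in zip(merged["a1"], merged["a2"])])
    if palindromic_policy == "drop_all":
        drop = pal
    elif palindromic_policy == "drop_ambiguous":
        ambiguous = (merged["freq"].between(0.4, 0.6) |
                     merged["freq_out"].between(0.4, 0.6))
        drop = pal & ambiguous.to_numpy()
    else:
        drop = np.zeros(len(merged), dtype=bool)
    if drop.any():
        logger.info("harmonize: dropped %d palindromic variant(s) (%s)",
                    int(drop.sum()), palindromic_policy)
    merged = merged.loc[~drop]
    if len(merged) == 0:
        raise EmptyInputError("harmonize: no variants left after palindromic filter")
    logger.info("harmonize: %d shared variants, %d outcome beta(s) flipped", len(merged), n_flip)

    df = pd.DataFrame({
        "snp": merged["snp"], "chrom": merged["chrom"], "pos": merged["pos"],
        "a1": merged["a1"], "a2": merged["a2"], "freq": merged["freq"],
        "bzx": merged["beta"], "se_zx": merged["se"], "p_zx": merged["p"],
        "n_x": merged["n"],
        "bzy": merged["beta_out"], "se_zy": merged["se_out"], "p_zy": merged["p_out"],
        "n_y": merged["n_out"],
    })
    df = df.sort_values(["chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    return HarmonizedPair(exposure.trait, outcome.trait, df)
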