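"""Synthetic GWAS summary statistics with planted truths.

Two generators cover the two inference stages:

* :func:`simulate_instruments` draws quasi-independent instrument-level
  exposure/outcome effect pairs under the proportionality model
  b_zy = b_xy * b_zx + gamma (gamma non-zero only for planted horizontally
  pleiotropic variants), with sampling noise at the standard
  unit-variance-phenotype, Hardy-Weinberg SE calculus
  se = (2 p (1-p) n)^(-1/2).

* :func:`simulate_region` draws a dense local region for two traits from
  z ~ MVN(R lambda, R) over an AR(1) LD matrix R, with a shared or distinct
  causal variant per trait — the data-generating models of the H4 and H3
  colocalization hypotheses.

Named presets reproduce the study conditions of the pig average-daily-gain
analyses: planted causal effects and instrument counts per outcome trait,
noise-free scenarios embedding the published pleiotropic variant effects, and
shared/distinct-causal colocalization regions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ld import LDMatrix, make_ar1_ld
from .sumstats import HarmonizedPair, SumStatsTable, two_sided_p

__all__ = [
    "InstrumentScenario",
    "RegionScenario",
    "simulate_instruments",
    "simulate_region",
    "scenario_preset",
    "identity_ld",
    "PRESET_NAMES",
]

#: minimum expected |z| of a true instrument effect; guarantees genome-wide
#: significance (p < 2e-9) of the underlying signal so the significance filter
#: is a no-op on simulated instruments and recovery tests carry no
#: winner's-curse selection bias.
MIN_EXPECTED_Z = 6.0

# exposure/outcome sample sizes of the five pig traits (phenotyped animals)
TRAIT_N = {"ADG": 20555, "BFT": 39323, "LMDEP": 24215, "AFF": 5707, "NSB": 17077}

# published causal-effect estimates and instrument counts per outcome
TABLE3 = {
    "BFT": (0.13, 115),
    "LMDEP": (0.35, 113),
    "AFF": (-3.24, 106),
    "NSB": (-0.05, 112),
}

# published pleiotropic variants: (b_zx, se_zx, b_zy, se_zy, chrom, pos)
TABLE2 = {
    "BFT": [
        (-3.28, 0.58, -0.14, 0.03, "1", 158_058_352),
        (-5.47, 0.81, -0.21, 0.04, "1", 162_719_373),
        (-3.26, 0.59, -0.17, 0.03, "1", 162_899_224),
        (2.33, 0.57, 0.14, 0.03, "7", 29_132_104),
    ],
    "LMDEP": [
        (6.63, 1.52, -0.23, 0.07, "7", 21_813_401),
        (-3.20, 0.77, 0.45, 0.08, "7", 33_305_936),
    ],
}

PRESET_NAMES = (
    "null", "table3_bft", "table3_lmdep", "table3_aff", "table3_nsb",
    "table2_bft_pleio", "table2_lmdep_pleio", "coloc_shared", "coloc_distinct",
)


@dataclass
class InstrumentScenario:
    """Data-generating conditions for one instrument-level simulation.

    ``pleiotropy`` lists (index, gamma) direct outcome effects; ``planted``
    rows are fixed, noise-free (b_zx, se_zx, b_zy, se_zy, chrom, pos) variants
    appended verbatim after the drawn instruments; ``overlap_rho`` correlates
    the exposure and outcome estimation errors (shared samples);
    ``noise_free`` suppresses all sampling noise (observed = true effects).
    """

    m: int
    b_xy_true: float
    n_exp: int
    n_out: int
    bzx_sd: float = 0.15
    maf_range: tuple[float, float] = (0.1, 0.5)
    pleiotropy: list[tuple[int, float]] = field(default_factory=list)
    overlap_rho: float = 0.0
    seed: int = 0
    noise_free: bool = False
    planted: list[tuple] = field(default_factory=list)
    exposure_trait: str = "exposure"
    outcome_trait: str = "outcome"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_exp < 10 or self.n_out < 10:
            raise ValueError("sample sizes must be >= 10")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (-1 < self.overlap_rho < 1):
            raise ValueError("overlap_rho must lie in (-1, 1)")
        for idx, _ in self.pleiotropy:
            if not (0 <= idx < self.m):
                raise ValueError(f"pleiotropy index {idx} out of range for m={self.m}")


@dataclass
class RegionScenario:
    """Conditions for a two-trait dense-region simulation.

    ``causal_1 == causal_2`` plants a shared causal variant (the H4 world);
    distinct indices plant trait-specific causal variants (H3).  ``lambda_*``
    is the non-centrality: the expected marginal z at the causal variant.
    """

    n_snps: int
    rho: float
    causal_1: int
    causal_2: int
    lambda_1: float
    lambda_2: float
    n1: int
    n2: int
    seed: int = 0
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing_bp: int = 1_000

    def __post_init__(self) -> None:
        if not (0 <= self.causal_1 < self.n_snps and 0 <= self.causal_2 < self.n_snps):
            raise ValueError("causal indices must lie in [0, n_snps)")
        if self.lambda_1 < 0 or self.lambda_2 < 0:
            raise ValueError("lambda must be >= 0")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")

    @property
    def shared(self) -> bool:
        return self.causal_1 == self.causal_2


def _scenario_to_yaml(scn, path: str | Path) -> None:
    d = asdict(scn)
    d["kind"] = type(scn).__name__
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def scenario_from_yaml(path: str | Path):
    d = yaml.safe_load(Path(path).read_text())
    kind = d.pop("kind")
    cls = {"InstrumentScenario": InstrumentScenario, "RegionScenario": RegionScenario}[kind]
    if "pleiotropy" in d:
        d["pleiotropy"] = [tuple(t) for t in d["pleiotropy"]]
    if "planted" in d:
        d["planted"] = [tuple(t) for t in d["planted"]]
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    return cls(**d)


InstrumentScenario.to_yaml = _scenario_to_yaml
RegionScenario.to_yaml = _scenario_to_yaml


def identity_ld(ids) -> LDMatrix:
    """LD matrix of quasi-independent variants (r = 0 off-diagonal)."""
    ids = list(ids)
    return LDMatrix(ids, np.eye(len(ids)), validate=False)


def _truncated_effects(rng: np.random.Generator, sd: float, se: np.ndarray) -> np.ndarray:
    """True effects ~ N(0, sd^2) resampled until expected |z| >= MIN_EXPECTED_Z."""
    b = rng.normal(0.0, sd, se.shape[0])
    for _ in range(10_000):
        weak = np.abs(b) / se < MIN_EXPECTED_Z
        if not weak.any():
            return b
        b[weak] = rng.normal(0.0, sd, int(weak.sum()))
    raise RuntimeError(
        "instrument-effect truncation did not converge; "
        "bzx_sd is too small relative to (2 maf (1-maf) n_exp)^(-1/2)")


def simulate_instruments(scn: InstrumentScenario) -> HarmonizedPair:
    """Draw a harmonized exposure/outcome instrument panel.

    Returns a :class:`HarmonizedPair` whose variants are quasi-independent
    (use :func:`identity_ld` for the matching LD matrix).  Drawn instruments
    are placed 2 Mb apart; planted rows keep their stated coordinates.
    """
    rng = np.random.default_rng(scn.seed)
    maf = rng.uniform(scn.maf_range[0], scn.maf_range[1], scn.m)
    se_zx = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * scn.n_exp)
    se_zy = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * scn.n_out)
    bzx_true = _truncated_effects(rng, scn.bzx_sd, se_zx)
    gamma = np.zeros(scn.m)
    for idx, g in scn.pleiotropy:
        gamma[idx] += g
    bzy_true = scn.b_xy_true * bzx_true + gamma

    if scn.noise_free:
        bzx, bzy = bzx_true, bzy_true
    else:
        e_x = rng.standard_normal(scn.m)
        e_y = scn.overlap_rho * e_x + np.sqrt(1.0 - scn.overlap_rho ** 2) * rng.standard_normal(scn.m)
        bzx = bzx_true + se_zx * e_x
        bzy = bzy_true + se_zy * e_y

    rows = pd.DataFrame({
        "snp": [f"iv_{i + 1}" for i in range(scn.m)],
        "chrom": "1",
        "pos": 1 + 2_000_000 * np.arange(scn.m),
        "a1": "A", "a2": "G", "freq": maf,
        "bzx": bzx, "se_zx": se_zx, "p_zx": two_sided_p(bzx / se_zx), "n_x": scn.n_exp,
        "bzy": bzy, "se_zy": se_zy, "p_zy": two_sided_p(bzy / se_zy), "n_y": scn.n_out,
    })

    if scn.planted:
        pl = pd.DataFrame(
            scn.planted, columns=["bzx", "se_zx", "bzy", "se_zy", "chrom", "pos"])
        pl["snp"] = pl["chrom"].astype(str) + ":" + pl["pos"].astype(str)
        pl["a1"], pl["a2"], pl["freq"] = "A", "G", 0.3
        pl["p_zx"] = two_sided_p(pl["bzx"] / pl["se_zx"])
        pl["p_zy"] = two_sided_p(pl["bzy"] / pl["se_zy"])
        pl["n_x"], pl["n_y"] = scn.n_exp, scn.n_out
        rows = pd.concat([rows, pl[rows.columns]], ignore_index=True)

    rows = rows.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return HarmonizedPair(scn.exposure_trait, scn.outcome_trait, rows)


def simulate_region(scn: RegionScenario) -> tuple[SumStatsTable, SumStatsTable, LDMatrix]:
    """Draw marginal summary statistics for one region and two traits.

    Marginal z-scores follow MVN(R lambda_t, R): the mean is the LD-projected
    causal signal, the covariance the LD among null and causal variants.
    Betas are recovered on the unit-variance scale as z / sqrt(n_t); variants
    sit ``spacing_bp`` apart so window arithmetic is exact.
    """
    rng = np.random.default_rng(scn.seed)
    ld = make_ar1_ld(scn.n_snps, scn.rho)

    pos = scn.start_pos + scn.spacing_bp * np.arange(scn.n_snps)
    tables = []
    for causal, lam, n, trait in ((scn.causal_1, scn.lambda_1, scn.n1, "trait1"),
                                  (scn.causal_2, scn.lambda_2, scn.n2, "trait2")):
        mean = lam * ld.r[:, causal]
        eps = rng.standard_normal(scn.n_snps)
        if scn.rho > 0:
            # MVN(0, R) for AR(1) R via the first-order recursion
            # (exactly the Cholesky factor of R applied to eps)
            w = eps * np.sqrt(1.0 - scn.rho ** 2)
            w[0] = eps[0]
            noise = np.empty(scn.n_snps)
            acc = 0.0
            for i, wi in enumerate(w):
                acc = scn.rho * acc + wi
                noise[i] = acc
        else:
            noise = eps
        z = mean + noise
        se = np.full(scn.n_snps, 1.0 / np.sqrt(n))
        df = pd.DataFrame({
            "snp": ld.variant_ids, "chrom": scn.chrom, "pos": pos,
            "a1": "A", "a2": "G", "freq": 0.3,
            "beta": z * se, "se": se, "p": two_sided_p(z), "n": n,
        })
        tables.append(SumStatsTable(trait, df))
    return tables[0], tables[1], ld


def scenario_preset(name: str, seed: int = 0):
    """Named study-condition presets.

    ``table3_*`` plant the published causal-effect estimates with the
    published instrument counts and sample sizes; ``table2_*_pleio`` embed
    the published pleiotropic-variant effect rows, noise-free, among valid
    instruments at the corresponding causal ratio; ``coloc_shared`` /
    ``coloc_distinct`` define 1001-SNP AR(1) regions (rho = 0.9,
    non-centrality 12) with one shared, or two 200-SNP-separated, causal
    variants; ``null`` has no causal effect and no pleiotropy.
    """
    if name == "null":
        return InstrumentScenario(
            m=100, b_xy_true=0.0, n_exp=TRAIT_N["ADG"], n_out=TRAIT_N["BFT"],
            seed=seed, exposure_trait="ADG", outcome_trait="null_outcome")
    if name.startswith("table3_"):
        trait = name.removeprefix("table3_").upper()
        if trait not in TABLE3:
            raise ValueError(f"unknown preset {name!r}")
        b_xy, m = TABLE3[trait]
        return InstrumentScenario(
            m=m, b_xy_true=b_xy, n_exp=TRAIT_N["ADG"], n_out=TRAIT_N[trait],
            seed=seed, exposure_trait="ADG", outcome_trait=trait)
    if name.endswith("_pleio") and name.startswith("table2_"):
        trait = name.removeprefix("table2_").removesuffix("_pleio").upper()
        if trait not in TABLE2:
            raise ValueError(f"unknown preset {name!r}")
        b_xy, m = TABLE3[trait]
        return InstrumentScenario(
            m=m, b_xy_true=b_xy, n_exp=TRAIT_N["ADG"], n_out=TRAIT_N[trait],
            maf_range=(0.3, 0.3), noise_free=True, planted=list(TABLE2[trait]),
            seed=seed, exposure_trait="ADG", outcome_trait=trait)
    if name == "coloc_shared":
        return RegionScenario(n_snps=1001, rho=0.9, causal_1=500, causal_2=500,
                              lambda_1=12.0, lambda_2=12.0, n1=20_000, n2=20_000, seed=seed)
    if name == "coloc_distinct":
        return RegionScenario(n_snps=1001, rho=0.9, causal_1=400, causal_2=600,
                              lambda_1=12.0, lambda_2=12.0, n1=20_000, n2=20_000, seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")
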