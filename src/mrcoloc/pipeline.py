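"""End-to-end orchestration: simulate/load -> MR -> colocalization -> genes.

The pipeline is configured by a plain mapping (usually loaded from YAML),
writes only tab-delimited tables plus a JSON provenance block, and is
deterministic under a fixed seed.  Every numeric threshold has the package
default and can be overridden under ``thresholds:`` / ``coloc:`` /
``annotate:`` keys.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (AnnotationResult, GeneModel, annotate_variants,
                       load_gene_models, shared_gene_sets)
from .coloc import ColocPriors, coloc_sensitivity
from .gsmr import GsmrModel, GsmrResults, MrStudyResult, _HEIDI_COLS
from .instruments import assemble_instruments, clump, gw_filter, strength_filter
from .ld import LDMatrix
from .simulate import (InstrumentScenario, RegionScenario, identity_ld,
                       scenario_preset, simulate_instruments, simulate_region)
from .sumstats import (HarmonizedPair, SumStatsTable, harmonize,
                       meta_fixed_ivw, read_sumstats)

logger = logging.getLogger("mrcoloc")

__all__ = ["PipelineConfig", "run_pipeline", "run_preset_chain"]

_DEFAULT_THRESHOLDS = {
    "p_threshold": 5e-8,
    "clump_r2": 0.05,
    "clump_window_bp": 1_000_000,
    "f_min": 10.0,
    "heidi_alpha": 0.01,
    "min_instruments": 10,
    "family_alpha": 0.05,
    "palindromic_policy": "drop_ambiguous",
}

_DEFAULT_COLOC = {
    "half_windows": [100_000, 250_000, 500_000],
    "p1": 1e-4, "p2": 1e-4, "p12": 1e-5, "W": 0.15 ** 2,
}

_DEFAULT_ANNOTATE = {"flank_bp": 0, "coloc_flank_bp": 500_000}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, cfg: dict, out_dir=None, seed=None) -> "PipelineConfig":
        cfg = dict(cfg)
        if out_dir is not None:
            cfg["out_dir"] = out_dir
        if seed is not None:
            cfg["seed"] = seed
        if "out_dir" not in cfg:
            raise ValueError("config requires out_dir")
        thresholds = {**_DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
        unknown = set(thresholds) - set(_DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold key(s): {sorted(unknown)}")
        if not cfg.get("simulate") and not cfg.get("inputs"):
            raise ValueError("config needs a simulate: or inputs: section")
        return cls(
            out_dir=Path(cfg["out_dir"]), seed=int(cfg.get("seed", 0)),
            simulate=cfg.get("simulate") or {}, inputs=cfg.get("inputs") or {},
            thresholds=thresholds,
            coloc={**_DEFAULT_COLOC, **cfg.get("coloc", {})},
            annotate={**_DEFAULT_ANNOTATE, **cfg.get("annotate", {})})

    @classmethod
    def from_yaml(cls, path, out_dir=None, seed=None) -> "PipelineConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()),
                                out_dir=out_dir, seed=seed)


def run_preset_chain(
    pair: HarmonizedPair,
    ld: LDMatrix | None = None,
    **thresholds,
) -> GsmrResults:
    """Selection + MR chain on an already-harmonized pair.

    Convenience used both by the pipeline's simulate mode and by recovery
    studies: significance filter -> clump -> strength filter -> assemble ->
    HEIDI -> IVW with the package defaults (overridable by keyword).
    """
    th = {**_DEFAULT_THRESHOLDS, **thresholds}
    if ld is None:
        ld = identity_ld(pair.df["snp"])
    out = gw_filter(pair, th["p_threshold"])
    out = clump(out, ld, th["clump_r2"], th["clump_window_bp"])
    out = strength_filter(out, th["f_min"])
    iset = assemble_instruments(out, ld, th["min_instruments"])
    return GsmrModel(iset, th["heidi_alpha"], th["min_instruments"]).fit()


def _synthetic_gene_models(pairs: dict[str, HarmonizedPair],
                           span_bp: int = 20_000) -> list[GeneModel]:
    """Deterministic gene models tiling the simulated instrument positions.

    One gene is centred on every third instrument position so that the
    zero-flank annotation yields overlapping but non-identical per-analysis
    gene sets (a stand-in for real gene models in fully simulated runs).
    """
    positions = sorted({(row.chrom, int(row.pos))
                        for p in pairs.values()
                        for row in p.df.itertuples()})
    models = []
    for k, (chrom, pos) in enumerate(positions):
        if k % 3 == 0:
            start = max(1, pos - span_bp // 2)
            models.append(GeneModel(gene_id=f"SYNG{k:04d}", chrom=chrom,
                                    start=start, end=pos + span_bp // 2,
                                    symbol=f"SYNG{k:04d}"))
    return models


def _load_inputs(cfg: PipelineConfig):
    inp = cfg.inputs
    exposure = read_sumstats(inp["exposure"], inp.get("dialect", "cojo_ma"))
    outcomes = [read_sumstats(p, inp.get("dialect", "cojo_ma"))
                for p in inp["outcomes"]]
    ld = LDMatrix.from_file(inp["ld"]) if "ld" in inp else None
    th = cfg.thresholds
    pairs = {}
    for out in outcomes:
        pair = harmonize(exposure, out, th["palindromic_policy"])
        pairs[out.trait] = pair
    return pairs, ld


def run_pipeline(config: dict | PipelineConfig, out_dir=None, seed=None) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the provenance dict that is also written to ``run.json``.
    Output tables: ``gsmr_results.tsv`` (per-outcome causal estimates),
    ``heidi_excluded.tsv`` (pleiotropic variants), ``instruments.tsv``,
    ``coloc_results.tsv`` + ``coloc_snp_detail.tsv``, ``annotation.tsv``
    and ``venn_counts.tsv``.  On a stage failure the partial outputs are
    kept, a ``FAILED`` marker is written, and the error re-raised.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_mapping(
        config, out_dir=out_dir, seed=seed)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    provenance: dict = {
        "package": "mrcoloc", "version": __version__,
        "python": platform.python_version(), "numpy": np.__version__,
        "seed": cfg.seed, "thresholds": th, "coloc": cfg.coloc,
        "annotate": cfg.annotate, "stages": {},
    }
    stage = "setup"
    try:
        # ---- data -----------------------------------------------------------
        gene_models: list[GeneModel] | None = None
        if cfg.simulate:
            stage = "simulate"
            presets = cfg.simulate.get(
                "instrument_presets",
                ["table3_bft", "table3_lmdep", "table3_aff", "table3_nsb"])
            pairs: dict[str, HarmonizedPair] = {}
            for k, name in enumerate(presets):
                scn = scenario_preset(name, seed=cfg.seed * 131 + k)
                if not isinstance(scn, InstrumentScenario):
                    raise ValueError(f"{name} is not an instrument preset")
                pair = simulate_instruments(scn)
                pairs[pair.outcome_trait] = pair
            region_preset = cfg.simulate.get("region_preset", "coloc_shared")
            region_scn = scenario_preset(region_preset, seed=cfg.seed * 131 + 97)
            ld = None
            provenance["stages"]["simulate"] = {
                "instrument_presets": presets, "region_preset": region_preset}
        else:
            stage = "meta"
            meta_groups = cfg.inputs.get("meta")
            if meta_groups:
                for trait, paths in meta_groups.items():
                    tables = [read_sumstats(p) for p in paths]
                    merged = meta_fixed_ivw(tables, trait=trait)
                    merged_path = out / f"meta_{trait}.ma"
                    from .sumstats import write_sumstats
                    write_sumstats(merged, merged_path)
            stage = "load"
            pairs, ld = _load_inputs(cfg)
            region_scn = None
            if "gene_models" in cfg.inputs:
                gene_models = load_gene_models(cfg.inputs["gene_models"])

        # ---- MR -------------------------------------------------------------
        stage = "gsmr"
        fits: dict[str, GsmrResults] = {}
        errors: dict[str, str] = {}
        inst_frames = []
        for trait, pair in pairs.items():
            try:
                res = run_preset_chain(pair, ld, **{k: th[k] for k in th
                                                    if k not in ("family_alpha",
                                                                 "palindromic_policy")})
                fits[trait] = res
                f = res.instruments_used.records.copy()
                f.insert(0, "outcome", trait)
                inst_frames.append(f)
            except Exception as exc:
                errors[trait] = f"{type(exc).__name__}: {exc}"
                logger.error("gsmr[%s]: %s", trait, errors[trait])
        study = MrStudyResult(
            exposure_trait=next(iter(pairs.values())).exposure_trait if pairs else "exposure",
            fits=fits, bonferroni_alpha=th["family_alpha"] / max(len(pairs), 1),
            errors=errors)
        study.to_frame().to_csv(out / "gsmr_results.tsv", sep="\t", index=False,
                                float_format="%.6g")
        study.heidi_frame().to_csv(out / "heidi_excluded.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        if inst_frames:
            pd.concat(inst_frames, ignore_index=True).to_csv(
                out / "instruments.tsv", sep="\t", index=False, float_format="%.6g")
        else:
            (out / "instruments.tsv").write_text("")
        provenance["stages"]["gsmr"] = {
            "bonferroni_alpha": study.bonferroni_alpha,
            "n_outcomes": len(pairs), "errors": errors,
            "significant": study.significant}

        # ---- colocalization -------------------------------------------------
        stage = "coloc"
        priors = ColocPriors(p1=cfg.coloc["p1"], p2=cfg.coloc["p2"],
                             p12=cfg.coloc["p12"], W=cfg.coloc["W"])
        coloc_rows = []
        detail_frames = []
        if cfg.simulate and region_scn is not None:
            t1, t2, _ = simulate_region(region_scn)
            top_iv = [(region_scn.chrom,
                       region_scn.start_pos + region_scn.spacing_bp * region_scn.causal_1)]
            sens = coloc_sensitivity(t1, t2, top_iv,
                                     tuple(cfg.coloc["half_windows"]), priors)
            coloc_rows.append(sens)
        elif not cfg.simulate:
            for trait, res in fits.items():
                ivs = [(r.chrom, int(r.pos))
                       for r in fits[trait].instruments_used.records.itertuples()]
                pair = pairs[trait]
                sens = coloc_sensitivity(pair.exposure_table(), pair.outcome_table(),
                                         ivs, tuple(cfg.coloc["half_windows"]), priors)
                if len(sens):
                    sens.insert(0, "outcome", trait)
                    coloc_rows.append(sens)
        coloc_table = (pd.concat(coloc_rows, ignore_index=True)
                       if coloc_rows else pd.DataFrame())
        coloc_table.to_csv(out / "coloc_results.tsv", sep="\t", index=False,
                           float_format="%.6g")
        # per-SNP detail for the widest window of each analysis
        if cfg.simulate and region_scn is not None:
            from .coloc import build_regions, coloc_pp
            hw = max(cfg.coloc["half_windows"])
            region = build_regions(top_iv, hw)[0]
            res = coloc_pp(t1.slice_region(region.chrom, region.start, region.end),
                           t2.slice_region(region.chrom, region.start, region.end),
                           priors, region)
            detail = res.snp_detail.copy()
            top_chrom, top_pos = res.top_pos
            detail["r2_to_top"] = [
                region_scn.rho ** (2 * abs(p - top_pos) // region_scn.spacing_bp)
                for p in detail["pos"]]
            detail_frames.append(detail)
        if detail_frames:
            pd.concat(detail_frames, ignore_index=True).to_csv(
                out / "coloc_snp_detail.tsv", sep="\t", index=False, float_format="%.6g")
        else:
            (out / "coloc_snp_detail.tsv").write_text("")
        provenance["stages"]["coloc"] = {"n_rows": int(len(coloc_table))}

        # ---- annotation -----------------------------------------------------
        stage = "annotate"
        if gene_models is None:
            gene_models = _synthetic_gene_models(pairs)
            provenance["stages"]["annotate"] = {"gene_models": "synthetic"}
        ann_rows = []
        gene_sets: dict[str, set[str]] = {}
        for trait, res in fits.items():
            recs = res.instruments_used.records
            ann = annotate_variants(recs, gene_models, cfg.annotate["flank_bp"])
            names: set[str] = set()
            for vid, genes in ann.variant_genes.items():
                for g in genes:
                    names.add(g.name)
                    ann_rows.append({"outcome": trait, "snp": vid, "gene": g.name,
                                     "gene_chrom": g.chrom, "gene_start": g.start,
                                     "gene_end": g.end})
            gene_sets[trait] = names
        pd.DataFrame(ann_rows).to_csv(out / "annotation.tsv", sep="\t", index=False)
        if len(gene_sets) >= 2:
            venn = shared_gene_sets(gene_sets)
            venn.to_frame().to_csv(out / "venn_counts.tsv", sep="\t", index=False)
            provenance["stages"].setdefault("annotate", {}).update(
                {"union": len(venn.union), "core": len(venn.core),
                 "shared_fraction": venn.shared_fraction})
        else:
            (out / "venn_counts.tsv").write_text("")

        provenance["status"] = "ok"
    except Exception as exc:
        provenance["status"] = "failed"
        provenance["failed_stage"] = stage
        provenance["error"] = f"{type(exc).__name__}: {exc}"
        (out / "FAILED").write_text(f"{stage}: {provenance['error']}\n")
        (out / "run.json").write_text(json.dumps(provenance, indent=2, default=str))
        raise
    (out / "run.json").write_text(json.dumps(provenance, indent=2, default=str))
    return provenance
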