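"""Positional gene annotation and cross-analysis gene-set intersection.

Instrumental variants are mapped to genes by positional overlap with a
zero-bp flank (a variant must fall inside the gene body), while colocalized
top variants use a +-500 kb proximity search; both are the same interval
query with a different ``flank_bp``.  Gene sets from the per-outcome
analyses are intersected into an exclusive Venn partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("mrcoloc")

__all__ = [
    "GeneModel",
    "AnnotationResult",
    "load_gene_models",
    "write_gene_models",
    "annotate_variants",
    "shared_gene_sets",
    "ld_between",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene on 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    symbol: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")

    @property
    def name(self) -> str:
        return self.symbol or self.gene_id


class GeneModelParseError(ValueError):
    pass


def _sorted(models: list[GeneModel]) -> list[GeneModel]:
    return sorted(models, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))


def load_gene_models(
    path: str | Path,
    fmt: str | None = None,
    approved_symbols: set[str] | None = None,
) -> list[GeneModel]:
    """Read gene models from GFF3 (rows of type ``gene``), BED or TSV.

    BED intervals (0-based half-open) are converted to 1-based inclusive.
    Entries without a symbol are retained (flagged by ``symbol is None``);
    when ``approved_symbols`` is given, genes whose symbol is absent from
    the allow-list are dropped with a logged count.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".gff": "gff3", ".gff3": "gff3", ".bed": "bed", ".tsv": "tsv"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer gene-model format from {path.name!r}")

    models: list[GeneModel] = []
    if fmt == "gff3":
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
        for g in db.features_of_type("gene"):
            gid = g.attributes.get("ID", [g.id])[0]
            sym = (g.attributes.get("Name") or g.attributes.get("gene_name") or [None])[0]
            models.append(GeneModel(gene_id=str(gid).removeprefix("gene:"),
                                    chrom=str(g.seqid).removeprefix("chr"),
                                    start=g.start, end=g.end, symbol=sym,
                                    strand=g.strand or "."))
    elif fmt == "bed":
        for ln, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GeneModelParseError(f"{path.name}:{ln}: fewer than 4 BED columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GeneModelParseError(f"{path.name}:{ln}: {exc}") from None
            strand = parts[5] if len(parts) >= 6 else "."
            models.append(GeneModel(gene_id=parts[3],
                                    chrom=parts[0].removeprefix("chr"),
                                    start=start0 + 1, end=end0,
                                    symbol=parts[3], strand=strand))
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        need = {"gene_id", "symbol", "chrom", "start", "end", "strand"}
        if not need.issubset(df.columns):
            raise GeneModelParseError(
                f"{path.name}: TSV gene models need columns {sorted(need)}")
        for _, row in df.iterrows():
            sym = row["symbol"]
            models.append(GeneModel(
                gene_id=str(row["gene_id"]), chrom=str(row["chrom"]),
                start=int(row["start"]), end=int(row["end"]),
                symbol=None if pd.isna(sym) else str(sym), strand=str(row["strand"])))
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")

    n_nosym = sum(1 for g in models if g.symbol is None)
    if n_nosym:
        logger.info("load_gene_models: %d gene(s) without a symbol retained", n_nosym)
    if approved_symbols is not None:
        before = len(models)
        models = [g for g in models if g.symbol in approved_symbols]
        logger.info("load_gene_models: allow-list kept %d/%d genes", len(models), before)
    return _sorted(models)


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"gene_id": g.gene_id, "symbol": g.symbol, "chrom": g.chrom,
          "start": g.start, "end": g.end, "strand": g.strand} for g in _sorted(models)])
    df.to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationResult:
    """Variant-to-gene assignments and/or gene-set intersection counts.

    ``variant_genes`` maps variant id to the (position-sorted) overlapping
    genes; ``gene_sets`` holds the per-analysis gene-name sets;
    ``venn_counts`` maps each non-empty analysis subset (frozenset of names)
    to the number of genes in exactly those analyses, so the counts
    partition the union.
    """

    variant_genes: dict[str, list[GeneModel]] = field(default_factory=dict)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    venn_counts: dict[frozenset, int] = field(default_factory=dict)
    shared_fraction: float | None = None

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.gene_sets.values():
            out |= s
        return out

    @property
    def core(self) -> set[str]:
        sets = list(self.gene_sets.values())
        if not sets:
            return set()
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"analyses": "+".join(sorted(k)), "n_analyses": len(k), "count": v}
                for k, v in sorted(self.venn_counts.items(),
                                   key=lambda kv: (len(kv[0]), sorted(kv[0])))]
        return pd.DataFrame(rows)


def annotate_variants(
    variants,
    genes: list[GeneModel],
    flank_bp: int = 0,
) -> AnnotationResult:
    """Map each variant to the genes overlapping pos within ``flank_bp``.

    ``variants`` is a DataFrame with ``snp``/``chrom``/``pos`` columns or an
    iterable of (id, chrom, pos).  A variant v maps to gene g iff
    g.start - flank_bp <= v.pos <= g.end + flank_bp on the same chromosome.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if isinstance(variants, pd.DataFrame):
        triples = list(zip(variants["snp"], variants["chrom"], variants["pos"]))
    else:
        triples = [(str(i), str(c), int(p)) for i, c, p in variants]

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open interval [start - flank, end + flank + 1) covers the
        # 1-based inclusive window
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - flank_bp, g.end + flank_bp + 1, g)

    result = AnnotationResult()
    for vid, chrom, pos in triples:
        tree = trees.get(str(chrom))
        hits = [iv.data for iv in tree[int(pos)]] if tree is not None else []
        result.variant_genes[vid] = _sorted(hits)
    return result


def shared_gene_sets(sets: dict[str, set[str]]) -> AnnotationResult:
    """Exclusive Venn partition and shared fraction of >= 2 gene sets.

    ``shared_fraction`` is |all-way intersection| / |union|.
    """
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    names = sorted(sets)
    result = AnnotationResult(gene_sets={k: set(v) for k, v in sets.items()})
    union = result.union
    membership: dict[str, frozenset] = {
        g: frozenset(n for n in names if g in sets[n]) for g in union}
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
    for m in membership.values():
        counts[m] += 1
    result.venn_counts = counts
    result.shared_fraction = (len(result.core) / len(union)) if union else 0.0
    return result


def ld_between(ld, a: str, b: str) -> float:
    """Squared LD correlation between two variants of an LD matrix."""
    return ld.r2_between(a, b)
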