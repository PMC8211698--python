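"""Readers and writers for the plain-text formats the pipeline consumes.

Every reader returns one of the containers in :mod:`bodymap.datatypes` and
enforces its invariants on load; every ``write_* / read_*`` pair round-trips
field-for-field.  Interval inputs are BED-style 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ConservationScores,
    ExpressionMatrix,
    FormatError,
    GenomeBinTable,
    IntervalSet,
    OrthologMap,
    PeiTable,
    PhyloTree,
    SampleMetadata,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrix + metadata

def read_expression_table(path, metadata_path=None,
                          class_path=None) -> tuple[ExpressionMatrix, SampleMetadata | None]:
    """Read a TSV expression matrix (first column gene id, header samples).

    ``class_path`` may point to a two-column TSV (gene_id, transcript_class);
    absent a class table every gene defaults to PCG.  When ``metadata_path``
    is given the sample sets of matrix and metadata are cross-validated.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression cell in {path}: {exc}") from exc
    if class_path is not None:
        cls = pd.read_csv(class_path, sep="\t", index_col=0).iloc[:, 0]
        missing = values.index.difference(cls.index)
        if len(missing):
            raise FormatError(f"genes missing from class table: {list(missing[:10])}")
        classes = cls.reindex(values.index)
    else:
        classes = pd.Series("PCG", index=values.index)
    expr = ExpressionMatrix(values, classes)
    meta = None
    if metadata_path is not None:
        meta = read_sample_metadata(metadata_path)
        meta.cross_validate(expr)
    return expr, meta


def write_expression_table(expr: ExpressionMatrix, path,
                           class_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
    if class_path is not None:
        expr.transcript_class.rename("transcript_class").to_csv(
            class_path, sep="\t", index_label="gene_id")


def read_sample_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome bins / intervals

def read_genome_bins(path) -> GenomeBinTable:
    """Read a per-bin structure table: chrom,start,end,x,y,z[,compartment,gc,gene_count]."""
    return GenomeBinTable(pd.read_csv(path, sep="\t"))


def write_genome_bins(bins: GenomeBinTable, path) -> None:
    bins.table.to_csv(path, sep="\t", index=False)


def read_intervals_bed(path) -> IntervalSet:
    """Read a 3+ column BED (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError("BED requires at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return IntervalSet(df)


def write_intervals_bed(ivs: IntervalSet, path) -> None:
    ivs.table.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# PEI tables

def read_pei_table(path, resolution: int = 20_000) -> PeiTable:
    pei = PeiTable(pd.read_csv(path, sep="\t"), resolution=resolution)
    if pei.n_collapsed:
        logger.info("collapsed %d duplicate PEI rows from %s", pei.n_collapsed, path)
    return pei


def write_pei_table(pei: PeiTable, path) -> None:
    pei.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees, orthologs, conservation

def read_tree_newick(path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_tree_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


def read_orthologs(path) -> OrthologMap:
    return OrthologMap(pd.read_csv(path, sep="\t"))


def write_orthologs(om: OrthologMap, path) -> None:
    om.table.to_csv(path, sep="\t", index=False)


def read_conservation(path) -> ConservationScores:
    return ConservationScores(pd.read_csv(path, sep="\t"))


def write_conservation(cs: ConservationScores, path) -> None:
    cs.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# validation dispatch (CLI `bodymap validate`)

_VALIDATORS = {
    "expr": lambda p: read_expression_table(p)[0],
    "bins": read_genome_bins,
    "bed": read_intervals_bed,
    "pei": read_pei_table,
    "tree": read_tree_newick,
    "orthologs": read_orthologs,
    "conservation": read_conservation,
}


def validate_file(path, fmt: str) -> str:
    """Parse ``path`` as ``fmt`` and return a one-line report; raise on failure."""
    if fmt not in _VALIDATORS:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_VALIDATORS)}")
    obj = _VALIDATORS[fmt](path)
    if isinstance(obj, ExpressionMatrix):
        return f"OK expr: {obj.values.shape[0]} genes x {obj.values.shape[1]} samples"
    if isinstance(obj, GenomeBinTable):
        return f"OK bins: {len(obj)} bins, width {obj.bin_width}"
    if isinstance(obj, IntervalSet):
        return f"OK bed: {len(obj)} intervals"
    if isinstance(obj, PeiTable):
        return f"OK pei: {len(obj.table)} interactions, {len(obj.species())} species"
    if isinstance(obj, PhyloTree):
        um = "ultrametric" if obj.ultrametric else "non-ultrametric"
        return f"OK tree: {len(obj.leaf_labels)} leaves, {um}"
    if isinstance(obj, OrthologMap):
        return f"OK orthologs: {len(obj.table)} families x {len(obj.species)} species"
    if isinstance(obj, ConservationScores):
        return f"OK conservation: {len(obj.table)} genes"
    return "OK"
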