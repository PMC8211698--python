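"""Core in-memory containers shared by every analysis stage.

The substrate of nearly every stage is a genes x samples TPM table
(:class:`ExpressionMatrix`) plus per-sample metadata.  3D genome analyses
operate on fixed-width genomic bins carrying spatial coordinates and
chromatin annotations; comparative analyses tie single-copy ortholog
expression to a timetree.

All genomic coordinates are 0-based half-open throughout the package;
1-based inputs must be converted at the I/O boundary.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

TRANSCRIPT_CLASSES = ("PCG", "TUCP", "lncRNA", "circRNA", "miRNA")

#: Per-class TPM detection thresholds: a transcript counts as detected when
#: it reaches the threshold in at least one sample (miRNAs are quantified on
#: a different library type and use a higher cut-off; circRNAs a lower one).
DETECTION_THRESHOLDS = {
    "PCG": 0.1,
    "TUCP": 0.1,
    "lncRNA": 0.1,
    "circRNA": 0.05,
    "miRNA": 1.0,
}


class FormatError(ValueError):
    """Raised when an on-disk table violates its schema or an invariant."""


def _check_unique(values, what: str) -> None:
    values = pd.Index(values)
    if values.has_duplicates:
        dups = sorted(set(values[values.duplicated()]))
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix in TPM with per-gene class labels."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    transcript_class: pd.Series  # gene id -> class label

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression values must be finite")
        if (arr < 0).any():
            raise FormatError("expression values must be non-negative")
        self.transcript_class = self.transcript_class.reindex(self.values.index)
        if self.transcript_class.isna().any():
            missing = list(self.values.index[self.transcript_class.isna()])
            raise FormatError(f"genes without transcript class: {missing[:10]}")
        bad = set(self.transcript_class) - set(TRANSCRIPT_CLASSES)
        if bad:
            raise FormatError(f"unknown transcript class labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def tissue_means(self, metadata: "SampleMetadata") -> pd.DataFrame:
        """Average replicates within each tissue (genes x tissues)."""
        tissue_of = metadata.table.set_index("sample_id")["tissue"]
        groups = tissue_of.reindex(self.sample_ids)
        return self.values.T.groupby(groups.to_numpy()).mean().T

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        return ExpressionMatrix(self.values.loc[genes],
                                self.transcript_class.loc[genes])


@dataclass
class SampleMetadata:
    """One row per sample: tissue, species, replicate and optional group."""

    table: pd.DataFrame  # columns: sample_id, tissue, species, replicate[, group]

    REQUIRED = ("sample_id", "tissue", "species", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        _check_unique(self.table["sample_id"], "sample ids in metadata")
        triple = self.table[["tissue", "species", "replicate"]]
        if triple.duplicated().any():
            dups = triple[triple.duplicated()].to_records(index=False).tolist()
            raise FormatError(f"duplicate (tissue, species, replicate): {dups}")
        if (self.table["replicate"].to_numpy() < 1).any():
            raise FormatError("replicate indices must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def cross_validate(self, expr: ExpressionMatrix) -> None:
        """Require metadata samples == matrix samples, naming offenders."""
        meta = set(self.sample_ids)
        mat = set(expr.sample_ids)
        if meta != mat:
            raise FormatError(
                "metadata/matrix sample mismatch: "
                f"missing from metadata {sorted(mat - meta)}, "
                f"missing from matrix {sorted(meta - mat)}")


@dataclass
class GenomeBinTable:
    """Fixed-width genomic bins with 3D coordinates and chromatin annotation.

    Columns: chrom, start, end, x, y, z and optionally compartment
    ({A, B, unassigned}), gc (fraction) and gene_count.  Bin width must be
    constant within one structure.
    """

    table: pd.DataFrame
    bin_width: int = field(init=False)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "start", "end", "x", "y", "z"):
            if col not in t.columns:
                raise FormatError(f"bin table missing column {col!r}")
        if (t["end"].to_numpy() <= t["start"].to_numpy()).any():
            raise FormatError("bin end must exceed start (0-based half-open)")
        widths = np.unique(t["end"].to_numpy() - t["start"].to_numpy())
        if len(widths) > 1:
            raise FormatError(f"mixed bin width: {widths.tolist()}")
        self.bin_width = int(widths[0])
        if "compartment" not in t.columns:
            t = t.assign(compartment="unassigned")
        bad = set(t["compartment"]) - {"A", "B", "unassigned"}
        if bad:
            raise FormatError(f"unknown compartment labels: {sorted(bad)}")
        if "gc" in t.columns:
            gc = t["gc"].to_numpy(dtype=float)
            ok = np.isnan(gc) | ((gc >= 0) & (gc <= 1))
            if not ok.all():
                raise FormatError("gc must lie in [0, 1]")
        self.table = (t.sort_values(["chrom", "start"], kind="mergesort")
                      .reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    def coords(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def require(self, column: str) -> pd.Series:
        """Fail fast when an optional annotation column is absent."""
        if column not in self.table.columns:
            raise FormatError(f"bin table lacks required column {column!r}")
        return self.table[column]


@dataclass
class IntervalSet:
    """Sorted genomic intervals (chrom, start, end, name), 0-based half-open."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "start", "end"):
            if col not in t.columns:
                raise FormatError(f"interval table missing column {col!r}")
        if "name" not in t.columns:
            t = t.assign(name=[f"iv{i}" for i in range(len(t))])
        if (t["end"].to_numpy() <= t["start"].to_numpy()).any():
            raise FormatError("interval end must exceed start")
        if t[["chrom", "start", "end", "name"]].duplicated().any():
            raise FormatError("duplicate intervals")
        self.table = (t[["chrom", "start", "end", "name"]]
                      .sort_values(["chrom", "start", "end"], kind="mergesort")
                      .reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PeiTable:
    """Promoter-enhancer interactions per species at a fixed bin resolution.

    Bins are encoded as resolution-agnostic ``"chrom:start"`` strings.
    Duplicate (species, gene, enhancer bin) rows are collapsed on load.
    """

    table: pd.DataFrame  # columns: species, gene_id, promoter_bin, enhancer_bin
    resolution: int = 20_000
    n_collapsed: int = 0

    REQUIRED = ("species", "gene_id", "promoter_bin", "enhancer_bin")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"PEI table missing required columns: {missing}")
        if self.resolution <= 0:
            raise FormatError("PEI resolution must be positive")
        before = len(self.table)
        self.table = (self.table[list(self.REQUIRED)]
                      .drop_duplicates(["species", "gene_id", "enhancer_bin"])
                      .reset_index(drop=True))
        self.n_collapsed = before - len(self.table)

    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def counts(self) -> pd.DataFrame:
        """Distinct enhancer bins per (gene, species); NaN where a gene has
        no row for a species (callers decide whether absence means 0)."""
        return (self.table.groupby(["gene_id", "species"])["enhancer_bin"]
                .nunique().unstack())


@dataclass
class PhyloTree:
    """Rooted species tree with branch lengths in millions of years."""

    tree: dendropy.Tree
    ultrametric: bool = field(init=False)

    ULTRAMETRIC_RTOL = 1e-6

    def __post_init__(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length: {edge.length}")
        depths = self._leaf_depths()
        dmax = max(depths.values())
        self.ultrametric = bool(
            dmax == 0
            or max(depths.values()) - min(depths.values()) <= self.ULTRAMETRIC_RTOL * dmax)
        if not self.ultrametric:
            warnings.warn("tree is not ultrametric; divergence times are "
                          "half path lengths and may be asymmetric in depth",
                          stacklevel=2)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"unparseable newick: {exc}") from exc
        return cls(tree)

    def _leaf_depths(self) -> dict[str, float]:
        out = {}
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def distance_matrix(self) -> pd.DataFrame:
        """Pairwise patristic (path-length) distances between leaves."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = self.leaf_labels
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for a in labels:
            for b in labels:
                if a != b:
                    out.loc[a, b] = pdm.patristic_distance(taxa[a], taxa[b])
        return out

    def divergence_times(self) -> pd.DataFrame:
        """Pairwise divergence time = half the leaf-to-leaf path length."""
        return self.distance_matrix() / 2.0

    def shared_path_matrix(self) -> pd.DataFrame:
        """Shared root-to-tip path length for each leaf pair (BM covariance
        structure up to the diffusion rate)."""
        depths = self._leaf_depths()
        labels = self.leaf_labels
        dist = self.distance_matrix()
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for a in labels:
            for b in labels:
                out.loc[a, b] = 0.5 * (depths[a] + depths[b] - dist.loc[a, b])
        return out

    def leaf_depths(self) -> pd.Series:
        d = self._leaf_depths()
        return pd.Series(d, index=self.leaf_labels)

    def terminal_branch_length(self, species: str) -> float:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == species:
                return float(leaf.edge.length or 0.0)
        raise KeyError(f"{species!r} is not a leaf of the tree")

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


@dataclass
class OrthologMap:
    """Single-copy ortholog table: one gene-id column per species."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise FormatError("ortholog map has missing cells")
        for col in self.table.columns:
            _check_unique(self.table[col], f"gene ids in species {col!r}")

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    def genes_for(self, species: str) -> pd.Series:
        return self.table[species]


@dataclass
class ConservationScores:
    """Per-gene nucleotide conservation: phastCons in [0,1] and phyloP."""

    table: pd.DataFrame  # columns: gene_id, phastcons, phylop

    def __post_init__(self) -> None:
        for col in ("gene_id", "phastcons", "phylop"):
            if col not in self.table.columns:
                raise FormatError(f"conservation table missing column {col!r}")
        _check_unique(self.table["gene_id"], "gene ids in conservation table")
        pc = self.table["phastcons"].to_numpy(dtype=float)
        if ((pc < 0) | (pc > 1)).any():
            raise FormatError("phastCons scores must lie in [0, 1]")
        self.table = self.table.reset_index(drop=True)


@dataclass
class SignatureMatrix:
    """Marker genes x cell types mean reference expression (linear TPM)."""

    values: pd.DataFrame  # index = marker genes, columns = cell types
    marker_stats: pd.DataFrame | None = None  # per-marker selection statistics

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "marker genes")
        _check_unique(self.values.columns, "cell types")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any() or not np.all(np.isfinite(arr)):
            raise FormatError("signature entries must be finite and >= 0")
        if (arr.sum(axis=1) == 0).any():
            raise FormatError("signature contains an all-zero marker row")

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns
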