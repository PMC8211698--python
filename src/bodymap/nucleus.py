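"""Radial analysis of reconstructed 3D genome structures.

The nuclear center is the unweighted centroid of all bin coordinates, so
every radial quantity is invariant under rigid rotation and translation of
the structure.  Analyses: per-chromosome radial position versus sequence
features, equal-width radial shells with compartment-A fractions, and a
binomial enrichment test for within-TAD co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenomeBinTable, IntervalSet, SampleMetadata


@dataclass
class RadialProfile:
    center: np.ndarray
    distances: pd.Series            # per-bin distance to the center
    relative: pd.Series             # distance / max distance, in [0, 1]
    per_chromosome: pd.DataFrame    # mean distance, gc, gene density per chrom
    correlations: pd.DataFrame      # feature -> spearman_r, p (vs chrom mean distance)


def radial_profile(bins: GenomeBinTable,
                   exclude_chroms: tuple[str, ...] = ("chrX", "X")) -> RadialProfile:
    """Per-chromosome radial position and its correlation with GC/gene density.

    The X chromosome is excluded by default (X inactivation dominates its
    positioning).  Correlations are Spearman over chromosomes, two-sided p.
    """
    t = bins.table[~bins.table["chrom"].isin(exclude_chroms)].reset_index(drop=True)
    if len(t) == 0:
        raise ValueError("no bins left after chromosome exclusion")
    xyz = t[["x", "y", "z"]].to_numpy(dtype=float)
    center = xyz.mean(axis=0)
    dist = np.linalg.norm(xyz - center, axis=1)
    dmax = dist.max()
    if dmax == 0:
        raise ValueError("all bins coincident; radial profile undefined")
    rel = dist / dmax

    per = pd.DataFrame({"chrom": t["chrom"], "distance": dist})
    agg = {"distance": ("distance", "mean")}
    if "gc" in t.columns:
        per["gc"] = t["gc"]
        agg["gc"] = ("gc", "mean")
    if "gene_count" in t.columns:
        per["gene_count"] = t["gene_count"]
        agg["gene_density"] = ("gene_count", "mean")
    chrom_stats = per.groupby("chrom").agg(**agg)

    corr_rows = {}
    for feature in [c for c in chrom_stats.columns if c != "distance"]:
        if len(chrom_stats) < 3 or chrom_stats[feature].std() == 0:
            corr_rows[feature] = {"spearman_r": float("nan"), "p": float("nan")}
            continue
        r, p = stats.spearmanr(chrom_stats["distance"], chrom_stats[feature])
        corr_rows[feature] = {"spearman_r": float(r), "p": float(p)}
    correlations = pd.DataFrame(corr_rows).T
    return RadialProfile(center, pd.Series(dist), pd.Series(rel),
                         chrom_stats, correlations)


@dataclass
class ShellProfile:
    shells: pd.DataFrame   # midpoint, n_bins, a_fraction, included per shell
    spearman_r: float      # A fraction vs shell midpoint over included shells
    p: float
    n_shells: int
    min_bins: int


def shell_profile(bins: GenomeBinTable, n_shells: int = 20,
                  min_bins: int = 250, equal_volume: bool = False,
                  exclude_chroms: tuple[str, ...] = ("chrX", "X")) -> ShellProfile:
    """Compartment-A fraction across equal-width radial shells.

    The unit interval of relative distance is split into ``n_shells`` equal
    radial widths (``equal_volume=True`` uses equal-volume radii instead);
    shells with fewer than ``min_bins`` labeled bins are excluded from the
    correlation.  Spearman r relates per-shell A fraction to shell midpoint.
    """
    t = bins.table[~bins.table["chrom"].isin(exclude_chroms)]
    labeled = t[t["compartment"].isin(["A", "B"])].reset_index(drop=True)
    if len(labeled) == 0:
        raise ValueError("no compartment-labeled bins")
    xyz = t[["x", "y", "z"]].to_numpy(dtype=float)
    center = xyz.mean(axis=0)
    lab_xyz = labeled[["x", "y", "z"]].to_numpy(dtype=float)
    dist = np.linalg.norm(lab_xyz - center, axis=1)
    rel = dist / np.linalg.norm(xyz - center, axis=1).max()

    if equal_volume:
        edges = (np.arange(n_shells + 1) / n_shells) ** (1.0 / 3.0)
    else:
        edges = np.arange(n_shells + 1) / n_shells
    idx = np.clip(np.searchsorted(edges, rel, side="right") - 1, 0, n_shells - 1)
    is_a = (labeled["compartment"] == "A").to_numpy()

    n_bins = np.bincount(idx, minlength=n_shells)
    n_a = np.bincount(idx, weights=is_a, minlength=n_shells)
    with np.errstate(invalid="ignore"):
        a_frac = np.where(n_bins > 0, n_a / np.maximum(n_bins, 1), np.nan)
    mid = (edges[:-1] + edges[1:]) / 2.0
    included = n_bins >= min_bins
    shells = pd.DataFrame({"midpoint": mid, "n_bins": n_bins,
                           "a_fraction": a_frac, "included": included})
    if included.sum() < 3 or np.nanstd(a_frac[included]) == 0:
        return ShellProfile(shells, float("nan"), float("nan"), n_shells, min_bins)
    r, p = stats.spearmanr(mid[included], a_frac[included])
    return ShellProfile(shells, float(r), float(p), n_shells, min_bins)


@dataclass
class CoexpressionTest:
    cutoff: float          # Pearson-r co-expression cut-off
    n_within_tad: int      # within-TAD gene pairs (n)
    k_coexpressed: int     # co-expressed within-TAD pairs (k)
    p0: float              # global co-expressed fraction (same-chromosome pairs)
    p_value: float         # one-sided binomial P(X >= k | n, p0)
    enrichment: float      # (k/n) / p0


def assign_genes_to_tads(gene_positions: pd.DataFrame,
                         tads: IntervalSet) -> pd.Series:
    """Map genes to TADs by midpoint within [start, end); NaN when outside."""
    out = pd.Series(pd.NA, index=gene_positions["gene_id"], dtype="object")
    mid = ((gene_positions["start"] + gene_positions["end"]) // 2).to_numpy()
    for chrom, sub in tads.table.groupby("chrom"):
        sel = (gene_positions["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["name"].to_numpy()
        pos = mid[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        vals = np.where(ok, names[np.clip(j, 0, None)], None)
        out.loc[gene_positions.loc[sel, "gene_id"]] = vals
    return out


def tad_coexpression_test(expr: ExpressionMatrix,
                          gene_positions: pd.DataFrame, tads: IntervalSet,
                          metadata: SampleMetadata | None = None,
                          cutoff: float = 0.7) -> CoexpressionTest:
    """Binomial test of within-TAD co-expression against the chromosome-wide rate.

    A gene pair is co-expressed when the Pearson correlation of their
    tissue-mean log2(TPM + 1) profiles reaches ``cutoff``.  The background
    rate p0 is the co-expressed fraction among all same-chromosome pairs;
    the within-TAD co-expressed count k out of n pairs is tested one-sided
    against Binomial(n, p0).
    """
    profiles = expr.tissue_means(metadata) if metadata is not None else expr.values
    if profiles.shape[1] < 2:
        raise ValueError("co-expression needs >= 2 tissues")
    gp = gene_positions[gene_positions["gene_id"].isin(profiles.index)]
    tad_of = assign_genes_to_tads(gp, tads)

    log_prof = np.log2(profiles.loc[gp["gene_id"]].to_numpy(dtype=float) + 1.0)
    sd = log_prof.std(axis=1)
    keep = sd > 0
    gp = gp[keep].reset_index(drop=True)
    log_prof = log_prof[keep]
    tad_of = tad_of[gp["gene_id"]]

    z = (log_prof - log_prof.mean(axis=1, keepdims=True)) / log_prof.std(axis=1, keepdims=True)
    corr = (z @ z.T) / z.shape[1]
    co = corr >= cutoff

    chroms = gp["chrom"].to_numpy()
    same_chrom = chroms[:, None] == chroms[None, :]
    upper = np.triu(np.ones_like(co, dtype=bool), k=1)

    bg_mask = same_chrom & upper
    if bg_mask.sum() == 0:
        raise ValueError("no same-chromosome gene pairs for the background rate")
    p0 = float(co[bg_mask].mean())

    tad_labels = tad_of.to_numpy()
    has_tad = pd.notna(tad_labels)
    same_tad = has_tad[:, None] & has_tad[None, :] & (tad_labels[:, None] == tad_labels[None, :])
    within = same_tad & upper
    n = int(within.sum())
    if n == 0:
        raise ValueError("no within-TAD gene pairs")
    k = int(co[within].sum())
    p_value = float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    enrichment = (k / n) / p0 if p0 > 0 else float("inf")
    return CoexpressionTest(cutoff, n, k, p0, p_value, enrichment)
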