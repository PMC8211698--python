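"""Atlas-level expression statistics.

Detection fractions per transcript class, the tau tissue-specificity score,
transcriptome complexity (expression mass captured by the most abundant
transcripts), tissue-specific / ubiquitous gene sets, and marker-gene
correlation association.

tau for a gene with per-tissue mean profile x over n tissues is

    tau = sum_i (1 - x_i / max(x)) / (n - 1)

so a uniform profile scores 0 and a single-tissue profile scores 1.
Replicates are averaged within tissue first so unequal replicate numbers do
not bias the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DETECTION_THRESHOLDS,
    ExpressionMatrix,
    SampleMetadata,
)

#: Published class-specific tau cut-offs: specific when tau >= 0.75,
#: ubiquitous when tau <= 0.30.
TAU_SPECIFIC = 0.75
TAU_UBIQUITOUS = 0.30


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class DetectionResult:
    detected: pd.Series             # gene -> bool (any sample >= class threshold)
    fraction_by_tissue: pd.DataFrame  # tissue x class detected fraction
    thresholds: dict[str, float]


def detect_transcribed(expr: ExpressionMatrix,
                       metadata: SampleMetadata | None = None,
                       thresholds: dict[str, float] | None = None,
                       strict: bool = False) -> DetectionResult:
    """Flag transcribed genes and per-tissue detected fractions per class.

    A gene is detected when its maximum over the relevant samples reaches
    the class threshold (``>=`` by default; ``strict=True`` switches to
    ``>``).  Per-tissue fractions use only that tissue's samples.
    """
    thresholds = dict(DETECTION_THRESHOLDS if thresholds is None else thresholds)
    if any(v <= 0 for v in thresholds.values()):
        raise ValueError("detection thresholds must be positive")
    classes = expr.transcript_class
    unknown = set(classes) - set(thresholds)
    if unknown:
        raise ValueError(f"no threshold for transcript class(es): {sorted(unknown)}")
    thr = classes.map(thresholds).to_numpy(dtype=float)

    def _hit(maxima: np.ndarray) -> np.ndarray:
        return maxima > thr if strict else maxima >= thr

    detected = pd.Series(_hit(expr.values.to_numpy().max(axis=1)),
                         index=expr.gene_ids)
    if metadata is None:
        groups = {"all": list(expr.sample_ids)}
    else:
        metadata.cross_validate(expr)
        groups = {t: list(g["sample_id"])
                  for t, g in metadata.table.groupby("tissue")}
    rows = {}
    for tissue, samples in groups.items():
        maxima = expr.values[samples].to_numpy().max(axis=1)
        hits = pd.Series(_hit(maxima), index=expr.gene_ids)
        rows[tissue] = hits.groupby(classes).mean()
    fraction = pd.DataFrame(rows).T.fillna(0.0)
    return DetectionResult(detected, fraction, thresholds)


@dataclass
class SpecificityResult:
    tau: pd.Series            # gene -> tau in [0,1]; NaN when undetected everywhere
    tissue_means: pd.DataFrame  # per-tissue mean profile used
    log_transformed: bool


def tau_from_profile(profile: np.ndarray) -> float:
    """tau of a single non-negative per-tissue profile (NaN if all zero)."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be 1-D with >= 2 tissues")
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def compute_tau(expr: ExpressionMatrix, metadata: SampleMetadata,
                log_transform: bool = False) -> SpecificityResult:
    """Per-gene tau on replicate-averaged tissue profiles.

    Works on linear TPM by default; ``log_transform`` switches the profile
    to log2(TPM + 1) before scaling.
    """
    means = expr.tissue_means(metadata)
    if means.shape[1] < 2:
        raise ValueError("tau requires >= 2 tissues")
    profile = np.log2(means.to_numpy() + 1.0) if log_transform else means.to_numpy()
    m = profile.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = profile / m[:, None]
    tau = (1.0 - scaled).sum(axis=1) / (profile.shape[1] - 1)
    tau = pd.Series(np.where(m > 0, tau, np.nan), index=expr.gene_ids)
    return SpecificityResult(tau, means, log_transform)


@dataclass
class SpecificSets:
    by_tissue: dict[str, list[str]]  # tissue -> specific genes (tau >= cut-off)
    ubiquitous: list[str]            # tau <= ubiquitous cut-off
    tau_specific: float
    tau_ubiquitous: float


def specific_gene_sets(spec: SpecificityResult,
                       tau_specific: float = TAU_SPECIFIC,
                       tau_ubiquitous: float = TAU_UBIQUITOUS) -> SpecificSets:
    """Assign specific genes to their maximal-expression tissue."""
    if not 0 <= tau_ubiquitous < tau_specific <= 1:
        raise ValueError("require 0 <= tau_ubiquitous < tau_specific <= 1")
    tau = spec.tau
    defined = tau.dropna()
    specific = defined[defined >= tau_specific].index
    home = spec.tissue_means.loc[specific].idxmax(axis=1)
    by_tissue: dict[str, list[str]] = {t: [] for t in spec.tissue_means.columns}
    for gene, tissue in home.items():
        by_tissue[tissue].append(gene)
    ubiquitous = list(defined[defined <= tau_ubiquitous].index)
    return SpecificSets(by_tissue, ubiquitous, tau_specific, tau_ubiquitous)


@dataclass
class ComplexityResult:
    complexity: pd.Series   # tissue -> fraction in (0,1]; NaN when nothing transcribed
    k: pd.Series            # tissue -> number of top transcripts used
    n_transcribed: pd.Series


def compute_complexity(expr: ExpressionMatrix, metadata: SampleMetadata,
                       top_fraction: float = 0.005,
                       thresholds: dict[str, float] | None = None) -> ComplexityResult:
    """Fraction of per-tissue expression mass held by the top transcripts.

    Per tissue (replicates averaged) the transcribed transcripts are those
    whose tissue-mean TPM reaches the class detection threshold; with N of
    them, k = max(1, round(top_fraction x N)) and the complexity is the TPM
    mass of the k most abundant over the total transcribed mass.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    thresholds = dict(DETECTION_THRESHOLDS if thresholds is None else thresholds)
    thr = expr.transcript_class.map(thresholds).to_numpy(dtype=float)
    means = expr.tissue_means(metadata)
    comp, ks, ns = {}, {}, {}
    for tissue in means.columns:
        x = means[tissue].to_numpy()
        x = x[x >= thr]
        n = len(x)
        if n == 0:
            comp[tissue], ks[tissue], ns[tissue] = float("nan"), 0, 0
            continue
        k = max(1, _round_half_away(top_fraction * n))
        top = np.sort(x)[::-1][:k]
        comp[tissue] = float(top.sum() / x.sum())
        ks[tissue], ns[tissue] = k, n
    return ComplexityResult(pd.Series(comp), pd.Series(ks), pd.Series(ns))


@dataclass
class MarkerAssociation:
    marker: str
    r: pd.Series              # gene -> Pearson r with marker profile
    p: pd.Series              # two-sided p per gene
    specific_set: list[str]   # top decile by r
    excluded: list[str]       # zero-variance genes


def marker_correlation(expr: ExpressionMatrix, metadata: SampleMetadata,
                       marker_gene: str,
                       top_fraction: float = 0.10) -> MarkerAssociation:
    """Correlate every gene with a marker across tissue-mean profiles.

    The marker-specific set is the top ``top_fraction`` (default decile,
    size ceil(fraction x eligible)) of genes ranked by Pearson r.
    """
    if marker_gene not in expr.gene_ids:
        raise KeyError(f"marker {marker_gene!r} absent from matrix")
    means = expr.tissue_means(metadata)
    marker = means.loc[marker_gene].to_numpy(dtype=float)
    if np.std(marker) == 0:
        raise ValueError(f"marker {marker_gene!r} is constant across tissues")
    mat = means.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    eligible = (sd > 0) & (means.index != marker_gene)
    excluded = list(means.index[(sd == 0)])

    mz = (marker - marker.mean()) / marker.std()
    xz = (mat[eligible] - mat[eligible].mean(axis=1, keepdims=True)) / sd[eligible][:, None]
    n = len(marker)
    r = (xz @ mz) / n
    r = np.clip(r, -1.0, 1.0)
    # two-sided t test on the correlation
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    genes = means.index[eligible]
    r_s = pd.Series(r, index=genes)
    p_s = pd.Series(p, index=genes)
    k = math.ceil(top_fraction * len(genes))
    top = list(r_s.sort_values(ascending=False, kind="mergesort").index[:k])
    return MarkerAssociation(marker_gene, r_s, p_s, top, excluded)
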