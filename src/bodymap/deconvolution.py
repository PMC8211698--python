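"""Signature construction and cell-type proportion estimation.

Markers are selected per cluster by a one-vs-rest rank-sum test with BH
correction plus a log2 fold-change cut-off on TPM + 1; the signature entry
for a marker is its per-cluster mean reference expression (linear TPM).
Proportions in bulk samples are recovered by non-negative least squares on
the shared signature genes, renormalized to sum to one — a deterministic
solver for the same signature-mixture model that support-vector-regression
deconvolution tools target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SignatureMatrix

logger = logging.getLogger(__name__)


def build_signature(reference: ExpressionMatrix, labels: pd.Series,
                    fdr: float = 0.05, min_log2fc: float = 1.0,
                    max_markers_per_type: int | None = None) -> SignatureMatrix:
    """Select cluster markers and assemble the signature matrix.

    ``labels`` maps reference sample id -> cluster.  Per gene and cluster a
    one-sided Wilcoxon rank-sum test (cluster vs rest) and log2 fold change
    on mean(TPM) + 1 are computed; markers pass q <= ``fdr`` and
    log2FC >= ``min_log2fc`` and are assigned to their maximal-mean cluster.
    ``max_markers_per_type`` truncates each cluster's list ranked by q then
    |log2FC|.
    """
    labels = labels.reindex(reference.sample_ids)
    if labels.isna().any():
        raise ValueError("every reference profile needs a cluster label")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError("need >= 3 profiles per cluster")

    vals = reference.values
    means = vals.T.groupby(labels.to_numpy()).mean().T  # genes x clusters
    rows = []
    for cl in clusters:
        in_cl = vals.loc[:, labels == cl].to_numpy()
        out_cl = vals.loc[:, labels != cl].to_numpy()
        mean_in = in_cl.mean(axis=1)
        mean_out = out_cl.mean(axis=1)
        log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
        p = np.array([
            stats.ranksums(in_cl[i], out_cl[i], alternative="greater").pvalue
            for i in range(in_cl.shape[0])
        ])
        q = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame({"gene_id": vals.index, "cluster": cl,
                           "log2fc": log2fc, "p": p, "q": q})
        rows.append(df)
    all_stats = pd.concat(rows, ignore_index=True)
    passing = all_stats[(all_stats["q"] <= fdr)
                        & (all_stats["log2fc"] >= min_log2fc)].copy()
    # a gene may pass in several clusters; keep its maximal-mean cluster
    passing["home"] = means.loc[passing["gene_id"]].idxmax(axis=1).to_numpy()
    passing = passing[passing["cluster"] == passing["home"]]
    if max_markers_per_type is not None:
        passing = (passing
                   .assign(absfc=passing["log2fc"].abs())
                   .sort_values(["cluster", "q", "absfc"],
                                ascending=[True, True, False], kind="mergesort")
                   .groupby("cluster", group_keys=False)
                   .head(max_markers_per_type))
    empty = set(clusters) - set(passing["cluster"])
    if empty:
        logger.warning("clusters with zero passing markers: %s", sorted(empty))
    markers = passing["gene_id"].tolist()
    if not markers:
        raise ValueError("no markers passed the selection thresholds")
    sig = means.loc[markers, clusters]
    marker_stats = passing.set_index("gene_id")[["cluster", "log2fc", "p", "q"]]
    return SignatureMatrix(sig, marker_stats)


@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    residual: pd.Series        # pre-normalization NNLS residual norm
    n_shared_genes: int
    n_dropped_genes: int       # bulk genes absent from the signature


def estimate_proportions(bulk: ExpressionMatrix,
                         signature: SignatureMatrix) -> DeconvolutionResult:
    """Per-sample NNLS of the bulk marker vector on the signature columns."""
    shared = signature.values.index.intersection(bulk.gene_ids)
    dropped = len(bulk.gene_ids) - len(shared)
    if len(shared) < 2:
        raise ValueError("fewer than 2 signature genes shared with bulk")
    s = signature.values.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(s) < s.shape[1]:
        raise ValueError("signature is rank-deficient on the shared genes")
    if dropped:
        logger.info("ignoring %d bulk genes absent from the signature", dropped)
    b = bulk.values.loc[shared].to_numpy(dtype=float)
    props, resid = [], []
    for j in range(b.shape[1]):
        coef, rnorm = optimize.nnls(s, b[:, j])
        total = coef.sum()
        props.append(coef / total if total > 0 else np.full(len(coef), np.nan))
        resid.append(rnorm)
    proportions = pd.DataFrame(props, index=bulk.sample_ids,
                               columns=signature.cell_types)
    return DeconvolutionResult(proportions,
                               pd.Series(resid, index=bulk.sample_ids),
                               len(shared), dropped)
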