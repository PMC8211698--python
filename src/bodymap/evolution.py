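"""Cross-species comparative statistics.

Percent-spliced-in (PSI) matrices, sample/species divergence correlation
matrices, principal variance component analysis (PVCA), neighbor-joining
expression trees on 1 - r distances with gene-bootstrap branch-length
distributions, and correlation-versus-divergence-time trends.

Rank statistics (Spearman) run on raw TPM; parametric statistics (Pearson,
PCA) run on log2(TPM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

from .datatypes import OrthologMap, PhyloTree

# ---------------------------------------------------------------------------
# PSI


@dataclass
class PsiMatrix:
    psi: pd.DataFrame       # exon x sample PSI in [0,1]; NaN below coverage
    coverage: pd.DataFrame  # inclusion + exclusion reads
    min_coverage: int


def compute_psi(inclusion: pd.DataFrame, exclusion: pd.DataFrame,
                min_coverage: int = 10) -> PsiMatrix:
    """PSI = I / (I + E) wherever coverage I + E reaches ``min_coverage``."""
    if not inclusion.index.equals(exclusion.index) or \
            not inclusion.columns.equals(exclusion.columns):
        raise ValueError("inclusion/exclusion tables must share dimensions")
    inc = inclusion.to_numpy(dtype=float)
    exc = exclusion.to_numpy(dtype=float)
    if (inc < 0).any() or (exc < 0).any():
        raise ValueError("counts must be non-negative")
    cov = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(cov >= min_coverage, inc / cov, np.nan)
    return PsiMatrix(pd.DataFrame(psi, index=inclusion.index,
                                  columns=inclusion.columns),
                     pd.DataFrame(cov, index=inclusion.index,
                                  columns=inclusion.columns),
                     min_coverage)


# ---------------------------------------------------------------------------
# divergence matrices


@dataclass
class DivergenceMatrix:
    corr: pd.DataFrame           # units x units correlation, unit = (species, tissue)
    method: str
    mean_between_species: float  # within-tissue, between-species mean r
    mean_between_tissues: float  # within-species, between-tissue mean r
    undefined_pairs: list[tuple]


def _corr_matrix(mat: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        mat = np.apply_along_axis(stats.rankdata, 0, mat)
    sd = mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(mat, rowvar=False)
    c[np.ix_(sd == 0, np.arange(mat.shape[1]))] = np.nan
    c[np.ix_(np.arange(mat.shape[1]), sd == 0)] = np.nan
    np.fill_diagonal(c, 1.0)
    return c


def divergence_matrix(expr_by_species: dict[str, pd.DataFrame],
                      orthologs: OrthologMap,
                      method: str = "spearman") -> DivergenceMatrix:
    """Pairwise correlation between (species, tissue) expression profiles.

    ``expr_by_species`` maps species to a genes x tissues TPM table indexed
    by that species' own gene ids; the ortholog map aligns them to common
    family rows.  Pearson correlations are computed on log2(TPM + 1),
    Spearman on raw values.  Group means cover between-species entries
    within the same tissue and between-tissue entries within one species.
    """
    method = method.lower()
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    aligned = []
    units = []
    for sp in orthologs.species:
        if sp not in expr_by_species:
            continue
        genes = orthologs.genes_for(sp)
        tab = expr_by_species[sp]
        present = genes.isin(tab.index)
        aligned.append((sp, tab, genes, present))
    if not aligned:
        raise ValueError("no species shared between expression tables and orthologs")
    keep = np.logical_and.reduce([p.to_numpy() for _, _, _, p in aligned])
    if keep.sum() < 2:
        raise ValueError("fewer than 2 common ortholog families after intersection")
    cols = []
    for sp, tab, genes, _ in aligned:
        sub = tab.loc[genes[keep]]
        for tissue in tab.columns:
            units.append((sp, tissue))
            cols.append(sub[tissue].to_numpy(dtype=float))
    mat = np.stack(cols, axis=1)
    if method == "pearson":
        mat = np.log2(mat + 1.0)
    c = _corr_matrix(mat, method)
    idx = pd.MultiIndex.from_tuples(units, names=["species", "tissue"])
    corr = pd.DataFrame(c, index=idx, columns=idx)

    undefined = [(units[i], units[j])
                 for i in range(len(units)) for j in range(i + 1, len(units))
                 if np.isnan(c[i, j])]
    sp_vals, ti_vals = [], []
    for i, (sp_i, t_i) in enumerate(units):
        for j in range(i + 1, len(units)):
            sp_j, t_j = units[j]
            if t_i == t_j and sp_i != sp_j:
                sp_vals.append(c[i, j])
            elif sp_i == sp_j and t_i != t_j:
                ti_vals.append(c[i, j])
    sp_ok = [v for v in sp_vals if not np.isnan(v)]
    ti_ok = [v for v in ti_vals if not np.isnan(v)]
    return DivergenceMatrix(corr, method,
                            float(np.mean(sp_ok)) if sp_ok else float("nan"),
                            float(np.mean(ti_ok)) if ti_ok else float("nan"),
                            undefined)


# ---------------------------------------------------------------------------
# PVCA


@dataclass
class PvcaResult:
    wapv: pd.Series             # factor (+ "residual") -> weighted avg proportion variance
    n_components: int
    weights: np.ndarray         # eigen-fraction weights over retained components
    per_component: pd.DataFrame  # component x factor variance fractions


def _between_fraction(scores: np.ndarray, levels: np.ndarray) -> float:
    """Method-of-moments between-level variance fraction of one factor."""
    total = scores.var(ddof=1)
    if total == 0:
        return 0.0
    uniq, inv = np.unique(levels, return_inverse=True)
    k, n = len(uniq), len(scores)
    if k < 2:
        return 0.0
    group_mean = np.bincount(inv, weights=scores) / np.bincount(inv)
    resid = scores - group_mean[inv]
    msw = (resid**2).sum() / (n - k) if n > k else 0.0
    msb = (np.bincount(inv) * (group_mean - scores.mean())**2).sum() / (k - 1)
    sizes = np.bincount(inv)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    sigma_b = max(0.0, (msb - msw) / n0)
    return float(min(1.0, sigma_b / total))


def pvca(expr: pd.DataFrame, factors: pd.DataFrame,
         var_threshold: float = 0.9) -> PvcaResult:
    """Principal variance component analysis over design factors.

    ``expr`` is genes x samples; ``factors`` maps each sample to factor
    levels (e.g. species, tissue).  Genes are standardized, principal
    components retained up to ``var_threshold`` cumulative variance, each
    component's variance is split across factors by a one-way
    method-of-moments decomposition, and per-factor fractions are averaged
    with eigen-fraction weights, renormalized with the residual so the
    reported WAPVs sum to 1.
    """
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must lie in (0, 1]")
    factors = factors.loc[list(expr.columns)]
    for f in factors.columns:
        counts = factors[f].value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError(f"factor {f!r} needs >= 2 levels with >= 2 samples")
    for i, f in enumerate(factors.columns):
        for g in factors.columns[i + 1:]:
            part_f = pd.factorize(factors[f])[0]
            part_g = pd.factorize(factors[g])[0]
            # identical partitions <=> the joint partition adds no levels
            if len(set(zip(part_f, part_g))) == len(set(part_f)) == len(set(part_g)):
                raise ValueError(f"factors {f!r} and {g!r} are confounded "
                                 "(identical sample partition)")

    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    x = x[sd > 0]
    x = (x - x.mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
    # PCA over samples
    xc = x - x.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    cum = np.cumsum(frac)
    n_comp = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_comp = min(n_comp, len(frac))
    weights = frac[:n_comp] / frac[:n_comp].sum()

    rows = []
    for c in range(n_comp):
        scores = vt[c] * s[c]
        fracs = {f: _between_fraction(scores, factors[f].to_numpy())
                 for f in factors.columns}
        resid = max(0.0, 1.0 - sum(fracs.values()))
        norm = sum(fracs.values()) + resid
        rows.append({**{f: v / norm for f, v in fracs.items()},
                     "residual": resid / norm})
    per_component = pd.DataFrame(rows)
    wapv_raw = per_component.mul(weights, axis=0).sum(axis=0)
    wapv = wapv_raw / wapv_raw.sum()
    return PvcaResult(wapv, n_comp, weights, per_component)


# ---------------------------------------------------------------------------
# neighbor-joining expression trees


@dataclass
class ExpressionTree:
    newick: str
    total_length: float
    distances: pd.DataFrame   # 1 - r species matrix
    n_clamped: int            # negative NJ branch lengths clamped to 0


def _pairwise_one_minus_r(expr: pd.DataFrame, method: str) -> pd.DataFrame:
    mat = expr.to_numpy(dtype=float).T  # genes x species
    if method == "pearson":
        mat = np.log2(mat + 1.0)
    c = _corr_matrix(mat, method)
    if np.isnan(c).any():
        raise ValueError("undefined pairwise correlation (constant profile?)")
    return pd.DataFrame(1.0 - c, index=expr.index, columns=expr.index)


def tree_from_distances(dist: pd.DataFrame) -> tuple[str, float, int]:
    """Neighbor joining on a distance matrix; returns (newick, total, n_clamped)."""
    labels = list(dist.index)
    d = dist.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    if len(labels) < 2:
        raise ValueError("need >= 2 taxa")
    if len(labels) == 2:
        total = float(d[0, 1])
        return f"({labels[0]}:{total / 2},{labels[1]}:{total / 2});", total, 0
    tree = nj(DistanceMatrix(d, ids=labels))
    n_clamped = 0
    total = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is not None:
            if node.length < 0:
                n_clamped += 1
                node.length = 0.0
            total += node.length
    return str(tree).strip(), float(total), n_clamped


def build_expression_tree(expr: pd.DataFrame,
                          method: str = "spearman") -> ExpressionTree:
    """NJ tree over species on D = 1 - r expression distances.

    ``expr`` is species x genes (one tissue); negative NJ branch lengths are
    clamped to zero and counted.
    """
    method = method.lower()
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 species")
    dist = _pairwise_one_minus_r(expr, method)
    newick, total, n_clamped = tree_from_distances(dist)
    return ExpressionTree(newick, total, dist, n_clamped)


@dataclass
class BranchLengthDistribution:
    totals: np.ndarray
    median: float
    iqr: tuple[float, float]
    point_estimate: float


def branch_length_distribution(expr: pd.DataFrame, method: str = "spearman",
                               n_replicates: int = 100,
                               seed: int = 0) -> BranchLengthDistribution:
    """Gene-bootstrap distribution of NJ total branch length.

    Each replicate resamples genes with replacement (same size), rebuilds
    the tree and records its total branch length.
    """
    rng = np.random.default_rng(seed)
    point = build_expression_tree(expr, method).total_length
    n_genes = expr.shape[1]
    totals = np.empty(n_replicates)
    for r in range(n_replicates):
        cols = rng.integers(0, n_genes, size=n_genes)
        boot = expr.iloc[:, cols]
        boot.columns = [f"b{i}" for i in range(n_genes)]
        totals[r] = build_expression_tree(boot, method).total_length
    q1, q3 = np.percentile(totals, [25, 75])
    return BranchLengthDistribution(totals, float(np.median(totals)),
                                    (float(q1), float(q3)), point)


# ---------------------------------------------------------------------------
# divergence-time trends


@dataclass
class TimeTrend:
    per_tissue: pd.DataFrame  # tissue -> spearman_r, p, slope, intercept, n_pairs
    mean_spearman: float


def divergence_time_trend(div: DivergenceMatrix, tree: PhyloTree) -> TimeTrend:
    """Correlation-vs-divergence-time trend per tissue.

    For each tissue: Spearman r between the between-species correlation and
    the pairwise divergence time over species pairs, plus a linear
    regression of correlation on log10(time in MY).
    """
    times = tree.divergence_times()
    units = list(div.corr.index)
    tissues = sorted({t for _, t in units})
    rows = {}
    for tissue in tissues:
        sp = [s for s, t in units if t == tissue]
        pairs = [(a, b) for i, a in enumerate(sp) for b in sp[i + 1:]]
        if len(pairs) < 3:
            raise ValueError(f"tissue {tissue!r}: need >= 3 species pairs "
                             f"(got {len(pairs)})")
        rs, ts = [], []
        for a, b in pairs:
            if a not in times.index or b not in times.index:
                raise ValueError(f"species {a!r}/{b!r} missing from tree")
            rs.append(div.corr.loc[(a, tissue), (b, tissue)])
            ts.append(times.loc[a, b])
        rs, ts = np.asarray(rs), np.asarray(ts)
        rho, p = stats.spearmanr(rs, ts)
        slope, intercept = np.polyfit(np.log10(ts), rs, 1)
        rows[tissue] = {"spearman_r": float(rho), "p": float(p),
                        "slope": float(slope), "intercept": float(intercept),
                        "n_pairs": len(pairs)}
    table = pd.DataFrame(rows).T
    return TimeTrend(table, float(table["spearman_r"].mean()))
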