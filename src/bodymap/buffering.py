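"""Enhancer-redundancy buffering of expression evolution.

The analysis chain: count distinct enhancer bins interacting with each
gene's promoter per species; relate enhancer dose to expression level;
split genes into a multi-enhancer class (median count >= 5 across species)
and a few-enhancer class (median <= 1); match each class 1-1 to
expression-matched controls; compare cross-species expression correlation
between class and controls over species pairs (Wilcoxon signed-rank) and
against divergence time; and contrast sequence conservation between
evolutionarily stable (low CV) and variable (high CV) genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import ConservationScores, PeiTable, PhyloTree

#: Class thresholds on the cross-species median enhancer count.
MULTI_ENHANCER_MIN = 5
FEW_ENHANCER_MAX = 1


@dataclass
class GeneEnhancerProfile:
    counts: pd.DataFrame       # gene x species distinct enhancer-bin counts
    median: pd.Series          # per-gene median count across species
    n_zero_filled: int         # (gene, species) cells absent from the PEI table


def enhancer_counts(pei: PeiTable, genes: list[str] | None = None) -> GeneEnhancerProfile:
    """Distinct enhancer bins per gene and species, plus the species median.

    ``genes`` fixes the gene universe (e.g. the single-copy ortholog set);
    genes absent from a species' table get count 0 for that species.
    """
    counts = pei.counts()
    if genes is not None:
        counts = counts.reindex(genes)
    n_filled = int(counts.isna().to_numpy().sum())
    counts = counts.fillna(0).astype(int)
    return GeneEnhancerProfile(counts, counts.median(axis=1), n_filled)


@dataclass
class DoseResponse:
    per_species: pd.DataFrame  # species -> spearman_r, p, n
    bins: pd.DataFrame         # species x count-bin median expression
    cap: int


def dose_response(profile: GeneEnhancerProfile, expr: pd.DataFrame,
                  cap: int = 10) -> DoseResponse:
    """Expression by enhancer count per species.

    ``expr`` is species x genes (log2 scale).  Counts above ``cap`` are
    pooled into the top bin for the per-bin summaries; the Spearman
    correlation uses the raw counts.
    """
    common = profile.counts.index.intersection(expr.columns)
    counts = profile.counts.loc[common]
    rows, bin_rows = {}, {}
    for sp in expr.index:
        if sp not in counts.columns:
            continue
        c = counts[sp].to_numpy()
        if len(np.unique(c)) < 2:
            raise ValueError(f"degenerate dose: all genes share one enhancer "
                             f"count in species {sp!r}")
        e = expr.loc[sp, common].to_numpy(dtype=float)
        r, p = stats.spearmanr(c, e)
        rows[sp] = {"spearman_r": float(r), "p": float(p), "n": len(c)}
        capped = np.minimum(c, cap)
        bin_rows[sp] = pd.Series(e).groupby(capped).median()
    return DoseResponse(pd.DataFrame(rows).T, pd.DataFrame(bin_rows).T, cap)


@dataclass
class MatchedSets:
    pairs: pd.DataFrame    # treatment_gene, control_gene, covariate values
    pre_gap: float         # |treatment mean - pool mean| before matching
    post_gap: float        # |treatment mean - control mean| after matching


def match_controls(treatment: pd.Series, pool: pd.Series,
                   optimal: bool = False) -> MatchedSets:
    """1-1 expression-matched controls drawn from ``pool``.

    Greedy nearest-neighbor without replacement: treatment genes are
    processed in descending covariate order (ties broken by gene id) and
    each takes its nearest remaining pool gene (covariate ties again by
    gene id).  ``optimal=True`` solves the assignment problem instead
    (minimal total |difference|), practical for small sets.
    """
    if len(pool) < len(treatment):
        raise ValueError(f"pool ({len(pool)}) smaller than treatment "
                         f"({len(treatment)})")
    if not (np.isfinite(treatment.to_numpy(dtype=float)).all()
            and np.isfinite(pool.to_numpy(dtype=float)).all()):
        raise ValueError("matching covariate must be finite")
    pre_gap = abs(float(treatment.mean()) - float(pool.mean()))

    t_order = treatment.sort_index(kind="mergesort") \
                       .sort_values(ascending=False, kind="mergesort")
    if optimal:
        tv = t_order.to_numpy(dtype=float)
        pv = pool.to_numpy(dtype=float)
        cost = np.abs(tv[:, None] - pv[None, :])
        ti, pj = optimize.linear_sum_assignment(cost)
        chosen = dict(zip(t_order.index[ti], pool.index[pj]))
        pairs = pd.DataFrame({
            "treatment_gene": list(t_order.index),
            "control_gene": [chosen[g] for g in t_order.index],
        })
    else:
        pool_sorted = pool.sort_index(kind="mergesort") \
                          .sort_values(kind="mergesort")
        pool_ids = list(pool_sorted.index)
        pool_vals = pool_sorted.to_numpy(dtype=float)
        alive = np.ones(len(pool_ids), dtype=bool)
        rows = []
        for gene, value in t_order.items():
            live = np.flatnonzero(alive)
            diffs = np.abs(pool_vals[live] - value)
            j = live[int(np.argmin(diffs))]  # argmin takes the first minimum:
            # pool is sorted by (covariate, gene id), so ties resolve to the
            # lexicographically smaller gene id at the lower covariate
            rows.append((gene, pool_ids[j]))
            alive[j] = False
        pairs = pd.DataFrame(rows, columns=["treatment_gene", "control_gene"])
    pairs["treatment_value"] = treatment.loc[pairs["treatment_gene"]].to_numpy()
    pairs["control_value"] = pool.loc[pairs["control_gene"]].to_numpy()
    post_gap = abs(float(pairs["treatment_value"].mean())
                   - float(pairs["control_value"].mean()))
    return MatchedSets(pairs, pre_gap, post_gap)


@dataclass
class ConservationTrend:
    per_pair: pd.DataFrame   # species_a, species_b, time_mya, r_set, r_control
    signed_rank_p: float     # paired Wilcoxon over species pairs
    slope_set: float         # regression of r on log10 time
    slope_control: float
    median_diff: float       # median of r_set - r_control


def conservation_vs_divergence(gene_set: list[str], control_set: list[str],
                               expr: pd.DataFrame,
                               tree: PhyloTree) -> ConservationTrend:
    """Cross-species expression conservation of a gene set vs matched controls.

    For every species pair, Spearman r of expression across the set's genes
    (jointly) is computed for the set and for the controls; the paired
    values are compared by a Wilcoxon signed-rank test over identical
    species-pair lists and regressed on log10 divergence time.
    """
    times = tree.divergence_times()
    species = [s for s in expr.index if s in times.index]
    if len(species) < 3:
        raise ValueError("need >= 3 species for pairwise trends")
    rows = []
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            r_set = stats.spearmanr(expr.loc[a, gene_set],
                                    expr.loc[b, gene_set]).statistic
            r_ctl = stats.spearmanr(expr.loc[a, control_set],
                                    expr.loc[b, control_set]).statistic
            rows.append({"species_a": a, "species_b": b,
                         "time_mya": float(times.loc[a, b]),
                         "r_set": float(r_set), "r_control": float(r_ctl)})
    per_pair = pd.DataFrame(rows)
    diffs = per_pair["r_set"] - per_pair["r_control"]
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(per_pair["r_set"], per_pair["r_control"]).pvalue)
    logt = np.log10(per_pair["time_mya"].to_numpy(dtype=float))
    slope_set = float(np.polyfit(logt, per_pair["r_set"], 1)[0])
    slope_ctl = float(np.polyfit(logt, per_pair["r_control"], 1)[0])
    return ConservationTrend(per_pair, p, slope_set, slope_ctl,
                             float(diffs.median()))


@dataclass
class CvClasses:
    cv: pd.Series            # per-gene CV of expression across species
    stable: list[str]        # m lowest-CV genes
    variable: list[str]      # m highest-CV genes
    phastcons_p: float       # Bonferroni-corrected rank-sum p
    phylop_p: float
    medians: pd.DataFrame    # class x score medians


def cv_conservation_classes(expr: pd.DataFrame,
                            conservation: ConservationScores,
                            class_size: int,
                            linear_scale: bool = True) -> CvClasses:
    """Sequence conservation of evolutionarily stable vs variable genes.

    CV = sd / mean of per-species expression (linear scale by default:
    ``expr`` on log2 scale is exponentiated first; ``linear_scale=False``
    computes CV directly on the given values).  The ``class_size`` lowest-
    and highest-CV genes form the stable/variable classes; phastCons and
    phyloP are compared by two-sided Wilcoxon rank-sum tests, Bonferroni-
    corrected over the two tests.
    """
    cons = conservation.table.set_index("gene_id")
    genes = [g for g in expr.columns if g in cons.index]
    vals = expr[genes].to_numpy(dtype=float)
    if linear_scale:
        vals = np.power(2.0, vals)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    cv = pd.Series(cv, index=genes).dropna()
    if class_size > len(cv) // 2:
        raise ValueError(f"class_size {class_size} exceeds half the "
                         f"{len(cv)} genes with defined CV")
    ranked = cv.sort_index(kind="mergesort").sort_values(kind="mergesort")
    stable = list(ranked.index[:class_size])
    variable = list(ranked.index[-class_size:])
    ps = {}
    med_rows = {}
    for score in ("phastcons", "phylop"):
        a = cons.loc[stable, score].to_numpy(dtype=float)
        b = cons.loc[variable, score].to_numpy(dtype=float)
        p = stats.ranksums(a, b).pvalue
        ps[score] = min(1.0, 2.0 * float(p))  # Bonferroni over the two scores
        med_rows[score] = {"stable": float(np.median(a)),
                           "variable": float(np.median(b))}
    return CvClasses(cv, stable, variable, ps["phastcons"], ps["phylop"],
                     pd.DataFrame(med_rows))


def buffering_classes(profile: GeneEnhancerProfile,
                      multi_min: int = MULTI_ENHANCER_MIN,
                      few_max: int = FEW_ENHANCER_MAX) -> tuple[list[str], list[str]]:
    """Multi-enhancer and few-enhancer gene classes on the species median."""
    med = profile.median
    multi = list(med.index[med >= multi_min])
    few = list(med.index[med <= few_max])
    return multi, few


def buffering_analysis(pei: PeiTable, expr: pd.DataFrame, tree: PhyloTree,
                       multi_min: int = MULTI_ENHANCER_MIN,
                       few_max: int = FEW_ENHANCER_MAX) -> dict:
    """Full chain: counts -> classes -> expression-matched controls -> trend.

    Returns the multi-enhancer trend (vs few-enhancer matched controls) and
    the complementary few-enhancer trend (vs multi/mid-enhancer controls),
    mirroring the stability/viability contrast.
    """
    profile = enhancer_counts(pei, genes=list(expr.columns))
    multi, few = buffering_classes(profile, multi_min, few_max)
    if not multi or not few:
        raise ValueError("empty enhancer class; adjust thresholds")
    mean_expr = expr.mean(axis=0)
    n = min(len(multi), len(few))
    multi_t = list(mean_expr.loc[multi].sort_values(ascending=False).index[:n])
    matched = match_controls(mean_expr.loc[multi_t], mean_expr.loc[few])
    controls = list(matched.pairs["control_gene"])
    trend_multi = conservation_vs_divergence(multi_t, controls, expr, tree)

    pool_non_few = mean_expr.index.difference(few)
    few_t = few[: len(pool_non_few)]
    matched_few = match_controls(mean_expr.loc[few_t],
                                 mean_expr.loc[pool_non_few])
    trend_few = conservation_vs_divergence(
        few_t, list(matched_few.pairs["control_gene"]), expr, tree)
    return {
        "profile": profile,
        "multi_set": multi_t,
        "few_set": few_t,
        "matched_multi": matched,
        "matched_few": matched_few,
        "trend_multi": trend_multi,
        "trend_few": trend_few,
    }
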