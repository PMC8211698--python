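"""Gaussian trait-evolution models on a species tree: BM, OU, shifted OU.

Per gene, leaf log-expression values x are modelled as multivariate normal
with a covariance structure implied by the tree:

* Brownian motion (BM): E[x] = mu, Cov(i, j) = sigma2 * t_shared(i, j)
  where t_shared is the shared root-to-tip path length.
* Ornstein-Uhlenbeck (OU), root conditioned at the optimum theta:
  E[x] = theta, Cov(i, j) = sigma2 / (2 alpha) *
  (exp(-alpha d_ij) - exp(-alpha (t_i + t_j))); this parameterization
  converges to BM as alpha -> 0, so BM is the exact alpha = 0 boundary of
  the OU fit and the likelihoods nest.  A ``stationary`` root mode
  (Cov = sigma2 / (2 alpha) * exp(-alpha d_ij)) is available and matches
  the simulator's draw from the stationary distribution.
* Shifted OU: one extra optimum on the focal species' terminal branch,
  displacing that leaf's mean by delta * (1 - exp(-alpha t_focal)).

sigma2 and the mean parameters are profiled out in closed form (GLS), so
each fit is a one-dimensional search over alpha on a fixed log-spaced grid
(alpha = 0 included) followed by a deterministic local refinement.  Model
choice is by AICc; species-specific shifts are called by a likelihood-ratio
test (chi-square, 1 df) with Benjamini-Hochberg correction across genes
within each focal species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import PhyloTree

_LOG2PI = np.log(2.0 * np.pi)

#: Fixed alpha search grid (per-MY units); 0 is the exact BM boundary.
ALPHA_GRID = np.concatenate([[0.0], np.geomspace(1e-4, 20.0, 48)])


class TreeContext:
    """Precomputed tree matrices shared across per-gene fits."""

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        self.labels = tree.leaf_labels
        self.n = len(self.labels)
        self.dist = tree.distance_matrix().loc[self.labels, self.labels].to_numpy()
        self.shared = tree.shared_path_matrix().loc[self.labels, self.labels].to_numpy()
        self.depths = tree.leaf_depths().loc[self.labels].to_numpy()
        self.terminal = np.array([tree.terminal_branch_length(s) for s in self.labels])
        self._cache: dict[tuple, tuple[np.ndarray, float]] = {}

    def corr_matrix(self, alpha: float, root: str) -> tuple[np.ndarray, float]:
        """Scaled covariance R with V = sigma2 * R, plus log det R."""
        key = (float(alpha), root)
        if key in self._cache:
            return self._cache[key]
        if alpha == 0.0:
            r = self.shared.copy()
        elif root == "fixed":
            tt = self.depths[:, None] + self.depths[None, :]
            r = (np.exp(-alpha * self.dist) - np.exp(-alpha * tt)) / (2 * alpha)
        elif root == "stationary":
            r = np.exp(-alpha * self.dist) / (2 * alpha)
        else:
            raise ValueError(f"unknown root mode {root!r}")
        sign, logdet = np.linalg.slogdet(r)
        if sign <= 0:
            raise np.linalg.LinAlgError("non-PD scaled covariance")
        out = (np.linalg.inv(r), float(logdet))
        if len(self._cache) < 4096:
            self._cache[key] = out
        return out


def _gls_profile(x: np.ndarray, design: np.ndarray, rinv: np.ndarray,
                 logdet: float) -> tuple[float, np.ndarray, float]:
    """Profiled Gaussian log-likelihood given scaled covariance inverse.

    Returns (logLik, beta_hat, sigma2_hat) with sigma2 at its ML value.
    """
    n = len(x)
    xtri = design.T @ rinv
    beta = np.linalg.solve(xtri @ design, xtri @ x)
    resid = x - design @ beta
    quad = float(resid @ rinv @ resid)
    sigma2 = max(quad / n, 1e-300)
    ll = -0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + n)
    return ll, beta, sigma2


@dataclass
class ModelFit:
    model: str
    loglik: float
    sigma2: float
    alpha: float | None = None
    mean: float = 0.0          # BM root state / OU optimum theta
    shift: float | None = None  # shifted-OU optimum displacement delta
    n_params: int = 2
    converged: bool = True

    def aicc(self, n: int) -> float:
        k = self.n_params
        if n - k - 1 <= 0:
            return float("inf")
        return -2 * self.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_bm(x: np.ndarray, ctx: TreeContext) -> ModelFit:
    if np.ptp(x) == 0:
        # degenerate: identical leaf values; sigma2 -> 0, likelihood unbounded
        return ModelFit("BM", np.inf, 0.0, alpha=None, mean=float(x[0]), n_params=2)
    rinv, logdet = ctx.corr_matrix(0.0, "fixed")
    ones = np.ones((ctx.n, 1))
    ll, beta, sigma2 = _gls_profile(x, ones, rinv, logdet)
    return ModelFit("BM", ll, sigma2, alpha=None, mean=float(beta[0]), n_params=2)


def _design(ctx: TreeContext, alpha: float, focal_idx: int | None) -> np.ndarray:
    ones = np.ones((ctx.n, 1))
    if focal_idx is None or alpha <= 0:
        # at alpha = 0 the shift weight vanishes: the limit model is plain BM
        return ones
    w = np.zeros((ctx.n, 1))
    w[focal_idx, 0] = 1.0 - np.exp(-alpha * ctx.terminal[focal_idx])
    return np.hstack([ones, w])


def _fit_ou_like(x: np.ndarray, ctx: TreeContext, focal_idx: int | None,
                 root: str) -> ModelFit:
    if np.ptp(x) == 0:
        name = "OU" if focal_idx is None else "OU-shift"
        return ModelFit(name, np.inf, 0.0, alpha=0.0, mean=float(x[0]),
                        shift=0.0 if focal_idx is not None else None,
                        n_params=3 if focal_idx is None else 4)

    def nll(alpha: float) -> float:
        if root == "stationary" and alpha <= 0:
            return np.inf
        try:
            rinv, logdet = ctx.corr_matrix(alpha, root)
            ll, _, _ = _gls_profile(x, _design(ctx, alpha, focal_idx), rinv, logdet)
        except np.linalg.LinAlgError:
            return np.inf
        return -ll

    grid_vals = np.array([nll(a) for a in ALPHA_GRID])
    best = int(np.argmin(grid_vals))
    lo = ALPHA_GRID[max(best - 1, 0)]
    hi = ALPHA_GRID[min(best + 1, len(ALPHA_GRID) - 1)]
    alpha = ALPHA_GRID[best]
    converged = True
    if hi > lo and hi > 0:
        res = optimize.minimize_scalar(nll, bounds=(max(lo, 1e-9), hi),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        if np.isfinite(res.fun) and res.fun <= grid_vals[best]:
            alpha = float(res.x)
        converged = bool(res.success)
    if nll(alpha) > grid_vals[best]:
        alpha = float(ALPHA_GRID[best])
    rinv, logdet = ctx.corr_matrix(alpha, root)
    ll, beta, sigma2 = _gls_profile(x, _design(ctx, alpha, focal_idx), rinv, logdet)
    if focal_idx is None:
        return ModelFit("OU", ll, sigma2, alpha=alpha, mean=float(beta[0]),
                        n_params=3, converged=converged)
    shift = float(beta[1]) if len(beta) > 1 else 0.0
    return ModelFit("OU-shift", ll, sigma2, alpha=alpha, mean=float(beta[0]),
                    shift=shift, n_params=4, converged=converged)


def fit_ou(x: np.ndarray, ctx: TreeContext, root: str = "fixed") -> ModelFit:
    return _fit_ou_like(x, ctx, None, root)


def fit_shifted_ou(x: np.ndarray, ctx: TreeContext, focal_species: str,
                   root: str = "fixed") -> ModelFit:
    if focal_species not in ctx.labels:
        raise KeyError(f"{focal_species!r} is not a leaf of the tree")
    return _fit_ou_like(x, ctx, ctx.labels.index(focal_species), root)


def ou_loglik(values: pd.Series, tree: PhyloTree, alpha: float,
              root: str = "fixed") -> float:
    """Profiled OU log-likelihood at a fixed alpha (diagnostic helper)."""
    ctx = TreeContext(tree)
    x = values.loc[ctx.labels].to_numpy(dtype=float)
    rinv, logdet = ctx.corr_matrix(float(alpha), root)
    ll, _, _ = _gls_profile(x, np.ones((ctx.n, 1)), rinv, logdet)
    return ll


@dataclass
class OuBmFit:
    gene: str
    bm: ModelFit
    ou: ModelFit
    chosen: str               # AICc winner among {BM, OU}
    shift_fits: dict[str, ModelFit] = field(default_factory=dict)


def fit_ou_bm(values: pd.Series, tree: PhyloTree, gene: str = "",
              root: str = "fixed") -> OuBmFit:
    """ML BM and single-optimum OU fits for one gene; AICc model choice."""
    ctx = TreeContext(tree)
    return _fit_gene(values, ctx, gene, root)


def _fit_gene(values: pd.Series, ctx: TreeContext, gene: str,
              root: str) -> OuBmFit:
    x = values.loc[ctx.labels].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"gene {gene!r}: non-finite leaf values")
    if ctx.n < 3:
        raise ValueError("model fits require >= 3 leaves")
    bm = fit_bm(x, ctx)
    ou = fit_ou(x, ctx, root)
    # the alpha = 0 grid point makes OU contain BM exactly in fixed-root mode
    if root == "fixed" and ou.loglik < bm.loglik - 1e-9:
        ou.converged = False
    chosen = "BM" if bm.aicc(ctx.n) <= ou.aicc(ctx.n) else "OU"
    return OuBmFit(gene, bm, ou, chosen)


def fit_many(values: pd.DataFrame, tree: PhyloTree,
             root: str = "fixed") -> list[OuBmFit]:
    """Fit BM/OU to every gene column of a species x genes table."""
    ctx = TreeContext(tree)
    return [_fit_gene(values[g], ctx, str(g), root) for g in values.columns]


@dataclass
class ShiftCall:
    gene: str
    species: str
    direction: str     # "up" or "down"
    effect_size: float  # theta_shift - theta
    p: float
    q: float


@dataclass
class ShiftScan:
    calls: list[ShiftCall]
    table: pd.DataFrame  # gene x species p and q values, effect sizes
    fdr: float


def detect_shifts(values: pd.DataFrame, tree: PhyloTree,
                  focal_species: list[str] | None = None,
                  fdr: float = 0.05, root: str = "fixed") -> ShiftScan:
    """Likelihood-ratio scan for species-specific optimum shifts.

    For each gene and focal species, a shifted-OU model (extra optimum on
    the focal terminal branch) is tested against single-optimum OU
    (chi-square LRT, 1 df); q-values are Benjamini-Hochberg within species
    across genes and calls are made at q <= ``fdr``.
    """
    ctx = TreeContext(tree)
    if focal_species is None:
        focal_species = list(ctx.labels)
    for sp in focal_species:
        if sp not in ctx.labels:
            raise KeyError(f"focal species {sp!r} is not a leaf of the tree")
    genes = [str(g) for g in values.columns]
    records = []
    for g in genes:
        x = values[g].loc[ctx.labels].to_numpy(dtype=float)
        ou = fit_ou(x, ctx, root)
        for sp in focal_species:
            shifted = fit_shifted_ou(x, ctx, sp, root)
            if np.isinf(shifted.loglik) and np.isinf(ou.loglik):
                lrt = 0.0  # degenerate constant gene: no shift evidence
            else:
                lrt = 2.0 * (shifted.loglik - ou.loglik)
            failed = lrt < -1e-6  # nesting violated: optimizer failure
            lrt = max(lrt, 0.0)
            records.append({
                "gene": g, "species": sp,
                "effect_size": shifted.shift or 0.0,
                "lrt": lrt, "p": float(stats.chi2.sf(lrt, df=1)),
                "optimizer_failure": failed,
            })
    table = pd.DataFrame(records)
    table["q"] = np.nan
    for sp, idx in table.groupby("species").groups.items():
        table.loc[idx, "q"] = multipletests(table.loc[idx, "p"], method="fdr_bh")[1]
    calls = [
        ShiftCall(r.gene, r.species, "up" if r.effect_size > 0 else "down",
                  float(r.effect_size), float(r.p), float(r.q))
        for r in table.itertuples()
        if r.q <= fdr and not r.optimizer_failure
    ]
    return ShiftScan(calls, table, fdr)
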