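"""Synthetic-data generators with known ground truth.

Each generator emulates the statistical structure one downstream stage
assumes — a multi-tissue TPM atlas with planted tissue-specific genes,
ortholog expression evolving on a timetree, noisy cell-type mixtures,
a spherical nucleus with planted radial gradients, promoter-enhancer
tables with a planted buffering effect, and binomial exon-inclusion
counts.  Every generator is a pure function of its config (seed included),
and returns its ground truth alongside the data so recovery tests can
consume only the data and compare against truth.

Expression is log-normal throughout: planted effects are additive on the
log scale and noise is Gaussian on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenomeBinTable,
    IntervalSet,
    PeiTable,
    PhyloTree,
    SampleMetadata,
    SignatureMatrix,
)

#: Default study timetree: nine mammals with divergence times (MY) matching
#: widely used estimates (mouse-rat 15.9, murids-guinea pig 70, cat-dog 55,
#: pig-sheep 64, boreoeutherian root 96).
DEFAULT_TIMETREE = (
    "(((((mouse:15.9,rat:15.9):54.1,guinea_pig:70):12,rabbit:82):8,"
    "macaque:90):6,((pig:64,sheep:64):14,(cat:55,dog:55):23):18);"
)


def default_timetree() -> PhyloTree:
    return PhyloTree.from_newick(DEFAULT_TIMETREE)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one global seed out to independent per-component streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# multi-tissue atlas


@dataclass
class AtlasSimConfig:
    """Multi-tissue, multi-replicate TPM atlas with planted specific genes."""

    n_genes: int = 2000
    n_tissues: int = 10
    replicates: int = 3
    fraction_specific: float = 0.2
    log_mean: float = 1.0       # baseline mean of log TPM
    log_sd: float = 1.0         # baseline sd of log TPM across genes
    fold_up: float = 50.0       # multiplicative elevation in the home tissue
    noise_sd: float = 0.2       # lognormal replicate noise (log scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_specific <= 1:
            raise ValueError("fraction_specific must lie in [0, 1]")
        if self.fold_up <= 1:
            raise ValueError("fold_up must exceed 1")
        if min(self.n_genes, self.n_tissues, self.replicates) < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class AtlasSim:
    expr: ExpressionMatrix
    metadata: SampleMetadata
    truth: pd.DataFrame  # gene_id, home_tissue ("ubiquitous" for background)


def simulate_atlas(config: AtlasSimConfig) -> AtlasSim:
    c = config
    rng_base, rng_home, rng_noise = _rngs(c.seed, 3)
    tissues = [f"tissue{i:02d}" for i in range(c.n_tissues)]
    genes = [f"g{i:05d}" for i in range(c.n_genes)]

    n_spec = int(round(c.fraction_specific * c.n_genes))
    home = np.full(c.n_genes, -1)
    home[:n_spec] = rng_home.integers(0, c.n_tissues, size=n_spec)

    base = rng_base.normal(c.log_mean, c.log_sd, size=c.n_genes)
    log_mu = np.tile(base[:, None], (1, c.n_tissues))
    spec_idx = np.arange(n_spec)
    log_mu[spec_idx, home[:n_spec]] += np.log(c.fold_up)

    cols, col_mu = [], []
    for j, t in enumerate(tissues):
        for r in range(1, c.replicates + 1):
            cols.append(f"{t}_rep{r}")
            col_mu.append(log_mu[:, j])
    log_vals = np.stack(col_mu, axis=1)
    log_vals = log_vals + rng_noise.normal(0.0, c.noise_sd, size=log_vals.shape)
    values = pd.DataFrame(np.exp(log_vals), index=genes, columns=cols)

    meta = SampleMetadata(pd.DataFrame({
        "sample_id": cols,
        "tissue": [s.rsplit("_rep", 1)[0] for s in cols],
        "species": "pig",
        "replicate": [int(s.rsplit("_rep", 1)[1]) for s in cols],
    }))
    truth = pd.DataFrame({
        "gene_id": genes,
        "home_tissue": [tissues[h] if h >= 0 else "ubiquitous" for h in home],
    })
    expr = ExpressionMatrix(values, pd.Series("PCG", index=genes))
    return AtlasSim(expr, meta, truth)


# ---------------------------------------------------------------------------
# phylogenetic expression evolution (BM / OU / OU with lineage shift)


@dataclass
class PhyloSimConfig:
    """Ortholog log-expression evolving on a fixed timetree.

    ``model`` per gene is one of {"BM", "OU", "OU-shift"}.  BM leaves are
    multivariate normal with covariance sigma2 x shared path length; OU
    leaves follow the stationary OU covariance (sigma2 / 2 alpha) x
    exp(-alpha x path distance) around optimum theta; a shift adds
    ``shift_size`` to the optimum on the focal terminal branch, displacing
    the focal leaf mean by shift_size x (1 - exp(-alpha t_focal)).
    """

    tree: PhyloTree = field(default_factory=default_timetree)
    n_genes: int = 200
    model: str = "BM"              # applied to every gene
    sigma2: float = 0.01           # diffusion variance per MY
    alpha: float = 0.05            # OU pull strength per MY
    theta: float = 2.0             # OU optimum (log expression)
    root_state: float = 2.0        # BM root state
    shift_species: str | None = None
    shift_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.model not in ("BM", "OU", "OU-shift"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model.startswith("OU") and self.alpha == 0:
            raise ValueError("alpha = 0 degenerates OU to BM; request BM instead")
        if self.model == "OU-shift":
            if self.shift_species is None:
                raise ValueError("OU-shift requires shift_species")
            if self.shift_species not in self.tree.leaf_labels:
                raise ValueError(f"{self.shift_species!r} is not a leaf of the tree")
            if len(self.tree.leaf_labels) < 3:
                raise ValueError("shift genes require a tree with >= 3 leaves")


@dataclass
class PhyloSim:
    values: pd.DataFrame  # species x genes log expression
    truth: pd.DataFrame   # gene, model, shift_species, shift_size


def phylo_covariance(config: PhyloSimConfig) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Leaf mean vector and covariance matrix implied by the config."""
    c = config
    labels = c.tree.leaf_labels
    if c.model == "BM":
        cov = c.sigma2 * c.tree.shared_path_matrix().loc[labels, labels].to_numpy()
        mean = np.full(len(labels), c.root_state)
    else:
        d = c.tree.distance_matrix().loc[labels, labels].to_numpy()
        cov = (c.sigma2 / (2 * c.alpha)) * np.exp(-c.alpha * d)
        mean = np.full(len(labels), c.theta)
        if c.model == "OU-shift":
            i = labels.index(c.shift_species)
            t_f = c.tree.terminal_branch_length(c.shift_species)
            mean[i] += c.shift_size * (1.0 - np.exp(-c.alpha * t_f))
    return mean, cov, labels


def simulate_phylo_expression(config: PhyloSimConfig) -> PhyloSim:
    c = config
    rng, = _rngs(c.seed, 1)
    mean, cov, labels = phylo_covariance(c)
    # one Cholesky, reused across genes, keeps the draw bit-reproducible
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(labels)))
    z = rng.standard_normal(size=(len(labels), c.n_genes))
    vals = mean[:, None] + chol @ z
    genes = [f"og{i:05d}" for i in range(c.n_genes)]
    values = pd.DataFrame(vals, index=labels, columns=genes)
    truth = pd.DataFrame({
        "gene": genes,
        "model": c.model,
        "shift_species": c.shift_species if c.model == "OU-shift" else "",
        "shift_size": c.shift_size if c.model == "OU-shift" else 0.0,
    })
    return PhyloSim(values, truth)


# ---------------------------------------------------------------------------
# cell-type mixtures


@dataclass
class MixtureSimConfig:
    """Noisy bulk mixtures of a signature matrix with known proportions."""

    signature: SignatureMatrix = None  # type: ignore[assignment]
    n_samples: int = 50
    dirichlet_alpha: float = 1.0   # symmetric concentration over cell types
    noise_sd: float = 0.1          # additive Gaussian on the log scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signature is None:
            raise ValueError("signature is required")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        s = self.signature.values.to_numpy(dtype=float)
        if np.linalg.matrix_rank(s) < s.shape[1]:
            raise ValueError("signature columns must be linearly independent")


@dataclass
class MixtureSim:
    bulk: ExpressionMatrix
    proportions: pd.DataFrame  # samples x cell types (rows sum to 1)


def simulate_mixtures(config: MixtureSimConfig) -> MixtureSim:
    c = config
    rng_prop, rng_noise = _rngs(c.seed, 2)
    sig = c.signature.values
    k = sig.shape[1]
    props = rng_prop.dirichlet(np.full(k, c.dirichlet_alpha), size=c.n_samples)
    clean = sig.to_numpy() @ props.T  # genes x samples
    if c.noise_sd > 0:
        clean = clean * np.exp(rng_noise.normal(0.0, c.noise_sd, size=clean.shape))
    samples = [f"bulk{i:03d}" for i in range(c.n_samples)]
    bulk = ExpressionMatrix(
        pd.DataFrame(clean, index=sig.index, columns=samples),
        pd.Series("PCG", index=sig.index))
    proportions = pd.DataFrame(props, index=samples, columns=sig.columns)
    return MixtureSim(bulk, proportions)


def simulate_reference_profiles(n_types: int = 3, markers_per_type: int = 50,
                                profiles_per_type: int = 5, fold: float = 8.0,
                                base_log_mean: float = 1.0, noise_sd: float = 0.3,
                                seed: int = 0) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Labeled reference profiles with planted disjoint marker sets.

    Returns (reference expression, profile -> cluster labels, truth table of
    planted markers).  Used to exercise signature construction.
    """
    rng_base, rng_noise = _rngs(seed, 2)
    n_genes = n_types * markers_per_type
    genes = [f"m{i:04d}" for i in range(n_genes)]
    types = [f"type{chr(ord('A') + t)}" for t in range(n_types)]
    base = rng_base.normal(base_log_mean, 0.5, size=n_genes)
    log_mu = np.tile(base[:, None], (1, n_types))
    for t in range(n_types):
        rows = slice(t * markers_per_type, (t + 1) * markers_per_type)
        log_mu[rows, t] += np.log(fold)
    cols, labels, mu_cols = [], [], []
    for t, name in enumerate(types):
        for r in range(profiles_per_type):
            cols.append(f"{name}_ref{r}")
            labels.append(name)
            mu_cols.append(log_mu[:, t])
    vals = np.exp(np.stack(mu_cols, axis=1)
                  + rng_noise.normal(0.0, noise_sd, size=(n_genes, len(cols))))
    expr = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols),
                            pd.Series("PCG", index=genes))
    truth = pd.DataFrame({
        "gene_id": genes,
        "cell_type": np.repeat(types, markers_per_type),
    })
    return expr, pd.Series(labels, index=cols), truth


# ---------------------------------------------------------------------------
# spherical nucleus with planted radial gradients and TAD co-expression


@dataclass
class NucleusSimConfig:
    """Bins uniform in a unit ball with planted compartment/GC gradients.

    P(compartment A) = clip(1 - g x relative radius, 0, 1); GC decreases
    linearly with radius by ``gc_slope``.  Genes are tiled into TADs; genes
    within one TAD share a latent tissue profile so that the expected
    pairwise profile correlation equals ``coexpr_within_tad``.
    """

    n_chroms: int = 18
    bins_per_chrom: int = 500
    bin_width: int = 100_000
    gradient: float = 1.0          # g: radial compartment-A gradient strength
    gc_base: float = 0.48
    gc_slope: float = 0.06         # GC drop from center to periphery
    gc_noise_sd: float = 0.01
    genes_per_chrom: int = 40
    genes_per_tad: int = 4
    n_tissues: int = 10
    coexpr_within_tad: float = 0.0  # planted within-TAD profile correlation
    expr_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bins_per_chrom < 1 or self.n_chroms < 1:
            raise ValueError("bins per chrom and n_chroms must be >= 1")
        if not 0 <= self.coexpr_within_tad <= 1:
            raise ValueError("coexpr_within_tad must lie in [0, 1]")
        if self.gradient < 0:
            raise ValueError("gradient must be >= 0")


@dataclass
class NucleusSim:
    bins: GenomeBinTable
    tads: IntervalSet
    expr: ExpressionMatrix          # gene x tissue (one profile per gene)
    gene_positions: pd.DataFrame    # gene_id, chrom, start, end
    truth: pd.DataFrame             # gene_id, tad


def simulate_nucleus(config: NucleusSimConfig) -> NucleusSim:
    c = config
    rng_pos, rng_comp, rng_gc, rng_expr = _rngs(c.seed, 4)
    n = c.n_chroms * c.bins_per_chrom

    # uniform in the unit ball via radius ~ U^(1/3) x random direction
    direction = rng_pos.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = rng_pos.uniform(size=n) ** (1.0 / 3.0)
    xyz = direction * radius[:, None]

    # at g = 1 this is the planted 1 - r gradient; at g = 0 a flat 50% A
    # probability (radius-independent), so the null keeps both labels
    p_a = np.clip((1.0 + c.gradient) / 2.0 - c.gradient * radius, 0.0, 1.0)
    compartment = np.where(rng_comp.uniform(size=n) < p_a, "A", "B")
    gc = np.clip(c.gc_base - c.gc_slope * radius
                 + rng_gc.normal(0.0, c.gc_noise_sd, size=n), 0.0, 1.0)

    chroms = np.repeat([f"chr{i + 1}" for i in range(c.n_chroms)], c.bins_per_chrom)
    starts = np.tile(np.arange(c.bins_per_chrom) * c.bin_width, c.n_chroms)
    # gene density follows the planted A/GC organization loosely: more genes
    # in A bins
    gene_count = rng_gc.poisson(np.where(compartment == "A", 3.0, 1.0))
    bins = GenomeBinTable(pd.DataFrame({
        "chrom": chroms, "start": starts, "end": starts + c.bin_width,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "compartment": compartment, "gc": gc, "gene_count": gene_count,
    }))

    # TADs tile each chromosome; genes placed evenly inside TADs
    chrom_span = c.bins_per_chrom * c.bin_width
    n_tads_per_chrom = max(1, c.genes_per_chrom // c.genes_per_tad)
    tad_width = chrom_span // n_tads_per_chrom
    tad_rows, gene_rows = [], []
    rho = c.coexpr_within_tad
    profiles, gene_ids, gene_tads = [], [], []
    for ci in range(c.n_chroms):
        chrom = f"chr{ci + 1}"
        for ti in range(n_tads_per_chrom):
            t_start = ti * tad_width
            name = f"{chrom}_tad{ti:03d}"
            tad_rows.append((chrom, t_start, t_start + tad_width, name))
            latent = rng_expr.normal(0.0, 1.0, size=c.n_tissues)
            for gi in range(c.genes_per_tad):
                gid = f"{name}_g{gi}"
                g_start = t_start + (gi + 1) * tad_width // (c.genes_per_tad + 2)
                gene_rows.append((gid, chrom, g_start, g_start + 1000))
                noise = rng_expr.normal(0.0, 1.0, size=c.n_tissues)
                prof = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise
                profiles.append(prof * c.expr_noise_sd + 2.0)
                gene_ids.append(gid)
                gene_tads.append(name)
    tads = IntervalSet(pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "name"]))
    gene_positions = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    tissues = [f"tissue{i:02d}" for i in range(c.n_tissues)]
    expr = ExpressionMatrix(
        pd.DataFrame(np.exp(np.stack(profiles)), index=gene_ids, columns=tissues),
        pd.Series("PCG", index=pd.Index(gene_ids)))
    truth = pd.DataFrame({"gene_id": gene_ids, "tad": gene_tads})
    return NucleusSim(bins, tads, expr, gene_positions, truth)


# ---------------------------------------------------------------------------
# enhancer-redundancy buffering


@dataclass
class BufferingSimConfig:
    """PEI tables plus cross-species expression with a planted buffering effect.

    Per-gene enhancer count k is geometric (capped); expression is additive
    on the log scale (``expr_per_enhancer`` x k) and the per-species noise
    sd shrinks with k: sd = max(floor, base_noise_sd - buffering_effect x k).
    """

    n_genes: int = 2000
    tree: PhyloTree = field(default_factory=default_timetree)
    enhancer_geom_p: float = 0.35
    enhancer_cap: int = 10
    expr_per_enhancer: float = 0.1   # additive log-expression per enhancer
    base_log_mean: float = 2.0
    base_log_sd: float = 1.5
    base_noise_sd: float = 2.5       # per-species deviation sd at k = 0
    buffering_effect: float = 0.3    # sd reduction per enhancer
    noise_floor: float = 0.15
    resolution: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be > 0")
        if self.buffering_effect < 0:
            raise ValueError("buffering_effect must be >= 0")
        if self.base_noise_sd < self.noise_floor:
            raise ValueError("base_noise_sd must be >= noise_floor")


@dataclass
class BufferingSim:
    pei: PeiTable
    expr: pd.DataFrame   # species x genes log2 expression
    truth: pd.DataFrame  # gene_id, enhancer_count, noise_sd


def simulate_pei_buffering(config: BufferingSimConfig) -> BufferingSim:
    c = config
    rng_count, rng_base, rng_noise = _rngs(c.seed, 3)
    species = c.tree.leaf_labels
    genes = [f"bg{i:05d}" for i in range(c.n_genes)]

    counts = np.minimum(rng_count.geometric(c.enhancer_geom_p, size=c.n_genes) - 1,
                        c.enhancer_cap)
    base = rng_base.normal(c.base_log_mean, c.base_log_sd, size=c.n_genes)
    mean = base + c.expr_per_enhancer * counts
    sd = np.maximum(c.noise_floor, c.base_noise_sd - c.buffering_effect * counts)

    vals = mean[None, :] + rng_noise.normal(0.0, 1.0, size=(len(species), c.n_genes)) * sd[None, :]
    expr = pd.DataFrame(vals, index=species, columns=genes)

    gi_rep = np.repeat(np.arange(c.n_genes), counts)
    offset = np.concatenate([np.arange(k) for k in counts]) if len(gi_rep) else np.array([], dtype=int)
    enh_pos = (c.n_genes + gi_rep * c.enhancer_cap + offset) * c.resolution
    one_species = pd.DataFrame({
        "gene_id": np.asarray(genes, dtype=object)[gi_rep],
        "promoter_bin": [f"chr1:{g * c.resolution}" for g in gi_rep],
        "enhancer_bin": [f"chr1:{p}" for p in enh_pos],
    })
    pei_df = pd.concat([one_species.assign(species=sp) for sp in species],
                       ignore_index=True)
    pei = PeiTable(pei_df, resolution=c.resolution)
    truth = pd.DataFrame({"gene_id": genes, "enhancer_count": counts,
                          "noise_sd": sd})
    return BufferingSim(pei, expr, truth)


# ---------------------------------------------------------------------------
# exon inclusion counts (PSI)


def simulate_psi(n_exons: int, n_samples: int, coverage: int,
                 psi_truth, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Binomial inclusion/exclusion counts around a true PSI.

    ``psi_truth`` is a scalar or per-exon array in [0, 1].  Returns
    (inclusion, exclusion, truth) tables; at coverage 0 all counts are 0
    and downstream PSI is flagged missing by the coverage filter.
    """
    psi = np.broadcast_to(np.asarray(psi_truth, dtype=float), (n_exons,)).copy()
    if ((psi < 0) | (psi > 1)).any():
        raise ValueError("psi_truth must lie in [0, 1]")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng, = _rngs(seed, 1)
    incl = rng.binomial(coverage, psi[:, None], size=(n_exons, n_samples))
    excl = coverage - incl
    exons = [f"exon{i:05d}" for i in range(n_exons)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    inclusion = pd.DataFrame(incl, index=exons, columns=samples)
    exclusion = pd.DataFrame(excl, index=exons, columns=samples)
    truth = pd.DataFrame({"exon_id": exons, "psi": psi})
    return inclusion, exclusion, truth
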