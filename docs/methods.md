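# Methods

This note documents the models behind each analysis stage, the defaults of
the synthetic-data generators, and the numerical and design choices that
were genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Expression model and conventions

Expression is handled as TPM. All planted effects in the generators are
additive on the log scale and noise is Gaussian on the log scale
(equivalently, lognormal TPM): rank statistics (Spearman, tau) are
invariant to the base of the log, and the parametric stages (Pearson
correlation, PCA/PVCA, BM/OU likelihoods) operate on log2(TPM + 1), a
variance-stabilized scale. Genomic coordinates are 0-based half-open
everywhere inside the package; GFF-style 1-based inputs must be converted
at the I/O boundary. Gene-to-interval assignment uses the gene midpoint
with half-open intervals, so a midpoint exactly at an interval's `end`
belongs to the next interval.

## Atlas statistics

*Detection*: a transcript is detected when it reaches its class threshold
(PCG/TUCP/lncRNA 0.1 TPM, circRNA 0.05, miRNA 1.0 — miRNAs come from a
separate small-RNA library type, hence the different cut-off) in at least
one sample. The comparison is `>=` by default with a `strict` flag for
`>`; the two differ only for values exactly at the threshold.

*Tau*: replicates are averaged per tissue before scaling, so tissues with
more replicates do not dominate the profile. Tau is computed on linear
TPM by default; a `log_transform` flag applies log2(TPM + 1) first, which
compresses fold-changes and lowers tau for a given profile. Tau is
undefined (NaN) for genes with an all-zero profile.

*Complexity*: per tissue, transcripts whose replicate-averaged TPM reaches
the class threshold are "transcribed"; with N of them,
k = max(1, round(0.005·N)) (round half away from zero, so the value is
platform-independent) and complexity = TPM mass of the top k over the
total transcribed mass. The abundance-mass reading is used rather than a
transcript-count reading, because counting transcripts would make the
statistic identically 0.005 and uninformative; with mass it measures how
concentrated a tissue's output is.

*Marker sets*: Pearson correlation of every gene with the marker across
tissue-mean profiles; the marker-specific set is the top
ceil(0.10·eligible) genes by r. Zero-variance genes are excluded and
reported; a constant marker is an error.

## Comparative evolution

*PSI*: inclusion / (inclusion + exclusion), missing below a coverage of
10 reads by default.

*Divergence matrices*: all (species, tissue) profile pairs are correlated
(Spearman on raw TPM, Pearson on log2(TPM + 1)); the two reported group
means cover between-species-within-tissue and between-tissue-within-
species entries. Constant profiles yield NaN entries and are listed.

*PVCA*: genes are standardized, PCA is taken over samples, and the
smallest component set reaching 90% cumulative variance (configurable) is
retained. Per component, each factor's share is the method-of-moments
between-level variance (clipped to [0, 1]) over the component variance;
the unexplained remainder is the residual. Factor shares are averaged
with eigen-fraction weights and renormalized to sum exactly to 1.
Method-of-moments rather than REML keeps the decomposition deterministic
and dependency-free; for the balanced designs the generators produce the
two agree closely. Confounded factors (identical sample partitions) are
rejected by name.

*Expression trees*: neighbor joining (via scikit-bio) on D = 1 − r.
Negative NJ branch lengths are clamped to zero and counted in the result.
Two species degenerate to a single branch of length D. "Random sampling"
for the branch-length distribution is a gene bootstrap: resample genes
with replacement at the original size, rebuild, record the total length
(100 replicates by default) — the standard stability device for
expression trees.

*BM/OU*: one gene at a time, leaf values x are multivariate normal.
BM: mean μ·1, Cov = σ²·t_shared. OU: the likelihood is conditioned on the
root sitting at the optimum θ, giving
Cov_ij = σ²/(2α)·(e^(−α·d_ij) − e^(−α·(t_i + t_j))). This
parameterization converges to BM exactly as α → 0, so the BM likelihood
is the α = 0 boundary of the OU fit and the nesting
logLik(shifted OU) ≥ logLik(OU) ≥ logLik(BM) holds by construction. A
`stationary` root mode (Cov = σ²/(2α)·e^(−α·d_ij)) is available and
matches the simulator, which draws the root from the stationary
distribution; the stationary likelihood does *not* converge to BM as
α → 0 (its variance diverges), which is why the conditioned form is the
fitting default. σ² and the mean parameters are profiled out in closed
form (GLS), so each fit is a one-dimensional search over α on a fixed
log-spaced grid (0 plus 48 points in [1e-4, 20] per MY) followed by
bounded local refinement — deterministic, no random starts. Model choice
is by AICc (n = number of leaves; with 9 leaves AICc is conservative, so
single-optimum OU is only chosen on strong evidence). Genes with
identical values at all leaves are degenerate (σ̂² = 0, unbounded
likelihood); they are reported as BM with no shift evidence.

*Shifts*: per gene and focal species, a shifted-OU model adds one optimum
on the focal terminal branch, displacing that leaf's mean by
δ·(1 − e^(−α·t_focal)); 2·ΔlogLik is referred to χ²₁ and q-values are
Benjamini–Hochberg within species across genes (the analysis reports
per-species shift counts, so that is the natural family). Shifted-OU
likelihoods below the OU likelihood are impossible under this scheme and
are flagged as optimizer failures if they occur. A correction for
nucleotide-level divergence between species is *not* implemented — the
upstream procedure it would mirror is not specified — so shift calls on
real data conflate expression and alignment-quality divergence; on
synthetic data this does not arise.

## Deconvolution

Markers are selected per cluster by a one-sided Wilcoxon rank-sum test
(cluster vs rest) with BH correction (q ≤ 0.05) and log2 fold change
≥ 1 on mean TPM + 1; a gene passing in several clusters is kept in its
maximal-mean cluster. The signature entry is the per-cluster mean in
linear TPM. Proportions are non-negative least squares of the bulk marker
vector on the signature columns, renormalized to sum to one; the
pre-normalization residual is reported per sample. NNLS replaces the
ν-SVR solver of the external deconvolution service the field commonly
uses: it is deterministic, exactly recovers noise-free mixtures, and
targets the same linear mixture model. Proportions are invariant to
global rescaling of a bulk sample (NNLS on c·b gives c·coefficients, and
the simplex renormalization removes c).

## Nuclear geometry

The nuclear center is the unweighted centroid of all bin coordinates —
parameter-free and equivariant, so every radial quantity is invariant
under rigid motions of the structure. The X chromosome is excluded by
default (X inactivation dominates its positioning). Shells are equal in
radial *width* on relative distance (distance / max distance), 20 by
default; an equal-volume option exists. Shells with fewer than 250
labeled bins are excluded from the shell correlation. The within-TAD
co-expression test calls a gene pair co-expressed when the Pearson r of
tissue-mean log2(TPM + 1) profiles reaches a cutoff (0.7 default; the
cutoff is always part of the result because the choice is a genuine free
parameter), takes the background rate p₀ from all same-chromosome pairs,
and tests the within-TAD count one-sided against Binomial(n, p₀).

## Synthetic-data generators

Each generator is a pure function of its config (one seed, fanned out to
per-component streams via `SeedSequence.spawn`), and returns ground truth
alongside the data. Defaults, and why:

- **Atlas** (`AtlasSimConfig`): 2000 genes × 10 tissues × 3 replicates,
  20% planted tissue-specific at 50-fold elevation, baseline log-TPM
  N(1, 1), replicate noise sd 0.2 — a planted effect large enough that
  tau recovery is a property of the statistic, not of luck, at a size
  that keeps the suite fast.
- **Phylo** (`PhyloSimConfig`): a nine-mammal ultrametric timetree with
  literature divergence times (mouse–rat 15.9 MY, murids–guinea pig 70,
  cat–dog 55, pig–sheep 64, root 96) is the default tree. BM σ² = 0.01
  per MY; OU α = 0.05 per MY, θ = 2 — at these values the stationary sd
  is ≈ 0.32 log units and terminal branches are several OU half-lives
  long, so a "4 stationary sd" optimum shift displaces the focal leaf by
  nearly its full size.
- **Mixtures** (`MixtureSimConfig`): Dirichlet(1, …, 1) proportions
  (uninformative over the simplex), lognormal multiplicative noise
  (sd 0.1 on the log scale).
- **Nucleus** (`NucleusSimConfig`): bins uniform in the unit ball;
  P(A) = clip((1 + g)/2 − g·radius), which is the planted 1 − r gradient
  at g = 1 and a flat 50% at g = 0 (the g = 0 null must keep both labels,
  which a pure 1 − g·r form cannot); GC declines linearly with radius;
  genes tile TADs and share a within-TAD latent tissue profile with
  correlation ρ.
- **Buffering** (`BufferingSimConfig`): 2000 genes, geometric enhancer
  counts (capped at 10), +0.1 log-expression per enhancer, baseline
  spread sd 1.5, per-species deviation sd 2.5 shrinking by 0.3 per
  enhancer (floor 0.15). The noise-dominated regime is deliberate: the
  paired signed-rank test over species pairs reuses the same gene sets in
  every pair, so it is anti-conservative for *any* systematic difference
  in set composition; with between-species noise large relative to
  between-gene spread, per-pair rank noise dominates composition wobble
  and the matched-control chain is calibrated under the null while the
  planted buffering effect remains unambiguous. The moderate dose effect
  keeps the expression-matched control pool on common support.
- **PSI**: Binomial(coverage, ψ) inclusion counts; coverage 0 yields
  all-zero counts that the coverage filter flags as missing.

What the generators do *not* emulate: gene-length and GC biases,
count-level (Poisson/NB) noise, unbalanced replicate designs, correlated
gene modules outside TADs, assembly or mapping artifacts, and
time-dependent species noise. Passing recovery tests therefore
demonstrates correctness of the statistics under the stated model, not
robustness to real-data pathologies.

## Enhancer buffering chain

Enhancer counts are distinct enhancer bins per (gene, species); genes
absent from a species' interaction table count 0 there (absence of called
interactions is the observable) and the filled cells are tallied for
audit. Classes use the cross-species *median* count: multi ≥ 5, few ≤ 1
(both configurable). Matching is greedy 1-1 nearest neighbor without
replacement on mean log expression, treatment processed in descending
covariate order with lexicographic tie-breaks — deterministic and
order-stable; an optimal-assignment mode (`optimal=True`, Hungarian
algorithm) exists for small sets. No caliper is applied. Per species
pair, the Spearman correlation is computed across the set's genes jointly
(matching the set-level phrasing of the analysis), the set-vs-control
comparison is a paired Wilcoxon signed-rank over identical species-pair
lists, and each set's correlations are regressed on log10(divergence
time). CV classes take sd/mean of per-species expression on the linear
scale (conventional CV; a log-scale option exists), the m lowest/highest
CV genes, and compare phastCons and phyloP by two-sided rank-sum tests,
Bonferroni-corrected over the two scores.

## Known limitations

- The shell-profile Spearman correlation is computed over ~16–20 shell
  summary points; any such rank statistic has a null sd of about
  1/sqrt(K − 1) ≈ 0.25 *regardless of how many bins each shell holds*, so
  a "no gradient" structure still produces |r| in the 0.2–0.5 range
  roughly 40% of the time. The per-shell fractions, counts, and the
  p-value reported alongside r are the better-calibrated null readouts.
- OU parameters on small trees (≤ 10 leaves) are weakly identified; AICc
  intentionally favors BM unless the OU signal is strong.
- The matched-control buffering test inherits the anti-conservativeness
  described above whenever set composition differs systematically; on
  real data, report the per-pair differences and effect size alongside
  the signed-rank p.
- PVCA's method-of-moments decomposition assumes approximately balanced
  designs; heavily unbalanced designs shift variance between factors and
  residual.
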