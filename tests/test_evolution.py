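"""Comparative statistics: PSI, divergence, PVCA, NJ trees, time trends."""

import numpy as np
import pandas as pd
import pytest

from bodymap import evolution as evo
from bodymap.datatypes import OrthologMap, PhyloTree


class TestPsi:
    def test_ratio_identity(self):
        inc = pd.DataFrame([[30]], index=["e"], columns=["s"])
        exc = pd.DataFrame([[10]], index=["e"], columns=["s"])
        assert evo.compute_psi(inc, exc).psi.iloc[0, 0] == pytest.approx(0.75)

    def test_boundary_zero(self):
        inc = pd.DataFrame([[0]], index=["e"], columns=["s"])
        exc = pd.DataFrame([[50]], index=["e"], columns=["s"])
        assert evo.compute_psi(inc, exc).psi.iloc[0, 0] == 0.0

    def test_coverage_filter(self):
        inc = pd.DataFrame([[4]], index=["e"], columns=["s"])
        exc = pd.DataFrame([[4]], index=["e"], columns=["s"])
        assert np.isnan(evo.compute_psi(inc, exc, min_coverage=10).psi.iloc[0, 0])

    def test_exhaustive_small_grid(self):
        # every (I, E) pair on a small grid: PSI = I/(I+E) iff coverage >= 5
        cells = [(i, e) for i in range(8) for e in range(8)]
        inc = pd.DataFrame([[i for i, _ in cells]], index=["e"]).T
        inc.index = [f"x{k}" for k in range(len(cells))]
        inc.columns = ["s"]
        exc = inc.copy()
        exc["s"] = [e for _, e in cells]
        res = evo.compute_psi(inc, exc, min_coverage=5)
        for k, (i, e) in enumerate(cells):
            got = res.psi.iloc[k, 0]
            if i + e >= 5:
                assert got == pytest.approx(i / (i + e))
            else:
                assert np.isnan(got)

    def test_negative_counts_rejected(self):
        inc = pd.DataFrame([[-1]], index=["e"], columns=["s"])
        exc = pd.DataFrame([[5]], index=["e"], columns=["s"])
        with pytest.raises(ValueError, match="non-negative"):
            evo.compute_psi(inc, exc)


def _ortho(species, n):
    return OrthologMap(pd.DataFrame({sp: [f"{sp}_{i}" for i in range(n)]
                                     for sp in species}))


def _species_table(sp, mat, tissues):
    return pd.DataFrame(mat, index=[f"{sp}_{i}" for i in range(mat.shape[0])],
                        columns=tissues)


class TestDivergenceMatrix:
    def test_identical_profiles_r_one(self):
        rng = np.random.default_rng(0)
        mat = rng.gamma(2, 5, size=(50, 2))
        orth = _ortho(["a", "b"], 50)
        tabs = {"a": _species_table("a", mat, ["t1", "t2"]),
                "b": _species_table("b", mat, ["t1", "t2"])}
        dm = evo.divergence_matrix(tabs, orth)
        assert dm.corr.loc[("a", "t1"), ("b", "t1")] == pytest.approx(1.0)
        assert dm.mean_between_species == pytest.approx(1.0)

    def test_spearman_hand_value(self):
        # ranks (1,2,3) vs (3,1,2): rho = 1 - 6*6/(3*8) = -0.5
        orth = _ortho(["a", "b"], 3)
        tabs = {"a": _species_table("a", np.array([[1.0], [2.0], [3.0]]), ["t"]),
                "b": _species_table("b", np.array([[3.0], [1.0], [2.0]]), ["t"])}
        dm = evo.divergence_matrix(tabs, orth)
        assert dm.corr.loc[("a", "t"), ("b", "t")] == pytest.approx(-0.5)

    def test_constant_profile_flagged(self):
        orth = _ortho(["a", "b"], 4)
        tabs = {"a": _species_table("a", np.ones((4, 1)), ["t"]),
                "b": _species_table("b", np.arange(4.0)[:, None], ["t"])}
        dm = evo.divergence_matrix(tabs, orth)
        assert np.isnan(dm.corr.loc[("a", "t"), ("b", "t")])
        assert len(dm.undefined_pairs) == 1

    def test_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(1)
        orth = _ortho(["a", "b", "c"], 30)
        tabs = {sp: _species_table(sp, rng.gamma(2, 5, (30, 3)), ["t1", "t2", "t3"])
                for sp in ["a", "b", "c"]}
        dm = evo.divergence_matrix(tabs, orth)
        c = dm.corr.to_numpy()
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert np.nanmax(np.abs(c)) <= 1 + 1e-12


class TestPvca:
    def _design(self, n_species=3, n_tissues=4, reps=1):
        samples, rows = [], []
        for s in range(n_species):
            for t in range(n_tissues):
                for r in range(reps):
                    samples.append(f"sp{s}_t{t}_r{r}")
                    rows.append((f"sp{s}", f"t{t}"))
        factors = pd.DataFrame(rows, columns=["species", "tissue"], index=samples)
        return samples, factors

    def test_planted_tissue_factor(self):
        rng = np.random.default_rng(2)
        samples, factors = self._design(reps=2)
        offsets = {t: rng.normal(0, 3, 500) for t in factors["tissue"].unique()}
        cols = [offsets[factors.loc[s, "tissue"]] for s in samples]
        expr = pd.DataFrame(np.array(cols).T + rng.normal(0, 1e-6, (500, len(samples))),
                            columns=samples)
        res = evo.pvca(expr, factors)
        assert res.wapv["tissue"] > 0.9
        assert res.wapv["species"] < 0.05

    def test_pure_noise_residual(self):
        rng = np.random.default_rng(3)
        samples, factors = self._design(n_species=4, n_tissues=5, reps=2)
        expr = pd.DataFrame(rng.normal(0, 1, (1000, len(samples))), columns=samples)
        res = evo.pvca(expr, factors)
        assert res.wapv["residual"] > 0.8

    def test_wapv_sums_to_one_and_factor_order_equivariant(self):
        rng = np.random.default_rng(4)
        samples, factors = self._design(reps=2)
        expr = pd.DataFrame(rng.gamma(2, 1, (200, len(samples))), columns=samples)
        res = evo.pvca(expr, factors)
        assert res.wapv.sum() == pytest.approx(1.0, abs=1e-9)
        res_swapped = evo.pvca(expr, factors[["tissue", "species"]])
        for f in ("species", "tissue", "residual"):
            assert res.wapv[f] == pytest.approx(res_swapped.wapv[f], abs=1e-12)

    def test_confounded_factors_rejected(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(8)]
        factors = pd.DataFrame({
            "species": ["a"] * 4 + ["b"] * 4,
            "site": ["x"] * 4 + ["y"] * 4,   # identical partition
        }, index=samples)
        expr = pd.DataFrame(rng.normal(size=(50, 8)), columns=samples)
        with pytest.raises(ValueError, match="confounded"):
            evo.pvca(expr, factors)


class TestExpressionTree:
    def test_three_taxon_equidistant(self):
        d = pd.DataFrame(2.0 * (1 - np.eye(3)), index=list("ABC"), columns=list("ABC"))
        newick, total, clamped = evo.tree_from_distances(d)
        assert total == pytest.approx(3.0)
        assert clamped == 0

    def test_two_species_single_branch(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.gamma(2, 5, (2, 100)), index=["a", "b"])
        tree = evo.build_expression_tree(expr)
        assert tree.total_length == pytest.approx(
            float(tree.distances.loc["a", "b"]))

    def test_additive_recovery(self):
        from conftest import random_additive_distances
        rng = np.random.default_rng(7)
        for n_taxa in (4, 5):
            for _ in range(50):
                d, total = random_additive_distances(rng, n_taxa)
                _, got, clamped = evo.tree_from_distances(d)
                assert got == pytest.approx(total, abs=1e-9)
                assert clamped == 0

    def test_identical_profiles_zero_length(self):
        expr = pd.DataFrame(np.tile(np.random.default_rng(8).gamma(2, 5, 50), (3, 1)),
                            index=["a", "b", "c"])
        tree = evo.build_expression_tree(expr)
        assert tree.total_length == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_determinism_and_degenerate(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(np.tile(rng.gamma(2, 5, 60), (4, 1)),
                            index=list("abcd"))
        res1 = evo.branch_length_distribution(expr, n_replicates=20, seed=11)
        res2 = evo.branch_length_distribution(expr, n_replicates=20, seed=11)
        np.testing.assert_array_equal(res1.totals, res2.totals)
        np.testing.assert_allclose(res1.totals, 0.0, atol=1e-12)

    def test_bootstrap_median_near_point_estimate(self, timetree):
        from bodymap import simulate as sim
        ps = sim.simulate_phylo_expression(sim.PhyloSimConfig(
            tree=timetree, n_genes=1000, model="BM", sigma2=0.05, seed=10))
        expr = np.exp(ps.values)
        res = evo.branch_length_distribution(expr, n_replicates=50, seed=12)
        assert abs(res.median - res.point_estimate) / res.point_estimate < 0.1


class TestTimeTrend:
    def _div(self, corr_by_pair, tissue="t"):
        species = sorted({s for pair in corr_by_pair for s in pair})
        units = [(s, tissue) for s in species]
        idx = pd.MultiIndex.from_tuples(units, names=["species", "tissue"])
        mat = pd.DataFrame(np.eye(len(units)), index=idx, columns=idx)
        for (a, b), r in corr_by_pair.items():
            mat.loc[(a, tissue), (b, tissue)] = r
            mat.loc[(b, tissue), (a, tissue)] = r
        return evo.DivergenceMatrix(mat, "spearman", np.nan, np.nan, [])

    def test_monotone_decreasing_gives_minus_one(self):
        tree = PhyloTree.from_newick("((A:10,B:10):40,(C:30,D:30):20);")
        # times: AB=10, CD=30, all cross pairs tie at 50; correlations
        # decrease with time and tie exactly where times tie
        corr = {("A", "B"): 0.9, ("C", "D"): 0.7,
                ("A", "C"): 0.4, ("A", "D"): 0.4,
                ("B", "C"): 0.4, ("B", "D"): 0.4}
        res = evo.divergence_time_trend(self._div(corr), tree)
        assert res.per_tissue.loc["t", "spearman_r"] == pytest.approx(-1.0)
        assert res.per_tissue.loc["t", "slope"] < 0

    def test_two_species_rejected(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="pairs"):
            evo.divergence_time_trend(self._div({("A", "B"): 0.5}), tree)

    def test_shuffled_null_small_correlation(self, timetree):
        rng = np.random.default_rng(13)
        species = timetree.leaf_labels
        hits = 0
        for _ in range(40):
            corr = {}
            for i, a in enumerate(species):
                for b in species[i + 1:]:
                    corr[(a, b)] = rng.uniform(0.3, 0.9)
            res = evo.divergence_time_trend(self._div(corr), timetree)
            if abs(res.per_tissue.loc["t", "spearman_r"]) < 0.4:
                hits += 1
        assert hits >= 0.8 * 40
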