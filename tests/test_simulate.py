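"""Generator contracts: determinism, planted structure, closed-form checks."""

import numpy as np
import pandas as pd
import pytest

from bodymap import atlas, simulate as sim


class TestAtlasSim:
    def test_determinism(self):
        cfg = sim.AtlasSimConfig(n_genes=100, seed=7)
        a = sim.simulate_atlas(cfg)
        b = sim.simulate_atlas(sim.AtlasSimConfig(n_genes=100, seed=7))
        pd.testing.assert_frame_equal(a.expr.values, b.expr.values)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_extreme_fold_gives_tau_one(self):
        cfg = sim.AtlasSimConfig(n_genes=200, n_tissues=8, fraction_specific=0.5,
                                 fold_up=1e6, noise_sd=0.0, seed=1)
        a = sim.simulate_atlas(cfg)
        spec = atlas.compute_tau(a.expr, a.metadata)
        planted = a.truth[a.truth.home_tissue != "ubiquitous"].gene_id
        assert (spec.tau.loc[planted] > 0.999).all()

    def test_no_planted_genes_low_tau(self):
        cfg = sim.AtlasSimConfig(n_genes=300, fraction_specific=0.0,
                                 noise_sd=0.1, seed=2)
        a = sim.simulate_atlas(cfg)
        assert (a.truth.home_tissue == "ubiquitous").all()
        spec = atlas.compute_tau(a.expr, a.metadata)
        assert spec.tau.median() < 0.3

    def test_fold_up_monotone_in_tau(self):
        taus = []
        for fold in (2.0, 10.0, 100.0):
            cfg = sim.AtlasSimConfig(n_genes=300, fraction_specific=0.3,
                                     fold_up=fold, noise_sd=0.2, seed=3)
            a = sim.simulate_atlas(cfg)
            spec = atlas.compute_tau(a.expr, a.metadata)
            planted = a.truth[a.truth.home_tissue != "ubiquitous"].gene_id
            taus.append(spec.tau.loc[planted].mean())
        assert taus[0] < taus[1] < taus[2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sim.AtlasSimConfig(fold_up=0.5)
        with pytest.raises(ValueError):
            sim.AtlasSimConfig(fraction_specific=1.5)


class TestPhyloSim:
    def test_bm_two_leaf_contrast_variance(self):
        # Var(x_A - x_B) under BM with sigma2 = 2 on two branches of 1 MY is
        # 2 * sigma2 * t = 4; check the empirical variance over 10,000 draws
        tree = sim.PhyloTree.from_newick("(A:1,B:1);")
        cfg = sim.PhyloSimConfig(tree=tree, n_genes=10_000, model="BM",
                                 sigma2=2.0, seed=5)
        ps = sim.simulate_phylo_expression(cfg)
        contrast = ps.values.loc["A"] - ps.values.loc["B"]
        assert float(contrast.var()) == pytest.approx(4.0, rel=0.05)

    def test_ou_large_alpha_independent(self, timetree):
        cfg = sim.PhyloSimConfig(tree=timetree, n_genes=5000, model="OU",
                                 alpha=5.0, sigma2=10.0, theta=1.0, seed=6)
        ps = sim.simulate_phylo_expression(cfg)
        c = np.corrcoef(ps.values.to_numpy())
        off = c[~np.eye(len(c), dtype=bool)]
        assert np.abs(off).max() < 0.08
        sd = np.sqrt(cfg.sigma2 / (2 * cfg.alpha))
        assert ps.values.to_numpy().mean() == pytest.approx(1.0, abs=3 * sd / 50)

    def test_zero_shift_identical_to_ou(self, timetree):
        base = dict(tree=timetree, n_genes=500, alpha=0.05, sigma2=0.01,
                    theta=2.0, seed=8)
        ou = sim.simulate_phylo_expression(sim.PhyloSimConfig(model="OU", **base))
        shifted = sim.simulate_phylo_expression(sim.PhyloSimConfig(
            model="OU-shift", shift_species="cat", shift_size=0.0, **base))
        pd.testing.assert_frame_equal(ou.values, shifted.values)

    def test_alpha_zero_ou_rejected(self, timetree):
        with pytest.raises(ValueError, match="BM"):
            sim.PhyloSimConfig(tree=timetree, model="OU", alpha=0.0)

    def test_shift_species_must_be_leaf(self, timetree):
        with pytest.raises(ValueError, match="leaf"):
            sim.PhyloSimConfig(tree=timetree, model="OU-shift",
                               shift_species="unicorn", shift_size=1.0)


class TestMixtureSim:
    @pytest.fixture()
    def signature(self):
        ref, labels, _ = sim.simulate_reference_profiles(seed=0)
        from bodymap.deconvolution import build_signature
        return build_signature(ref, labels)

    def test_noise_free_pure_sample(self, signature):
        cfg = sim.MixtureSimConfig(signature=signature, n_samples=3,
                                   noise_sd=0.0, seed=0)
        mx = sim.simulate_mixtures(cfg)
        recon = signature.values.to_numpy() @ mx.proportions.to_numpy().T
        np.testing.assert_allclose(mx.bulk.values.to_numpy(), recon, rtol=1e-12)

    def test_proportions_on_simplex(self, signature):
        mx = sim.simulate_mixtures(sim.MixtureSimConfig(signature=signature,
                                                        n_samples=40, seed=1))
        p = mx.proportions.to_numpy()
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_determinism(self, signature):
        a = sim.simulate_mixtures(sim.MixtureSimConfig(signature=signature, seed=2))
        b = sim.simulate_mixtures(sim.MixtureSimConfig(signature=signature, seed=2))
        pd.testing.assert_frame_equal(a.bulk.values, b.bulk.values)


class TestNucleusSim:
    def test_determinism(self):
        a = sim.simulate_nucleus(sim.NucleusSimConfig(n_chroms=4, bins_per_chrom=50, seed=3))
        b = sim.simulate_nucleus(sim.NucleusSimConfig(n_chroms=4, bins_per_chrom=50, seed=3))
        pd.testing.assert_frame_equal(a.bins.table, b.bins.table)
        pd.testing.assert_frame_equal(a.expr.values, b.expr.values)

    def test_bins_inside_unit_ball(self):
        ns = sim.simulate_nucleus(sim.NucleusSimConfig(n_chroms=4, bins_per_chrom=200, seed=4))
        assert (np.linalg.norm(ns.bins.coords(), axis=1) <= 1.0 + 1e-12).all()

    def test_gradient_monotone_in_shell_correlation(self):
        from bodymap.nucleus import shell_profile
        rs = []
        for g in (0.3, 0.6, 1.0):
            ns = sim.simulate_nucleus(sim.NucleusSimConfig(
                n_chroms=18, bins_per_chrom=1000, gradient=g, seed=5))
            rs.append(shell_profile(ns.bins, min_bins=100).spearman_r)
        assert rs[0] > rs[2]
        assert rs[1] > rs[2] or rs[0] > rs[1]

    def test_within_tad_correlation_planted(self):
        ns = sim.simulate_nucleus(sim.NucleusSimConfig(
            n_chroms=2, bins_per_chrom=100, genes_per_chrom=40,
            genes_per_tad=4, n_tissues=30, coexpr_within_tad=0.8, seed=6))
        log_expr = np.log(ns.expr.values.to_numpy())
        truth = ns.truth.set_index("gene_id")["tad"]
        within, between = [], []
        genes = list(ns.expr.gene_ids)
        c = np.corrcoef(log_expr)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                (within if truth[genes[i]] == truth[genes[j]] else between).append(c[i, j])
        assert np.mean(within) > 0.5
        assert abs(np.mean(between)) < 0.15


class TestBufferingSim:
    def test_determinism(self, timetree):
        cfg = sim.BufferingSimConfig(tree=timetree, n_genes=100, seed=9)
        a = sim.simulate_pei_buffering(cfg)
        b = sim.simulate_pei_buffering(sim.BufferingSimConfig(
            tree=timetree, n_genes=100, seed=9))
        pd.testing.assert_frame_equal(a.pei.table, b.pei.table)
        pd.testing.assert_frame_equal(a.expr, b.expr)

    def test_dose_effect_positive(self, timetree):
        bs = sim.simulate_pei_buffering(sim.BufferingSimConfig(
            tree=timetree, n_genes=5000, seed=10))
        from scipy.stats import spearmanr
        truth = bs.truth.set_index("gene_id")
        for sp in bs.expr.index:
            r = spearmanr(truth["enhancer_count"],
                          bs.expr.loc[sp, truth.index]).statistic
            assert r > 0

    def test_noise_sd_shrinks_with_count(self, timetree):
        bs = sim.simulate_pei_buffering(sim.BufferingSimConfig(
            tree=timetree, n_genes=2000, buffering_effect=0.3, seed=11))
        t = bs.truth
        assert t.loc[t.enhancer_count >= 5, "noise_sd"].max() \
            < t.loc[t.enhancer_count <= 1, "noise_sd"].min()

    def test_floor_respected(self, timetree):
        bs = sim.simulate_pei_buffering(sim.BufferingSimConfig(
            tree=timetree, n_genes=500, buffering_effect=1.0, seed=12))
        assert (bs.truth.noise_sd >= 0.15 - 1e-12).all()


class TestPsiSim:
    def test_boundary_psi_one(self):
        _, exc, _ = sim.simulate_psi(50, 4, coverage=100, psi_truth=1.0, seed=0)
        assert (exc.to_numpy() == 0).all()

    def test_binomial_concentration(self):
        inc, exc, _ = sim.simulate_psi(200, 1, coverage=10_000, psi_truth=0.5, seed=1)
        emp = inc.to_numpy() / (inc.to_numpy() + exc.to_numpy())
        assert np.abs(emp - 0.5).max() < 0.02

    def test_zero_coverage_flagged_missing(self):
        from bodymap.evolution import compute_psi
        inc, exc, _ = sim.simulate_psi(10, 2, coverage=0, psi_truth=0.5, seed=2)
        assert (inc.to_numpy() == 0).all()
        psi = compute_psi(inc, exc, min_coverage=10)
        assert psi.psi.isna().all().all()

    def test_determinism(self):
        a = sim.simulate_psi(20, 3, 50, 0.3, seed=3)
        b = sim.simulate_psi(20, 3, 50, 0.3, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
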