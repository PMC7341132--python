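"""Design matrices, genomic REML, and GBLUP prediction."""

import numpy as np
import pandas as pd
import pytest

from haplogs.gblup import (DesignMatrix, build_hap_design, build_snp_design,
                           gblup_predict, reml_fit)
from haplogs.genio import GenotypeMatrix
from haplogs.hapblocks import build_blocks
from haplogs.simdata import SimConfig, simulate_phenotypes, simulate_population
from haplogs.fieldadj import combine_trials


def _sim_xy(seed, n_lines=(40, 30, 30), h=0.5):
    cfg = SimConfig(seed=seed, cluster_sizes=n_lines, n_chromosomes=3,
                    markers_per_chromosome=(40,) * 3, n_qtl=20,
                    heritability_targets={"t": h}, spatial_trend_amplitude=0)
    pop = simulate_population(cfg)
    y = combine_trials(simulate_phenotypes(pop, cfg), "t")
    return pop, y


class TestBuildSnpDesign:
    def test_symmetric_frequency_codings(self):
        # p1 = p2 = 0.5: genotypes (2,1,0) code to (1, 0, -1)
        g = GenotypeMatrix(list("abcd"), ["m1"],
                           np.array([[2], [1], [0], [1]], dtype=np.int8))
        W = build_snp_design(g)
        np.testing.assert_allclose(W.W[:, 0], [1.0, 0.0, -1.0, 0.0])

    def test_skewed_frequency_codings(self):
        # p1 = 0.25 over the reference -> codings (1.5, 0.5, -0.5)
        g = GenotypeMatrix(list("abcd"), ["m1"],
                           np.array([[2], [0], [0], [0]], dtype=np.int8))
        W = build_snp_design(g)
        np.testing.assert_allclose(sorted(W.W[:, 0]), [-0.5, -0.5, -0.5, 1.5])

    def test_columns_centred_over_reference(self, small_pop):
        W = build_snp_design(small_pop.genotypes)
        np.testing.assert_allclose(W.W.sum(axis=0), 0.0, atol=1e-9)

    def test_monomorphic_columns_dropped(self):
        d = np.array([[2, 2], [0, 2], [2, 2]], dtype=np.int8)
        g = GenotypeMatrix(list("abc"), ["poly", "mono"], d)
        W = build_snp_design(g)
        assert W.col_ids == ["poly"]

    def test_empty_reference_rejected(self, small_pop):
        with pytest.raises(ValueError, match="nonempty"):
            build_snp_design(small_pop.genotypes, freq_ref=[])


class TestBuildHapDesign:
    def test_biallelic_block_carrier_coding(self):
        # two alleles at frequency 0.5: carriers code +1, non-carriers -1
        d = np.array([[2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int8)
        g = GenotypeMatrix(list("abcd"), ["m1", "m2"], d)
        from haplogs.genio import GeneticMap
        gmap = GeneticMap.from_arrays(["m1", "m2"], ["1", "1"], [0.0, 1.0])
        W = build_hap_design(build_blocks(g, gmap, 2))
        np.testing.assert_allclose(W.W[:, 0], [1.0, 1.0, -1.0, -1.0])
        np.testing.assert_allclose(W.W[:, 1], [-1.0, -1.0, 1.0, 1.0])

    def test_three_allele_block_substitution(self):
        # frequencies (0.5, 0.25, 0.25); a carrier of allele 2 codes
        # (-1.0, 1.5, -0.5) across the block's columns
        d = np.array([[2, 2], [2, 2], [0, 2], [2, 0]], dtype=np.int8)
        g = GenotypeMatrix(list("abcd"), ["m1", "m2"], d)
        from haplogs.genio import GeneticMap
        gmap = GeneticMap.from_arrays(["m1", "m2"], ["1", "1"], [0.0, 1.0])
        W = build_hap_design(build_blocks(g, gmap, 2))
        np.testing.assert_allclose(W.W[2], [-1.0, 1.5, -0.5])

    def test_block_rows_sum_to_zero(self, small_pop):
        hbs = build_blocks(small_pop.genotypes, small_pop.gmap, 5)
        W = build_hap_design(hbs)
        # per line, Σ_k x_k = 2 and frequencies sum to 1 -> row sums 0
        np.testing.assert_allclose(W.W.sum(axis=1), 0.0, atol=1e-9)


class TestRemlFit:
    def test_recovers_simulated_components(self):
        """Estimates fall within ±2 Monte-Carlo SE of the truth at n=500."""
        rng = np.random.default_rng(42)
        n, m = 500, 400
        s_a2, s_e2 = 0.02, 1.0
        est = []
        for _ in range(20):
            Wm = rng.integers(0, 2, size=(n, m)) * 2.0
            Wm -= Wm.mean(axis=0)
            ids = [f"L{i}" for i in range(n)]
            alpha = rng.normal(0, np.sqrt(s_a2), m)
            y = pd.Series(Wm @ alpha + rng.normal(0, np.sqrt(s_e2), n) + 3.0,
                          index=ids)
            vc = reml_fit(y, DesignMatrix(ids, list(range(m)), Wm))
            assert vc.converged
            est.append((vc.sigma_marker2, vc.sigma_e2))
        est = np.array(est)
        for truth, col in ((s_a2, 0), (s_e2, 1)):
            se = est[:, col].std(ddof=1) / np.sqrt(len(est))
            assert abs(est[:, col].mean() - truth) < 2 * se + 1e-12

    def test_constant_phenotype_degenerate_flagged(self):
        rng = np.random.default_rng(0)
        ids = [f"L{i}" for i in range(30)]
        Wm = rng.normal(size=(30, 10))
        y = pd.Series(5.0, index=ids)
        vc = reml_fit(y, DesignMatrix(ids, list(range(10)), Wm))
        assert vc.sigma_marker2 == 0.0 and vc.sigma_e2 == 0.0
        assert not vc.converged

    def test_matches_brute_force_reml_on_small_instance(self):
        """Spectral fit equals a dense grid/Nelder-Mead REML on n=50."""
        rng = np.random.default_rng(3)
        n, m = 50, 30
        Wm = rng.normal(size=(n, m))
        ids = [f"L{i}" for i in range(n)]
        y_arr = Wm @ rng.normal(0, 0.3, m) + rng.normal(0, 1.0, n)
        y = pd.Series(y_arr, index=ids)
        vc = reml_fit(y, DesignMatrix(ids, list(range(m)), Wm))

        # independent oracle: direct restricted likelihood on the explicit
        # covariance matrix, optimised on a fine grid + golden refinement
        K = Wm @ Wm.T
        X = np.ones((n, 1))

        def nll(params):
            s2, se2 = np.exp(params)
            V = K * s2 + np.eye(n) * se2
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y_arr)
            r = y_arr - X @ beta
            _, ld_V = np.linalg.slogdet(V)
            _, ld_X = np.linalg.slogdet(XtViX)
            return 0.5 * (ld_V + ld_X + r @ Vi @ r)

        from scipy.optimize import minimize
        best = min(
            (minimize(nll, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12})
             for x0 in ([np.log(0.1), 0.0], [np.log(0.3), np.log(0.5)])),
            key=lambda r: r.fun)
        s2_o, se2_o = np.exp(best.x)
        assert vc.sigma_marker2 == pytest.approx(s2_o, rel=1e-4, abs=1e-6)
        assert vc.sigma_e2 == pytest.approx(se2_o, rel=1e-4)


class TestGblupPredict:
    def test_interpolation_limit_sigma_e_zero(self):
        rng = np.random.default_rng(2)
        n, m = 25, 60
        Wm = rng.normal(size=(n, m))        # full row rank
        ids = [f"L{i}" for i in range(n)]
        y = pd.Series(rng.normal(size=n), index=ids)
        from haplogs.gblup import VarianceComponents
        vc = VarianceComponents(1.0, 0.0, 0.0, 0, True)
        fit = gblup_predict(y, DesignMatrix(ids, list(range(m)), Wm),
                            training=ids, vc=vc)
        np.testing.assert_allclose(fit.additive_values, y - fit.mu, atol=1e-8)

    def test_additive_values_equal_W_times_effects(self):
        pop, y = _sim_xy(0)
        W = build_snp_design(pop.genotypes)
        lines = list(y.index)
        fit = gblup_predict(y, W, training=lines[:70], validation=lines[70:])
        np.testing.assert_allclose(fit.additive_values,
                                   W.W @ fit.effects.to_numpy(), atol=1e-12)

    def test_column_permutation_invariance(self):
        pop, y = _sim_xy(1)
        W = build_snp_design(pop.genotypes)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(W.col_ids))
        Wp = DesignMatrix(W.line_ids, [W.col_ids[j] for j in perm],
                          W.W[:, perm])
        lines = list(y.index)
        a = gblup_predict(y, W, lines[:70], lines[70:]).additive_values
        b = gblup_predict(y, Wp, lines[:70], lines[70:]).additive_values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_design_scale_invariance(self):
        """Replacing W by cW leaves predictions unchanged (σ̂² rescales)."""
        pop, y = _sim_xy(2)
        W = build_snp_design(pop.genotypes)
        Wc = DesignMatrix(W.line_ids, W.col_ids, 3.0 * W.W)
        lines = list(y.index)
        a = gblup_predict(y, W, lines[:70], lines[70:])
        b = gblup_predict(y, Wc, lines[:70], lines[70:])
        np.testing.assert_allclose(a.additive_values, b.additive_values,
                                   atol=1e-8)
        assert b.vc.sigma_marker2 == pytest.approx(a.vc.sigma_marker2 / 9.0,
                                                   rel=1e-6)

    def test_haploblock_of_one_marker_equals_snp_model(self):
        """The two-column multi-allelic coding of a single SNP spans the
        same one-dimensional space, so predictions coincide."""
        pop, y = _sim_xy(3)
        g, gmap = pop.genotypes, pop.gmap
        Ws = build_snp_design(g)
        Wh = build_hap_design(build_blocks(g, gmap, 1))
        lines = list(y.index)
        a = gblup_predict(y, Ws, lines[:70], lines[70:]).additive_values
        b = gblup_predict(y, Wh, lines[:70], lines[70:]).additive_values
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_kernel_form_equals_effect_level_mme(self):
        """Kernel (G_W) solution agrees with the explicit mixed-model
        equations solved at the effect level, across random instances."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, m = 30, 45
            Wm = rng.normal(size=(n, m))
            ids = [f"L{i}" for i in range(n)]
            y = pd.Series(rng.normal(size=n), index=ids)
            W = DesignMatrix(ids, list(range(m)), Wm)
            vc = reml_fit(y, W)
            fit = gblup_predict(y, W, training=ids, vc=vc)
            # oracle: solve [1'1  1'W; W'1  W'W + δI][μ;α] = [1'y; W'y]
            delta = vc.sigma_e2 / vc.sigma_marker2
            lhs = np.zeros((m + 1, m + 1))
            lhs[0, 0] = n
            lhs[0, 1:] = Wm.sum(axis=0)
            lhs[1:, 0] = Wm.sum(axis=0)
            lhs[1:, 1:] = Wm.T @ Wm + delta * np.eye(m)
            rhs = np.concatenate([[y.sum()], Wm.T @ y.to_numpy()])
            sol = np.linalg.solve(lhs, rhs)
            np.testing.assert_allclose(fit.mu, sol[0], atol=1e-8)
            np.testing.assert_allclose(fit.additive_values, Wm @ sol[1:],
                                       atol=1e-8)

    def test_overlapping_training_validation_rejected(self):
        pop, y = _sim_xy(4)
        W = build_snp_design(pop.genotypes)
        lines = list(y.index)
        with pytest.raises(ValueError, match="overlap"):
            gblup_predict(y, W, lines[:50], lines[40:60])

    def test_higher_heritability_predicts_better(self):
        """Cross-validated r is higher for an h²=0.7 trait than 0.3."""
        from haplogs.crossval import cross_validate, make_kfold

        wins = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, cluster_sizes=(50, 40, 40),
                            n_chromosomes=3, markers_per_chromosome=(60,) * 3,
                            n_qtl=30, spatial_trend_amplitude=0)
            pop = simulate_population(cfg)
            ph = simulate_phenotypes(pop, cfg)
            g = pop.genotypes
            W = build_snp_design(g)
            rs = {}
            for trait in ("yield", "protein"):     # h² 0.3 vs 0.7
                y = combine_trials(ph, trait)
                scheme = make_kfold(list(y.index), k=4, repetitions=1,
                                    seed=seed)
                rs[trait] = cross_validate(y, W, scheme)["r"].mean()
            wins += rs["protein"] > rs["yield"]
        assert wins >= 8
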