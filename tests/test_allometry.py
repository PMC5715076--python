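"""Tree summaries, Strahler ratio fits, tapering, area conservation,
effective numbers and the regression toolbox."""

import math

import numpy as np
import pandas as pd
import pytest

import windtree as wt
from windtree import allometry as am
from windtree import synthetic
from windtree.genome import random_genome

from conftest import mean_path_oracle


class TestTreeSummary:
    def test_seedling(self, params, rng):
        tree = wt.Tree(params, random_genome(rng), (2.0, -1.0), rng)
        s = am.tree_summary(tree)
        assert s.H == pytest.approx(params.L)
        assert s.N == 1 and s.C == 0.0
        assert s.B == pytest.approx(params.V0)
        assert s.d_trunk == params.d0

    def test_crown_radius_closed_form(self, params, rng):
        # four foliages at the corners of a square of half-side a:
        # var_x = var_y = a^2, so C = a*sqrt(2)
        tree = wt.Tree(params, random_genome(rng), (0, 0), rng)
        s = am.tree_summary(tree)
        a = 1.0
        centers = np.array([[a, a, 2], [a, -a, 2], [-a, a, 2], [-a, -a, 2]],
                           dtype=float)
        C = float(np.sqrt(centers[:, 0].var() + centers[:, 1].var()))
        assert C == pytest.approx(a * math.sqrt(2))

    def test_bare_dead_tree(self, params, rng):
        tree = wt.Tree(params, random_genome(rng), (0, 0), rng)
        tree.remove_subtree(0)
        s = am.tree_summary(tree)
        assert s.N == 0 and s.B == 0.0 and s.H == 0.0


class TestSelfSimilarRatios:
    def test_exact_fractal_recovers_construction(self):
        tree = synthetic.self_similar_tree(K=4, R_n=4, R_l=2)
        r = am.self_similar_ratios(tree)
        assert r.R_n == pytest.approx(4.0, abs=1e-9)
        assert r.R_l == pytest.approx(2.0, abs=1e-9)
        assert r.D == pytest.approx(2.0, abs=1e-9)
        assert r.D_ci[0] <= 2.0 + 1e-9 and r.D_ci[1] >= 2.0 - 1e-9

    def test_rank_counts_decrease(self):
        tree = synthetic.self_similar_tree(K=4, R_n=3, R_l=2)
        tab = am.rank_table(tree)
        assert (np.diff(tab["n"]) < 0).all()
        assert tab["n"].iloc[0] == 3 ** 3

    def test_too_few_ranks_flagged(self, params):
        tree = synthetic.comb_tree(params, 5)
        with pytest.raises(ValueError):
            am.self_similar_ratios(tree)


class TestTapering:
    def test_twig_and_chain(self, params):
        tree = synthetic.comb_tree(params, 3)
        ell = am.mean_path_lengths(tree)
        assert ell[-1] == pytest.approx(params.L)       # the twig
        assert ell[0] == pytest.approx(3 * params.L)    # the root of 3

    def test_matches_enumeration_oracle(self, random_trees):
        for tree in random_trees[:60]:
            ell = am.mean_path_lengths(tree)
            assert np.allclose(ell, mean_path_oracle(tree), atol=1e-9)


class TestLeonardo:
    def test_equal_diameters_give_ratio_two(self, params, rng):
        tree = wt.Tree(params, random_genome(rng), (0, 0), rng)
        tree.attach_children(0, 2, (30, -30, 90), rng)
        df = am.leonardo_ratios(tree)
        assert len(df) == 1
        assert df["ratio"].iloc[0] == pytest.approx(2.0)

    def test_area_preserving_split_gives_ratio_one(self, params, rng):
        tree = wt.Tree(params, random_genome(rng), (0, 0), rng)
        a, b = tree.attach_children(0, 2, (30, -30, 90), rng)
        tree.col("d")[[a, b]] = params.d0 / math.sqrt(2)
        df = am.leonardo_ratios(tree)
        assert df["ratio"].iloc[0] == pytest.approx(1.0)


class TestEffectiveNumbers:
    def test_equal_trees(self):
        N, M = am.effective_numbers(np.full(7, 2.5))
        assert N == pytest.approx(7.0) and M == pytest.approx(2.5)

    def test_two_unequal_masses(self):
        N, M = am.effective_numbers(np.array([1.0, 3.0]))
        assert N == pytest.approx(1.6) and M == pytest.approx(2.5)

    def test_single_tree(self):
        N, M = am.effective_numbers(np.array([0.7]))
        assert N == pytest.approx(1.0) and M == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            am.effective_numbers(np.array([]))


class TestFits:
    def test_exact_power_law(self):
        x = np.array([1.0, 2.0, 5.0, 10.0, 30.0])
        y = 3.0 * x ** 2
        for fit in (am.rma_fit(x, y), am.ls_fit(x, y)):
            assert fit.slope == pytest.approx(2.0)
            assert 10 ** fit.intercept == pytest.approx(3.0)

    def test_rma_equals_ls_over_correlation(self):
        rng = np.random.default_rng(1)
        x = 10 ** rng.uniform(0, 2, 200)
        y = 2.0 * x ** 1.5 * np.exp(rng.normal(0, 0.3, 200))
        r = am.rma_fit(x, y)
        l = am.ls_fit(x, y)
        corr = np.corrcoef(np.log10(x), np.log10(y))[0, 1]
        assert r.slope == pytest.approx(l.slope / corr, rel=1e-9)

    def test_weights_can_reproduce_subset_fit(self):
        rng = np.random.default_rng(2)
        x = 10 ** rng.uniform(0, 2, 100)
        y = x ** 1.2 * np.exp(rng.normal(0, 0.2, 100))
        w = np.zeros(100)
        w[:40] = 1.0
        weighted = am.rma_fit(x, y, w + 1e-300)
        subset = am.rma_fit(x[:40], y[:40])
        assert weighted.slope == pytest.approx(subset.slope, rel=1e-6)

    def test_invariance_to_order_and_weight_scale(self):
        rng = np.random.default_rng(3)
        x = 10 ** rng.uniform(0, 2, 50)
        y = x ** 0.8 * np.exp(rng.normal(0, 0.1, 50))
        w = rng.uniform(0.5, 2.0, 50)
        f1 = am.rma_fit(x, y, w)
        perm = rng.permutation(50)
        f2 = am.rma_fit(x[perm], y[perm], w[perm])
        f3 = am.rma_fit(x, y, 100.0 * w)
        assert f1.slope == pytest.approx(f2.slope)
        assert f1.slope == pytest.approx(f3.slope)
        assert f1.slope_ci == pytest.approx(f3.slope_ci)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            am.rma_fit([1.0, 2.0], [1.0, 2.0])


class TestForestAllometry:
    def test_peripheral_trees_excluded(self):
        df = pd.DataFrame({
            "H": np.full(20, 2.0), "C": np.full(20, 1.0),
            "N": np.full(20, 4.0), "B": np.full(20, 0.1),
            "d_trunk": np.linspace(0.1, 1, 20),
            "x": np.linspace(0, 50, 20), "y": np.zeros(20),
        })
        r = np.hypot(df.x, df.y)
        kept = int(((r <= 0.9 * 40.0)).sum())
        fits = am.forest_allometry(df, R=40.0)
        assert fits["H"].n == kept

    def test_derived_leaf_mass_exponent(self):
        rng = np.random.default_rng(4)
        df = synthetic.analytic_cohort(300, rng)
        fits = am.forest_allometry(df, R=40.0, central_fraction=1.0)
        assert fits["ML"].slope == pytest.approx(
            fits["N"].slope / fits["B"].slope)


class TestSelfThinning:
    def test_constructed_slope_recovered(self):
        N = np.logspace(1, 4, 30)
        M = 10.0 * N ** -1.5
        fit = am.self_thinning_fit(N, M)
        assert fit.slope == pytest.approx(-1.5)

    def test_constant_series_flagged(self):
        with pytest.raises(ValueError):
            am.self_thinning_fit(np.full(10, 5.0), np.linspace(1, 2, 10))

    def test_weighting_matches_closed_form(self):
        # heteroscedastic two-cluster data: WLS slope equals the weighted
        # normal-equation solution computed directly
        N = np.array([10.0, 10.0, 1000.0, 1000.0, 100.0])
        M = np.array([5.0, 6.0, 0.1, 0.12, 1.0])
        w = N
        x, y = np.log10(N), np.log10(M)
        mx = (w * x).sum() / w.sum()
        my = (w * y).sum() / w.sum()
        slope = ((w * (x - mx) * (y - my)).sum()
                 / (w * (x - mx) ** 2).sum())
        fit = am.self_thinning_fit(N, M)
        assert fit.slope == pytest.approx(slope)


class TestSensitivity:
    def test_linear_beta_gives_unit_sensitivity(self):
        p = np.linspace(1.0, 2.0, 5)
        assert am.sensitivity(p, 3.0 * p) == pytest.approx(1.0)

    def test_constant_beta_gives_zero(self):
        p = np.linspace(1.0, 2.0, 5)
        assert am.sensitivity(p, np.full(5, 2.0)) == pytest.approx(0.0)

    def test_quadratic_matches_analytic_derivative(self):
        p0 = 2.0
        h = 0.01
        p = np.array([p0 - h, p0, p0 + h])
        beta = p ** 2
        # regression slope over symmetric points equals d(beta)/dp at p0
        s = am.sensitivity(p, beta, p_ref=p0, beta_ref=p0 ** 2)
        assert s == pytest.approx((p0 / p0 ** 2) * 2 * p0, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            am.sensitivity([1.0], [1.0])
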