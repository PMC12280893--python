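"""Independent contrasts, Blomberg's K and PGLS.

The frozen reference values on the 8-tip fixture were computed with the
standard R toolchain (ape::pic, stats::cor.test, phytools::phylosig,
nlme::gls with an ape::corBrownian correlation) on identical inputs.
"""

import numpy as np
import pytest

from nichetrack.io_formats import read_tree
from nichetrack.phylo_comparative import (K_tests, blomberg_K, pgls, pic,
                                          pic_correlation, simulate_bm)
from nichetrack.synthetic_data import gen_tree

from conftest import make_star_tree

# R oracle values for the (tree8, traits8) fixture
R_PIC_X_SORTED = [-2.19302326, -0.35125954, 0.18676786, 0.43799707,
                  3.42865823, 4.98213163, 6.92436849]
R_COR = dict(r=0.67314717, p=0.097437021, ci=(-0.16206451, 0.94643796))
R_K = 0.38949776
R_PGLS = dict(beta=(3.3035117826, 0.5162659856),
              se=(2.7549518024, 0.2502844026),
              t=(1.199117814, 2.062717374),
              p=(0.2756853819, 0.0847371565),
              sigma2=5.61798974)


class TestPic:
    def test_two_tip_analytic(self):
        t = read_tree("(A:1,B:1);")
        c = pic(t, {"A": 3.0, "B": 1.0})
        assert abs(c[0]) == pytest.approx(np.sqrt(2.0))

    def test_constant_trait_all_zero(self, tree8):
        assert pic(tree8, {lab: 5.0 for lab in tree8.tip_labels}) == pytest.approx(
            np.zeros(7))

    def test_three_tip_hand_worked_pruning(self):
        # contrast(A,B) = (1-3)/sqrt(2); ancestor value 2, branch 0.5+0.5=1.0
        # contrast(anc,C) = (2-6)/sqrt(1.0+1.5)
        t = read_tree("((A:1,B:1):0.5,C:1.5);")
        c = np.sort(np.abs(pic(t, {"A": 1.0, "B": 3.0, "C": 6.0})))
        assert c == pytest.approx(np.sort(np.abs(
            [(1 - 3) / np.sqrt(2), (2 - 6) / np.sqrt(2.5)])))

    def test_matches_r_ape_oracle(self, tree8, traits8):
        x, _ = traits8
        assert np.sort(pic(tree8, x)) == pytest.approx(R_PIC_X_SORTED, abs=1e-7)

    def test_translation_invariance(self, tree8, traits8):
        x, _ = traits8
        shifted = {k: v + 123.4 for k, v in x.items()}
        assert pic(tree8, shifted) == pytest.approx(pic(tree8, x))

    def test_polytomy_rejected_with_guidance(self):
        t = read_tree("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="resolve"):
            pic(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_sum_sq_contrasts_equals_reml_rate(self, tree8, traits8):
        from nichetrack.niche_models import bm_rate_reml
        x, _ = traits8
        c = pic(tree8, x)
        # mean squared contrast is exactly the REML Brownian rate
        assert np.mean(c ** 2) == pytest.approx(bm_rate_reml(tree8, x))


class TestPicCorrelation:
    def test_perfect_correlation(self, tree8, traits8):
        x, _ = traits8
        assert pic_correlation(tree8, x, x).r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, tree8, traits8):
        x, _ = traits8
        neg = {k: -v for k, v in x.items()}
        assert pic_correlation(tree8, x, neg).r == pytest.approx(-1.0)

    def test_matches_r_cor_test_oracle(self, tree8, traits8):
        x, y = traits8
        r = pic_correlation(tree8, x, y)
        assert r.r == pytest.approx(R_COR["r"], abs=1e-7)
        assert r.p == pytest.approx(R_COR["p"], rel=1e-6)
        assert r.ci95 == pytest.approx(R_COR["ci"], abs=1e-7)

    def test_too_few_contrasts_error(self):
        t = read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="contrasts"):
            pic_correlation(t, {"A": 1, "B": 2, "C": 3}, {"A": 2, "B": 1, "C": 0})

    def test_recovers_known_bivariate_correlation(self):
        """Bivariate Brownian traits with rho = 0.8 on 200 tips."""
        tree = gen_tree(200, 3)
        rng = np.random.default_rng(12)
        rho = 0.8
        rs = []
        for _ in range(30):
            z = simulate_bm(tree, 2, rng)
            labels = tree.tip_labels
            x = dict(zip(labels, z[:, 0]))
            y = dict(zip(labels, rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]))
            rs.append(pic_correlation(tree, x, y).r)
        assert abs(np.mean(rs) - rho) < 0.1


class TestBlombergK:
    def test_star_tree_K_is_exactly_one(self):
        star = make_star_tree(8, branch=2.5)
        rng = np.random.default_rng(0)
        x = dict(zip(star.tip_labels, rng.standard_normal(8)))
        assert blomberg_K(star, x) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, tree8, traits8):
        x, _ = traits8
        scaled = {k: 17.5 * v for k, v in x.items()}
        assert blomberg_K(tree8, scaled) == pytest.approx(blomberg_K(tree8, x))

    def test_branch_rescaling_invariance(self, tree8, traits8):
        x, _ = traits8
        assert blomberg_K(tree8.scaled(3.7), x) == pytest.approx(
            blomberg_K(tree8, x))

    def test_matches_r_phytools_oracle(self, tree8, traits8):
        x, _ = traits8
        assert blomberg_K(tree8, x) == pytest.approx(R_K, abs=1e-7)

    def test_constant_trait_undefined(self, tree8):
        with pytest.raises(ValueError):
            blomberg_K(tree8, {lab: 2.0 for lab in tree8.tip_labels})

    def test_bm_simulations_center_on_one(self):
        tree = gen_tree(50, 42)
        rng = np.random.default_rng(8)
        from nichetrack.phylo_comparative import _K_from_parts, _K_setup
        C, labels, C_inv, ones_Cinv, denom, expected, n = _K_setup(tree)
        sims = simulate_bm(tree, 1000, rng)
        Ks = _K_from_parts(C_inv, ones_Cinv, denom, expected, n, sims)
        assert abs(np.mean(Ks) - 1.0) < 0.05


class TestKTests:
    def test_below_null_median_gives_large_p(self):
        tree = gen_tree(30, 6)
        # a tree-independent (shuffled) trait has low K: p_gt1 near 1
        rng = np.random.default_rng(13)
        x = dict(zip(tree.tip_labels, rng.standard_normal(30)))
        res = K_tests(tree, x, n_perm=200, n_sim=400, seed=1)
        if res.K < 1.0:
            assert res.p_gt1 > 0.5

    def test_determinism_under_seed(self, tree8, traits8):
        x, _ = traits8
        a = K_tests(tree8, x, n_perm=99, n_sim=99, seed=5)
        b = K_tests(tree8, x, n_perm=99, n_sim=99, seed=5)
        assert a == b

    def test_p_never_exactly_zero(self, tree8, traits8):
        x, _ = traits8
        res = K_tests(tree8, x, n_perm=50, n_sim=50, seed=2)
        assert res.p_perm >= 1 / 51 and res.p_gt1 >= 1 / 51

    def test_permutation_p_roughly_uniform_under_shuffled_traits(self):
        """Tip shuffling destroys signal: rejection rate ~ alpha."""
        tree = gen_tree(25, 9)
        rng = np.random.default_rng(21)
        labels = tree.tip_labels
        rej = 0
        reps = 200
        for i in range(reps):
            x = dict(zip(labels, rng.standard_normal(25)))
            if K_tests(tree, x, n_perm=199, n_sim=1, seed=1000 + i).p_perm <= 0.05:
                rej += 1
        assert abs(rej / reps - 0.05) < 0.045

    def test_invalid_counts(self, tree8, traits8):
        x, _ = traits8
        with pytest.raises(ValueError):
            K_tests(tree8, x, n_perm=0)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        star = make_star_tree(10, branch=1.0)
        rng = np.random.default_rng(30)
        labels = star.tip_labels
        xv = rng.standard_normal(10)
        yv = 2.0 * xv + rng.standard_normal(10)
        fit = pgls(star, dict(zip(labels, yv)), [dict(zip(labels, xv))])
        X = np.column_stack([np.ones(10), xv])
        beta_ols = np.linalg.lstsq(X, yv, rcond=None)[0]
        assert fit.beta == pytest.approx(beta_ols, abs=1e-10)

    def test_exact_linear_relation_any_tree(self, tree8, traits8):
        x, _ = traits8
        y = {k: 2.0 * v + 1.0 for k, v in x.items()}
        fit = pgls(tree8, y, [x])
        assert fit.beta == pytest.approx([1.0, 2.0], abs=1e-8)

    def test_four_tip_dense_gls_oracle(self):
        t = read_tree("((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);")
        y = {"A": 1.0, "B": 2.5, "C": 0.5, "D": 3.0}
        x = {"A": 0.2, "B": 1.1, "C": -0.4, "D": 2.0}
        fit = pgls(t, y, [x])
        C, labels = t.vcv()
        Ci = np.linalg.inv(C)
        X = np.column_stack([np.ones(4), [x[lab] for lab in labels]])
        yv = np.array([y[lab] for lab in labels])
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ yv)
        assert fit.beta == pytest.approx(beta, abs=1e-10)
        resid = yv - X @ beta
        sigma2 = float(resid @ Ci @ resid) / 2  # n - p = 2
        assert fit.sigma2_hat == pytest.approx(sigma2)

    def test_matches_r_nlme_gls_oracle(self, tree8, traits8):
        x, y = traits8
        fit = pgls(tree8, y, [x])
        assert fit.beta == pytest.approx(R_PGLS["beta"], abs=1e-7)
        assert fit.se == pytest.approx(R_PGLS["se"], abs=1e-7)
        assert fit.t == pytest.approx(R_PGLS["t"], abs=1e-6)
        assert fit.p == pytest.approx(R_PGLS["p"], abs=1e-7)
        assert fit.sigma2_hat == pytest.approx(R_PGLS["sigma2"], abs=1e-6)

    def test_collinear_predictors_rejected(self, tree8, traits8):
        x, _ = traits8
        x2 = {k: 2.0 * v for k, v in x.items()}
        with pytest.raises(ValueError, match="ollinear"):
            pgls(tree8, x, [x, x2])

    def test_mismatched_trait_keys_rejected(self, tree8, traits8):
        x, y = traits8
        bad = dict(x)
        bad["nonexistent_tip"] = bad.pop(tree8.tip_labels[0])
        with pytest.raises(ValueError, match="match"):
            pgls(tree8, y, [bad])
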