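import numpy as np
import pandas as pd
import pytest

import phasegraph as pg
from phasegraph.io import DimensionError
from phasegraph.stats import CollinearityError, DegenerateControlError


def ar1_samples(rng, n, k, rho=0.9):
    """Rows with AR(1) correlation across the k within-levels."""
    cov = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    return rng.multivariate_normal(np.zeros(k), cov, size=n)


class TestGgEpsilon:
    def test_two_levels_is_exactly_one(self, rng):
        assert pg.gg_epsilon(rng.standard_normal((30, 2))) == 1.0

    def test_spherical_covariance_is_near_one(self, rng):
        y = rng.standard_normal((5000, 5))  # iid: compound symmetric
        assert pg.gg_epsilon(y) > 0.99

    def test_rank_one_contrast_covariance_attains_lower_bound(self):
        # all within-variation along a single contrast direction
        n, k = 40, 5
        t = np.linspace(-1, 1, k)
        scores = np.linspace(-2, 2, n)
        y = np.outer(scores, t)
        assert pg.gg_epsilon(y) == pytest.approx(1 / (k - 1), abs=1e-10)

    def test_bounds_on_correlated_data(self, rng):
        y = ar1_samples(rng, 82, 11)
        eps = pg.gg_epsilon(y)
        assert 1 / 10 < eps < 1

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = ar1_samples(rng, 60, 6)
        expected = pingouin.epsilon(pd.DataFrame(y), correction="gg")
        assert pg.gg_epsilon(y) == pytest.approx(float(expected), rel=1e-6)


class TestMauchly:
    def test_two_levels_trivially_spherical(self, rng):
        w, p = pg.mauchly_sphericity(rng.standard_normal((30, 2)))
        assert (w, p) == (1.0, 1.0)

    def test_spherical_data_rarely_rejected(self, rng):
        rejections = 0
        for _ in range(100):
            y = rng.standard_normal((82, 5))
            _, p = pg.mauchly_sphericity(y)
            rejections += p < 0.05
        assert rejections <= 12

    def test_ar1_data_strongly_rejected(self, rng):
        hits = 0
        for _ in range(40):
            y = ar1_samples(rng, 82, 6)
            w, p = pg.mauchly_sphericity(y)
            assert w < 1
            hits += p < 0.05
        assert hits >= 38  # >= 95% power at this effect size

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = ar1_samples(rng, 60, 5)
        res = pingouin.sphericity(pd.DataFrame(y))
        w, p = pg.mauchly_sphericity(y)
        assert w == pytest.approx(float(res.W), rel=1e-6)
        assert p == pytest.approx(float(res.pval), rel=1e-4)


class TestRmGlm:
    def test_df_pattern_matches_design(self, rng):
        y = rng.standard_normal((82, 11))
        one = pg.rm_glm(y, [rng.standard_normal(82)])
        assert one.f_main["covariate_0"].df2 == 80
        z2 = [rng.standard_normal(82), rng.standard_normal(82)]
        two = pg.rm_glm(y, z2)
        for eff in two.f_main.values():
            assert eff.df2 == 79
        assert two.scale_effect.df1 == 10
        assert two.scale_effect.df2 == 10 * 79

    def test_two_levels_have_epsilon_one(self, rng):
        res = pg.rm_glm(rng.standard_normal((40, 2)),
                        [rng.standard_normal(40)])
        assert res.gg_epsilon == 1.0
        assert res.mauchly_w == 1.0

    def test_perfect_linear_relation(self, rng):
        z = rng.standard_normal(50)
        y = np.tile(1.5 + 2.0 * z, (4, 1)).T  # same relation at every scale
        res = pg.rm_glm(y, [z])
        assert res.f_interaction["covariate_0"].f == pytest.approx(0.0)
        assert res.f_main["covariate_0"].p < 1e-30

    def test_tracer_names_used(self, rng):
        rcps = pg.RegionalPetVector(rng.uniform(1, 3, 30), "rCPS")
        suv = pg.RegionalPetVector(rng.uniform(4, 8, 30), "SUV")
        res = pg.rm_glm(rng.standard_normal((30, 3)), [rcps, suv])
        assert set(res.f_main) == {"rCPS", "SUV"}
        assert set(res.f_interaction) == {"rCPS", "SUV"}

    def test_identical_covariates_raise(self, rng):
        z = rng.standard_normal(30)
        with pytest.raises(CollinearityError):
            pg.rm_glm(rng.standard_normal((30, 3)), [z, z.copy()])

    def test_f_invariant_to_covariate_rescaling(self, rng):
        y = rng.standard_normal((40, 5))
        z = rng.standard_normal(40)
        a = pg.rm_glm(y, [z])
        b = pg.rm_glm(y, [5.0 * z + 3.0])
        assert a.f_main["covariate_0"].f == pytest.approx(
            b.f_main["covariate_0"].f, rel=1e-10)

    def test_result_dataframe_layout(self, rng):
        res = pg.rm_glm(rng.standard_normal((30, 4)),
                        [rng.standard_normal(30)], metric="node_strength")
        df = res.to_dataframe()
        assert set(df["kind"]) == {"within", "main", "interaction"}
        assert (df["metric"] == "node_strength").all()


class TestPosthocCorrelations:
    def test_partial_reduces_to_pearson_when_control_orthogonal(self):
        # Hadamard-type construction: r_xy = 0.5 exactly, r_xz = r_yz = 0
        x = np.array([1.0, 1, -1, -1])
        u = np.array([1.0, -1, 1, -1])
        z = np.array([1.0, -1, -1, 1])
        y = 0.5 * x + np.sqrt(3) / 2 * u
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.5)
        assert np.corrcoef(y, z)[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert pg.partial_correlation(x, y, z) == pytest.approx(0.5)

    def test_identity_is_significant_at_any_family_size(self, rng):
        x = rng.standard_normal(30)
        target = pg.RegionalPetVector(x - x.min() + 1.0, "rCPS")
        table = pg.posthoc_correlations(x[:, None], target,
                                        n_comparisons=10000)
        assert table["r"].iloc[0] == pytest.approx(1.0)
        assert bool(table["significant"].iloc[0])

    def test_known_population_partial_correlation(self, rng):
        """Trivariate normal with analytic partial correlation 0.3."""
        n = 100_000
        rho_xz = rho_yz = 0.5
        partial = 0.3
        r_xy = partial * (1 - rho_xz ** 2) + rho_xz * rho_yz
        cov = np.array([[1, r_xy, rho_xz],
                        [r_xy, 1, rho_yz],
                        [rho_xz, rho_yz, 1]])
        x, y, z = rng.multivariate_normal(np.zeros(3), cov, size=n).T
        assert pg.partial_correlation(x, y, z) == pytest.approx(0.3, abs=0.01)

    def test_degenerate_control_raises(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        with pytest.raises(DegenerateControlError):
            pg.partial_correlation(x, y, 2 * x + 1)

    def test_affine_invariance(self, rng):
        m = rng.standard_normal((40, 3))
        t = rng.standard_normal(40)
        c = rng.standard_normal(40)
        target = pg.RegionalPetVector(t - t.min() + 1, "rCPS")
        control = pg.RegionalPetVector(c - c.min() + 1, "SUV")
        a = pg.posthoc_correlations(m, target, control)
        b = pg.posthoc_correlations(
            4.0 * m + 7.0,
            pg.RegionalPetVector(2.0 * target.values + 1.0, "rCPS"),
            pg.RegionalPetVector(0.5 * control.values + 2.0, "SUV"))
        np.testing.assert_allclose(a["r"], b["r"], atol=1e-12)

    def test_region_count_mismatch(self, rng):
        with pytest.raises(DimensionError):
            pg.posthoc_correlations(rng.standard_normal((10, 2)),
                                    pg.RegionalPetVector(np.ones(12), "rCPS"))

    def test_bonferroni_family_scales_p(self, rng):
        m = rng.standard_normal((40, 2))
        target = pg.RegionalPetVector(rng.uniform(1, 2, 40), "rCPS")
        small = pg.posthoc_correlations(m, target, n_comparisons=1)
        big = pg.posthoc_correlations(m, target, n_comparisons=44)
        np.testing.assert_allclose(np.minimum(small["p"] * 44, 1.0),
                                   big["p_bonferroni"])
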