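import numpy as np
import pytest
from scipy import integrate, stats

from cormotif import (
    ModerationParams,
    SimulationSpec,
    estimate_w,
    fit_variance_prior,
    moderate,
    moderated_t,
    pooled_stats,
    simulate_model_based,
)
from cormotif.moderated import alt_logdensity, null_logdensity

from conftest import make_study


class TestPooledStats:
    def test_constant_groups(self):
        # gene 1: cases (1,1,1), controls (0,0,0); gene 2 keeps s2 non-degenerate
        study = make_study(
            [[1, 1, 1, 0, 0, 0], [2, 0, 1, 1, 0, 2]], n_case=3, n_control=3
        )
        ps = pooled_stats(study)
        assert ps.y[0] == pytest.approx(1.0)
        assert ps.s2[0] == 0.0
        assert ps.v == pytest.approx(2 / 3)
        assert ps.df_resid == 4

    def test_hand_arithmetic(self):
        # cases (2,4), controls (1,3): y=1, s2=((2-3)^2+(4-3)^2+(1-2)^2+(3-2)^2)/2=2
        study = make_study([[2, 4, 1, 3], [5, 1, 2, 2]], n_case=2, n_control=2)
        ps = pooled_stats(study)
        assert ps.y[0] == pytest.approx(1.0)
        assert ps.s2[0] == pytest.approx(2.0)
        assert ps.v == pytest.approx(1.0)

    def test_replicate_order_invariance(self, rng):
        vals = rng.normal(size=(10, 6))
        a = pooled_stats(make_study(vals, 3, 3))
        perm = vals[:, [2, 0, 1, 5, 3, 4]]  # permute within each group
        b = pooled_stats(make_study(perm, 3, 3))
        np.testing.assert_allclose(a.y, b.y)
        np.testing.assert_allclose(a.s2, b.s2)

    def test_all_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            pooled_stats(make_study(np.ones((3, 4)), 2, 2))


class TestVariancePrior:
    def test_parameter_recovery(self):
        # sigma^2 from the scaled inverse chi2 prior, s2 from its chi2
        # sampling layer; the moment estimator should recover both
        rng = np.random.default_rng(11)
        g, n0, s0_sq, df = 100_000, 4.0, 0.02, 4.0
        sigma2 = n0 * s0_sq / rng.chisquare(n0, size=g)
        s2 = sigma2 * rng.chisquare(df, size=g) / df
        n0_hat, s0_hat = fit_variance_prior(s2, df)
        assert n0_hat == pytest.approx(n0, rel=0.05)
        assert s0_hat == pytest.approx(s0_sq, rel=0.05)

    def test_identical_variances_hit_infinite_prior_df(self):
        n0, s0 = fit_variance_prior(np.full(100, 0.5), 4.0)
        assert np.isinf(n0)
        # with n0 = inf every shrunken variance is s0^2
        params = ModerationParams(n0=n0, s0_sq=s0, w=0.0, v=0.5, df_resid=4.0)
        ps = pooled_stats(
            make_study(np.random.default_rng(0).normal(size=(20, 6)), 3, 3)
        )
        t = moderated_t(ps, params)
        np.testing.assert_allclose(t, ps.y / np.sqrt(params.v * s0))

    def test_scale_equivariance(self, rng):
        s2 = stats.invgamma.rvs(2.0, scale=0.1, size=5000,
                                random_state=np.random.default_rng(3))
        n0_a, s0_a = fit_variance_prior(s2, 4.0)
        n0_b, s0_b = fit_variance_prior(7.0 * s2, 4.0)
        assert n0_b == pytest.approx(n0_a, rel=1e-8)
        assert s0_b == pytest.approx(7.0 * s0_a, rel=1e-8)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="too few genes"):
            fit_variance_prior(np.ones(5), 4.0)


class TestModeratedT:
    def test_no_shrinkage_limit_is_ordinary_t(self, rng):
        study = make_study(rng.normal(size=(30, 6)), 3, 3)
        ps = pooled_stats(study)
        params = ModerationParams(n0=0.0, s0_sq=1.0, w=0.0, v=ps.v,
                                  df_resid=ps.df_resid)
        t = moderated_t(ps, params)
        case, ctrl = study.case_values, study.control_values
        ref = stats.ttest_ind(case, ctrl, axis=1).statistic
        np.testing.assert_allclose(t, ref, rtol=1e-10)

    def test_hand_arithmetic(self):
        ps_like = pooled_stats(
            make_study([[2.0, 4.0, 1.0, 3.0], [0.0, 5.0, 1.0, 2.0]], 2, 2)
        )
        params = ModerationParams(n0=4.0, s0_sq=2.0, w=0.0, v=1.0, df_resid=2.0)
        # gene 1: y=1, s2=2 -> shrunken variance (4*2 + 2*2)/6 = 2, t = 1/sqrt(2)
        t = moderated_t(ps_like, params)
        assert t[0] == pytest.approx(1.0 / np.sqrt(2.0))

    def test_linear_in_mean_difference(self, rng):
        vals = rng.normal(size=(15, 6))
        ps = pooled_stats(make_study(vals, 3, 3))
        params = ModerationParams(n0=4.0, s0_sq=0.02, w=0.0, v=ps.v,
                                  df_resid=ps.df_resid)
        t1 = moderated_t(ps, params)
        ps.y = 2.0 * ps.y
        np.testing.assert_allclose(moderated_t(ps, params), 2.0 * t1)


class TestEstimateW:
    def test_null_data_gives_near_zero_w(self):
        rng = np.random.default_rng(8)
        t = rng.standard_t(8, size=20_000)
        est = estimate_w(t, df_total=8.0, v=2 / 3)
        assert est.scale < 1.2
        assert est.w < 0.3

    def test_scale_recovery_under_mixture(self):
        rng = np.random.default_rng(9)
        t = rng.standard_t(6, size=50_000)
        alt = rng.random(50_000) < 0.10
        t[alt] *= 3.0
        est = estimate_w(t, df_total=6.0, v=1.0)
        assert est.scale == pytest.approx(3.0, rel=0.10)
        assert est.w == pytest.approx((est.scale**2 - 1.0) * 1.0)

    def test_override_bypasses_estimation(self, small_sim):
        mat = moderate(small_sim.data, w=4.0)
        v = 2 / 3
        np.testing.assert_allclose(mat.scale_alt, np.sqrt(1 + 4.0 / v))


class TestDensities:
    def test_scale_one_alt_equals_null(self):
        t = np.linspace(-8, 8, 101)
        np.testing.assert_allclose(
            alt_logdensity(t, 6.0, 1.0), null_logdensity(t, 6.0)
        )

    def test_center_point_scaling(self):
        assert alt_logdensity(0.0, 6.0, 2.0) == pytest.approx(
            null_logdensity(0.0, 6.0) - np.log(2.0)
        )

    @pytest.mark.parametrize("df,scale", [(6.0, 2.0), (8.0, 5.0), (3.5, 1.3)])
    def test_alt_density_integrates_to_one(self, df, scale):
        val, _ = integrate.quad(
            lambda x: np.exp(alt_logdensity(x, df, scale)), -np.inf, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_ratio_even_and_monotone(self):
        t = np.linspace(0.0, 50.0, 400)
        lr = alt_logdensity(t, 8.0, 2.5) - null_logdensity(t, 8.0)
        lr_neg = alt_logdensity(-t, 8.0, 2.5) - null_logdensity(-t, 8.0)
        np.testing.assert_allclose(lr, lr_neg, atol=1e-12)
        assert np.all(np.diff(lr) > 0)
        assert np.all(np.isfinite(lr))


def test_null_pipeline_t_distribution_ks():
    """On data generated from the hierarchical model with no signal, the
    moderated t of null genes should follow Student t with the total df."""
    spec = SimulationSpec(patterns=[(0,), (1,)], counts=[10_000, 0],
                          w0=4.0, seed=0)
    sim = simulate_model_based(spec)
    mat = moderate(sim.data, w=0.0)
    stat = stats.kstest(mat.t[:, 0], "t", args=(mat.df[0],))
    assert stat.pvalue > 0.01
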