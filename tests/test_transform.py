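"""The measure-preserving map and density/trajectory transforms."""

import math

import numpy as np
import pytest

import truescale as ts
from truescale.densities import Density1D, JointDensity2D
from truescale.priors import EmpiricalPrior


def uniform_density(n=512):
    g = np.linspace(0, 1, n)
    return Density1D(g, np.ones(n), kind="analytic")


def integrate_between(grid, p, a, b, n=2000):
    """Trapezoid integral of an interpolated gridded density over [a, b]."""
    x = np.linspace(a, b, n)
    return np.trapezoid(np.interp(x, grid, p), x)


class TestBuildMap:
    def test_uniform_to_uniform_is_identity(self):
        prior = EmpiricalPrior(np.linspace(0, 1, 101), np.linspace(0, 1, 101))
        m = ts.build_map(uniform_density(), prior)
        s = np.linspace(0, 1, 33)
        assert np.allclose(m.forward(s), s, atol=1e-6)

    def test_uniform_source_composes_with_age_invcdf(self):
        prior = ts.AgePrior(T=math.log(2))  # gamma = 1
        m = ts.build_map(uniform_density(), prior)
        assert m.forward(0.5) == pytest.approx(-math.log(0.75), abs=1e-6)

    def test_linear_change_of_variables(self):
        # if p_s is the target pdf rescaled onto [0, 1] via x = s*T,
        # cumulative masses match linearly and tau is the line x = s*T
        prior = ts.AgePrior(T=20.0)
        g = np.linspace(0, 1, 1024)
        p = np.asarray(prior.pdf(g * 20.0)) * 20.0
        m = ts.build_map(Density1D(g, p, kind="analytic"), prior)
        s = np.linspace(0.01, 0.99, 50)
        assert np.max(np.abs(m.forward(s) - 20.0 * s)) < 0.01

    def test_monotone_and_measure_preserving_invariant(self, rng):
        s_data = rng.beta(2, 1, 800)
        p_s = ts.kde_reflecting(s_data, 0.05)
        prior = ts.AgePrior(T=20.0)
        m = ts.build_map(p_s, prior)
        assert np.all(np.diff(m.x_grid) >= 0)
        # P_x(tau(s)) = P_s(s)
        check = np.asarray(prior.cdf(m.x_grid)) - m.source_cdf
        assert np.max(np.abs(check)) < 1e-6

    def test_roundtrip_inverse(self, rng):
        p_s = ts.kde_reflecting(rng.uniform(0, 1, 500), 0.06)
        m = ts.build_map(p_s, ts.AgePrior(T=20.0))
        s = np.linspace(0.05, 0.95, 40)
        assert np.max(np.abs(m.inverse(m.forward(s)) - s)) < 1e-6

    def test_zero_mass_region_warns(self):
        g = np.linspace(0, 1, 401)
        p = np.where((g > 0.4) & (g < 0.6), 0.0, 2.0)
        d = Density1D(g, p, kind="analytic")
        with pytest.warns(UserWarning, match="zero-mass"):
            ts.build_map(d, ts.AgePrior(T=10.0))


class TestTransformDensity:
    @pytest.fixture
    def setup(self, rng):
        s_data = rng.uniform(0, 1, 2000) ** 0.7
        p_s = ts.kde_reflecting(s_data, 0.05)
        prior = ts.AgePrior(T=20.0)
        return p_s, ts.build_map(p_s, prior), prior

    def test_integrates_to_one(self, setup):
        p_s, m, _ = setup
        p_x = ts.transform_density(p_s, m)
        assert p_x.integral() == pytest.approx(1.0, abs=1e-4)

    def test_self_consistency_recovers_prior_pdf(self, setup):
        # the map was built from p_s, so pushing p_s forward must give
        # back the prior's own density
        p_s, m, prior = setup
        p_x = ts.transform_density(p_s, m)
        expected = np.asarray(prior.pdf(np.clip(p_x.grid, 0, prior.T)))
        err = np.max(np.abs(p_x.p - expected)) / expected.max()
        assert err < 1e-3

    def test_area_conserved_on_random_intervals(self, setup, rng):
        p_s, m, _ = setup
        p_x = ts.transform_density(p_s, m)
        for _ in range(20):
            s1, s2 = np.sort(rng.uniform(0.02, 0.98, 2))
            mass_s = integrate_between(p_s.grid, p_s.p, s1, s2)
            mass_x = integrate_between(
                p_x.grid, p_x.p, float(m.forward(s1)), float(m.forward(s2))
            )
            assert mass_x == pytest.approx(mass_s, abs=1e-4)

    def test_roundtrip_recovers_pseudotime_density(self, setup):
        p_s, m, _ = setup
        p_x = ts.transform_density(p_s, m)
        back = ts.transform_density(p_x, m.inverted())
        interp = np.interp(p_s.grid, back.grid, back.p)
        inner = (p_s.grid > 0.02) & (p_s.grid < 0.98)
        assert np.max(np.abs(interp[inner] - p_s.p[inner])) / p_s.p.max() < 1e-3


class TestTransformJoint:
    @pytest.fixture
    def joint(self, rng):
        s = rng.uniform(0, 1, 400)
        y = rng.normal(3.0 * s, 0.5)
        return ts.kde_joint(
            ts.PseudotimeSample(s=s, y=y), ts.Bandwidths(0.06, 0.3)
        )

    def test_identity_map_preserves_joint(self, joint):
        prior = EmpiricalPrior(np.linspace(0, 1, 201), np.linspace(0, 1, 201))
        m = ts.build_map(joint.marginal_s(), prior)
        # not the identity map (marginal is non-uniform) unless source is;
        # build a true identity instead
        g = np.linspace(0, 1, 512)
        ident = ts.TransformMap(s_grid=g, x_grid=g, source_cdf=g)
        out = ts.transform_joint(joint, ident)
        interp = np.empty_like(out.p)
        for j in range(out.grid_y.size):
            interp[:, j] = np.interp(out.grid_s, joint.grid_s, joint.p[:, j])
        assert np.max(np.abs(out.p - interp)) < 1e-10

    def test_y_marginal_consistent_with_density_transform(self, joint):
        prior = ts.AgePrior(T=20.0)
        marg_s = joint.marginal_s()
        # renormalize the marginal (tiny y-truncation) before map building
        m = ts.build_map(marg_s, prior)
        out = ts.transform_joint(joint, m)
        p_x = ts.transform_density(marg_s, m)
        out_marg = np.trapezoid(out.p, out.grid_y, axis=1)
        assert np.max(np.abs(out_marg - p_x.p)) / p_x.p.max() < 1e-3

    def test_integrates_to_one(self, joint):
        m = ts.build_map(joint.marginal_s(), ts.AgePrior(T=20.0))
        out = ts.transform_joint(joint, m)
        assert out.integral() == pytest.approx(1.0, abs=2e-3)

    def test_three_cell_change_of_variables_oracle(self):
        s = np.array([0.25, 0.5, 0.75])
        y = np.array([1.0, 2.0, 3.0])
        joint = ts.kde_joint(ts.PseudotimeSample(s=s, y=y), ts.Bandwidths(0.1, 0.4))
        prior = ts.AgePrior(T=10.0)
        m = ts.build_map(joint.marginal_s(), prior)
        out = ts.transform_joint(joint, m)
        # oracle: s = tau^{-1}(x) by interpolation, Jacobian by central FD
        xg = out.grid_s
        s_of_x = np.interp(xg, m.x_grid, m.s_grid)
        jac = np.gradient(s_of_x, xg)
        for i in (50, 200, 400):
            row = np.array(
                [np.interp(s_of_x[i], joint.grid_s, joint.p[:, j])
                 for j in range(joint.grid_y.size)]
            )
            assert np.allclose(out.p[i], row * jac[i], rtol=1e-6, atol=1e-9)

    def test_non_monotone_map_rejected(self):
        g = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="nondecreasing"):
            ts.TransformMap(s_grid=g, x_grid=g[::-1], source_cdf=g)


class TestConditionalDensity:
    def test_columns_normalized(self, rng):
        s = rng.uniform(0, 1, 300)
        y = rng.normal(0, 1, 300)
        joint = ts.kde_joint(ts.PseudotimeSample(s=s, y=y), ts.Bandwidths(0.07, 0.3))
        cond = ts.conditional_density(joint)
        for i in np.flatnonzero(cond.valid):
            assert np.trapezoid(cond.p[i], cond.grid_y) == pytest.approx(1.0, abs=1e-3)

    def test_independent_marker_gives_identical_columns(self, rng):
        s = rng.uniform(0, 1, 4000)
        y = rng.normal(0, 1, 4000)
        joint = ts.kde_joint(ts.PseudotimeSample(s=s, y=y), ts.Bandwidths(0.08, 0.25))
        cond = ts.conditional_density(joint)
        cols = cond.p[cond.valid]
        spread = np.max(np.abs(cols - cols.mean(axis=0)), axis=0)
        # finite-sample KDE wobble only; columns share one shape
        assert spread.max() < 0.15 * cols.max()

    def test_three_cell_hand_normalized_oracle(self):
        grid_s = np.linspace(0, 1, 8)
        grid_y = np.linspace(-1, 1, 5)
        p = np.outer(np.linspace(0.2, 1.0, 8), np.ones(5))
        joint = JointDensity2D(grid_s, grid_y, p)
        cond = ts.conditional_density(joint)
        for i in range(8):
            norm = np.trapezoid(p[i], grid_y)
            assert np.allclose(cond.p[i], p[i] / norm)

    def test_zero_mass_columns_masked_not_propagated(self):
        grid_s = np.linspace(0, 1, 10)
        grid_y = np.linspace(0, 1, 6)
        p = np.ones((10, 6))
        p[3] = 1e-9  # nearly empty column
        cond = ts.conditional_density(JointDensity2D(grid_s, grid_y, p))
        assert not cond.valid[3]
        assert np.isnan(cond.p[3]).all()
        summ = ts.trajectory_summary(cond)
        assert np.isnan(summ.median[3])
        assert np.isfinite(summ.median[cond.valid]).all()


class TestTrajectorySummary:
    def test_gaussian_columns_have_normal_quartiles(self):
        grid_x = np.linspace(0, 1, 6)
        grid_y = np.linspace(-5, 5, 801)
        mu, sigma = 0.7, 0.9
        col = np.exp(-0.5 * ((grid_y - mu) / sigma) ** 2)
        joint = JointDensity2D(grid_x, grid_y, np.tile(col, (6, 1)))
        summ = ts.trajectory_summary(ts.conditional_density(joint))
        dy = grid_y[1] - grid_y[0]
        assert summ.median[0] == pytest.approx(mu, abs=2 * dy)
        assert summ.lower[0] == pytest.approx(mu - 0.6745 * sigma, abs=2 * dy)
        assert summ.upper[0] == pytest.approx(mu + 0.6745 * sigma, abs=2 * dy)

    def test_bands_are_nested(self, rng):
        s = rng.uniform(0, 1, 500)
        y = rng.normal(2 * s, 0.4)
        joint = ts.kde_joint(ts.PseudotimeSample(s=s, y=y), ts.Bandwidths(0.07, 0.2))
        summ = ts.trajectory_summary(ts.conditional_density(joint))
        v = np.isfinite(summ.median)
        assert np.all(summ.lower[v] <= summ.median[v] + 1e-12)
        assert np.all(summ.median[v] <= summ.upper[v] + 1e-12)

    def test_invalid_quantiles_rejected(self):
        grid = np.linspace(0, 1, 4)
        cond = ts.conditional_density(
            JointDensity2D(grid, grid, np.ones((4, 4)))
        )
        with pytest.raises(ValueError, match="quantiles"):
            ts.trajectory_summary(cond, quantiles=(0.5, 0.25))


class TestHalfMaxCrossing:
    def test_logistic_profile_midpoint(self):
        x = np.linspace(0, 20, 400)
        y = 1 + 99 / (1 + np.exp(-(x - 7.0) / 0.5))
        assert ts.half_max_crossing(x, y) == pytest.approx(7.0, abs=0.05)

    def test_flat_profile_rejected(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="never crosses"):
            ts.half_max_crossing(x, np.ones(50))


class TestSurfaceNormalization:
    def test_rim_median_is_one(self, rng):
        y = rng.lognormal(0, 1, (500, 2))
        depths = rng.uniform(0, 300, 500)
        out = ts.normalize_to_surface_median(y, depths, cutoff=150.0)
        rim = depths <= 150.0
        assert np.allclose(np.median(out[rim], axis=0), 1.0)

    def test_scale_invariance(self, rng):
        y = rng.lognormal(0, 1, 200)
        depths = rng.uniform(0, 300, 200)
        a = ts.normalize_to_surface_median(y, depths)
        b = ts.normalize_to_surface_median(17.3 * y, depths)
        assert np.allclose(a, b)

    def test_five_cell_hand_computed(self):
        y = np.array([2.0, 4.0, 6.0, 10.0, 20.0])
        depths = np.array([10.0, 50.0, 100.0, 200.0, 260.0])
        out = ts.normalize_to_surface_median(y, depths, cutoff=150.0)
        assert np.allclose(out, y / 4.0)  # median of first three cells

    def test_no_rim_cells_errors(self):
        with pytest.raises(ValueError, match="within"):
            ts.normalize_to_surface_median(
                np.array([1.0, 2.0]), np.array([200.0, 250.0]), cutoff=150.0
            )
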