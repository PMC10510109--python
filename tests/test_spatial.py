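"""Spatial statistics: edge correction, K/L estimators, envelope, tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memnano import spatial, synthgen
from memnano.core import PointPattern, Region

from .oracles import circle_fraction_by_sampling, ripley_k_naive


class TestEdgeWeight:
    def test_interior_edge_corner(self, region_nm):
        assert spatial.edge_weight((500, 500), 100, region_nm) == pytest.approx(1.0)
        assert spatial.edge_weight((0, 500), 100, region_nm) == pytest.approx(2.0)
        assert spatial.edge_weight((0, 0), 100, region_nm) == pytest.approx(4.0)

    def test_matches_arc_sampling_oracle(self, region_nm, rng):
        for _ in range(25):
            c = tuple(rng.uniform(0, 1000, size=2))
            r = rng.uniform(1, 450)
            p = circle_fraction_by_sampling(c, r, region_nm)
            assert 1.0 / spatial.edge_weight(c, r, region_nm) == pytest.approx(
                p, abs=2e-4
            )

    @given(
        x=st.floats(1.0, 999.0),
        y=st.floats(1.0, 999.0),
        r=st.floats(0.5, 499.0),
    )
    def test_weight_at_least_one(self, x, y, r):
        reg = Region(1000.0, 1000.0)
        assert spatial.edge_weight((x, y), r, reg) >= 1.0

    def test_errors(self, region_nm):
        with pytest.raises(ValueError, match="outside the region"):
            spatial.edge_weight((1500, 500), 10, region_nm)
        with pytest.raises(ValueError, match="positive"):
            spatial.edge_weight((500, 500), 0.0, region_nm)


class TestRipleyK:
    def test_two_point_hand_value(self, region_nm):
        # both points deep interior at distance 200: w = 1, so the two
        # ordered pairs give K = A * 2 / (n (n-1)) = A = 1e6 once r >= 200
        pat = PointPattern(np.array([[400.0, 500.0], [600.0, 500.0]]), region_nm)
        grid = spatial.RadiusGrid(np.array([100.0, 200.0, 300.0]))
        k = spatial.ripley_k(pat, grid)
        np.testing.assert_allclose(k.k_values, [0.0, 1e6, 1e6])

    def test_zero_below_min_pair_distance(self, region_nm):
        pat = synthgen.gen_csr_pattern(50, region_nm, seed=3)
        from scipy.spatial.distance import pdist

        dmin = pdist(pat.points).min()
        grid = spatial.RadiusGrid(np.array([dmin * 0.5, dmin * 0.99]))
        assert (spatial.ripley_k(pat, grid).k_values == 0).all()

    def test_matches_bruteforce_oracle(self, region_nm):
        radii = np.array([20.0, 60.0, 120.0, 240.0])
        grid = spatial.RadiusGrid(radii)
        for seed in range(5):
            n = 20 + 30 * seed
            pat = synthgen.gen_csr_pattern(n, region_nm, seed=100 + seed)
            fast = spatial.ripley_k(pat, grid).k_values
            naive = ripley_k_naive(pat, radii)
            np.testing.assert_allclose(fast, naive, rtol=1e-10)

    def test_monotone_nondecreasing(self, region_nm):
        pat = synthgen.gen_csr_pattern(150, region_nm, seed=5)
        k = spatial.ripley_k(pat, spatial.default_radius_grid())
        assert (np.diff(k.k_values) >= 0).all()

    def test_translation_and_permutation_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(100, 900, size=(80, 2))
        grid = spatial.default_radius_grid(100.0, 10.0)
        base = spatial.ripley_k(
            PointPattern(pts, Region(1000, 1000)), grid
        ).k_values
        shifted = spatial.ripley_k(
            PointPattern(pts + 37.5, Region(1075, 1075)), grid
        ).k_values
        # translation moves points relative to the window, so only compare
        # a translation of both: shift pattern and window together
        same_window = spatial.ripley_k(
            PointPattern(pts[rng.permutation(80)], Region(1000, 1000)), grid
        ).k_values
        np.testing.assert_allclose(base, same_window, rtol=1e-10)
        assert shifted.shape == base.shape  # smoke: larger window changes K

    def test_scaling_covariance(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 1000, size=(60, 2))
        s = 2.5
        grid = spatial.RadiusGrid(np.array([30.0, 90.0, 150.0]))
        grid_s = spatial.RadiusGrid(grid.radii * s)
        k1 = spatial.ripley_k(PointPattern(pts, Region(1000, 1000)), grid).k_values
        k2 = spatial.ripley_k(
            PointPattern(pts * s, Region(1000 * s, 1000 * s)), grid_s
        ).k_values
        np.testing.assert_allclose(k2, s**2 * k1, rtol=1e-9)

    def test_errors(self, region_nm):
        with pytest.raises(ValueError, match="at least 2"):
            spatial.ripley_k(
                PointPattern(np.array([[1.0, 1.0]]), region_nm),
                spatial.default_radius_grid(),
            )
        with pytest.raises(ValueError, match="empty"):
            spatial.RadiusGrid(np.array([]))


class TestLCurve:
    def test_csr_expectation_zero(self):
        grid = spatial.RadiusGrid(np.array([10.0, 50.0, 100.0]))
        k = spatial.KEstimate(
            radii=grid, k_values=np.pi * grid.radii**2, n=100, area=1e6
        )
        np.testing.assert_allclose(spatial.l_curve(k).l_minus_r, 0.0, atol=1e-12)

    def test_four_pi_r_squared(self):
        grid = spatial.RadiusGrid(np.array([10.0, 50.0, 100.0]))
        k = spatial.KEstimate(
            radii=grid, k_values=4 * np.pi * grid.radii**2, n=100, area=1e6
        )
        np.testing.assert_allclose(spatial.l_curve(k).l_minus_r, grid.radii)

    def test_zero_k(self):
        grid = spatial.RadiusGrid(np.array([10.0, 50.0]))
        k = spatial.KEstimate(radii=grid, k_values=np.zeros(2), n=100, area=1e6)
        np.testing.assert_allclose(spatial.l_curve(k).l_minus_r, -grid.radii)


class TestEnvelope:
    def test_determinism(self, region_nm):
        grid = spatial.default_radius_grid(100.0, 20.0)
        a = spatial.csr_envelope(100, region_nm, grid, n_sims=100, seed=4)
        b = spatial.csr_envelope(100, region_nm, grid, n_sims=100, seed=4)
        np.testing.assert_array_equal(
            a.upper_percentile_values, b.upper_percentile_values
        )

    def test_shrinks_with_n(self, region_nm):
        grid = spatial.default_radius_grid(200.0, 40.0)
        small = spatial.csr_envelope(50, region_nm, grid, n_sims=200, seed=5)
        large = spatial.csr_envelope(1000, region_nm, grid, n_sims=200, seed=6)
        assert (
            large.upper_percentile_values < small.upper_percentile_values
        ).all()

    def test_minimum_sims_enforced(self, region_nm):
        with pytest.raises(ValueError, match="n_sims"):
            spatial.csr_envelope(
                100, region_nm, spatial.default_radius_grid(), n_sims=50, seed=1
            )


class TestNormalizeAndLmax:
    def _env(self, grid, values):
        return spatial.Envelope(
            radii=grid,
            upper_percentile_values=values,
            percentile=99.0,
            n_sims=100,
            n=100,
            region=Region(1000, 1000),
        )

    def test_self_normalization(self):
        grid = spatial.RadiusGrid(np.array([10.0, 20.0, 30.0]))
        env_vals = np.array([2.0, 3.0, 1.5])
        l = spatial.LCurve(radii=grid, l_minus_r=env_vals.copy())
        norm = spatial.normalize_and_lmax(l, self._env(grid, env_vals))
        np.testing.assert_allclose(norm.values, 1.0)
        assert norm.l_max == pytest.approx(1.0)
        assert norm.r_at_max == 10.0  # ties broken by smallest radius

    def test_zero_curve(self):
        grid = spatial.RadiusGrid(np.array([10.0, 20.0]))
        l = spatial.LCurve(radii=grid, l_minus_r=np.zeros(2))
        norm = spatial.normalize_and_lmax(l, self._env(grid, np.ones(2)))
        assert norm.l_max == 0.0

    def test_nonpositive_envelope_excluded(self):
        grid = spatial.RadiusGrid(np.array([10.0, 20.0, 30.0]))
        l = spatial.LCurve(radii=grid, l_minus_r=np.array([5.0, 1.0, 2.0]))
        env = self._env(grid, np.array([-0.5, 1.0, 1.0]))
        norm = spatial.normalize_and_lmax(l, env)
        np.testing.assert_array_equal(norm.radii, [20.0, 30.0])
        assert norm.l_max == pytest.approx(2.0) and norm.r_at_max == 30.0
        with pytest.raises(ValueError, match="positive envelope"):
            spatial.normalize_and_lmax(l, self._env(grid, -np.ones(3)))

    def test_thomas_pattern_exceeds_envelope(self, region_nm):
        grid = spatial.default_radius_grid(240.0, 5.0)
        model = synthgen.ClusterModel(n_clusters=50, region=region_nm)
        pat, _ = synthgen.gen_cluster_pattern(model, seed=77)
        env = spatial.csr_envelope(pat.n, region_nm, grid, n_sims=100, seed=78)
        norm = spatial.normalize_and_lmax(
            spatial.l_curve(spatial.ripley_k(pat, grid)), env
        )
        assert norm.l_max > 1.0


class TestBootstrapLmax:
    def test_identical_groups(self):
        vals = np.array([1.0, 1.2, 1.4, 1.1])
        res = spatial.bootstrap_lmax(vals, vals.copy(), n_boot=1000, seed=1)
        assert res.observed_difference == 0.0
        assert res.p_value == 1.0

    def test_p_floor_and_bounds(self, rng):
        a = rng.normal(10.0, 0.1, size=15)
        b = rng.normal(0.0, 0.1, size=15)
        res = spatial.bootstrap_lmax(a, b, n_boot=2000, seed=2)
        assert res.p_value >= 1.0 / 2001
        assert res.p_value < 0.01

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            spatial.bootstrap_lmax(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="n_boot"):
            spatial.bootstrap_lmax(
                np.array([1.0, 2.0]), np.array([1.0, 2.0]), n_boot=10
            )


class TestLabelingDensity:
    def _pat(self, n, region, seed):
        return synthgen.gen_csr_pattern(n, region, seed=seed)

    def test_identical_densities(self, region_nm):
        pats = [self._pat(100, region_nm, s) for s in range(4)]
        res = spatial.labeling_density(pats, ["a", "a", "b", "b"])
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_separated_groups_hand_anova(self, region_nm):
        pats = [self._pat(n, region_nm, s) for s, n in enumerate([100] * 3 + [200] * 3)]
        res = spatial.labeling_density(pats, ["a"] * 3 + ["b"] * 3)
        # densities {100,100,100} vs {200,200,200} per um^2: zero within-group
        # variance, so F is infinite and p vanishes
        assert res.p_value < 0.01
        np.testing.assert_allclose(res.densities[0], 100.0)
        np.testing.assert_allclose(res.densities[1], 200.0)

    def test_matches_scipy_on_nondegenerate_data(self, region_nm, rng):
        from scipy.stats import f_oneway

        ns = rng.integers(80, 140, size=9)
        pats = [self._pat(int(n), region_nm, 50 + i) for i, n in enumerate(ns)]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = spatial.labeling_density(pats, groups)
        ref = f_oneway(*[d for d in res.densities])
        assert res.f_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_errors(self, region_nm):
        pats = [self._pat(10, region_nm, s) for s in range(3)]
        with pytest.raises(ValueError, match="2 groups"):
            spatial.labeling_density(pats, ["a", "a", "a"])
        with pytest.raises(ValueError, match="fewer than 2 sheets"):
            spatial.labeling_density(pats, ["a", "a", "b"])


class TestMonotoneClusteringResponse:
    def test_lmax_increases_as_clusters_tighten(self, region_nm):
        """Median L_max rises as the Thomas dispersion shrinks 80->40->20 nm."""
        grid = spatial.default_radius_grid(240.0, 10.0)
        medians = []
        for sd in (80.0, 40.0, 20.0):
            lmaxes = []
            for rep in range(15):
                model = synthgen.ClusterModel(
                    n_clusters=50, cluster_sd=sd, region=region_nm
                )
                pat, _ = synthgen.gen_cluster_pattern(model, seed=1000 + rep)
                env = spatial.csr_envelope(
                    pat.n, region_nm, grid, n_sims=100, seed=2000 + rep
                )
                norm = spatial.normalize_and_lmax(
                    spatial.l_curve(spatial.ripley_k(pat, grid)), env
                )
                lmaxes.append(norm.l_max)
            medians.append(np.median(lmaxes))
        assert medians[0] < medians[1] < medians[2]
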