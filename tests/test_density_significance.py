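import numpy as np
import pytest
from scipy.stats import norm

from vocamap import (
    CellMixtures,
    DensityGrid,
    GridSpec,
    bootstrap_cell_distributions,
    density,
    embedding_entropy,
    pooled_density,
    sidak_threshold,
    significance_map,
)


@pytest.fixture
def unit_grid():
    return GridSpec(x_range=(-20.0, 20.0), y_range=(-20.0, 20.0), n_x=40, n_y=40)


def make_mixture_grid(grid, weights, means, sigmas):
    """CellMixtures with the same univariate model at every cell."""
    k = len(weights)
    shape = (grid.n_x, grid.n_y, k)
    return CellMixtures(
        grid=grid,
        weights=np.broadcast_to(np.asarray(weights, float), shape).copy(),
        means=np.broadcast_to(np.asarray(means, float), shape).copy(),
        sigmas=np.broadcast_to(np.asarray(sigmas, float), shape).copy(),
        n_components=np.full((grid.n_x, grid.n_y), k),
    )


class TestDensity:
    def test_single_point_gaussian(self, unit_grid):
        pt = np.array([[3.2, -4.1]])
        d = density(pt, grid=unit_grid, sigma=2.0)
        ix, iy = unit_grid.locate(pt)
        assert np.unravel_index(np.argmax(d.rho), d.rho.shape) == (ix[0], iy[0])
        # profile proportional to a 2-D Gaussian centred on the point
        xc, yc = unit_grid.x_centers, unit_grid.y_centers
        expected = np.exp(
            -((xc[:, None] - pt[0, 0]) ** 2 + (yc[None, :] - pt[0, 1]) ** 2) / (2 * 4.0)
        )
        expected /= expected.sum() * unit_grid.cell_area
        assert np.allclose(d.rho, expected, rtol=1e-10)

    def test_normalization_contract(self, unit_grid):
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=5, size=(37, 2))
        for method in ("exact", "binned"):
            d = density(pts, grid=unit_grid, sigma=3.0, method=method)
            assert d.total_mass == pytest.approx(1.0, abs=1e-6)

    def test_two_distant_points_equal_maxima(self, unit_grid):
        pts = np.array([[-10.0, 0.0], [10.0, 0.0]])
        d = density(pts, grid=unit_grid, sigma=1.5)
        ix, iy = unit_grid.locate(pts)
        v1, v2 = d.rho[ix[0], iy[0]], d.rho[ix[1], iy[1]]
        assert v1 == pytest.approx(v2, rel=1e-9)
        # closed-form two-Gaussian sum at the first peak
        xc, yc = unit_grid.x_centers[ix[0]], unit_grid.y_centers[iy[0]]
        raw = sum(
            np.exp(-((xc - p[0]) ** 2 + (yc - p[1]) ** 2) / (2 * 1.5**2)) for p in pts
        )
        grid_total = 0.0
        for p in pts:
            gx = np.exp(-((unit_grid.x_centers - p[0]) ** 2) / (2 * 1.5**2))
            gy = np.exp(-((unit_grid.y_centers - p[1]) ** 2) / (2 * 1.5**2))
            grid_total += np.outer(gx, gy).sum()
        assert v1 == pytest.approx(raw / (grid_total * unit_grid.cell_area), rel=1e-9)

    def test_binned_close_to_exact(self, unit_grid):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=4, size=(200, 2))
        de = density(pts, grid=unit_grid, sigma=3.0, method="exact")
        db = density(pts, grid=unit_grid, sigma=3.0, method="binned")
        hi = de.rho > 0.25 * de.rho.max()
        assert np.median(np.abs(db.rho[hi] - de.rho[hi]) / de.rho[hi]) < 0.05

    def test_empty_subset_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            density(np.empty((0, 2)), grid=unit_grid)


class TestEntropy:
    def test_single_cell_zero_bits(self, unit_grid):
        rho = np.zeros((unit_grid.n_x, unit_grid.n_y))
        rho[5, 5] = 1.0 / unit_grid.cell_area
        assert embedding_entropy(DensityGrid(unit_grid, rho)) == pytest.approx(0.0)

    def test_uniform_log2_g(self, unit_grid):
        g = unit_grid.n_x * unit_grid.n_y
        rho = np.full((unit_grid.n_x, unit_grid.n_y), 1.0 / (g * unit_grid.cell_area))
        h = embedding_entropy(DensityGrid(unit_grid, rho))
        assert h == pytest.approx(np.log2(g), rel=1e-12)

    def test_half_half_one_bit(self, unit_grid):
        rho = np.zeros((unit_grid.n_x, unit_grid.n_y))
        rho[3, 3] = rho[30, 30] = 0.5 / unit_grid.cell_area
        assert embedding_entropy(DensityGrid(unit_grid, rho)) == pytest.approx(1.0)

    def test_unnormalized_rejected(self, unit_grid):
        rho = np.full((unit_grid.n_x, unit_grid.n_y), 1.0)
        with pytest.raises(ValueError, match="not normalized"):
            embedding_entropy(DensityGrid(unit_grid, rho))


class TestSidak:
    def test_single_comparison(self):
        assert sidak_threshold(0.05, 0.0) == pytest.approx(0.05)

    def test_closed_form_20_comparisons(self):
        h = np.log2(20.0)
        assert sidak_threshold(0.05, h) == pytest.approx(1 - 0.95 ** (1 / 20))

    def test_alpha_to_zero_limit(self):
        assert sidak_threshold(1e-12, 3.0) < 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sidak_threshold(0.0, 1.0)
        with pytest.raises(ValueError):
            sidak_threshold(0.05, -1.0)


class TestBootstrap:
    def test_identical_coordinates_give_point_masses(self, unit_grid):
        pts = np.tile([[1.0, 2.0]], (10, 1))
        q = bootstrap_cell_distributions(pts, grid=unit_grid, sigma=2.0, n_boot=20, seed=0)
        assert np.all(q.sigmas == 0.0)
        assert np.all(q.n_components == 1)

    def test_seeded_determinism(self, unit_grid):
        rng = np.random.default_rng(5)
        pts = rng.normal(scale=4, size=(40, 2))
        q1 = bootstrap_cell_distributions(pts, grid=unit_grid, sigma=2.0, n_boot=50, seed=3)
        q2 = bootstrap_cell_distributions(pts, grid=unit_grid, sigma=2.0, n_boot=50, seed=3)
        assert np.array_equal(q1.weights, q2.weights)
        assert np.array_equal(q1.means, q2.means)
        assert np.array_equal(q1.sigmas, q2.sigmas)

    def test_bootstrap_mean_consistent_with_point_estimate(self, unit_grid):
        rng = np.random.default_rng(11)
        pts = rng.normal(scale=4, size=(60, 2))
        q = bootstrap_cell_distributions(pts, grid=unit_grid, sigma=3.0, n_boot=1000, seed=1)
        pe = density(pts, grid=unit_grid, sigma=3.0, method="binned")
        hi = pe.rho > 0.5 * pe.rho.max()
        rel = np.abs(q.boot_mean[hi] - pe.rho[hi]) / pe.rho[hi]
        assert np.median(rel) < 0.05

    def test_mixture_weights_normalized(self, unit_grid):
        rng = np.random.default_rng(2)
        pts = rng.normal(scale=4, size=(30, 2))
        q = bootstrap_cell_distributions(pts, grid=unit_grid, sigma=2.0, n_boot=60, seed=2)
        assert np.allclose(q.weights.sum(axis=-1), 1.0, atol=1e-8)

    def test_bad_inputs(self, unit_grid):
        with pytest.raises(ValueError):
            bootstrap_cell_distributions(np.ones((5, 2)), grid=unit_grid, n_boot=1)
        with pytest.raises(ValueError):
            bootstrap_cell_distributions(np.ones((1, 2)), grid=unit_grid, n_boot=10)


class TestSignificanceMap:
    def test_identical_models_give_half(self, unit_grid):
        q = make_mixture_grid(unit_grid, [0.6, 0.4], [1.0, 3.0], [0.5, 0.2])
        sig = significance_map(q, q, alpha=0.05, H=0.0)
        assert np.allclose(sig.p_ht, 0.5, atol=1e-12)
        assert not sig.mask_any.any()

    def test_point_mass_strictly_above(self, unit_grid):
        q_wt = make_mixture_grid(unit_grid, [1.0], [1.0], [0.1])
        q_ht = make_mixture_grid(unit_grid, [1.0], [10.0], [0.0])  # atom at 10
        sig = significance_map(q_wt, q_ht, alpha=0.05, H=0.0)
        assert np.allclose(sig.p_ht, 1.0, atol=1e-12)
        assert sig.mask_ht_greater.all()

    @pytest.mark.parametrize("delta", [0.0, 0.5, 1.0, 2.5])
    def test_gaussian_separation_closed_form(self, unit_grid, delta):
        q_wt = make_mixture_grid(unit_grid, [1.0], [0.0], [1.0])
        q_ht = make_mixture_grid(unit_grid, [1.0], [delta], [1.0])
        sig = significance_map(q_wt, q_ht, alpha=0.05, H=0.0)
        assert np.allclose(sig.p_ht, norm.cdf(delta / np.sqrt(2)), atol=1e-12)

    def test_trapezoid_agrees_with_analytic(self):
        grid = GridSpec((-1.0, 1.0), (-1.0, 1.0), n_x=3, n_y=3)
        rng = np.random.default_rng(0)
        def random_mix():
            w = rng.dirichlet(np.ones(2))
            return make_mixture_grid(grid, w, rng.normal(size=2), rng.uniform(0.2, 1.0, 2))
        q_wt, q_ht = random_mix(), random_mix()
        s_a = significance_map(q_wt, q_ht, alpha=0.05, H=0.0, method="analytic")
        s_t = significance_map(q_wt, q_ht, alpha=0.05, H=0.0, method="trapezoid")
        assert np.allclose(s_a.p_ht, s_t.p_ht, atol=1e-4)

    def test_alpha_corrected_formula(self, unit_grid):
        q = make_mixture_grid(unit_grid, [1.0], [0.0], [1.0])
        sig = significance_map(q, q, alpha=0.05, H=5.0)
        assert sig.m == pytest.approx(32.0)
        assert sig.alpha_corrected == pytest.approx(1 - 0.95 ** (1 / 32))

    def test_grid_mismatch_rejected(self, unit_grid):
        other = GridSpec((-5.0, 5.0), (-5.0, 5.0), n_x=10, n_y=10)
        q1 = make_mixture_grid(unit_grid, [1.0], [0.0], [1.0])
        q2 = make_mixture_grid(other, [1.0], [0.0], [1.0])
        with pytest.raises(ValueError, match="different grids"):
            significance_map(q1, q2)


def test_pooled_density_average(unit_grid):
    rng = np.random.default_rng(8)
    a = density(rng.normal(size=(20, 2)), grid=unit_grid, sigma=2.0)
    b = density(rng.normal(loc=3, size=(20, 2)), grid=unit_grid, sigma=2.0)
    pooled = pooled_density(a, b)
    assert np.allclose(pooled.rho, 0.5 * (a.rho + b.rho))
    assert pooled.total_mass == pytest.approx(1.0, abs=1e-9)
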