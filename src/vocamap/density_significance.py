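"""Density maps, map entropy, and the bootstrap significance map.

Given the 2-D repertoire map, each genotype's vocalizations are turned into
a gridded probability density rho_g(x, y) by Gaussian smoothing (default
width sigma = 4 map units).  To decide where the two genotypes' repertoires
differ, the sampling variability of each density is estimated by
bootstrapping: the embedded points of each group are resampled with
replacement n_boot times, every resample is smoothed into a density grid,
and at each grid cell the resulting n_boot density values are summarized by
a univariate Gaussian mixture (1-3 components, chosen per cell by AIC; a
zero-variance cell becomes a point mass).  The per-cell statistic

    P_HT(x, y) = Prob(rho_HT(x, y) > rho_WT(x, y))

is computed from the two fitted cell models under independence.  Cells with
P_HT < alpha' or P_HT > 1 - alpha' are flagged, where alpha' is the Šidák
per-test level alpha' = 1 - (1 - alpha)^(1/m).  The effective number of
comparisons m = 2^H is taken (conservatively) from the entropy H of the
pooled map density rho = (rho_HT + rho_WT) / 2, discretized on the same
grid: H = -sum_i p_i log2 p_i with p_i = rho_i * cell_area.

Because the per-cell models are Gaussian mixtures, P(X > Y) has an exact
closed form (a weighted sum of normal CDF terms); this is the default
evaluation route, with a trapezoidal numerical integrator available for
cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import ndtr  # fast standard normal CDF

from .embedding import RepertoireMap

try:  # optional JIT acceleration of the per-cell EM
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "GridSpec",
    "DensityGrid",
    "CellMixtures",
    "SignificanceMap",
    "density",
    "pooled_density",
    "embedding_entropy",
    "sidak_threshold",
    "bootstrap_cell_distributions",
    "significance_map",
]


# ---------------------------------------------------------------------------
# grid and density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular evaluation grid over the repertoire map."""

    x_range: tuple[float, float]
    y_range: tuple[float, float]
    n_x: int = 100
    n_y: int = 100

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.x_range[1] <= self.x_range[0] or self.y_range[1] <= self.y_range[0]:
            raise ValueError("empty grid range")

    @classmethod
    def from_points(
        cls,
        points: np.ndarray,
        n_x: int = 100,
        n_y: int = 100,
        margin: float = 12.0,
    ) -> "GridSpec":
        """Grid covering the points with a margin (>= 3 sigma recommended)."""
        pts = np.asarray(points, dtype=float)
        return cls(
            x_range=(pts[:, 0].min() - margin, pts[:, 0].max() + margin),
            y_range=(pts[:, 1].min() - margin, pts[:, 1].max() + margin),
            n_x=n_x,
            n_y=n_y,
        )

    @property
    def cell_w(self) -> float:
        return (self.x_range[1] - self.x_range[0]) / self.n_x

    @property
    def cell_h(self) -> float:
        return (self.y_range[1] - self.y_range[0]) / self.n_y

    @property
    def cell_area(self) -> float:
        return self.cell_w * self.cell_h

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_range[0] + (np.arange(self.n_x) + 0.5) * self.cell_w

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_range[0] + (np.arange(self.n_y) + 0.5) * self.cell_h

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices (ix, iy) of each point, clipped to the grid."""
        pts = np.asarray(points, dtype=float)
        ix = np.floor((pts[:, 0] - self.x_range[0]) / self.cell_w).astype(int)
        iy = np.floor((pts[:, 1] - self.y_range[0]) / self.cell_h).astype(int)
        return np.clip(ix, 0, self.n_x - 1), np.clip(iy, 0, self.n_y - 1)

    def covers(self, points: np.ndarray) -> bool:
        pts = np.asarray(points, dtype=float)
        return bool(
            (pts[:, 0] >= self.x_range[0]).all()
            and (pts[:, 0] <= self.x_range[1]).all()
            and (pts[:, 1] >= self.y_range[0]).all()
            and (pts[:, 1] <= self.y_range[1]).all()
        )


@dataclass
class DensityGrid:
    """Normalized probability density over the map grid for one group."""

    grid: GridSpec
    rho: np.ndarray  # (n_x, n_y), integrates to 1 over the grid
    group: str = "pooled"
    sigma: float = 4.0

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (self.grid.n_x, self.grid.n_y):
            raise ValueError("rho shape does not match grid")
        if np.any(self.rho < 0):
            raise ValueError("density values must be >= 0")

    @property
    def total_mass(self) -> float:
        return float(self.rho.sum() * self.grid.cell_area)

    def cell_probabilities(self) -> np.ndarray:
        return self.rho * self.grid.cell_area


def _points_of(map_or_points, subset=None) -> np.ndarray:
    pts = (
        map_or_points.coordinates
        if isinstance(map_or_points, RepertoireMap)
        else np.asarray(map_or_points, dtype=float)
    )
    if subset is not None:
        subset = np.asarray(subset)
        pts = pts[subset]
    if pts.size == 0:
        raise ValueError("empty point subset")
    return pts


def density(
    map_or_points,
    subset=None,
    grid: GridSpec | None = None,
    sigma: float = 4.0,
    group: str = "pooled",
    method: str = "exact",
) -> DensityGrid:
    """Gaussian-smoothed density of a point subset, normalized on the grid.

    ``method="exact"`` sums an isotropic Gaussian kernel (std ``sigma``)
    per point at every cell center; ``method="binned"`` histograms the
    points and convolves with the same Gaussian — the route used for the
    bootstrap resamples, identical up to the cell-width binning error.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pts = _points_of(map_or_points, subset)
    if grid is None:
        grid = GridSpec.from_points(pts, margin=3.0 * sigma)
    if method == "exact":
        gx = np.exp(-((grid.x_centers[:, None] - pts[None, :, 0]) ** 2) / (2 * sigma**2))
        gy = np.exp(-((grid.y_centers[:, None] - pts[None, :, 1]) ** 2) / (2 * sigma**2))
        rho = gx @ gy.T
    elif method == "binned":
        rho = _binned_density(pts, grid, sigma)
    else:
        raise ValueError(f"unknown density method {method!r}")
    total = rho.sum() * grid.cell_area
    if total <= 0:
        raise ValueError("all density mass fell outside the grid")
    return DensityGrid(grid=grid, rho=rho / total, group=group, sigma=sigma)


def _binned_density(pts: np.ndarray, grid: GridSpec, sigma: float) -> np.ndarray:
    ix, iy = grid.locate(pts)
    counts = np.bincount(
        ix * grid.n_y + iy, minlength=grid.n_x * grid.n_y
    ).reshape(grid.n_x, grid.n_y)
    return ndimage.gaussian_filter(
        counts.astype(float),
        sigma=(sigma / grid.cell_w, sigma / grid.cell_h),
        mode="constant",
    )


def pooled_density(a: DensityGrid, b: DensityGrid) -> DensityGrid:
    """rho = (rho_a + rho_b) / 2 on a shared grid."""
    if a.grid != b.grid:
        raise ValueError("density grids do not match")
    return DensityGrid(
        grid=a.grid, rho=0.5 * (a.rho + b.rho), group="pooled", sigma=a.sigma
    )


def embedding_entropy(rho: DensityGrid) -> float:
    """Shannon entropy (bits) of the discretized map density.

    Uses the cell-probability convention p_i = rho_i * cell_area, the grid
    quadrature of -∬ rho log2 rho dx dy up to the (fixed) log cell area.
    """
    p = rho.cell_probabilities().ravel()
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"density not normalized (total mass {p.sum():.8f})")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def sidak_threshold(alpha: float, H: float) -> float:
    """Šidák per-cell level for m = 2**H effective comparisons (m unrounded)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if H < 0:
        raise ValueError("entropy must be >= 0")
    return float(1.0 - (1.0 - alpha) ** (2.0 ** -H))


# ---------------------------------------------------------------------------
# bootstrap + per-cell Gaussian mixtures
# ---------------------------------------------------------------------------

@dataclass
class CellMixtures:
    """Per-cell univariate Gaussian-mixture models of bootstrap densities.

    Arrays have shape (n_x, n_y, max_k); unused components carry zero
    weight.  A point mass is a component with sigma = 0.
    """

    grid: GridSpec
    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    n_components: np.ndarray  # (n_x, n_y) ints
    group: str = ""
    n_boot: int = 0
    sigma_map: float = 4.0
    boot_mean: np.ndarray | None = None

    @property
    def max_k(self) -> int:
        return self.weights.shape[-1]

    def mixture_mean(self) -> np.ndarray:
        return (self.weights * self.means).sum(axis=-1)


def _em_fixed_k(
    x: np.ndarray, k: int, n_iter: int = 80, rtol: float = 1e-7
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM for k-component 1-D GMMs, one model per row of x.

    Deterministic: means initialize at evenly spaced within-cell quantiles.
    Returns (weights, means, sigmas, loglik) with shapes (C, k) / (C,).
    """
    c, n = x.shape
    qs = (np.arange(k) + 1.0) / (k + 1.0)
    mu = np.quantile(x, qs, axis=1).T.copy()  # (C, k)
    sd0 = x.std(axis=1)
    var_floor = np.maximum(sd0**2 * 1e-6, 1e-300)
    sg = np.maximum(sd0, np.sqrt(var_floor))[:, None] * np.ones((1, k))
    w = np.full((c, k), 1.0 / k)
    log2pi = np.log(2.0 * np.pi)
    ll_old = np.full(c, -np.inf)
    for it in range(n_iter):
        z = (x[:, :, None] - mu[:, None, :]) / sg[:, None, :]
        logp = (
            np.log(np.maximum(w, 1e-300))[:, None, :]
            - np.log(sg)[:, None, :]
            - 0.5 * (z**2 + log2pi)
        )  # (C, n, k)
        mx = logp.max(axis=2, keepdims=True)
        lse = mx + np.log(np.exp(logp - mx).sum(axis=2, keepdims=True))
        ll = lse.sum(axis=(1, 2))
        resp = np.exp(logp - lse)
        nk = resp.sum(axis=1)  # (C, k)
        w = nk / n
        nk_safe = np.maximum(nk, 1e-12)
        mu = (resp * x[:, :, None]).sum(axis=1) / nk_safe
        var = (resp * (x[:, :, None] - mu[:, None, :]) ** 2).sum(axis=1) / nk_safe
        sg = np.sqrt(np.maximum(var, var_floor[:, None]))
        if it >= 5 and np.all(np.abs(ll - ll_old) <= rtol * (np.abs(ll) + 1.0)):
            ll_old = ll
            break
        ll_old = ll
    return w, mu, sg, ll_old


if _HAVE_NUMBA:

    @numba.njit(cache=True, parallel=True)
    def _fit_cells_nb(x_all, max_k, n_iter, rtol, weights, means, sigmas, ncomp):
        """Per-cell 1..max_k-component EM with AIC selection (see numpy path).

        Data are standardized per cell; the log-likelihood then differs from
        the raw-data one by a constant shared across k, so AIC ranking is
        unchanged.  Parameters are de-standardized before storing.
        """
        n_cells, n = x_all.shape
        log2pi = math.log(2.0 * math.pi)
        for ci in numba.prange(n_cells):
            x = x_all[ci]
            mean = x.mean()
            xmin = x.min()
            xmax = x.max()
            if xmax - xmin <= 1e-12 * max(abs(xmax), abs(xmin), 1.0):
                weights[ci, 0] = 1.0
                means[ci, 0] = mean
                ncomp[ci] = 1
                continue
            var = 0.0
            for t in range(n):
                var += (x[t] - mean) ** 2
            var /= n
            sd = math.sqrt(var)
            z = np.empty(n)
            for t in range(n):
                z[t] = (x[t] - mean) / sd
            zs = np.sort(z)
            best_aic = np.inf
            w = np.empty(max_k)
            mu = np.empty(max_k)
            sg = np.empty(max_k)
            inv = np.empty(max_k)
            pa = np.empty(max_k)
            nk = np.empty(max_k)
            s1 = np.empty(max_k)
            s2 = np.empty(max_k)
            for k in range(1, max_k + 1):
                if k == 1:
                    # standardized data: MLE is N(0, 1)
                    w[0], mu[0], sg[0] = 1.0, 0.0, 1.0
                    ll = -0.5 * n * (log2pi + 1.0)
                else:
                    for a in range(k):
                        w[a] = 1.0 / k
                        mu[a] = zs[int((a + 1.0) / (k + 1.0) * (n - 1))]
                        sg[a] = 1.0
                    ll = -np.inf
                    for it in range(n_iter):
                        ll_old = ll
                        ll = 0.0
                        for a in range(k):
                            nk[a] = 0.0
                            s1[a] = 0.0
                            s2[a] = 0.0
                            inv[a] = 1.0 / sg[a]
                        for t in range(n):
                            zt = z[t]
                            tot = 0.0
                            for a in range(k):
                                u = (zt - mu[a]) * inv[a]
                                q = w[a] * inv[a] * math.exp(-0.5 * u * u)
                                pa[a] = q
                                tot += q
                            if tot < 1e-300:
                                tot = 1e-300
                            ll += math.log(tot)
                            for a in range(k):
                                r = pa[a] / tot
                                nk[a] += r
                                s1[a] += r * zt
                                s2[a] += r * zt * zt
                        ll -= 0.5 * n * log2pi
                        for a in range(k):
                            na = nk[a] if nk[a] > 1e-12 else 1e-12
                            w[a] = nk[a] / n
                            m_ = s1[a] / na
                            v_ = s2[a] / na - m_ * m_
                            mu[a] = m_
                            sg[a] = math.sqrt(max(v_, 1e-6))
                        if it > 3 and abs(ll - ll_old) <= rtol * (abs(ll) + 1.0):
                            break
                aic = 2.0 * (3.0 * k - 1.0) - 2.0 * ll
                if aic < best_aic:
                    best_aic = aic
                    ncomp[ci] = k
                    for a in range(max_k):
                        if a < k:
                            weights[ci, a] = w[a]
                            means[ci, a] = mu[a] * sd + mean
                            sigmas[ci, a] = sg[a] * sd
                        else:
                            weights[ci, a] = 0.0
                            means[ci, a] = 0.0
                            sigmas[ci, a] = 0.0


def _fit_cell_mixtures(
    values: np.ndarray, max_k: int = 3, chunk: int = 1024, n_iter: int = 25
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """AIC-selected 1-3 component GMM per cell.

    ``values``: (n_boot, n_cells).  Zero-variance cells become point masses.
    """
    if _HAVE_NUMBA:
        n_cells = values.shape[1]
        weights = np.zeros((n_cells, max_k))
        means = np.zeros((n_cells, max_k))
        sigmas = np.zeros((n_cells, max_k))
        ncomp = np.ones(n_cells, dtype=np.int64)
        _fit_cells_nb(
            np.ascontiguousarray(values.T), max_k, n_iter, 1e-5,
            weights, means, sigmas, ncomp,
        )
        return weights, means, sigmas, ncomp
    n_boot, n_cells = values.shape
    weights = np.zeros((n_cells, max_k))
    means = np.zeros((n_cells, max_k))
    sigmas = np.zeros((n_cells, max_k))
    ncomp = np.ones(n_cells, dtype=int)

    x_all = values.T  # (cells, n_boot)
    spread = x_all.max(axis=1) - x_all.min(axis=1)
    scale = np.abs(x_all).max(axis=1)
    degenerate = spread <= 1e-12 * np.maximum(scale, 1.0)

    # point masses
    if degenerate.any():
        weights[degenerate, 0] = 1.0
        means[degenerate, 0] = x_all[degenerate].mean(axis=1)

    idx = np.flatnonzero(~degenerate)
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        x = x_all[sel]
        best_aic = np.full(sel.size, np.inf)
        for k in range(1, max_k + 1):
            w, mu, sg, ll = _em_fixed_k(x, k)
            aic = 2.0 * (3 * k - 1) - 2.0 * ll
            better = aic < best_aic
            if np.any(better):
                rows = sel[better]
                weights[rows, :] = 0.0
                means[rows, :] = 0.0
                sigmas[rows, :] = 0.0
                weights[rows, :k] = w[better]
                means[rows, :k] = mu[better]
                sigmas[rows, :k] = sg[better]
                ncomp[rows] = k
                best_aic[better] = aic[better]
    return weights, means, sigmas, ncomp


def bootstrap_cell_distributions(
    map_or_points,
    subset=None,
    grid: GridSpec | None = None,
    sigma: float = 4.0,
    n_boot: int = 1000,
    seed: int = 0,
    group: str = "",
    max_components: int = 3,
) -> CellMixtures:
    """Bootstrap the group's map density and fit per-cell mixture models.

    The group's embedded points are resampled with replacement ``n_boot``
    times; each resample is smoothed into a normalized density grid
    (histogram + Gaussian convolution).  At every cell the n_boot density
    values are modelled by a 1-3 component Gaussian mixture selected by
    AIC (zero-variance cells become point masses).  Deterministic given
    ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    pts = _points_of(map_or_points, subset)
    if pts.shape[0] < 2:
        raise ValueError("subset must contain >= 2 points")
    if grid is None:
        grid = GridSpec.from_points(pts, margin=3.0 * sigma)
    rng = np.random.default_rng(seed)
    n_pts = pts.shape[0]
    ix, iy = grid.locate(pts)
    flat = ix * grid.n_y + iy
    n_cells = grid.n_x * grid.n_y
    filt_sigma = (sigma / grid.cell_w, sigma / grid.cell_h)
    values = np.empty((n_boot, n_cells))
    for b in range(n_boot):
        draw = rng.integers(0, n_pts, size=n_pts)
        counts = np.bincount(flat[draw], minlength=n_cells).reshape(
            grid.n_x, grid.n_y
        )
        rho = ndimage.gaussian_filter(
            counts.astype(float), sigma=filt_sigma, mode="constant"
        )
        values[b] = (rho / (rho.sum() * grid.cell_area)).ravel()

    weights, means, sigmas, ncomp = _fit_cell_mixtures(values, max_k=max_components)
    shape3 = (grid.n_x, grid.n_y, max_components)
    return CellMixtures(
        grid=grid,
        weights=weights.reshape(shape3),
        means=means.reshape(shape3),
        sigmas=sigmas.reshape(shape3),
        n_components=ncomp.reshape(grid.n_x, grid.n_y),
        group=group,
        n_boot=n_boot,
        sigma_map=sigma,
        boot_mean=values.mean(axis=0).reshape(grid.n_x, grid.n_y),
    )


# ---------------------------------------------------------------------------
# significance map
# ---------------------------------------------------------------------------

@dataclass
class SignificanceMap:
    """Per-cell P_HT values with the Šidák-corrected significance masks."""

    grid: GridSpec
    p_ht: np.ndarray
    alpha: float
    H: float
    alpha_corrected: float = field(init=False)
    m: float = field(init=False)
    mask_ht_greater: np.ndarray = field(init=False)
    mask_wt_greater: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.p_ht = np.asarray(self.p_ht, dtype=float)
        if np.any(self.p_ht < 0) or np.any(self.p_ht > 1):
            raise ValueError("P_HT values must lie in [0, 1]")
        self.m = float(2.0**self.H)
        self.alpha_corrected = sidak_threshold(self.alpha, self.H)
        self.mask_ht_greater = self.p_ht > 1.0 - self.alpha_corrected
        self.mask_wt_greater = self.p_ht < self.alpha_corrected

    @property
    def mask_any(self) -> np.ndarray:
        return self.mask_ht_greater | self.mask_wt_greater

    @property
    def flagged_fraction(self) -> float:
        return float(self.mask_any.mean())


def _prob_greater_analytic(q_ht: CellMixtures, q_wt: CellMixtures) -> np.ndarray:
    """P(X > Y) for independent per-cell Gaussian mixtures, closed form."""
    w1, mu1, sg1 = q_ht.weights, q_ht.means, q_ht.sigmas
    w0, mu0, sg0 = q_wt.weights, q_wt.means, q_wt.sigmas
    diff = mu1[..., :, None] - mu0[..., None, :]
    s = np.sqrt(sg1[..., :, None] ** 2 + sg0[..., None, :] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_pair = ndtr(diff / s)
    atom = s == 0  # both components are point masses
    if np.any(atom):
        p_pair = np.where(atom & (diff > 0), 1.0, p_pair)
        p_pair = np.where(atom & (diff < 0), 0.0, p_pair)
        p_pair = np.where(atom & (diff == 0), 0.5, p_pair)  # tie convention
    wpair = w1[..., :, None] * w0[..., None, :]
    return np.clip((wpair * p_pair).sum(axis=(-2, -1)), 0.0, 1.0)


def _prob_greater_trapezoid(
    q_ht: CellMixtures, q_wt: CellMixtures, n_grid: int = 2048
) -> np.ndarray:
    """Trapezoidal-rule evaluation of P(X > Y) per cell (cross-check route).

    Continuous x continuous component pairs are integrated numerically on a
    shared density-value grid spanning both models' extreme quantiles; pairs
    involving point masses are handled analytically.
    """
    from scipy.stats import norm

    nx, ny, k = q_ht.weights.shape
    out = np.empty((nx, ny))
    z = norm.ppf(1e-6)  # ~ -4.75: 1e-6 .. 1-1e-6 quantile span
    for i in range(nx):
        for j in range(ny):
            w1, mu1, sg1 = q_ht.weights[i, j], q_ht.means[i, j], q_ht.sigmas[i, j]
            w0, mu0, sg0 = q_wt.weights[i, j], q_wt.means[i, j], q_wt.sigmas[i, j]
            p = 0.0
            act1, act0 = w1 > 0, w0 > 0
            los, his = [], []
            for mu, sg, act in ((mu1, sg1, act1), (mu0, sg0, act0)):
                cont = act & (sg > 0)
                if cont.any():
                    los.append((mu[cont] + z * sg[cont]).min())
                    his.append((mu[cont] - z * sg[cont]).max())
            u = np.linspace(min(los), max(his), n_grid) if los else None
            for a in range(k):
                if not act1[a]:
                    continue
                if sg1[a] == 0:
                    # HT atom: P(WT < atom) + half of any tied WT atoms
                    cdf = 0.0
                    for b in range(k):
                        if not act0[b]:
                            continue
                        if sg0[b] == 0:
                            cdf += w0[b] * (
                                1.0 if mu0[b] < mu1[a] else 0.5 if mu0[b] == mu1[a] else 0.0
                            )
                        else:
                            cdf += w0[b] * ndtr((mu1[a] - mu0[b]) / sg0[b])
                    p += w1[a] * cdf
                else:
                    pdf1 = norm.pdf(u, mu1[a], sg1[a])
                    cdf0 = np.zeros_like(u)
                    for b in range(k):
                        if not act0[b]:
                            continue
                        if sg0[b] == 0:
                            cdf0 += w0[b] * (u > mu0[b])
                        else:
                            cdf0 += w0[b] * ndtr((u - mu0[b]) / sg0[b])
                    p += w1[a] * np.trapezoid(pdf1 * cdf0, u)
            out[i, j] = min(max(p, 0.0), 1.0)
    return out


def significance_map(
    q_wt: CellMixtures,
    q_ht: CellMixtures,
    alpha: float = 0.05,
    H: float | None = None,
    method: str = "analytic",
) -> SignificanceMap:
    """Per-cell P_HT = P(rho_HT > rho_WT) with Šidák-corrected masks.

    ``H`` is the pooled-map entropy in bits; when omitted it is computed
    from the average of the two groups' bootstrap-mean densities.
    """
    if q_wt.grid != q_ht.grid:
        raise ValueError("cell models are defined on different grids")
    if H is None:
        if q_wt.boot_mean is None or q_ht.boot_mean is None:
            raise ValueError("H not given and bootstrap means unavailable")
        pooled = DensityGrid(
            grid=q_wt.grid,
            rho=0.5 * (q_wt.boot_mean + q_ht.boot_mean),
            group="pooled",
            sigma=q_wt.sigma_map,
        )
        H = embedding_entropy(pooled)
    if method == "analytic":
        p_ht = _prob_greater_analytic(q_ht, q_wt)
    elif method == "trapezoid":
        p_ht = _prob_greater_trapezoid(q_ht, q_wt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SignificanceMap(grid=q_wt.grid, p_ht=p_ht, alpha=alpha, H=float(H))
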