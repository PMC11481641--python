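"""Spatial interpolation of well indices: variograms, ordinary kriging, IDW.

Turns per-well index values into continuous surfaces on a regular grid and
rank-classified category maps. Ordinary kriging is global (no search
neighbourhood — monitoring networks here have a few dozen wells), solving
the semivariance system with the unbiasedness constraint via a Lagrange
multiplier; weights sum to one at every node and with a zero nugget the
surface honours the data exactly. Inverse-distance weighting is provided
as a model-free fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import least_squares

from .indices import RankScale

__all__ = [
    "VariogramModel",
    "RasterGrid",
    "empirical_semivariogram",
    "fit_variogram",
    "kriging_weights",
    "ordinary_kriging",
    "idw",
    "classify_raster",
    "grid_from_points",
]

NODATA = -9999.0


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram: ``gamma(0)=nugget``, sill ``nugget+psill``.

    Families: ``spherical`` (reaches the sill at ``range_m``),
    ``exponential`` (effective range ~3x the scale parameter) and
    ``gaussian``.
    """

    family: str
    nugget: float
    psill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.family not in ("spherical", "exponential", "gaussian"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill <= 0 or self.range_m <= 0:
            raise ValueError("variogram parameters out of bounds")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        a, c, c0 = self.range_m, self.psill, self.nugget
        if self.family == "spherical":
            hr = np.minimum(h / a, 1.0)
            g = c * (1.5 * hr - 0.5 * hr**3)
        elif self.family == "exponential":
            g = c * (1.0 - np.exp(-h / a))
        else:
            g = c * (1.0 - np.exp(-((h / a) ** 2)))
        return np.where(h > 0, c0 + g, 0.0)


@dataclass
class RasterGrid:
    """Regular grid with georeferencing: row 0 is the northernmost row.

    ``origin`` is the lower-left corner of the grid extent; cell centres are
    the prediction locations. ``values`` has shape (n_rows, n_cols).
    """

    origin: tuple[float, float]
    cell_size: float
    n_rows: int
    n_cols: int
    values: np.ndarray
    crs: str = ""
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"value matrix shape {self.values.shape} != "
                f"({self.n_rows}, {self.n_cols})"
            )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of cell centres, row-major north-first."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def like(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(
            self.origin, self.cell_size, self.n_rows, self.n_cols,
            values, self.crs, self.nodata,
        )


def grid_from_points(
    x, y, cell_size: float = 50.0, pad_fraction: float = 0.10, crs: str = ""
) -> RasterGrid:
    """Empty grid spanning the wells' bounding box padded by a fraction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pad_x = pad_fraction * max(np.ptp(x), cell_size)
    pad_y = pad_fraction * max(np.ptp(y), cell_size)
    x0, y0 = x.min() - pad_x, y.min() - pad_y
    n_cols = max(1, int(math.ceil((np.ptp(x) + 2 * pad_x) / cell_size)))
    n_rows = max(1, int(math.ceil((np.ptp(y) + 2 * pad_y) / cell_size)))
    vals = np.full((n_rows, n_cols), NODATA)
    return RasterGrid((x0, y0), cell_size, n_rows, n_cols, vals, crs)


def empirical_semivariogram(
    points, values, n_lags: int = 12, max_dist: float | None = None
):
    """Binned empirical semivariogram.

    Returns ``(lag_centers, gamma_hat, pair_counts)`` where ``gamma_hat`` is
    the mean of ``(z_i - z_j)^2 / 2`` over point pairs in each distance bin;
    empty bins are omitted.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(z) == 0:
        pass  # constant field is legal: gamma_hat = 0 everywhere
    iu, ju = np.triu_indices(len(pts), k=1)
    d = np.linalg.norm(pts[iu] - pts[ju], axis=-1)
    if np.all(d == 0):
        raise ValueError("all points are coincident")
    if max_dist is None:
        max_dist = float(d.max())
    sq = 0.5 * (z[iu] - z[ju]) ** 2
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= max_dist
    lags, gammas, counts = [], [], []
    for b in range(n_lags):
        m = keep & (which == b)
        if not m.any():
            continue
        lags.append(float(d[m].mean()))
        gammas.append(float(sq[m].mean()))
        counts.append(int(m.sum()))
    return np.array(lags), np.array(gammas), np.array(counts, dtype=int)


def fit_variogram(
    lags, gammas, counts, family: str = "spherical"
) -> tuple[VariogramModel, float]:
    """Weighted least-squares variogram fit (pair-count weights).

    Falls back (with a warning) to a default model — zero nugget, sill at
    the mean empirical semivariance, range at half the maximum lag — when
    fewer than 3 usable lags exist or the optimiser fails. Returns the
    model and the weighted RMS residual.
    """
    lags = np.asarray(lags, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    counts = np.asarray(counts, dtype=float)

    def fallback() -> tuple[VariogramModel, float]:
        sill = float(max(gammas.mean(), 1e-12)) if len(gammas) else 1.0
        rng = float(lags.max() / 2.0) if len(lags) else 1.0
        warnings.warn("variogram fit fell back to the default model")
        return VariogramModel(family, 0.0, sill, max(rng, 1e-9)), math.inf

    if len(lags) < 3:
        return fallback()

    wts = np.sqrt(counts / counts.sum())
    sill0 = max(float(gammas.mean()), 1e-12)
    rng0 = max(float(lags.max()) / 2.0, 1e-9)

    def resid(theta):
        nugget, psill, rng = theta
        model = VariogramModel(family, max(nugget, 0.0), max(psill, 1e-12), max(rng, 1e-9))
        return wts * (model(lags) - gammas)

    try:
        sol = least_squares(
            resid,
            x0=[0.0, sill0, rng0],
            bounds=([0.0, 1e-12, 1e-9], [np.inf, np.inf, np.inf]),
        )
        if not sol.success:
            return fallback()
    except Exception:
        return fallback()
    nugget, psill, rng = sol.x
    model = VariogramModel(family, float(nugget), float(psill), float(rng))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return model, rms


def _dedupe(points: np.ndarray, values: np.ndarray):
    """Average values at duplicated locations (kriging matrix singularity)."""
    seen: dict[tuple[float, float], list[float]] = {}
    order: list[tuple[float, float]] = []
    for p, v in zip(points, values):
        key = (float(p[0]), float(p[1]))
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(float(v))
    pts = np.array(order)
    vals = np.array([np.mean(seen[k]) for k in order])
    return pts, vals


def kriging_weights(points, model: VariogramModel, nodes):
    """Ordinary-kriging weights and Lagrange multipliers for target nodes.

    Solves the (n+1)x(n+1) semivariance system with the unit-sum constraint
    once (LU factorisation) and back-substitutes for all nodes. Returns
    ``(weights, mu, gamma0)`` with shapes (n, m), (m,), (n, m); the weight
    columns each sum to one.
    """
    pts = np.asarray(points, dtype=float)
    nodes = np.asarray(nodes, dtype=float)
    n = len(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = model(d)
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    try:
        lu = sla.lu_factor(a)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular kriging matrix") from exc

    d0 = np.linalg.norm(nodes[:, None, :] - pts[None, :, :], axis=-1)
    b = np.empty((n + 1, len(nodes)))
    b[:n, :] = model(d0).T
    b[n, :] = 1.0
    sol = sla.lu_solve(lu, b)
    return sol[:n, :], sol[n, :], b[:n, :]


def ordinary_kriging(
    points, values, grid: RasterGrid, model: VariogramModel
) -> tuple[RasterGrid, RasterGrid]:
    """Global ordinary kriging onto the grid's cell centres.

    Returns the prediction grid and the kriging-variance grid. Duplicate
    well locations are averaged first (they make the system singular).
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for kriging")
    pts, z = _dedupe(pts, z)
    if len(pts) < 3:
        raise ValueError("fewer than 3 distinct well locations")

    gx, gy = grid.cell_centers()
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    weights, mu, gamma0 = kriging_weights(pts, model, nodes)

    pred = weights.T @ z
    var = np.einsum("ij,ij->j", weights, gamma0) + mu
    var = np.maximum(var, 0.0)

    return (
        grid.like(pred.reshape(grid.n_rows, grid.n_cols)),
        grid.like(var.reshape(grid.n_rows, grid.n_cols)),
    )


def idw(points, values, grid: RasterGrid, power: float = 2.0) -> RasterGrid:
    """Inverse-distance-power weighted interpolation onto the grid.

    Exact at well locations (zero distance short-circuits); predictions are
    convex combinations, hence bounded by the data range.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if len(pts) < 1:
        raise ValueError("need at least one point")
    gx, gy = grid.cell_centers()
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.linalg.norm(nodes[:, None, :] - pts[None, :, :], axis=-1)
    pred = np.empty(len(nodes))
    hit = d < 1e-12
    any_hit = hit.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[any_hit] = 0.0
    pred[~any_hit] = (w[~any_hit] * z).sum(axis=1) / w[~any_hit].sum(axis=1)
    for i in np.nonzero(any_hit)[0]:
        pred[i] = z[hit[i]].mean()
    return grid.like(pred.reshape(grid.n_rows, grid.n_cols))


def classify_raster(grid: RasterGrid, scale: RankScale) -> tuple[RasterGrid, int]:
    """Map every non-nodata cell through a rank scale.

    Negative cells (possible kriging undershoot) become nodata; their count
    is returned alongside the categorical grid.
    """
    out = np.full_like(grid.values, grid.nodata)
    negatives = 0
    it = np.nditer(grid.values, flags=["multi_index"])
    for v in it:
        val = float(v)
        if val == grid.nodata or math.isnan(val):
            continue
        if val < 0:
            negatives += 1
            continue
        out[it.multi_index] = scale.classify(val).rank
    return grid.like(out), negatives
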