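"""Kernel utilization distributions, contour areas, and Bhattacharyya overlap.

All computation happens on a planar grid in km (azimuthal-equidistant
projection centered on the colony).  The UD is an isotropic bivariate-normal
kernel density renormalized to integrate to 1 over its grid; 50%/95%
contours are the smallest sets of cells containing that probability mass.

Overlap between two UDs is the Bhattacharyya affinity
BA = sum_cells sqrt(UD1 * UD2) * cell_area, which is 0 for disjoint and 1
for identical distributions.  Significance is assessed against a null built
by shuffling whole individuals between groups (1,000 randomizations by
default): pp is the proportion of random overlaps smaller than the observed
one, with pp < 0.025 or pp > 0.975 flagging a real difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "UDGrid",
    "OverlapTestResult",
    "reference_bandwidth",
    "kde_ud",
    "ud_contour_area",
    "mask_ud",
    "ba_overlap",
    "overlap_randomization_test",
]

_MAX_CELLS = 4_000_000


@dataclass
class UDGrid:
    """Discretized utilization distribution on a regular planar grid (km)."""

    x: np.ndarray  # cell-center x coordinates (nx,)
    y: np.ndarray  # cell-center y coordinates (ny,)
    density: np.ndarray  # (ny, nx), km^-2, integrates to 1
    cell_size_km: float
    bandwidth_km: float
    n_points: int

    @property
    def cell_area(self) -> float:
        return self.cell_size_km**2

    @property
    def integral(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class OverlapTestResult:
    """Observed BA, its randomization null, and the pp-value."""

    observed_ba: float
    permuted_ba: np.ndarray
    level: float
    n_rand: int
    seed: int | None

    @property
    def pp(self) -> float:
        return float(np.mean(self.permuted_ba < self.observed_ba))

    @property
    def significant(self) -> bool:
        return self.pp < 0.025 or self.pp > 0.975

    def to_dict(self) -> dict:
        return {
            "observed": self.observed_ba,
            "pp": self.pp,
            "n_rand": self.n_rand,
            "level": self.level,
            "seed": self.seed,
            "significant": self.significant,
        }


def reference_bandwidth(points: np.ndarray) -> float:
    """The ad hoc (bivariate-normal reference) smoothing parameter.

    h = 0.5 * (sd_x + sd_y) * n^(-1/6), in km, the standard home-range
    default for a bivariate normal reference density.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("points must be an (n >= 2, 2) array")
    sd = pts.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("all points identical: bandwidth undefined")
    return float(0.5 * (sd[0] + sd[1]) * len(pts) ** (-1.0 / 6.0))


def _grid_axes(points, h, cell_size, margin_factor=3.0):
    lo = points.min(axis=0) - margin_factor * h
    hi = points.max(axis=0) + margin_factor * h
    nx = int(np.ceil((hi[0] - lo[0]) / cell_size)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / cell_size)) + 1
    if nx * ny > _MAX_CELLS:
        raise MemoryError(
            f"grid of {nx} x {ny} cells exceeds the cap; increase cell_size"
        )
    x = lo[0] + cell_size * np.arange(nx)
    y = lo[1] + cell_size * np.arange(ny)
    return x, y


def kde_ud(
    points: np.ndarray,
    h: float | None = None,
    cell_size: float | None = None,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> UDGrid:
    """Isotropic Gaussian kernel UD of ``points`` (n, 2) km.

    ``h`` defaults to the reference bandwidth; ``cell_size`` to h/4 and may
    not exceed h/2 (grid must resolve the kernel).  ``grid`` pins the
    evaluation axes (used to place two UDs on a common grid).  The density
    is renormalized to integrate to exactly 1 over the grid.
    """
    pts = np.asarray(points, dtype=float)
    if h is None:
        h = reference_bandwidth(pts)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    if cell_size is None:
        cell_size = h / 4.0
    if cell_size > h / 2.0 + 1e-12:
        raise ValueError("cell_size must be <= h/2 to resolve the kernel")
    if grid is None:
        x, y = _grid_axes(pts, h, cell_size)
    else:
        x, y = grid
    # vectorized kernel sum over points, chunked over points to bound memory
    gx = x[None, :]  # (1, nx)
    gy = y[:, None]  # (ny, 1)
    dens = np.zeros((len(y), len(x)))
    norm = 1.0 / (2.0 * np.pi * h * h)
    for start in range(0, len(pts), 256):
        chunk = pts[start : start + 256]
        ex = np.exp(-((gx - chunk[:, 0, None, None]) ** 2) / (2 * h * h))  # (k, 1, nx)
        ey = np.exp(-((gy - chunk[:, 1, None, None]) ** 2) / (2 * h * h))  # (k, ny, 1)
        dens += norm * np.einsum("kij,kjl->il", ey, ex, optimize=True) / len(pts)
    total = dens.sum() * cell_size**2
    if total <= 0:
        raise ValueError("density integrates to zero on the grid")
    dens /= total
    return UDGrid(x=x, y=y, density=dens, cell_size_km=float(cell_size), bandwidth_km=float(h), n_points=len(pts))


def _level_mask(ud: UDGrid, level: float) -> np.ndarray:
    """Smallest set of cells (by descending density) holding >= level mass."""
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    mass = np.cumsum(flat[order]) * ud.cell_area
    k = int(np.searchsorted(mass, level)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.density.shape)


def ud_contour_area(ud: UDGrid, level: float, clip=None) -> tuple[float, np.ndarray]:
    """Area (km^2) of the ``level`` utilization contour, with its cell mask.

    ``clip``, if given, is a shapely polygon (in grid km coordinates) of
    ground to exclude (e.g. land beyond the coastline); cells whose centers
    fall inside it are removed before the area is reported.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    mask = _level_mask(ud, level)
    if clip is not None:
        import shapely

        xx, yy = np.meshgrid(ud.x, ud.y)
        on_land = shapely.contains_xy(clip, xx.ravel(), yy.ravel()).reshape(mask.shape)
        mask = mask & ~on_land
    return float(mask.sum() * ud.cell_area), mask


def mask_ud(ud: UDGrid, level: float) -> UDGrid:
    """Restrict a UD to its ``level`` contour and renormalize."""
    _, mask = ud_contour_area(ud, level)
    dens = np.where(mask, ud.density, 0.0)
    dens /= dens.sum() * ud.cell_area
    return UDGrid(ud.x, ud.y, dens, ud.cell_size_km, ud.bandwidth_km, ud.n_points)


def _resample(ud: UDGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Interpolate a normalized density onto new axes (no renormalization:
    the axes may cover only part of the UD's support)."""
    interp = RegularGridInterpolator((ud.y, ud.x), ud.density, bounds_error=False, fill_value=0.0)
    xx, yy = np.meshgrid(x, y)
    return interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(len(y), len(x))


def ba_overlap(ud1: UDGrid, ud2: UDGrid) -> float:
    """Bhattacharyya affinity between two UDs, in [0, 1].

    UDs on mismatched grids are resampled onto the union extent at the
    finer cell size and renormalized first.
    """
    same = (
        len(ud1.x) == len(ud2.x)
        and len(ud1.y) == len(ud2.y)
        and np.allclose(ud1.x, ud2.x)
        and np.allclose(ud1.y, ud2.y)
    )
    if same:
        ba = float(np.sum(np.sqrt(ud1.density * ud2.density)) * ud1.cell_area)
        return min(1.0, ba)
    # the integrand vanishes wherever either density is zero, so only the
    # intersection of the two extents matters
    cell = min(ud1.cell_size_km, ud2.cell_size_km)
    lo_x = max(ud1.x[0], ud2.x[0])
    hi_x = min(ud1.x[-1], ud2.x[-1])
    lo_y = max(ud1.y[0], ud2.y[0])
    hi_y = min(ud1.y[-1], ud2.y[-1])
    if lo_x > hi_x or lo_y > hi_y:
        return 0.0
    x = np.arange(lo_x, hi_x + cell, cell)
    y = np.arange(lo_y, hi_y + cell, cell)
    if len(x) * len(y) > _MAX_CELLS:
        raise MemoryError("unified grid exceeds the cell cap; increase cell_size")
    d1 = _resample(ud1, x, y)
    d2 = _resample(ud2, x, y)
    return min(1.0, float(np.sum(np.sqrt(d1 * d2)) * cell**2))


def _group_ud(points_list, grid, cell_size):
    pts = np.vstack(points_list)
    h = reference_bandwidth(pts)
    cs = min(cell_size, h / 2.0) if cell_size is not None else h / 4.0
    return kde_ud(pts, h=h, cell_size=cs, grid=grid)


def overlap_randomization_test(
    points_by_individual: dict,
    group_assignment: dict,
    level: float = 0.95,
    n_rand: int = 1000,
    cell_size: float | None = None,
    seed: int | None = None,
) -> OverlapTestResult:
    """Individual-randomization null for UD overlap between two groups.

    ``points_by_individual`` maps individual id -> (n, 2) km coordinates of
    its intensive-foraging locations; ``group_assignment`` maps each id to
    one of exactly two group labels.  Each randomization shuffles whole
    individuals between the groups (sizes preserved), recomputes each
    pseudo-group's bandwidth and level-masked UD, and the BA.  Degenerate
    pseudo-groups (all points identical) are redrawn, capped at
    10 * n_rand attempts.
    """
    ids = list(points_by_individual)
    groups = sorted({group_assignment[i] for i in ids})
    if len(groups) != 2:
        raise ValueError("group_assignment must define exactly two groups")
    g1 = [i for i in ids if group_assignment[i] == groups[0]]
    g2 = [i for i in ids if group_assignment[i] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 individuals per group")

    all_pts = np.vstack([points_by_individual[i] for i in ids])
    h_all = reference_bandwidth(all_pts)
    cs = cell_size if cell_size is not None else h_all / 4.0
    grid = _grid_axes(all_pts, h_all, cs)

    def masked_ba(ids_a, ids_b):
        ud_a = _group_ud([points_by_individual[i] for i in ids_a], grid, cs)
        ud_b = _group_ud([points_by_individual[i] for i in ids_b], grid, cs)
        return ba_overlap(mask_ud(ud_a, level), mask_ud(ud_b, level))

    observed = masked_ba(g1, g2)
    rng = np.random.default_rng(seed)
    permuted = []
    attempts = 0
    while len(permuted) < n_rand:
        if attempts >= 10 * n_rand:
            raise RuntimeError("too many degenerate randomizations")
        attempts += 1
        perm = rng.permutation(ids)
        pa, pb = list(perm[: len(g1)]), list(perm[len(g1) :])
        try:
            permuted.append(masked_ba(pa, pb))
        except ValueError:
            continue  # degenerate pseudo-group: redraw
    return OverlapTestResult(
        observed_ba=observed,
        permuted_ba=np.asarray(permuted),
        level=level,
        n_rand=n_rand,
        seed=seed,
    )
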