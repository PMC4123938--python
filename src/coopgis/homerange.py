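"""Kernel utilization distributions, home ranges and overlap.

A utilization distribution (UD) is the probability density of an animal's
location over the room.  It is estimated by a bivariate Gaussian kernel
density with a plug-in bandwidth computed along rotated axes: the points
are rotated to their principal axes, a two-stage univariate direct plug-in
selector (Gaussian kernels, normal-reference start for the highest-order
density functional) is applied on each rotated axis, and the resulting
diagonal bandwidth matrix is rotated back, giving a full symmetric
positive-definite H in m^2.

The home range at isopleth level p is the smallest set of grid cells
holding at least a fraction p of the UD mass; its area is the cell count
times the cell area, and the three overlap summaries (proportion of room,
proportion of the range overlapped by any conspecific, and pairwise
overlap area) are plain polygon-area computations on these isopleth
regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermeval
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .room import RoomGeometry

SQRT2PI = math.sqrt(2.0 * math.pi)


class DegenerateDataError(ValueError):
    """All points coincident (or otherwise rank-deficient for bandwidths)."""


@dataclass(frozen=True)
class BandwidthMatrix:
    """Symmetric positive-definite 2x2 kernel bandwidth matrix, m^2."""

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, float)
        if h.shape != (2, 2) or abs(h[0, 1] - h[1, 0]) > 1e-9:
            raise ValueError("H must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(h).min() <= 0:
            raise ValueError("H must be positive definite")
        object.__setattr__(self, "h", h)


@dataclass
class UDGrid:
    """Discretized utilization density over the room.

    ``density[iy, ix]`` is the probability density (1/m^2) at the center of
    cell (ix, iy); after room truncation the densities integrate to 1.
    """

    origin: tuple[float, float]
    cell_size: float
    density: np.ndarray  # shape (ny, nx)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.density.shape
        xs = self.origin[0] + self.cell_size * (np.arange(nx) + 0.5)
        ys = self.origin[1] + self.cell_size * (np.arange(ny) + 0.5)
        return xs, ys


@dataclass
class HomeRange:
    """Isopleth home range: smallest region holding fraction p of UD mass."""

    p: float
    region: BaseGeometry
    area: float  # m^2, cell count x cell area

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("isopleth level p must be in (0, 1)")


def _phi_deriv_sum(x: np.ndarray, g: float, r: int, max_pairs: float = 4e7) -> float:
    """Density functional psi_r = n^-2 sum_ij phi_g^{(r)}(x_i - x_j).

    Uses phi^{(r)}(u) = He_r(u) phi(u) (-1)^r / g^{r+1} with the
    probabilists' Hermite polynomial He_r; pairwise sums are chunked to
    bound memory.
    """
    n = len(x)
    coeffs = np.zeros(r + 1)
    coeffs[r] = 1.0
    chunk = max(1, int(max_pairs // n))
    total = 0.0
    for i0 in range(0, n, chunk):
        d = (x[i0 : i0 + chunk, None] - x[None, :]) / g
        total += float(np.sum(hermeval(d, coeffs) * np.exp(-0.5 * d * d)))
    sign = -1.0 if r % 2 else 1.0
    return sign * total / (n * n * g ** (r + 1) * SQRT2PI)


def _dpi_bandwidth_1d(x: np.ndarray) -> float:
    """Two-stage direct plug-in bandwidth for a univariate Gaussian KDE.

    Stage 0 estimates psi_8 by the normal reference, stage 1 estimates
    psi_6 and psi_4 with kernel functionals at their optimal pilot
    bandwidths, and the final bandwidth is the AMISE minimizer
    h = (R(K) / (mu_2^2 psi_4 n))^{1/5} with R(K) = 1/(2 sqrt(pi)),
    mu_2 = 1 for the Gaussian kernel.
    """
    n = len(x)
    sd = float(np.std(x, ddof=1))
    if sd <= 0:
        raise DegenerateDataError("axis has zero variance")
    # normal-reference psi_8 = 105 / (32 sqrt(pi) sd^9)
    psi8 = 105.0 / (32.0 * math.sqrt(math.pi) * sd**9)
    # phi^{(6)}(0) = -15/sqrt(2 pi); pilot g1 for psi_6
    k6_0 = -15.0 / SQRT2PI
    g1 = (-2.0 * k6_0 / (psi8 * n)) ** (1.0 / 9.0)
    psi6 = _phi_deriv_sum(x, g1, 6)
    if psi6 >= 0:  # psi_6 must be negative; fall back to normal reference
        psi6 = -15.0 / (16.0 * math.sqrt(math.pi) * sd**7)
    # phi^{(4)}(0) = 3/sqrt(2 pi); pilot g2 for psi_4
    k4_0 = 3.0 / SQRT2PI
    g2 = (2.0 * k4_0 / (-psi6 * n)) ** (1.0 / 7.0)
    psi4 = _phi_deriv_sum(x, g2, 4)
    if psi4 <= 0:  # psi_4 must be positive
        psi4 = 3.0 / (8.0 * math.sqrt(math.pi) * sd**5)
    rk = 1.0 / (2.0 * math.sqrt(math.pi))
    return (rk / (psi4 * n)) ** 0.2


def plugin_bandwidth(points: np.ndarray, max_points: int = 4000) -> BandwidthMatrix:
    """Bivariate plug-in bandwidth matrix computed along rotated axes.

    Points are rotated to the principal axes of their covariance, the
    two-stage univariate plug-in selector is run on each rotated axis, and
    the diagonal bandwidth matrix diag(h1^2, h2^2) is rotated back.  For
    more than ``max_points`` points the pairwise density functionals are
    evaluated on an evenly strided subsample.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 10:
        raise ValueError("need at least 10 points")
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    if np.linalg.eigvalsh(cov).min() <= 1e-12:
        raise DegenerateDataError("points are (near-)coincident or collinear")
    evals, evecs = np.linalg.eigh(cov)
    rot = centered @ evecs  # principal-axis coordinates
    if n > max_points:
        stride = int(math.ceil(n / max_points))
        rot_bw = rot[::stride]
    else:
        rot_bw = rot
    h1 = _dpi_bandwidth_1d(rot_bw[:, 0])
    h2 = _dpi_bandwidth_1d(rot_bw[:, 1])
    h_diag = np.diag([h1**2, h2**2])
    h = evecs @ h_diag @ evecs.T
    return BandwidthMatrix((h + h.T) / 2.0)


def kde_ud(
    points: np.ndarray,
    bandwidth: BandwidthMatrix,
    room: RoomGeometry,
    cell_size: float = 0.05,
) -> UDGrid:
    """Gaussian-kernel UD on a regular grid, truncated to the room.

    The kernel density is evaluated at cell centers across the room
    rectangle and renormalized so the truncated density integrates to 1.
    """
    if cell_size >= min(room.width, room.depth):
        raise ValueError("cell_size must be smaller than the room")
    pts = np.asarray(points, float)
    nx = int(round(room.width / cell_size))
    ny = int(round(room.depth / cell_size))
    xs = cell_size * (np.arange(nx) + 0.5)
    ys = cell_size * (np.arange(ny) + 0.5)
    hdet = np.linalg.det(bandwidth.h)
    norm = 1.0 / (2.0 * math.pi * math.sqrt(hdet))
    # whiten the points once; evaluate chunked over grid rows
    chol = np.linalg.cholesky(bandwidth.h)
    white_pts = np.linalg.solve(chol, pts.T).T  # (n, 2)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    white_grid = np.linalg.solve(chol, grid.T).T
    density = np.empty(len(grid))
    chunk = max(1, int(2e7 // max(len(pts), 1)))
    for i0 in range(0, len(grid), chunk):
        d0 = white_grid[i0 : i0 + chunk, 0][:, None] - white_pts[None, :, 0]
        d1 = white_grid[i0 : i0 + chunk, 1][:, None] - white_pts[None, :, 1]
        density[i0 : i0 + chunk] = np.exp(-0.5 * (d0 * d0 + d1 * d1)).sum(axis=1)
    density *= norm / len(pts)
    density = density.reshape(ny, nx)
    mass = density.sum() * cell_size**2
    if mass <= 0:
        raise ValueError("all kernel mass falls outside the room")
    density /= mass
    return UDGrid(origin=(0.0, 0.0), cell_size=cell_size, density=density)


def isopleth_homerange(ud: UDGrid, p: float = 0.95) -> HomeRange:
    """Smallest-cell-set home range at isopleth level p.

    Cells are ranked by density (ties broken in row-major order) and
    accumulated until their mass reaches p; the region polygon is the
    union of the selected cell squares.
    """
    if not 0 < p < 1:
        raise ValueError("isopleth level p must be in (0, 1)")
    ny, nx = ud.density.shape
    flat = ud.density.ravel()  # row-major: stable sort preserves tie order
    order = np.argsort(-flat, kind="stable")
    masses = flat[order] * ud.cell_area
    csum = np.cumsum(masses)
    target = min(p, float(csum[-1]))
    k = int(np.searchsorted(csum, target - 1e-12)) + 1
    chosen = order[:k]
    chosen = chosen[flat[chosen] > 0]
    cs = ud.cell_size
    ox, oy = ud.origin
    mask = np.zeros(ny * nx, bool)
    mask[chosen] = True
    mask = mask.reshape(ny, nx)
    boxes = []
    for iy in range(ny):  # merge runs of cells per row to keep the union small
        row = mask[iy]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
        for x0, x1 in zip(edges[::2], edges[1::2]):
            boxes.append(
                box(ox + x0 * cs, oy + iy * cs, ox + x1 * cs, oy + (iy + 1) * cs)
            )
    region = unary_union(boxes)
    return HomeRange(p=p, region=region, area=len(chosen) * ud.cell_area)


def proportion_of_room(hr: HomeRange, room: RoomGeometry) -> float:
    """Fraction of the room's floor area covered by the home range."""
    return hr.area / room.area


def overlap_with_conspecifics(hr: HomeRange, others: Sequence[HomeRange]) -> float:
    """Fraction of this range overlapped by the union of the others' ranges."""
    if hr.region.area <= 0:
        raise ValueError("home range has zero area; overlap undefined")
    if not others:
        return 0.0
    union = unary_union([o.region for o in others])
    return hr.region.intersection(union).area / hr.region.area


def pairwise_overlap(hr_i: HomeRange, hr_j: HomeRange) -> float:
    """Area (m^2) of the intersection of two home ranges; symmetric."""
    return hr_i.region.intersection(hr_j.region).area
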