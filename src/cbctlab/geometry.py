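"""Discrete X-ray transforms: ray geometries and sparse system matrices.

The forward operator maps an image (vectorized attenuation grid) to a
sinogram through exact pixel-intersection lengths computed with Siddon
ray tracing.  The adjoint is the sparse transpose, so the pair passes an
inner-product test to solver precision.

Coordinate conventions
----------------------
The image is centred at the origin.  For ``labels[i, j]`` (row ``i``
counted from the top), the physical centre is ``x = (j - (nc-1)/2) *
px`` and ``y = ((nr-1)/2 - i) * px``; rows at the top have the largest
``y``.  A parallel ray at view angle ``phi`` travels along
``(-sin(phi), cos(phi))`` and is indexed by the signed detector
coordinate ``s = x cos(phi) + y sin(phi)``.  Hence ``phi = 0`` rays run
up the columns (column sums) and ``phi = pi/2`` rays give row sums, the
layout of the 3x3 worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from numba import njit
from scipy import sparse

__all__ = [
    "ProjectionGeometry",
    "SystemMatrix",
    "SubsamplingSpec",
    "build_system_matrix",
    "forward_project",
    "back_project",
    "apply_subsampling",
    "parallel_geometry",
    "fan_geometry",
    "cone_geometry",
    "toy_geometry",
    "TOY_RAY_LABELS",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Acquisition geometry for one of the supported ray layouts.

    ``kind`` is one of ``parallel2d``, ``fan2d``, ``cone3d``,
    ``toy3x3``.  ``source_radius`` / ``detector_radius`` are the
    source-to-isocentre and isocentre-to-detector distances (fan/cone
    only).  ``det_offset`` shifts the detector laterally (offset-detector
    acquisitions); ``truncation`` records a kept detector-index window
    applied by :func:`apply_subsampling`.
    """

    kind: str
    n_views: int
    n_det_u: int
    det_spacing: float = 1.0
    angular_range: float = np.pi
    source_radius: float = 0.0
    detector_radius: float = 0.0
    n_det_v: int = 1
    det_spacing_v: Optional[float] = None
    det_offset: float = 0.0
    truncation: Optional[Tuple[int, int]] = None
    explicit_angles: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.det_spacing <= 0:
            raise ValueError("det_spacing must be positive")
        if self.kind not in ("parallel2d", "fan2d", "cone3d", "toy3x3"):
            raise ValueError(f"unsupported geometry kind {self.kind!r}")

    @property
    def angles(self) -> np.ndarray:
        if self.explicit_angles is not None:
            return np.asarray(self.explicit_angles, dtype=float)
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    @property
    def is_3d(self) -> bool:
        return self.kind == "cone3d"

    @property
    def sinogram_shape(self) -> tuple:
        if self.is_3d:
            return (self.n_views, self.n_det_u, self.n_det_v)
        return (self.n_views, self.n_det_u)

    @property
    def n_rays(self) -> int:
        return int(np.prod(self.sinogram_shape))

    def det_coords_u(self) -> np.ndarray:
        """Signed detector-u coordinates of the cell centres."""
        k = np.arange(self.n_det_u)
        return (k - (self.n_det_u - 1) / 2.0) * self.det_spacing + self.det_offset

    def det_coords_v(self) -> np.ndarray:
        sp = self.det_spacing_v if self.det_spacing_v is not None else self.det_spacing
        k = np.arange(self.n_det_v)
        return (k - (self.n_det_v - 1) / 2.0) * sp


def parallel_geometry(n_views, n_det, det_spacing=1.0, angular_range=np.pi,
                      det_offset=0.0) -> ProjectionGeometry:
    return ProjectionGeometry("parallel2d", n_views, n_det, det_spacing,
                              angular_range, det_offset=det_offset)


def fan_geometry(n_views, n_det, det_spacing, source_radius, detector_radius,
                 angular_range=2 * np.pi, det_offset=0.0) -> ProjectionGeometry:
    return ProjectionGeometry("fan2d", n_views, n_det, det_spacing,
                              angular_range, source_radius, detector_radius,
                              det_offset=det_offset)


def cone_geometry(n_views, n_det_u, n_det_v, det_spacing, source_radius,
                  detector_radius, angular_range=2 * np.pi,
                  det_offset=0.0, det_spacing_v=None) -> ProjectionGeometry:
    return ProjectionGeometry("cone3d", n_views, n_det_u, det_spacing,
                              angular_range, source_radius, detector_radius,
                              n_det_v=n_det_v, det_spacing_v=det_spacing_v,
                              det_offset=det_offset)


def toy_geometry() -> ProjectionGeometry:
    return ProjectionGeometry("toy3x3", 3, 3, 1.0, np.pi * 3 / 4)


#: (phi, s) labels of the nine toy rays, in printed order.
TOY_RAY_LABELS = [(phi, s) for phi in (0.0, np.pi / 4, np.pi / 2) for s in (1, 2, 3)]

# 9x9 binary incidence matrix of the worked example; row r, pixel (i,j)
# flattened row-major.  Diagonal rays use unit weights because the
# printed system sums pixel values with unit coefficients.
_TOY_ROWS = [
    [(0, 0), (1, 0), (2, 0)],  # (0, 1): column 1
    [(0, 1), (1, 1), (2, 1)],  # (0, 2)
    [(0, 2), (1, 2), (2, 2)],  # (0, 3)
    [(1, 0), (2, 1)],          # (pi/4, 1)
    [(0, 0), (1, 1), (2, 2)],  # (pi/4, 2)
    [(0, 1), (1, 2)],          # (pi/4, 3)
    [(2, 0), (2, 1), (2, 2)],  # (pi/2, 1): bottom row
    [(1, 0), (1, 1), (1, 2)],  # (pi/2, 2): middle row
    [(0, 0), (0, 1), (0, 2)],  # (pi/2, 3): top row
]


def _toy_matrix() -> np.ndarray:
    A = np.zeros((9, 9))
    for r, pixels in enumerate(_TOY_ROWS):
        for (i, j) in pixels:
            A[r, i * 3 + j] = 1.0
    return A


@dataclass(frozen=True)
class SystemMatrix:
    """Sparse discrete X-ray transform for a fixed geometry and grid."""

    matrix: sparse.csr_matrix
    geometry: ProjectionGeometry
    grid_shape: tuple
    pixel_size: float

    @property
    def n_rays(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]


@njit(cache=True)
def _siddon2d(x0, y0, x1, y1, nx, ny, px, rows, cols, vals):  # pragma: no cover
    """Exact pixel-intersection lengths for a batch of 2D rays.

    The grid spans [-nx*px/2, nx*px/2] x [-ny*px/2, ny*px/2]; pixel
    (ix, iy) has iy counted upward from the bottom edge.  Emits triples
    into the preallocated output arrays and returns the count.
    """
    ox = -nx * px / 2.0
    oy = -ny * px / 2.0
    n_out = 0
    eps = 1e-12
    for r in range(x0.size):
        dx = x1[r] - x0[r]
        dy = y1[r] - y0[r]
        length = np.sqrt(dx * dx + dy * dy)
        if length < eps:
            continue
        amin = 0.0
        amax = 1.0
        if abs(dx) > eps:
            a0 = (ox - x0[r]) / dx
            a1 = (ox + nx * px - x0[r]) / dx
            amin = max(amin, min(a0, a1))
            amax = min(amax, max(a0, a1))
        elif x0[r] <= ox or x0[r] >= ox + nx * px:
            continue
        if abs(dy) > eps:
            a0 = (oy - y0[r]) / dy
            a1 = (oy + ny * px - y0[r]) / dy
            amin = max(amin, min(a0, a1))
            amax = min(amax, max(a0, a1))
        elif y0[r] <= oy or y0[r] >= oy + ny * px:
            continue
        if amax - amin < eps:
            continue
        # collect plane crossings inside (amin, amax)
        n_alpha = 2
        if abs(dx) > eps:
            n_alpha += nx + 1
        if abs(dy) > eps:
            n_alpha += ny + 1
        alphas = np.empty(n_alpha, dtype=np.float64)
        alphas[0] = amin
        alphas[1] = amax
        m = 2
        if abs(dx) > eps:
            for i in range(nx + 1):
                a = (ox + i * px - x0[r]) / dx
                if amin < a < amax:
                    alphas[m] = a
                    m += 1
        if abs(dy) > eps:
            for i in range(ny + 1):
                a = (oy + i * px - y0[r]) / dy
                if amin < a < amax:
                    alphas[m] = a
                    m += 1
        al = np.sort(alphas[:m])
        for k in range(m - 1):
            seg = (al[k + 1] - al[k]) * length
            if seg <= eps:
                continue
            amid = 0.5 * (al[k] + al[k + 1])
            xm = x0[r] + amid * dx
            ym = y0[r] + amid * dy
            ix = int(np.floor((xm - ox) / px))
            iy = int(np.floor((ym - oy) / px))
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
                continue
            # flat index in row-major labels with row 0 at the top
            rows[n_out] = r
            cols[n_out] = (ny - 1 - iy) * nx + ix
            vals[n_out] = seg
            n_out += 1
    return n_out


@njit(cache=True)
def _siddon3d(x0, y0, z0, x1, y1, z1, nx, ny, nz, px, rows, cols, vals):  # pragma: no cover
    """3D analogue of :func:`_siddon2d` (isotropic voxels)."""
    ox = -nx * px / 2.0
    oy = -ny * px / 2.0
    oz = -nz * px / 2.0
    n_out = 0
    eps = 1e-12
    for r in range(x0.size):
        dx = x1[r] - x0[r]
        dy = y1[r] - y0[r]
        dz = z1[r] - z0[r]
        length = np.sqrt(dx * dx + dy * dy + dz * dz)
        if length < eps:
            continue
        amin = 0.0
        amax = 1.0
        ok = True
        for (d, o, nn, c0) in ((dx, ox, nx, x0[r]), (dy, oy, ny, y0[r]), (dz, oz, nz, z0[r])):
            if abs(d) > eps:
                a0 = (o - c0) / d
                a1 = (o + nn * px - c0) / d
                amin = max(amin, min(a0, a1))
                amax = min(amax, max(a0, a1))
            elif c0 <= o or c0 >= o + nn * px:
                ok = False
        if not ok or amax - amin < eps:
            continue
        n_alpha = 2 + (nx + 1) + (ny + 1) + (nz + 1)
        alphas = np.empty(n_alpha, dtype=np.float64)
        alphas[0] = amin
        alphas[1] = amax
        m = 2
        for (d, o, nn, c0) in ((dx, ox, nx, x0[r]), (dy, oy, ny, y0[r]), (dz, oz, nz, z0[r])):
            if abs(d) > eps:
                for i in range(nn + 1):
                    a = (o + i * px - c0) / d
                    if amin < a < amax:
                        alphas[m] = a
                        m += 1
        al = np.sort(alphas[:m])
        for k in range(m - 1):
            seg = (al[k + 1] - al[k]) * length
            if seg <= eps:
                continue
            amid = 0.5 * (al[k] + al[k + 1])
            xm = x0[r] + amid * dx
            ym = y0[r] + amid * dy
            zm = z0[r] + amid * dz
            ix = int(np.floor((xm - ox) / px))
            iy = int(np.floor((ym - oy) / px))
            iz = int(np.floor((zm - oz) / px))
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                continue
            rows[n_out] = r
            cols[n_out] = ((ny - 1 - iy) * nx + ix) * nz + iz
            vals[n_out] = seg
            n_out += 1
    return n_out


def ray_endpoints(geometry: ProjectionGeometry, grid_shape, pixel_size: float):
    """Physical start/end points of every ray, in sinogram C-order.

    Returns ``(starts, ends)`` with shape ``(n_rays, ndim)``.  Parallel
    rays are clipped to a circle safely containing the grid; divergent
    rays run from the source to the detector cell centre.
    """
    angles = geometry.angles
    u = geometry.det_coords_u()
    if geometry.kind == "parallel2d":
        half_diag = 0.51 * pixel_size * float(np.hypot(*grid_shape)) + 1.0
        phi = np.repeat(angles, u.size)
        s = np.tile(u, angles.size)
        ex, ey = np.cos(phi), np.sin(phi)       # detector axis
        dxr, dyr = -np.sin(phi), np.cos(phi)    # ray direction
        starts = np.stack([s * ex - half_diag * dxr, s * ey - half_diag * dyr], axis=1)
        ends = np.stack([s * ex + half_diag * dxr, s * ey + half_diag * dyr], axis=1)
        return starts, ends
    if geometry.kind == "fan2d":
        phi = np.repeat(angles, u.size)
        uu = np.tile(u, angles.size)
        sx = geometry.source_radius * np.sin(phi)
        sy = -geometry.source_radius * np.cos(phi)
        dxc = -geometry.detector_radius * np.sin(phi) + uu * np.cos(phi)
        dyc = geometry.detector_radius * np.cos(phi) + uu * np.sin(phi)
        return np.stack([sx, sy], axis=1), np.stack([dxc, dyc], axis=1)
    if geometry.kind == "cone3d":
        v = geometry.det_coords_v()
        phi = np.repeat(angles, u.size * v.size)
        uu = np.tile(np.repeat(u, v.size), angles.size)
        vv = np.tile(v, angles.size * u.size)
        sx = geometry.source_radius * np.sin(phi)
        sy = -geometry.source_radius * np.cos(phi)
        sz = np.zeros_like(phi)
        dxc = -geometry.detector_radius * np.sin(phi) + uu * np.cos(phi)
        dyc = geometry.detector_radius * np.cos(phi) + uu * np.sin(phi)
        dzc = vv
        return (np.stack([sx, sy, sz], axis=1), np.stack([dxc, dyc, dzc], axis=1))
    raise ValueError(f"no ray endpoints for kind {geometry.kind!r}")


def build_system_matrix(geometry: ProjectionGeometry, grid_shape, pixel_size=1.0) -> SystemMatrix:
    """Siddon-traced sparse system matrix for ``geometry`` on a grid.

    For ``kind='toy3x3'`` the 9x9 binary incidence matrix of the worked
    example is returned instead (its diagonal rays carry unit weights).
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if any(s <= 0 for s in grid_shape):
        raise ValueError("grid dimensions must be positive")
    if geometry.kind == "toy3x3":
        if grid_shape != (3, 3):
            raise ValueError("toy3x3 geometry requires a 3x3 grid")
        A = sparse.csr_matrix(_toy_matrix())
        return SystemMatrix(A, geometry, grid_shape, pixel_size)
    starts, ends = ray_endpoints(geometry, grid_shape, pixel_size)
    n_rays = starts.shape[0]
    if geometry.is_3d:
        nr, nc, ns = grid_shape
        cap = n_rays * (nr + nc + ns + 4)
        rows = np.empty(cap, dtype=np.int64)
        cols = np.empty(cap, dtype=np.int64)
        vals = np.empty(cap, dtype=np.float64)
        n = _siddon3d(
            np.ascontiguousarray(starts[:, 0]), np.ascontiguousarray(starts[:, 1]),
            np.ascontiguousarray(starts[:, 2]), np.ascontiguousarray(ends[:, 0]),
            np.ascontiguousarray(ends[:, 1]), np.ascontiguousarray(ends[:, 2]),
            nc, nr, ns, float(pixel_size), rows, cols, vals,
        )
    else:
        nr, nc = grid_shape
        cap = n_rays * (nr + nc + 3)
        rows = np.empty(cap, dtype=np.int64)
        cols = np.empty(cap, dtype=np.int64)
        vals = np.empty(cap, dtype=np.float64)
        n = _siddon2d(
            np.ascontiguousarray(starts[:, 0]), np.ascontiguousarray(starts[:, 1]),
            np.ascontiguousarray(ends[:, 0]), np.ascontiguousarray(ends[:, 1]),
            nc, nr, float(pixel_size), rows, cols, vals,
        )
    A = sparse.csr_matrix(
        (vals[:n], (rows[:n], cols[:n])), shape=(n_rays, int(np.prod(grid_shape)))
    )
    return SystemMatrix(A, geometry, grid_shape, pixel_size)


def forward_project(matrix: SystemMatrix, image: np.ndarray) -> np.ndarray:
    """Apply the discrete X-ray transform; returns the sinogram array."""
    img = np.asarray(image, dtype=float)
    if img.size != matrix.n_pixels:
        raise ValueError(f"image size {img.size} != n_pixels {matrix.n_pixels}")
    p = matrix.matrix @ img.ravel()
    return p.reshape(matrix.geometry.sinogram_shape)


def back_project(matrix: SystemMatrix, ray_values: np.ndarray) -> np.ndarray:
    """Exact adjoint (sparse transpose) of :func:`forward_project`."""
    p = np.asarray(ray_values, dtype=float)
    if p.size != matrix.n_rays:
        raise ValueError(f"ray vector size {p.size} != n_rays {matrix.n_rays}")
    img = matrix.matrix.T @ p.ravel()
    return img.reshape(matrix.grid_shape)


@dataclass(frozen=True)
class SubsamplingSpec:
    """View/detector selection realising the degradation operator S.

    ``view_step`` keeps every k-th view; ``view_indices`` an explicit
    subset; ``det_range`` a kept half-open detector-u index window
    (FOV truncation / offset detector).
    """

    view_step: int = 1
    view_indices: Optional[np.ndarray] = None
    det_range: Optional[Tuple[int, int]] = None


def apply_subsampling(sinogram, spec: SubsamplingSpec):
    """Restrict a sinogram to a view subset and detector window.

    Returns a new sinogram whose geometry metadata (explicit angles,
    detector count and offset, truncation record) describes exactly the
    kept rays, so downstream matrices and reconstructions agree.
    """
    geom = sinogram.geometry
    values = sinogram.values
    angles = geom.angles
    if spec.view_indices is not None:
        vidx = np.asarray(spec.view_indices, dtype=int)
    else:
        vidx = np.arange(geom.n_views)[:: spec.view_step]
    if vidx.size == 0:
        raise ValueError("empty view selection")
    values = values[vidx]
    angles = angles[vidx]
    n_det = geom.n_det_u
    det_offset = geom.det_offset
    trunc = geom.truncation
    if spec.det_range is not None:
        lo, hi = spec.det_range
        if not (0 <= lo < hi <= geom.n_det_u):
            raise ValueError("det_range outside detector")
        values = values[:, lo:hi]
        new_n = hi - lo
        det_offset = det_offset + (lo + (new_n - 1) / 2.0 - (geom.n_det_u - 1) / 2.0) * geom.det_spacing
        n_det = new_n
        trunc = (lo, hi)
    new_geom = replace(
        geom,
        n_views=vidx.size,
        n_det_u=n_det,
        det_offset=det_offset,
        truncation=trunc,
        explicit_angles=angles,
    )
    return sinogram.__class__(values=np.ascontiguousarray(values), geometry=new_geom,
                              provenance=sinogram.provenance + " | subsampled")
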