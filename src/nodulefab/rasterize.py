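"""Voxelization of watertight triangle meshes by vertical ray parity.

For every (x, y) sample column, all triangle crossings along z are counted;
a sample point is inside the mesh when an odd number of crossings lies below
it.  This is exact for points in general position with respect to the
surface; sample columns are therefore nudged by a tiny irrational offset so
that rays through vertices or edges (common for marching-cubes and lattice
meshes whose vertices sit on grid planes) have measure zero in practice.

This module is deliberately independent of :mod:`nodulefab.boxset` — the two
provide mutually checking routes to voxel occupancy.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .errors import ValidationError

__all__ = ["point_occupancy", "binary_occupancy", "occupancy_fractions"]

# deterministic sub-sample-spacing nudge applied to ray columns
_JITTER = (np.sqrt(2.0) - 1.0) * 1e-4


def point_occupancy(mesh: trimesh.Trimesh, x, y, z) -> np.ndarray:
    """Inside/outside flags on the grid of points ``x × y × z``.

    Parameters
    ----------
    mesh:
        Watertight triangle mesh (mm).
    x, y, z:
        1-D sample coordinate arrays per axis (mm).

    Returns
    -------
    Boolean array of shape ``(len(x), len(y), len(z))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if len(mesh.faces) == 0:
        return np.zeros((x.size, y.size, z.size), bool)

    dx = np.min(np.diff(x)) if x.size > 1 else 1.0
    dy = np.min(np.diff(y)) if y.size > 1 else 1.0
    xj = x + _JITTER * dx
    yj = y + _JITTER * 2.0 * dy

    tv = mesh.triangles  # (m, 3, 3)
    delta = np.zeros((x.size, y.size, z.size + 1), np.int32)

    ax, ay, az = tv[:, 0, 0], tv[:, 0, 1], tv[:, 0, 2]
    v0x, v0y = tv[:, 1, 0] - ax, tv[:, 1, 1] - ay
    v1x, v1y = tv[:, 2, 0] - ax, tv[:, 2, 1] - ay
    det = v0x * v1y - v0y * v1x
    bz0, bz1 = tv[:, 1, 2] - az, tv[:, 2, 2] - az

    tmin_x = tv[:, :, 0].min(axis=1)
    tmax_x = tv[:, :, 0].max(axis=1)
    tmin_y = tv[:, :, 1].min(axis=1)
    tmax_y = tv[:, :, 1].max(axis=1)
    ix0 = np.searchsorted(xj, tmin_x, side="left")
    ix1 = np.searchsorted(xj, tmax_x, side="right")
    iy0 = np.searchsorted(yj, tmin_y, side="left")
    iy1 = np.searchsorted(yj, tmax_y, side="right")

    live = (np.abs(det) > 1e-14) & (ix1 > ix0) & (iy1 > iy0)
    for m in np.nonzero(live)[0]:
        px = xj[ix0[m]:ix1[m]] - ax[m]
        py = yj[iy0[m]:iy1[m]] - ay[m]
        inv = 1.0 / det[m]
        u = (px[:, None] * v1y[m] - py[None, :] * v1x[m]) * inv
        v = (v0x[m] * py[None, :] - v0y[m] * px[:, None]) * inv
        hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not hit.any():
            continue
        zhit = az[m] + u * bz0[m] + v * bz1[m]
        hi, hj = np.nonzero(hit)
        kz = np.searchsorted(z, zhit[hi, hj], side="left")
        np.add.at(delta, (ix0[m] + hi, iy0[m] + hj, kz), 1)

    counts = np.cumsum(delta[:, :, :-1], axis=2)
    return (counts % 2) == 1


def binary_occupancy(mesh: trimesh.Trimesh, edges_x, edges_y, edges_z) -> np.ndarray:
    """Voxel-center inside flags for a rectilinear voxel grid given by edges."""
    cx = 0.5 * (np.asarray(edges_x)[:-1] + np.asarray(edges_x)[1:])
    cy = 0.5 * (np.asarray(edges_y)[:-1] + np.asarray(edges_y)[1:])
    cz = 0.5 * (np.asarray(edges_z)[:-1] + np.asarray(edges_z)[1:])
    return point_occupancy(mesh, cx, cy, cz)


def occupancy_fractions(
    mesh: trimesh.Trimesh, edges_x, edges_y, edges_z, supersample: int = 4
) -> np.ndarray:
    """Per-voxel material fractions estimated by ``supersample**3`` sub-points.

    Sub-sample points are placed at the centers of a uniform subdivision of
    each voxel, so the estimate converges to the true fraction as the
    supersampling factor grows.
    """
    if supersample < 1:
        raise ValidationError("supersample must be >= 1")

    def subcenters(edges):
        edges = np.asarray(edges, float)
        widths = np.diff(edges)
        offs = (np.arange(supersample) + 0.5) / supersample
        return (edges[:-1, None] + widths[:, None] * offs[None, :]).ravel()

    fine = point_occupancy(mesh, subcenters(edges_x), subcenters(edges_y), subcenters(edges_z))
    s = supersample
    nx, ny, nz = fine.shape[0] // s, fine.shape[1] // s, fine.shape[2] // s
    blocks = fine.reshape(nx, s, ny, s, nz, s)
    return blocks.mean(axis=(1, 3, 5))
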