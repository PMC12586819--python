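"""Exact axis-aligned box-cell geometry.

A :class:`BoxSet` is a rectilinear cell complex: sorted per-axis coordinate
arrays delimit a grid of cells and a boolean array marks which cells are
material.  Everything that matters downstream — volume, Boolean
combinations, per-voxel occupancy fractions, and the watertight boundary
mesh — is computed exactly (up to floating point) on this representation,
with no sampling or remeshing involved.  Lattice cubes and box primitives
are built on it, which is what makes the mesh Booleans of the assembly
pipeline exact whenever both operands are rectilinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import ValidationError

__all__ = ["BoxSet", "box_mesh"]

# metadata key under which meshes carry their generating BoxSet
METADATA_KEY = "box_cells"


@dataclass
class BoxSet:
    """Union of axis-aligned boxes stored as marked cells of a rectilinear grid.

    Parameters
    ----------
    xs, ys, zs:
        Strictly increasing cell-edge coordinates per axis (length >= 2), mm.
    inside:
        Boolean array of shape ``(len(xs)-1, len(ys)-1, len(zs)-1)`` marking
        material cells.  Space outside the grid is empty.
    """

    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        self.zs = np.asarray(self.zs, dtype=float)
        self.inside = np.asarray(self.inside, dtype=bool)
        for c in (self.xs, self.ys, self.zs):
            if c.ndim != 1 or c.size < 2 or np.any(np.diff(c) <= 0):
                raise ValidationError("cell edges must be strictly increasing, length >= 2")
        expect = (self.xs.size - 1, self.ys.size - 1, self.zs.size - 1)
        if self.inside.shape != expect:
            raise ValidationError(f"inside shape {self.inside.shape} != cells {expect}")

    # ------------------------------------------------------------------ build
    @classmethod
    def from_boxes(cls, boxes) -> "BoxSet":
        """Build from an iterable of ``(lo, hi)`` bounds pairs (each length-3)."""
        boxes = [(np.asarray(lo, float), np.asarray(hi, float)) for lo, hi in boxes]
        if not boxes:
            raise ValidationError("at least one box required")
        for lo, hi in boxes:
            if np.any(hi <= lo):
                raise ValidationError("box must have positive extent on every axis")
        coords = []
        for ax in range(3):
            vals = np.concatenate([[lo[ax], hi[ax]] for lo, hi in boxes])
            coords.append(np.unique(vals))
        xs, ys, zs = coords
        inside = np.zeros((xs.size - 1, ys.size - 1, zs.size - 1), dtype=bool)
        for lo, hi in boxes:
            i0, i1 = np.searchsorted(xs, [lo[0], hi[0]])
            j0, j1 = np.searchsorted(ys, [lo[1], hi[1]])
            k0, k1 = np.searchsorted(zs, [lo[2], hi[2]])
            inside[i0:i1, j0:j1, k0:k1] = True
        return cls(xs, ys, zs, inside)

    # ----------------------------------------------------------------- volume
    def volume(self) -> float:
        dx = np.diff(self.xs)
        dy = np.diff(self.ys)
        dz = np.diff(self.zs)
        return float(np.einsum("i,j,k,ijk->", dx, dy, dz, self.inside))

    @property
    def bounds(self) -> np.ndarray:
        return np.array(
            [[self.xs[0], self.ys[0], self.zs[0]], [self.xs[-1], self.ys[-1], self.zs[-1]]]
        )

    def is_empty(self) -> bool:
        return not bool(self.inside.any())

    # ----------------------------------------------------------- set algebra
    @staticmethod
    def _refine(a: "BoxSet", b: "BoxSet"):
        """Common refinement grid plus both inside arrays resampled onto it."""
        axes = []
        for ca, cb in ((a.xs, b.xs), (a.ys, b.ys), (a.zs, b.zs)):
            axes.append(np.unique(np.concatenate([ca, cb])))

        def remap(s: "BoxSet"):
            marks = []
            for coords, own in ((axes[0], s.xs), (axes[1], s.ys), (axes[2], s.zs)):
                centers = 0.5 * (coords[:-1] + coords[1:])
                idx = np.searchsorted(own, centers, side="right") - 1
                ok = (idx >= 0) & (idx < own.size - 1)
                marks.append((idx, ok))
            (ix, okx), (iy, oky), (iz, okz) = marks
            out = np.zeros((axes[0].size - 1, axes[1].size - 1, axes[2].size - 1), bool)
            sub = s.inside[np.ix_(ix[okx], iy[oky], iz[okz])]
            out[np.ix_(okx, oky, okz)] = sub
            return out

        return axes, remap(a), remap(b)

    def intersect(self, other: "BoxSet") -> "BoxSet":
        axes, ia, ib = self._refine(self, other)
        return BoxSet(axes[0], axes[1], axes[2], ia & ib)

    def union(self, other: "BoxSet") -> "BoxSet":
        axes, ia, ib = self._refine(self, other)
        return BoxSet(axes[0], axes[1], axes[2], ia | ib)

    def difference(self, other: "BoxSet") -> "BoxSet":
        axes, ia, ib = self._refine(self, other)
        return BoxSet(axes[0], axes[1], axes[2], ia & ~ib)

    # -------------------------------------------------------------- occupancy
    def occupancy(self, edges_x, edges_y, edges_z) -> np.ndarray:
        """Exact material volume fraction of each voxel of a rectilinear grid.

        ``edges_*`` are voxel edge coordinates (mm).  Returns fractions in
        [0, 1] of shape ``(len(edges_x)-1, len(edges_y)-1, len(edges_z)-1)``.
        """

        def overlap(cells: np.ndarray, edges: np.ndarray) -> np.ndarray:
            # (n_cells, n_vox) pairwise interval overlap lengths
            c_lo, c_hi = cells[:-1, None], cells[1:, None]
            v_lo, v_hi = edges[None, :-1], edges[None, 1:]
            return np.clip(np.minimum(c_hi, v_hi) - np.maximum(c_lo, v_lo), 0.0, None)

        ox = overlap(self.xs, np.asarray(edges_x, float))
        oy = overlap(self.ys, np.asarray(edges_y, float))
        oz = overlap(self.zs, np.asarray(edges_z, float))
        acc = np.tensordot(self.inside.astype(float), oz, axes=(2, 0))  # (cx,cy,vz)
        acc = np.tensordot(acc, oy, axes=(1, 0))  # (cx,vz,vy)
        acc = np.tensordot(acc, ox, axes=(0, 0))  # (vz,vy,vx)
        vol = np.einsum(
            "i,j,k->ijk",
            np.diff(np.asarray(edges_x, float)),
            np.diff(np.asarray(edges_y, float)),
            np.diff(np.asarray(edges_z, float)),
        )
        occ = np.transpose(acc, (2, 1, 0)) / vol
        return np.clip(occ, 0.0, 1.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Exact membership test for an array of points, shape (n, 3)."""
        pts = np.asarray(points, float)
        ix = np.searchsorted(self.xs, pts[:, 0], side="right") - 1
        iy = np.searchsorted(self.ys, pts[:, 1], side="right") - 1
        iz = np.searchsorted(self.zs, pts[:, 2], side="right") - 1
        ok = (
            (ix >= 0) & (ix < self.xs.size - 1)
            & (iy >= 0) & (iy < self.ys.size - 1)
            & (iz >= 0) & (iz < self.zs.size - 1)
        )
        out = np.zeros(pts.shape[0], bool)
        out[ok] = self.inside[ix[ok], iy[ok], iz[ok]]
        return out

    # ------------------------------------------------------------------ mesh
    def to_mesh(self, provenance: str = "box-cells") -> trimesh.Trimesh:
        """Extract the watertight, outward-oriented boundary surface."""
        pad = np.zeros(np.array(self.inside.shape) + 2, bool)
        pad[1:-1, 1:-1, 1:-1] = self.inside
        coords = (self.xs, self.ys, self.zs)
        tris = []

        for axis in range(3):
            diff = np.diff(pad.astype(np.int8), axis=axis)
            # diff = +1: empty->material crossing at this plane (normal -axis)
            # diff = -1: material->empty (normal +axis)
            for sign in (1, -1):
                idx = np.argwhere(np.moveaxis(diff, axis, 0) == sign)
                if idx.size == 0:
                    continue
                plane_i, cell_j, cell_k = idx[:, 0], idx[:, 1] - 1, idx[:, 2] - 1
                other = [a for a in range(3) if a != axis]
                cu, cv = coords[other[0]], coords[other[1]]
                x = coords[axis][plane_i]
                u0, u1 = cu[cell_j], cu[cell_j + 1]
                v0, v1 = cv[cell_k], cv[cell_k + 1]

                def corner(u, v):
                    p = np.empty((x.size, 3))
                    p[:, axis] = x
                    p[:, other[0]] = u
                    p[:, other[1]] = v
                    return p

                a, b, c, d = corner(u0, v0), corner(u1, v0), corner(u1, v1), corner(u0, v1)
                # winding a-b-c(-d) has normal +axis when (other0 x other1) == +axis,
                # which holds for the cyclic axis orders used here except axis=1
                flip = sign == 1
                if axis == 1:
                    flip = not flip
                if flip:
                    b, d = d, b
                tris.append(np.stack([a, b, c], axis=1))
                tris.append(np.stack([a, c, d], axis=1))

        if not tris:
            return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        tri = np.concatenate(tris, axis=0)
        verts = tri.reshape(-1, 3)
        faces = np.arange(verts.shape[0]).reshape(-1, 3)
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        if mesh.volume < 0:
            mesh.invert()
        mesh.metadata[METADATA_KEY] = self
        mesh.metadata["provenance"] = provenance
        return mesh


def box_mesh(lo, hi, provenance: str = "box") -> trimesh.Trimesh:
    """Axis-aligned box primitive carrying its exact BoxSet in metadata."""
    return BoxSet.from_boxes([(lo, hi)]).to_mesh(provenance=provenance)


def as_boxset(mesh: trimesh.Trimesh) -> BoxSet | None:
    """Return the BoxSet behind ``mesh`` if one is available.

    Either the mesh carries one in metadata (meshes built by this package), or
    it is recognisably a single axis-aligned box, in which case an equivalent
    BoxSet is reconstructed.  Returns None for general geometry.
    """
    bs = mesh.metadata.get(METADATA_KEY) if hasattr(mesh, "metadata") else None
    if isinstance(bs, BoxSet):
        return bs
    if len(mesh.faces) == 12 and len(mesh.vertices) == 8:
        lo, hi = mesh.bounds
        expect = np.array(np.meshgrid(*zip(lo, hi), indexing="ij")).reshape(3, -1).T
        got = mesh.vertices[np.lexsort(mesh.vertices.T[::-1])]
        expect = expect[np.lexsort(expect.T[::-1])]
        if np.allclose(got, expect, atol=1e-9) and abs(
            mesh.volume - np.prod(hi - lo)
        ) <= 1e-9 * max(np.prod(hi - lo), 1.0):
            return BoxSet.from_boxes([(lo, hi)])
    return None
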