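"""Boolean mesh assembly of the printable part-solid nodule.

The printable model is ``core ∪ (⋃_bands band ∩ lattice)``: each
ground-glass class mesh is intersected with its density lattice and the
results are united with the fully dense core into one watertight STL.

Boolean strategy: whenever both operands carry exact box-cell geometry
(lattice cubes, box primitives) the operation is performed exactly on the
rectilinear cell complex.  Otherwise a voxel-remesh fallback composes
inside/outside logic on a fine shared grid and re-extracts one surface with
marching cubes; such results are flagged ``voxel-remesh`` in their
provenance and are held to the same volume oracle as the exact path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure as skmeasure

from . import rasterize
from .boxset import BoxSet, as_boxset
from .errors import DomainError, InputError, ValidationError
from .lattice import LatticeSpec, build_lattice_mesh, lattice_boxset

__all__ = [
    "AssemblyPlan",
    "AssemblyResult",
    "boolean_intersection",
    "boolean_union",
    "assemble_partsolid_nodule",
    "write_stl",
    "read_stl",
    "empty_mesh",
]

DEFAULT_PITCH_MM = 0.05


def empty_mesh() -> trimesh.Trimesh:
    """Explicit empty result of a Boolean operation."""
    m = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
    m.metadata["provenance"] = "empty"
    return m


def _require_watertight(mesh: trimesh.Trimesh, label: str) -> None:
    if len(mesh.faces) == 0:
        raise ValidationError(f"{label}: empty mesh is not a valid Boolean operand")
    if not mesh.is_watertight:
        raise ValidationError(f"{label}: mesh is not watertight")


def _occupancy_at(mesh: trimesh.Trimesh, centers) -> np.ndarray:
    """Inside flags of a mesh at grid center coordinates (exact for box-cell)."""
    bs = as_boxset(mesh)
    cx, cy, cz = centers
    if bs is not None:
        ix = np.searchsorted(bs.xs, cx, side="right") - 1
        iy = np.searchsorted(bs.ys, cy, side="right") - 1
        iz = np.searchsorted(bs.zs, cz, side="right") - 1
        okx = (ix >= 0) & (ix < bs.xs.size - 1)
        oky = (iy >= 0) & (iy < bs.ys.size - 1)
        okz = (iz >= 0) & (iz < bs.zs.size - 1)
        out = np.zeros((cx.size, cy.size, cz.size), bool)
        sub = bs.inside[np.ix_(ix[okx], iy[oky], iz[okz])]
        out[np.ix_(okx, oky, okz)] = sub
        return out
    return rasterize.point_occupancy(mesh, cx, cy, cz)


def _remesh(mask: np.ndarray, pitch: float, lo: np.ndarray, provenance: str) -> trimesh.Trimesh:
    if not mask.any():
        return empty_mesh()
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5, spacing=(pitch,) * 3)
    verts = verts + lo - 0.5 * pitch - pitch  # centers origin minus pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    mesh.metadata["provenance"] = provenance
    return mesh


def _voxel_boolean(meshes, op, pitch: float) -> trimesh.Trimesh:
    bounds = np.array([m.bounds for m in meshes])
    if op == "intersection":
        lo = bounds[:, 0, :].max(axis=0)
        hi = bounds[:, 1, :].min(axis=0)
    else:
        lo = bounds[:, 0, :].min(axis=0)
        hi = bounds[:, 1, :].max(axis=0)
    lo = lo - 2 * pitch
    hi = hi + 2 * pitch
    shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int), 1)
    centers = [lo[ax] + (np.arange(shape[ax]) + 0.5) * pitch for ax in range(3)]
    mask = None
    for m in meshes:
        occ = _occupancy_at(m, centers)
        mask = occ if mask is None else (mask & occ if op == "intersection" else mask | occ)
    return _remesh(mask, pitch, lo, f"voxel-remesh {op} pitch={pitch}mm")


def boolean_intersection(
    a: trimesh.Trimesh, b: trimesh.Trimesh, pitch: float = DEFAULT_PITCH_MM
) -> trimesh.Trimesh:
    """Watertight mesh of ``a ∩ b`` (exact for box-cell operands).

    A disjoint pair returns an explicit empty mesh.  ``pitch`` controls the
    voxel-remesh fallback resolution for general geometry.
    """
    _require_watertight(a, "intersection operand a")
    _require_watertight(b, "intersection operand b")
    if np.any(a.bounds[1] <= b.bounds[0]) or np.any(b.bounds[1] <= a.bounds[0]):
        return empty_mesh()
    ba, bb = as_boxset(a), as_boxset(b)
    if ba is not None and bb is not None:
        out = ba.intersect(bb)
        if out.is_empty():
            return empty_mesh()
        return out.to_mesh(provenance="exact-box intersection")
    return _voxel_boolean([a, b], "intersection", pitch)


def boolean_union(meshes, pitch: float = DEFAULT_PITCH_MM) -> trimesh.Trimesh:
    """Watertight union of watertight meshes (exact for box-cell operands).

    Meshes whose bounding boxes do not touch are combined by concatenation
    (exact and volume-additive); overlapping groups are united via the exact
    box kernel or the voxel-remesh fallback.
    """
    meshes = list(meshes)
    if not meshes:
        return empty_mesh()
    for i, m in enumerate(meshes):
        _require_watertight(m, f"union operand {i}")
    if len(meshes) == 1:
        return meshes[0].copy()

    # group meshes whose bounding boxes overlap (union-find over pairs)
    n = len(meshes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = meshes[i].bounds, meshes[j].bounds
            if np.all(bi[1] > bj[0]) and np.all(bj[1] > bi[0]):
                parent[find(i)] = find(j)

    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(meshes[i])

    parts = []
    for members in groups.values():
        if len(members) == 1:
            parts.append(members[0])
            continue
        boxsets = [as_boxset(m) for m in members]
        if all(bs is not None for bs in boxsets):
            acc = boxsets[0]
            for bs in boxsets[1:]:
                acc = acc.union(bs)
            parts.append(acc.to_mesh(provenance="exact-box union"))
        else:
            parts.append(_voxel_boolean(members, "union", pitch))
    if len(parts) == 1:
        return parts[0]
    out = trimesh.util.concatenate(parts)
    out.metadata["provenance"] = "union of disjoint parts: " + "; ".join(
        str(p.metadata.get("provenance", "mesh")) for p in parts
    )
    return out


# ---------------------------------------------------------------- assembly
@dataclass
class AssemblyPlan:
    """Core mesh (printed fully dense) plus (band mesh, lattice) pairs.

    Each band's lattice may be given as a :class:`LatticeSpec` — in which
    case a covering lattice cube is generated automatically — or as an
    explicit lattice mesh, which must fully cover the band's bounding box.
    """

    core_mesh: trimesh.Trimesh | None
    bands: list = field(default_factory=list)  # [(name, band_mesh, LatticeSpec | Trimesh)]

    def __post_init__(self) -> None:
        if self.core_mesh is None and not self.bands:
            raise ValidationError("assembly plan needs a core or at least one band")


@dataclass
class AssemblyResult:
    mesh: trimesh.Trimesh
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2)


def _covering_lattice(spec: LatticeSpec, band_mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    p_mm = spec.period_um / 1000.0
    extent = float(np.max(band_mesh.bounds[1] - band_mesh.bounds[0]))
    side = max(extent + 2.0 * p_mm, 2.0 * p_mm)
    cube = build_lattice_mesh(spec, side)
    shift = band_mesh.bounds[0] - p_mm
    bs: BoxSet = cube.metadata["box_cells"]
    moved = BoxSet(bs.xs + shift[0], bs.ys + shift[1], bs.zs + shift[2], bs.inside)
    return moved.to_mesh(provenance=f"lattice {spec} covering band")


def assemble_partsolid_nodule(
    plan: AssemblyPlan,
    pitch: float = DEFAULT_PITCH_MM,
    resin_price_eur_per_ml: float | None = None,
) -> AssemblyResult:
    """Compose ``core ∪ (⋃ band ∩ lattice)`` into one printable mesh.

    The Boolean logic is evaluated per voxel center on a shared grid of
    ``pitch`` mm (exact membership for lattice geometry, ray parity for the
    band and core surfaces) and a single watertight surface is extracted.
    The manifest reports per-band material volumes (mm³ and mL) and an
    estimated resin cost.
    """
    if resin_price_eur_per_ml is None:
        from .config import defaults

        resin_price_eur_per_ml = defaults()["cost"]["resin_price_eur_per_ml"]
    bands = []
    for entry in plan.bands:
        if len(entry) != 3:
            raise ValidationError("each band must be (name, band_mesh, lattice)")
        name, band_mesh, lattice = entry
        _require_watertight(band_mesh, f"band {name!r}")
        if isinstance(lattice, LatticeSpec):
            lattice_mesh = _covering_lattice(lattice, band_mesh)
            spec_str = str(lattice)
        else:
            lattice_mesh = lattice
            _require_watertight(lattice_mesh, f"band {name!r} lattice")
            spec_str = str(lattice_mesh.metadata.get("provenance", "lattice"))
            if np.any(lattice_mesh.bounds[0] > band_mesh.bounds[0]) or np.any(
                lattice_mesh.bounds[1] < band_mesh.bounds[1]
            ):
                raise DomainError(
                    f"band {name!r}: lattice does not cover the band bounding box"
                )
        bands.append((name, band_mesh, lattice_mesh, spec_str))
    if plan.core_mesh is not None:
        _require_watertight(plan.core_mesh, "core")

    if plan.core_mesh is not None and not bands:
        mesh = plan.core_mesh.copy()
        mesh.metadata["provenance"] = "core only"
        vol = float(mesh.volume)
        manifest = {
            "pitch_mm": None,
            "bands": [],
            "core_volume_mm3": vol,
            "total_material_volume_mm3": vol,
            "total_material_volume_ml": vol / 1000.0,
            "estimated_resin_cost_eur": vol / 1000.0 * resin_price_eur_per_ml,
        }
        return AssemblyResult(mesh, manifest)

    all_meshes = [b[1] for b in bands] + ([plan.core_mesh] if plan.core_mesh is not None else [])
    bounds = np.array([m.bounds for m in all_meshes])
    lo = bounds[:, 0, :].min(axis=0) - 2 * pitch
    hi = bounds[:, 1, :].max(axis=0) + 2 * pitch
    shape = np.ceil((hi - lo) / pitch).astype(int)
    centers = [lo[ax] + (np.arange(shape[ax]) + 0.5) * pitch for ax in range(3)]

    mask = np.zeros(tuple(shape), bool)
    manifest_bands = []
    for name, band_mesh, lattice_mesh, spec_str in bands:
        band_occ = _occupancy_at(band_mesh, centers)
        if not band_occ.any():
            manifest_bands.append(
                {"band": name, "lattice": spec_str, "skipped": "band mesh empty on grid"}
            )
            continue
        lat_occ = _occupancy_at(lattice_mesh, centers)
        material = band_occ & lat_occ
        vol = float(material.sum()) * pitch ** 3
        manifest_bands.append(
            {
                "band": name,
                "lattice": spec_str,
                "band_volume_mm3": float(band_occ.sum()) * pitch ** 3,
                "material_volume_mm3": vol,
                "material_volume_ml": vol / 1000.0,
            }
        )
        mask |= material

    core_vol = 0.0
    if plan.core_mesh is not None:
        core_occ = _occupancy_at(plan.core_mesh, centers)
        core_vol = float(core_occ.sum()) * pitch ** 3
        mask |= core_occ

    mesh = _remesh(mask, pitch, lo, f"voxel-boolean assembly pitch={pitch}mm")
    total = core_vol + sum(b.get("material_volume_mm3", 0.0) for b in manifest_bands)
    manifest = {
        "pitch_mm": pitch,
        "bands": manifest_bands,
        "core_volume_mm3": core_vol,
        "total_material_volume_mm3": total,
        "total_material_volume_ml": total / 1000.0,
        "estimated_resin_cost_eur": total / 1000.0 * resin_price_eur_per_ml,
        "units": "mm",
    }
    return AssemblyResult(mesh, manifest)


# --------------------------------------------------------------------- STL
def write_stl(mesh: trimesh.Trimesh, path: str, mode: str = "binary") -> None:
    """Write STL (mm units by convention); ``mode`` is ``binary`` or ``ascii``."""
    if mode not in ("binary", "ascii"):
        raise DomainError(f"unknown STL mode {mode!r}")
    if len(mesh.faces) == 0:
        raise ValidationError("refusing to write an empty mesh")
    if mode == "binary":
        data = trimesh.exchange.stl.export_stl(mesh)
        with open(path, "wb") as fh:
            fh.write(data)
    else:
        text = trimesh.exchange.stl.export_stl_ascii(mesh)
        with open(path, "w") as fh:
            fh.write(text)


def read_stl(path: str) -> trimesh.Trimesh:
    """Read an STL file (binary or ascii) into a processed triangle mesh."""
    try:
        with open(path, "rb") as fh:
            data = trimesh.exchange.stl.load_stl(fh)
    except Exception as exc:
        raise InputError(f"malformed STL {path}: {exc}") from exc
    if data.get("faces") is None or len(data["faces"]) == 0:
        raise InputError(f"malformed STL {path}: no facets parsed")
    mesh = trimesh.Trimesh(**data, process=True)
    if mesh.volume < 0:
        mesh.invert()
    mesh.metadata["provenance"] = f"read_stl {path}"
    return mesh
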