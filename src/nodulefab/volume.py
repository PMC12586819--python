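"""HU volume handling: load, crop, resample, threshold, mesh, measure.

The segmentation front end of the phantom workflow: a CT-like volume is
cropped around the nodule, resampled to fine isotropic spacing, thresholded
into the four density classes of a part-solid nodule (solid core plus three
ground-glass bands), and each class is converted to a surface mesh for the
downstream Boolean assembly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as skmeasure

from .config import defaults
from .errors import ConfigurationError, DomainError, EmptySelectionError, InputError

__all__ = [
    "HUVolume",
    "HUClassSpec",
    "LabelVolume",
    "ROIStats",
    "default_classes",
    "load_volume",
    "save_labels",
    "resample_isotropic",
    "threshold_classes",
    "extract_class_meshes",
    "measure_roi_hu",
]

HU_MIN, HU_MAX = -1024.0, 3071.0  # 12-bit CT convention


@dataclass
class HUVolume:
    """Voxel grid of Hounsfield units with physical geometry.

    ``data[i, j, k]`` is the HU at physical position
    ``origin + (i, j, k) * spacing`` (voxel-center convention, mm).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, float).copy()
        )
        if self.data.ndim != 3:
            raise DomainError("HUVolume requires a 3-D array")
        if np.any(self.spacing <= 0):
            raise DomainError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise DomainError("HU data must be finite")

    @property
    def shape(self):
        return self.data.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self):
        """Per-axis physical center coordinates (mm)."""
        return [
            self.origin[ax] + np.arange(self.shape[ax]) * self.spacing[ax]
            for ax in range(3)
        ]


@dataclass
class LabelVolume:
    """Integer class labels (0 = background) sharing HUVolume geometry."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise DomainError("labels must be integers")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, float).copy()
        )

    @property
    def shape(self):
        return self.labels.shape


@dataclass(frozen=True)
class HUClassSpec:
    """Half-open/closed HU interval with a class name."""

    name: str
    lower: float
    upper: float
    lower_inclusive: bool = False
    upper_inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError(f"class {self.name}: lower must be < upper")

    def contains(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu)
        lo = hu >= self.lower if self.lower_inclusive else hu > self.lower
        hi = hu <= self.upper if self.upper_inclusive else hu < self.upper
        return lo & hi


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n: int


def default_classes() -> list[HUClassSpec]:
    """The four density classes: core (>0), gg1 (-300,0], gg2 (-500,-300],
    gg3 [-750,-500]; HU below -750 is background."""
    return [HUClassSpec(**c) for c in defaults()["hu_classes"]]


# --------------------------------------------------------------------- load
def _load_nifti(path: str) -> HUVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = np.asarray(img.header.get_zooms()[:3], float)
    origin = np.asarray(img.affine[:3, 3], float)
    return HUVolume(data, spacing, origin)


def _load_dicom_series(path: str) -> HUVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise InputError(f"no readable DICOM slices in {path}")

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=zpos)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    data = np.stack(planes, axis=-1)  # (row, col, slice)
    ds0 = slices[0]
    ps = [float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0])]
    if len(slices) > 1:
        dz = abs(zpos(slices[1]) - zpos(slices[0])) or float(
            getattr(ds0, "SliceThickness", 1.0)
        )
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    origin = np.zeros(3)
    if hasattr(ds0, "ImagePositionPatient"):
        origin = np.asarray([float(v) for v in ds0.ImagePositionPatient])
    return HUVolume(data, np.array([ps[0], ps[1], dz]), origin)


def load_volume(path: str, roi=None) -> HUVolume:
    """Load a NIfTI file or DICOM series directory as a HU-calibrated volume.

    DICOM rescale slope/intercept is applied; HU is clamped to
    ``[-1024, 3071]``.  ``roi``, if given, is a per-axis ``(lo, hi)`` voxel
    index box (half-open) that must lie within the array bounds.
    """
    if os.path.isdir(path):
        vol = _load_dicom_series(path)
    elif os.path.isfile(path):
        try:
            vol = _load_nifti(path)
        except Exception as exc:  # unreadable / wrong format
            raise InputError(f"cannot read {path} as NIfTI: {exc}") from exc
    else:
        raise InputError(f"no such file or directory: {path}")

    vol.data = np.clip(vol.data, HU_MIN, HU_MAX)
    if roi is not None:
        roi = np.asarray(roi, int)
        if roi.shape != (3, 2):
            raise DomainError("roi must be three (lo, hi) index pairs")
        for ax in range(3):
            lo, hi = roi[ax]
            if not (0 <= lo < hi <= vol.shape[ax]):
                raise DomainError(f"roi axis {ax} [{lo},{hi}) outside shape {vol.shape}")
        sl = tuple(slice(lo, hi) for lo, hi in roi)
        origin = vol.origin + roi[:, 0] * vol.spacing
        vol = HUVolume(vol.data[sl], vol.spacing, origin)
    return vol


def save_labels(labels: LabelVolume, path: str) -> None:
    """Write a label volume as NIfTI (uint8, spacing in the affine)."""
    import nibabel as nib

    affine = np.diag(list(labels.spacing) + [1.0])
    affine[:3, 3] = labels.origin
    nib.save(nib.Nifti1Image(labels.labels.astype(np.uint8), affine), path)


# ----------------------------------------------------------------- resample
def resample_isotropic(
    vol: HUVolume, target_spacing: float, interpolation: str = "linear"
) -> HUVolume:
    """Resample to isotropic voxels of ``target_spacing`` mm.

    The output shape is ``ceil(extent / target)`` per axis with
    ``extent = shape * spacing``.  Intensities are interpolated trilinearly
    (``"linear"``); label-like data should use ``"nearest"``.
    """
    if target_spacing <= 0:
        raise DomainError("target spacing must be positive")
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise DomainError(f"unknown interpolation {interpolation!r}")

    extent = np.asarray(vol.shape) * vol.spacing
    new_shape = np.ceil(extent / target_spacing - 1e-9).astype(int)
    grids = []
    for ax in range(3):
        # new voxel-center positions expressed in old fractional indices,
        # aligning the voxel-cell extents of both grids
        centers = (np.arange(new_shape[ax]) + 0.5) * target_spacing
        grids.append(centers / vol.spacing[ax] - 0.5)
    mesh = np.meshgrid(*grids, indexing="ij")
    data = ndimage.map_coordinates(
        vol.data, np.stack(mesh), order=order, mode="nearest"
    )
    new_origin = vol.origin - 0.5 * vol.spacing + 0.5 * target_spacing
    return HUVolume(data, np.full(3, float(target_spacing)), new_origin)


# ---------------------------------------------------------------- threshold
def _intervals_overlap(a: HUClassSpec, b: HUClassSpec) -> bool:
    lo = max(a.lower, b.lower)
    hi = min(a.upper, b.upper)
    if lo > hi:
        return False
    if lo < hi:
        return True
    # intervals touch at a single point: overlap only if both include it
    def includes(spec: HUClassSpec, x: float) -> bool:
        at_lower = x == spec.lower
        at_upper = x == spec.upper
        if at_lower and not spec.lower_inclusive:
            return False
        if at_upper and not spec.upper_inclusive:
            return False
        return True

    return includes(a, lo) and includes(b, lo)


def threshold_classes(
    vol: HUVolume, classes=None, mask: np.ndarray | None = None
) -> LabelVolume:
    """Assign each voxel the unique class containing its HU (0 = none).

    Classes must be pairwise non-overlapping; an optional binary mask
    restricts assignment (voxels outside the mask become 0).
    """
    classes = default_classes() if classes is None else list(classes)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            if _intervals_overlap(a, b):
                raise ConfigurationError(
                    f"classes {a.name!r} and {b.name!r} have overlapping HU intervals"
                )
    labels = np.zeros(vol.shape, dtype=np.uint8)
    for i, spec in enumerate(classes, start=1):
        labels[spec.contains(vol.data)] = i
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != vol.shape:
            raise DomainError("mask shape must match the volume")
        labels[~mask] = 0
    return LabelVolume(labels, vol.spacing, vol.origin)


# --------------------------------------------------------------------- mesh
def extract_class_meshes(labels: LabelVolume, class_id: int) -> trimesh.Trimesh:
    """Closed surface mesh (mm) of one label class via marching cubes.

    The binary class mask is contoured at iso-level 0.5 with the volume's
    spacing and origin applied, so the enclosed volume approximates the
    voxel-count volume of the mask.
    """
    mask = labels.labels == class_id
    if not mask.any():
        raise EmptySelectionError(f"class {class_id} not present in the label volume")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = skmeasure.marching_cubes(
        padded, level=0.5, spacing=tuple(labels.spacing)
    )
    verts = verts - labels.spacing + labels.origin  # undo the 1-voxel pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    mesh.metadata["provenance"] = f"marching-cubes class {class_id}"
    return mesh


# ---------------------------------------------------------------------- ROI
def measure_roi_hu(
    vol: HUVolume,
    center_mm,
    radius_mm: float,
    thickness_mm: float | None = None,
    axis: int = 2,
) -> ROIStats:
    """Mean/SD of HU over voxels whose centers lie within a spherical ROI.

    With ``thickness_mm`` the ROI becomes a slice-confined disc: a circle of
    ``radius_mm`` in the plane perpendicular to ``axis``, restricted to
    ``|distance along axis| <= thickness/2`` (mirroring a per-slice circular
    ROI).  SD is the population standard deviation.
    """
    if radius_mm <= 0:
        raise DomainError("ROI radius must be positive")
    center = np.asarray(center_mm, float)
    cx, cy, cz = vol.voxel_centers()
    dx = (cx - center[0])[:, None, None]
    dy = (cy - center[1])[None, :, None]
    dz = (cz - center[2])[None, None, :]
    if thickness_mm is None:
        sel = dx * dx + dy * dy + dz * dz <= radius_mm ** 2
    else:
        deltas = [dx, dy, dz]
        d_axis = deltas.pop(axis)
        in_plane = deltas[0] ** 2 + deltas[1] ** 2 <= radius_mm ** 2
        sel = in_plane & (np.abs(d_axis) <= thickness_mm / 2.0)
    vals = vol.data[sel]
    if vals.size == 0:
        raise DomainError("ROI does not intersect the volume")
    return ROIStats(mean=float(vals.mean()), sd=float(vals.std(ddof=0)), n=int(vals.size))
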