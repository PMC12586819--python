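"""Partial-volume density model, design selection, and virtual CT.

A CT voxel's HU is the volume-weighted average of the attenuation of the
materials it contains.  A lattice with material fill fraction ``f`` printed
in a resin of effective HU ``hu_material`` therefore reads

    HU(f) = f * hu_material + (1 - f) * hu_air,   hu_air = -1000.

Inverting this relation against measured cube HU values calibrates the
effective material HU; composing it with the lattice fill fraction predicts
the HU of any design; and a small virtual-CT simulator (occupancy ->
partial-volume HU -> Gaussian PSF -> noise) previews the appearance of a
design, including whether the periodic print pattern would be resolved
("visible") on the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage

from . import rasterize
from .boxset import as_boxset
from .config import defaults
from .errors import DomainError, FitError, NoFeasibleDesignError, ValidationError
from .lattice import DesignGrid, LatticeSpec, design_grid, fill_fraction
from .volume import HUVolume

__all__ = [
    "PartialVolumeModel",
    "CalibrationRecord",
    "VisibilityRule",
    "DefectExclusion",
    "MaterialFit",
    "default_model",
    "default_visibility_rules",
    "default_defect_exclusions",
    "predict_hu",
    "fit_material_hu",
    "select_lattice",
    "voxelize_occupancy",
    "simulate_ct",
    "lattice_visibility_score",
    "VisibilityResult",
]

HU_AIR = -1000.0


@dataclass(frozen=True)
class PartialVolumeModel:
    """Linear HU-vs-fill-fraction mixing model with fixed air HU."""

    hu_material: float
    hu_air: float = HU_AIR

    def __post_init__(self) -> None:
        if not self.hu_material > self.hu_air:
            raise ValidationError("hu_material must exceed hu_air")


@dataclass(frozen=True)
class CalibrationRecord:
    """One measured cube: design plus acquisition/reconstruction condition."""

    spec: LatticeSpec
    mean_hu: float
    sd_hu: float = 0.0
    kv: int | None = None
    ctdi_mgy: float | None = None
    algorithm: str | None = None
    kernel: str | None = None

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValidationError("sd_hu must be non-negative")


@dataclass(frozen=True)
class VisibilityRule:
    """Designs with void >= ``g_min_visible_um`` at this beam thickness show
    their lattice pattern on CT and are excluded from selection."""

    t_um: int
    g_min_visible_um: int
    kernel_scope: str = "hard"

    def excludes(self, spec: LatticeSpec) -> bool:
        return spec.t_um == self.t_um and spec.g_um >= self.g_min_visible_um


@dataclass(frozen=True)
class DefectExclusion:
    """A specific design observed to print defectively (never selected)."""

    t_um: int
    g_um: int
    reason: str = ""

    def excludes(self, spec: LatticeSpec) -> bool:
        return spec.t_um == self.t_um and spec.g_um == self.g_um


@dataclass(frozen=True)
class MaterialFit:
    """Result of calibrating the effective material HU."""

    model: PartialVolumeModel
    residuals_hu: np.ndarray
    rmse_hu: float
    n: int


def default_visibility_rules() -> list[VisibilityRule]:
    return [VisibilityRule(**r) for r in defaults()["visibility_rules"]]


def default_defect_exclusions() -> list[DefectExclusion]:
    return [DefectExclusion(**r) for r in defaults()["defect_exclusions"]]


def default_model() -> PartialVolumeModel:
    """Partial-volume model fitted to the packaged calibration anchors."""
    anchors = defaults()["partial_volume"]["calibration_anchors"]
    records = [
        CalibrationRecord(LatticeSpec(a["t_um"], a["g_um"]), mean_hu=a["mean_hu"])
        for a in anchors
    ]
    return fit_material_hu(records).model


# ------------------------------------------------------------------- model
def predict_hu(model: PartialVolumeModel, f: float) -> float:
    """HU of a print with material fill fraction ``f`` under linear mixing."""
    if not 0.0 <= f <= 1.0:
        raise DomainError(f"fill fraction {f} outside [0, 1]")
    return float(f * model.hu_material + (1.0 - f) * model.hu_air)


def fit_material_hu(records, hu_air: float = HU_AIR) -> MaterialFit:
    """Least-squares fit of the effective material HU from measured cubes.

    Solves ``mean_hu = hu_air + f * (hu_material - hu_air)`` over the
    records' fill fractions; requires at least two distinct fill fractions
    (otherwise the slope is the only unknown and a single f is still
    formally solvable but gives no residual information — treated as
    rank-deficient per the calibration contract).
    """
    records = list(records)
    if len(records) < 2:
        raise FitError("at least two calibration records are required")
    f = np.array([fill_fraction(r.spec) for r in records])
    y = np.array([r.mean_hu for r in records]) - hu_air
    if np.ptp(f) < 1e-12:
        raise FitError("all records share one fill fraction; material HU unidentifiable")
    span = float(f @ y / (f @ f))  # through-origin least squares in (f, HU - hu_air)
    model = PartialVolumeModel(hu_material=hu_air + span, hu_air=hu_air)
    resid = y - f * span
    return MaterialFit(
        model=model,
        residuals_hu=resid,
        rmse_hu=float(np.sqrt(np.mean(resid ** 2))),
        n=len(records),
    )


# --------------------------------------------------------------- selection
def select_lattice(
    model: PartialVolumeModel | None = None,
    target_hu_range=( -750.0, -500.0),
    grid: DesignGrid | None = None,
    rules=None,
    exclusions=None,
) -> LatticeSpec:
    """Pick the design whose predicted HU is nearest the target-range midpoint.

    Designs excluded by visibility rules or defect exclusions are skipped;
    ties break toward larger beam thickness (coarser beams print more
    reliably).  Raises :class:`NoFeasibleDesignError` if nothing remains.
    """
    model = default_model() if model is None else model
    grid = design_grid() if grid is None else grid
    rules = default_visibility_rules() if rules is None else list(rules)
    exclusions = default_defect_exclusions() if exclusions is None else list(exclusions)
    if len(grid) == 0:
        raise NoFeasibleDesignError("empty design grid")
    lo, hi = sorted(float(v) for v in target_hu_range)
    mid = 0.5 * (lo + hi)

    best = None
    for spec in grid:
        if any(r.excludes(spec) for r in rules) or any(e.excludes(spec) for e in exclusions):
            continue
        d = abs(predict_hu(model, fill_fraction(spec)) - mid)
        key = (d, -spec.t_um)
        if best is None or key < best[0]:
            best = (key, spec)
    if best is None:
        raise NoFeasibleDesignError(
            f"every design in the grid is excluded for target ({lo}, {hi}) HU"
        )
    return best[1]


# -------------------------------------------------------------- virtual CT
@dataclass
class Occupancy:
    """Per-voxel material volume fractions with physical geometry (mm)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        self.origin = np.asarray(self.origin, float).copy()

    def mean(self) -> float:
        return float(self.data.mean())


def voxelize_occupancy(
    mesh: trimesh.Trimesh, spacing: float, supersample: int = 4, padding_mm: float = 0.0
) -> Occupancy:
    """Per-voxel material fractions of a watertight mesh on an isotropic grid.

    Meshes carrying exact box-cell geometry are integrated analytically;
    general meshes are supersampled with ``supersample**3 >= 4**3`` ray-parity
    sub-points per voxel.  The grid covers the mesh bounds plus ``padding_mm``.
    """
    if spacing <= 0:
        raise DomainError("spacing must be positive")
    bs = as_boxset(mesh)
    if bs is None and not mesh.is_watertight:
        raise ValidationError("occupancy requires a watertight mesh")
    lo = mesh.bounds[0] - padding_mm
    hi = mesh.bounds[1] + padding_mm
    shape = np.maximum(np.ceil((hi - lo) / spacing - 1e-9).astype(int), 1)
    edges = [lo[ax] + np.arange(shape[ax] + 1) * spacing for ax in range(3)]
    if bs is not None:
        occ = bs.occupancy(*edges)
    else:
        if supersample < 4:
            raise DomainError("supersample must be at least 4 sub-samples per axis")
        occ = rasterize.occupancy_fractions(mesh, *edges, supersample=supersample)
    # voxel-center origin of the occupancy grid
    origin = lo + 0.5 * spacing
    return Occupancy(occ, np.full(3, float(spacing)), origin)


def simulate_ct(
    occ: Occupancy,
    model: PartialVolumeModel | None = None,
    psf_sigma_mm: float | None = None,
    noise_sd_hu: float | None = None,
    seed: int | None = None,
) -> HUVolume:
    """Virtual CT of an occupancy map: partial-volume HU, PSF blur, noise.

    ``HU = hu_air + occ * (hu_material - hu_air)`` convolved with an
    isotropic Gaussian PSF of ``psf_sigma_mm`` and, if requested, i.i.d.
    Gaussian noise (seeded).  This desk-scale simulator has no beam
    hardening, scatter, or reconstruction-kernel modelling.
    """
    cfg = defaults()["virtual_ct"]
    model = default_model() if model is None else model
    psf_sigma_mm = cfg["psf_sigma_mm"] if psf_sigma_mm is None else float(psf_sigma_mm)
    noise_sd_hu = cfg["noise_sd_hu"] if noise_sd_hu is None else float(noise_sd_hu)
    if psf_sigma_mm < 0 or noise_sd_hu < 0:
        raise DomainError("psf_sigma_mm and noise_sd_hu must be non-negative")

    hu = model.hu_air + occ.data * (model.hu_material - model.hu_air)
    if psf_sigma_mm > 0:
        hu = ndimage.gaussian_filter(hu, sigma=psf_sigma_mm / occ.spacing)
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sd_hu, size=hu.shape)
    return HUVolume(np.clip(hu, -1024.0, 3071.0), occ.spacing, occ.origin)


# -------------------------------------------------------------- visibility
@dataclass(frozen=True)
class VisibilityResult:
    score: float
    visible: bool
    cv: float
    spectral_peak: float


def lattice_visibility_score(
    vol: HUVolume,
    spec: LatticeSpec,
    roi=None,
    threshold: float | None = None,
) -> VisibilityResult:
    """Score how strongly the periodic lattice shows in a CT-like volume.

    The score combines the ROI coefficient of spatial variation of
    ``HU + 1000`` (air-referenced contrast) with the normalised spectral
    amplitude at the lattice frequency ``1/p``, averaged over axes.  The ROI
    (a per-axis slice triple; whole volume when None) must span at least
    three lattice periods on every axis so the spectral bin exists.
    """
    threshold = defaults()["visibility_score"]["threshold"] if threshold is None else threshold
    region = vol.data[roi] if roi is not None else vol.data
    p_mm = spec.period_um / 1000.0
    extents = np.asarray(region.shape) * vol.spacing
    if np.any(extents < 3.0 * p_mm - 1e-9):
        raise DomainError(
            f"ROI extents {extents} mm must cover >= 3 lattice periods ({3 * p_mm} mm)"
        )
    ref = float(region.mean()) + 1000.0  # distance above air
    ref = max(ref, 1.0)
    cv = float(region.std(ddof=0)) / ref

    peaks = []
    for ax in range(3):
        others = tuple(a for a in range(3) if a != ax)
        profile = region.mean(axis=others)
        n = profile.size
        amp = np.abs(np.fft.rfft(profile - profile.mean())) * 2.0 / n
        freqs = np.fft.rfftfreq(n, d=vol.spacing[ax])
        k = int(np.argmin(np.abs(freqs - 1.0 / p_mm)))
        peaks.append(amp[k] / ref)
    spectral = float(np.mean(peaks))
    score = cv + spectral
    return VisibilityResult(score=score, visible=score >= threshold, cv=cv, spectral_peak=spectral)
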