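"""Parametric cubic beam lattices for density-by-infill SLA printing.

A lattice cube is the union of three orthogonal families of square-section
beams (section ``t x t`` µm) laid out with period ``p = t + g`` µm, where
``g`` is the designed void side length.  A point is material when at least
two of its three coordinates fall inside a beam band, which gives the
closed-form material fill fraction

    f(r) = 3 r^2 - 2 r^3,   r = t / p.

Because CT density emulation relies on ``f``, the generated geometry must
realise the closed form exactly even when the cube side is not an integer
number of periods: the band pattern is phase-shifted so the clipped per-axis
material coverage equals the nominal duty cycle ``r``, making the enclosed
mesh volume exactly ``f * side^3``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .boxset import BoxSet
from .config import defaults
from .errors import DomainError, ValidationError

__all__ = ["LatticeSpec", "DesignGrid", "fill_fraction", "design_grid", "build_lattice_mesh"]

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class LatticeSpec:
    """Beam-lattice design: beam thickness ``t_um`` and void side ``g_um`` (µm).

    Both must be non-negative integer multiples of the printer spot size
    (default 85 µm); ``g_um = 0`` degenerates to a solid print.
    """

    t_um: int
    g_um: int
    spot_um: int = 85

    def __post_init__(self) -> None:
        if self.spot_um <= 0:
            raise ValidationError("spot size must be positive")
        if self.t_um <= 0:
            raise ValidationError("beam thickness must be positive")
        if self.g_um < 0:
            raise ValidationError("void side length cannot be negative")
        for label, v in (("beam thickness", self.t_um), ("void side length", self.g_um)):
            if v % self.spot_um != 0:
                raise ValidationError(
                    f"{label} {v} µm is not a multiple of the {self.spot_um} µm spot size"
                )

    @property
    def period_um(self) -> int:
        return self.t_um + self.g_um

    @property
    def duty(self) -> float:
        """Per-axis material duty cycle r = t / p."""
        return self.t_um / self.period_um

    def __str__(self) -> str:  # used in filenames and manifests
        return f"t{self.t_um}_g{self.g_um}"


@dataclass(frozen=True)
class DesignGrid:
    """Ordered cartesian product of beam thicknesses and void lengths."""

    thicknesses_um: tuple
    voids_um: tuple
    specs: tuple = field(init=False)

    def __post_init__(self) -> None:
        specs = tuple(
            LatticeSpec(t, g)
            for t, g in itertools.product(self.thicknesses_um, self.voids_um)
        )
        if len(set(specs)) != len(specs):
            raise ValidationError("design grid contains duplicate specifications")
        object.__setattr__(self, "specs", specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)


def fill_fraction(spec: LatticeSpec) -> float:
    """Material volume fraction of the beam lattice, ``3 r^2 - 2 r^3``.

    Derivation: with independent per-axis band indicators of probability
    ``r``, material = at least two of three indicators, and by
    inclusion-exclusion P = 3 r^2 (1 - r) + r^3 = 3 r^2 - 2 r^3.
    """
    r = spec.duty
    return 3.0 * r * r - 2.0 * r ** 3


def design_grid(thicknesses_um=None, voids_um=None, spot_um: int = 85) -> DesignGrid:
    """Build the calibration design grid (defaults: 3 x 6 = 18 samples).

    Raises :class:`ValidationError` naming any entry that is not a multiple
    of the printer spot size.
    """
    cfg = defaults()
    if thicknesses_um is None:
        thicknesses_um = cfg["design_grid"]["beam_thicknesses_um"]
    if voids_um is None:
        voids_um = cfg["design_grid"]["void_lengths_um"]
    bad = [v for v in list(thicknesses_um) + list(voids_um) if v % spot_um != 0]
    if bad:
        raise ValidationError(
            f"entries {bad} are not multiples of the {spot_um} µm spot size"
        )
    return DesignGrid(tuple(thicknesses_um), tuple(voids_um))


def _band_phase(t: float, p: float, side: float) -> float:
    """Phase shift (mm) equalising clipped per-axis coverage with t*side/p.

    ``cov(phi)`` — total length of band pattern ``[k p + phi, k p + phi + t]``
    clipped to ``[0, side]`` — is continuous, piecewise linear and periodic in
    ``phi`` with mean ``t * side / p``, so a root of ``cov - t*side/p``
    always exists; it is located by scan plus bisection.
    """
    target = t * side / p

    def cov(phi: float) -> float:
        k0 = int(np.ceil((-phi - t) / p)) - 1
        k1 = int(np.floor((side - phi) / p)) + 1
        ks = np.arange(k0, k1 + 1)
        lo = np.maximum(ks * p + phi, 0.0)
        hi = np.minimum(ks * p + phi + t, side)
        return float(np.clip(hi - lo, 0.0, None).sum())

    phis = np.linspace(0.0, p, 4097)
    vals = np.array([cov(ph) for ph in phis]) - target
    if np.all(np.abs(vals) < 1e-12):
        return 0.0
    idx = np.nonzero(np.diff(np.signbit(vals)))[0]
    if idx.size == 0:
        # fall back to the scan minimum (should not happen: mean equals target)
        return float(phis[np.argmin(np.abs(vals))])
    a, b = phis[idx[0]], phis[idx[0] + 1]
    fa = vals[idx[0]]
    for _ in range(200):
        m = 0.5 * (a + b)
        fm = cov(m) - target
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def _axis_bands(t: float, p: float, side: float) -> np.ndarray:
    """Clipped beam-band intervals [(lo, hi), ...] along one axis (mm)."""
    phi = _band_phase(t, p, side)
    k0 = int(np.ceil((-phi - t) / p)) - 1
    k1 = int(np.floor((side - phi) / p)) + 1
    ks = np.arange(k0, k1 + 1)
    lo = np.maximum(ks * p + phi, 0.0)
    hi = np.minimum(ks * p + phi + t, side)
    keep = hi - lo > 1e-12
    return np.stack([lo[keep], hi[keep]], axis=1)


def lattice_boxset(spec: LatticeSpec, cube_side_mm: float) -> BoxSet:
    """Exact box-cell representation of the lattice cube (mm)."""
    if spec.g_um == 0:
        return BoxSet.from_boxes([((0.0, 0.0, 0.0), (cube_side_mm,) * 3)])
    t = spec.t_um / UM_PER_MM
    p = spec.period_um / UM_PER_MM
    if cube_side_mm < 2.0 * p:
        raise DomainError(
            f"cube side {cube_side_mm} mm must cover at least two periods ({2 * p} mm)"
        )
    bands = _axis_bands(t, p, cube_side_mm)
    edges = np.unique(np.concatenate([[0.0, cube_side_mm], bands.ravel()]))
    edges = edges[(edges >= 0.0) & (edges <= cube_side_mm)]
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_band = np.any((centers[:, None] >= bands[None, :, 0]) &
                     (centers[:, None] < bands[None, :, 1]), axis=1)
    ax, ay, az = (in_band,) * 3
    two_of_three = (
        (ax[:, None, None] & ay[None, :, None])
        | (ax[:, None, None] & az[None, None, :])
        | (ay[None, :, None] & az[None, None, :])
    )
    return BoxSet(edges, edges, edges, two_of_three)


def build_lattice_mesh(spec: LatticeSpec, cube_side_mm: float) -> trimesh.Trimesh:
    """Watertight lattice-cube mesh (mm) with enclosed volume ``f * side^3``.

    Beams are clipped at the cube boundary so the outer faces are closed and
    the part is printable without protruding stubs.
    """
    bs = lattice_boxset(spec, cube_side_mm)
    mesh = bs.to_mesh(provenance=f"lattice {spec} side={cube_side_mm}mm")
    return mesh
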