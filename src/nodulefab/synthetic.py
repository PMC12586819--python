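"""Synthetic inputs: part-solid nodule volumes, reader responses, and the
published contingency-table fixtures.

Nothing here is downloaded: the nodule generator emulates a patient-style
part-solid nodule (solid core above 0 HU wrapped in concentric ground-glass
shells spanning 0 to -750 HU, plus noise) and the response generator
emulates a multi-reader blinded classification study with configurable
per-group sensitivity and specificity.  Both are fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .reader_stats import NEGATIVE, POSITIVE, RESPONSE_COLUMNS, ConfusionMatrix
from .volume import HUVolume, default_classes

__all__ = [
    "NoduleRecipe",
    "ResponseRecipe",
    "make_synthetic_nodule_volume",
    "make_synthetic_responses",
    "printed_count_fixtures",
]


@dataclass(frozen=True)
class NoduleRecipe:
    """Concentric-sphere part-solid nodule phantom recipe.

    Band mean HUs default to +150 / -150 / -400 / -625 (core, gg1, gg2, gg3)
    — inside both their class intervals and the HU ranges observed on
    patient part-solid nodules.  ``lobulation`` > 0 adds a low-order angular
    perturbation of the band radii for irregular, more lifelike outlines.
    """

    core_radius_mm: float = 2.0
    shell_outer_radii_mm: tuple = (3.0, 4.0, 5.0)
    band_mean_hu: tuple = (150.0, -150.0, -400.0, -625.0)
    noise_sd_hu: float = 0.0
    spacing_mm: float = 0.1
    margin_mm: float = 1.0
    lobulation: float = 0.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        radii = (self.core_radius_mm, *self.shell_outer_radii_mm)
        if len(self.shell_outer_radii_mm) != 3:
            raise ValidationError("exactly three shell outer radii are required")
        if any(b >= a for a, b in zip(radii[1:], radii[:-1])):
            raise ValidationError("radii must be strictly increasing")
        if len(self.band_mean_hu) != 4:
            raise ValidationError("four band mean HU values are required")
        if any(b >= a for a, b in zip(self.band_mean_hu[:-1], self.band_mean_hu[1:])):
            raise ValidationError("band means must be strictly decreasing core > gg1 > gg2 > gg3")
        for mean, spec in zip(self.band_mean_hu, default_classes()):
            if not spec.contains(np.array([mean]))[0]:
                raise ValidationError(
                    f"band mean {mean} HU lies outside its class {spec.name} "
                    f"({spec.lower}, {spec.upper})"
                )
        if self.noise_sd_hu < 0 or self.spacing_mm <= 0:
            raise ValidationError("noise_sd_hu must be >= 0 and spacing_mm > 0")


def make_synthetic_nodule_volume(recipe: NoduleRecipe) -> tuple[HUVolume, dict]:
    """Generate the nodule HU volume plus ground-truth per-band voxel volumes.

    Background is -1000 HU (air-like); each voxel inside a band gets the
    band's mean HU; seeded Gaussian noise is added on top.  Returns
    ``(volume, truth)`` where ``truth`` maps band name -> voxel-count volume
    in mm³ (before noise) and also records the voxel counts.
    """
    r_outer = recipe.shell_outer_radii_mm[-1]
    half = r_outer + recipe.margin_mm
    n = int(np.ceil(2 * half / recipe.spacing_mm))
    coords = (np.arange(n) + 0.5) * recipe.spacing_mm - half
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]
    r = np.sqrt(x * x + y * y + z * z)

    if recipe.lobulation > 0:
        # low-order angular modulation of all band radii (same shape factor)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(
                np.clip(np.divide(z, r, out=np.zeros_like(r), where=r > 0), -1, 1)
            )
            phi = np.arctan2(y, x)
        shape = 1.0 + recipe.lobulation * (
            0.5 * np.sin(2 * theta) * np.cos(2 * phi)
            + 0.3 * np.cos(3 * theta)
            + 0.2 * np.sin(2 * phi)
        )
        shape = np.where(r > 0, shape, 1.0)
        r = r / shape

    bounds = (recipe.core_radius_mm, *recipe.shell_outer_radii_mm)
    names = ("core", "gg1", "gg2", "gg3")
    data = np.full((n, n, n), -1000.0)
    truth = {"voxel_counts": {}, "band_volumes_mm3": {}}
    inner = 0.0
    voxvol = recipe.spacing_mm ** 3
    for name, mean, outer in zip(names, recipe.band_mean_hu, bounds):
        sel = (r >= inner) & (r < outer)
        data[sel] = mean
        truth["voxel_counts"][name] = int(sel.sum())
        truth["band_volumes_mm3"][name] = float(sel.sum()) * voxvol
        inner = outer

    if recipe.noise_sd_hu > 0:
        rng = np.random.default_rng(recipe.seed)
        data = data + rng.normal(0.0, recipe.noise_sd_hu, size=data.shape)

    origin = np.full(3, -half + 0.5 * recipe.spacing_mm)
    vol = HUVolume(np.clip(data, -1024.0, 3071.0), np.full(3, recipe.spacing_mm), origin)
    return vol, truth


@dataclass(frozen=True)
class ResponseRecipe:
    """Blinded reader-study response generator conditions.

    Defaults mirror the study design: 17 readers (5 senior, 12 residents),
    21 unique acquisitions (14 printed, 7 patient) presented 3 times each,
    i.e. 1071 responses.  Per-group sensitivity/specificity default to the
    near-chance operating points of the two experience groups; the Likert
    confidence distribution is mildly peaked at levels 2-3 (overall low
    confidence).
    """

    n_senior: int = 5
    n_resident: int = 12
    n_cases: int = 21
    n_printed_cases: int = 14
    presentations: int = 3
    sensitivity: dict = field(default_factory=lambda: {"senior": 0.424, "resident": 0.568})
    specificity: dict = field(default_factory=lambda: {"senior": 0.514, "resident": 0.571})
    confidence_probs: tuple = (0.15, 0.30, 0.30, 0.18, 0.07)
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_senior < 0 or self.n_resident < 0 or self.n_senior + self.n_resident == 0:
            raise ValidationError("at least one reader is required")
        if not 0 <= self.n_printed_cases <= self.n_cases:
            raise ValidationError("printed case count must be within the case count")
        for d in (self.sensitivity, self.specificity):
            for grp in ("senior", "resident"):
                if not 0.0 <= d[grp] <= 1.0:
                    raise ValidationError("sensitivity/specificity must be in [0, 1]")
        if abs(sum(self.confidence_probs) - 1.0) > 1e-9 or len(self.confidence_probs) != 5:
            raise ValidationError("confidence_probs must be 5 probabilities summing to 1")

    @property
    def n_readers(self) -> int:
        return self.n_senior + self.n_resident

    @property
    def n_responses(self) -> int:
        return self.n_readers * self.n_cases * self.presentations


def make_synthetic_responses(recipe: ResponseRecipe) -> pd.DataFrame:
    """Simulate the response table of a blinded reader study (seeded).

    Case truths are fixed (the first ``n_printed_cases`` cases are printed);
    every reader sees every case ``presentations`` times and calls it
    according to the group's sensitivity (printed cases) or specificity
    (patient cases); confidence is drawn from the recipe's distribution.
    """
    rng = np.random.default_rng(recipe.seed)
    rows = []
    readers = [(f"R{i+1:02d}", "senior") for i in range(recipe.n_senior)] + [
        (f"R{i+1+recipe.n_senior:02d}", "resident") for i in range(recipe.n_resident)
    ]
    truths = [POSITIVE] * recipe.n_printed_cases + [NEGATIVE] * (
        recipe.n_cases - recipe.n_printed_cases
    )
    levels = np.arange(1, 6)
    for reader_id, group in readers:
        sens = recipe.sensitivity[group]
        spec = recipe.specificity[group]
        for case_idx, truth in enumerate(truths):
            for pres in range(1, recipe.presentations + 1):
                u = rng.random()
                if truth == POSITIVE:
                    call = POSITIVE if u < sens else NEGATIVE
                else:
                    call = NEGATIVE if u < spec else POSITIVE
                conf = int(rng.choice(levels, p=recipe.confidence_probs))
                rows.append(
                    (reader_id, group, f"C{case_idx+1:02d}", pres, truth, call, conf)
                )
    df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    assert len(df) == recipe.n_responses
    return df


def printed_count_fixtures() -> dict[str, ConfusionMatrix]:
    """The published blinded-study contingency tables as fixtures.

    Returns overall / senior / resident confusion matrices and asserts the
    structural identities: senior + resident = overall cell by cell, and
    totals 1071 = 17 readers x 63 presentations, 315 = 5 x 63, 756 = 12 x 63.
    """
    overall = ConfusionMatrix(tp=375, fp=159, fn=339, tn=198)
    senior = ConfusionMatrix(tp=89, fp=51, fn=121, tn=54)
    resident = ConfusionMatrix(tp=286, fp=108, fn=218, tn=144)
    for attr in ("tp", "fp", "fn", "tn"):
        if getattr(senior, attr) + getattr(resident, attr) != getattr(overall, attr):
            raise DomainError(f"fixture cell {attr} violates senior + resident = overall")
    if (overall.total, senior.total, resident.total) != (1071, 315, 756):
        raise DomainError("fixture totals do not match 17/5/12 readers x 63 presentations")
    return {"overall": overall, "senior": senior, "resident": resident}
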