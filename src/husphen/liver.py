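"""Parametric and ordinal B-mode liver analysis.

Implements the region-of-interest (ROI) statistics used for the
hepatic-renal (HR) and hepatic-portal-vein (HPV) echogenicity ratios,
gray-level histogram (GLH) heterogeneity/anisotropy, portal-vein diameter
and the aggregation of operator-entered visual steatosis grades.

Conventions: the image origin is the top-left corner, the row index is the
depth direction (distance from the probe), pixel coordinates are 0-based,
and intensities are 8-bit arbitrary units (a.u.) in [0, 255].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateMeasurementError,
    DepthMismatchError,
    DomainError,
    GeometryError,
    IncompleteSetError,
    ResolutionError,
    ROIAreaError,
    ValidationError,
)

#: Imaging planes used by the liver protocol.
PLANES = (
    "left_lobe_long",
    "caudate_long",
    "right_median_axial",
    "liver_kidney_long",
    "portal_axial",
)

#: Planes entering the gray-level histogram analysis.
GLH_PLANES = ("left_lobe_long", "caudate_long", "right_median_axial")

#: Protocol ROI areas (mm^2) with their hard tolerances.
RATIO_ROI_AREA = (0.1, 0.02)
GLH_ROI_AREA = (1.0, 0.02)

#: Relative tolerance for depth matching of paired ROIs.
DEPTH_TOL = 0.10

MIN_ROI_PIXELS = 30

ECHOSTRUCTURE_LEVELS = (1, 2, 3, 4)
ECHOGENICITY_LEVELS = (0, 1, 2)
ASCITES_LEVELS = (0, 1)


@dataclass
class BModeImage:
    """An 8-bit grayscale B-mode frame with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D intensity grid, values in [0, 255] (a.u.).
    pixel_spacing
        Isotropic pixel size in mm/pixel.
    plane_label
        One of :data:`PLANES`, or ``None`` for synthetic phantoms.
    masks
        Optional named boolean region masks (same shape as ``pixels``).
    """

    pixels: np.ndarray
    pixel_spacing: float
    plane_label: str | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D grid")
        if self.pixel_spacing <= 0:
            raise ValidationError("pixel_spacing must be > 0")
        lo, hi = float(self.pixels.min(initial=0)), float(self.pixels.max(initial=0))
        if lo < 0 or hi > 255:
            raise ValidationError(f"intensities outside [0, 255]: [{lo}, {hi}]")
        if self.plane_label is not None and self.plane_label not in PLANES:
            raise ValidationError(f"unknown plane_label {self.plane_label!r}")
        for name, mask in self.masks.items():
            if np.shape(mask) != self.pixels.shape:
                raise ValidationError(f"mask {name!r} shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROISpec:
    """A circular ROI given by its center (row, col) and area in mm^2."""

    center: tuple[float, float]
    area_mm2: float
    shape: str = "circle"

    def __post_init__(self) -> None:
        if self.shape != "circle":
            raise ValidationError("only circular ROIs are supported")
        if self.area_mm2 <= 0:
            raise ValidationError("ROI area must be > 0")

    def radius_px(self, pixel_spacing: float) -> float:
        return math.sqrt(self.area_mm2 / math.pi) / pixel_spacing

    def depth_mm(self, pixel_spacing: float) -> float:
        """Distance of the ROI center from the probe (top image edge)."""
        return self.center[0] * pixel_spacing

    def mask(self, image: BModeImage) -> np.ndarray:
        r = self.radius_px(image.pixel_spacing)
        cr, cc = self.center
        nr, nc = image.shape
        if cr - r < -0.5 or cc - r < -0.5 or cr + r > nr - 0.5 or cc + r > nc - 0.5:
            raise GeometryError("ROI clipped by the image border")
        rows = np.arange(nr)[:, None]
        cols = np.arange(nc)[None, :]
        return (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2


@dataclass(frozen=True)
class RoiStats:
    mean: float
    sd: float
    n_pixels: int


@dataclass(frozen=True)
class GLHResult:
    """Gray-level histogram summary over the three protocol planes."""

    glh_means: dict[str, float]
    heterogeneity: float
    anisotropy: float


@dataclass(frozen=True)
class VisualGrade:
    """Operator-entered HFUS visual grading of the liver."""

    echostructure: int
    echogenicity_vs_cortex: int
    ascites: int

    def __post_init__(self) -> None:
        if self.echostructure not in ECHOSTRUCTURE_LEVELS:
            raise ValidationError("echostructure must be in 1-4")
        if self.echogenicity_vs_cortex not in ECHOGENICITY_LEVELS:
            raise ValidationError("echogenicity_vs_cortex must be in 0-2")
        if self.ascites not in ASCITES_LEVELS:
            raise ValidationError("ascites must be 0 or 1")


def roi_stats(image: BModeImage, roi: ROISpec) -> RoiStats:
    """Arithmetic mean and population SD of intensities under a circular ROI."""
    mask = roi.mask(image)
    n = int(mask.sum())
    if n < MIN_ROI_PIXELS:
        raise ResolutionError(f"ROI covers {n} px < {MIN_ROI_PIXELS}")
    vals = image.pixels[mask].astype(float)
    return RoiStats(float(vals.mean()), float(vals.std(ddof=0)), n)


def _check_area(roi: ROISpec, nominal: tuple[float, float], name: str) -> None:
    target, tol = nominal
    if abs(roi.area_mm2 - target) > tol + 1e-12:
        raise ROIAreaError(
            f"{name} ROI area {roi.area_mm2} mm^2 outside {target} +/- {tol} mm^2"
        )


def _check_depth(image: BModeImage, a: ROISpec, b: ROISpec) -> None:
    da, db = a.depth_mm(image.pixel_spacing), b.depth_mm(image.pixel_spacing)
    if abs(da - db) > DEPTH_TOL * max(da, db):
        raise DepthMismatchError(
            f"ROI depths {da:.2f} and {db:.2f} mm differ by more than "
            f"{DEPTH_TOL:.0%} of depth"
        )


def hepatic_renal_ratio(
    image: BModeImage, liver_roi: ROISpec, cortex_roi: ROISpec
) -> float:
    """Mean liver ROI gray level divided by the renal-cortex ROI gray level.

    Both ROIs must honor the 0.1 +/- 0.02 mm^2 protocol area and sit at the
    same distance from the probe (within 10% of depth).
    """
    _check_area(liver_roi, RATIO_ROI_AREA, "liver")
    _check_area(cortex_roi, RATIO_ROI_AREA, "renal-cortex")
    _check_depth(image, liver_roi, cortex_roi)
    liver = roi_stats(image, liver_roi)
    cortex = roi_stats(image, cortex_roi)
    if cortex.mean == 0:
        raise DomainError("renal-cortex ROI mean is zero")
    return liver.mean / cortex.mean


def hepatic_portal_ratio(
    image: BModeImage, liver_roi: ROISpec, pv_roi: ROISpec
) -> float:
    """Liver echogenicity normalized to blood within the portal-vein lumen."""
    _check_area(liver_roi, RATIO_ROI_AREA, "liver")
    _check_area(pv_roi, RATIO_ROI_AREA, "portal-vein")
    _check_depth(image, liver_roi, pv_roi)
    liver = roi_stats(image, liver_roi)
    pv = roi_stats(image, pv_roi)
    if pv.mean == 0:
        raise DomainError("portal-vein ROI mean is zero")
    return liver.mean / pv.mean


def glh_analysis(
    images: dict[str, BModeImage], rois: dict[str, ROISpec]
) -> GLHResult:
    """Gray-level histogram analysis over the three liver scanning planes.

    Returns the per-plane ROI means (echogenicity), the within-ROI SD of the
    right-median axial plane (tissue heterogeneity) and the population SD of
    the three plane means (anisotropy).
    """
    missing = [p for p in GLH_PLANES if p not in images or p not in rois]
    if missing:
        raise IncompleteSetError(f"missing plane(s): {', '.join(missing)}")
    means: dict[str, float] = {}
    heterogeneity = math.nan
    for plane in GLH_PLANES:
        _check_area(rois[plane], GLH_ROI_AREA, plane)
        stats = roi_stats(images[plane], rois[plane])
        means[plane] = stats.mean
        if plane == "right_median_axial":
            heterogeneity = stats.sd
    anisotropy = float(np.std(list(means.values()), ddof=0))
    return GLHResult(means, heterogeneity, anisotropy)


def pv_diameter(
    image: BModeImage,
    p1: tuple[float, float],
    p2: tuple[float, float],
) -> float:
    """Portal-vein diameter (mm) between two caliper endpoints in pixels."""
    nr, nc = image.shape
    for p in (p1, p2):
        if not (0 <= p[0] <= nr - 1 and 0 <= p[1] <= nc - 1):
            raise GeometryError(f"endpoint {p} outside the image")
    dist = math.hypot(p1[0] - p2[0], p1[1] - p2[1])
    if dist == 0:
        raise DegenerateMeasurementError("coincident caliper endpoints")
    return dist * image.pixel_spacing


_GRADE_LEVELS = {
    "echostructure": ECHOSTRUCTURE_LEVELS,
    "echogenicity_vs_cortex": ECHOGENICITY_LEVELS,
    "ascites": ASCITES_LEVELS,
}


def grade_frequency_table(
    grades: pd.DataFrame,
    group_cols: list[str] | tuple[str, ...] = ("sex", "diet", "age_weeks"),
) -> pd.DataFrame:
    """Per-group counts and percentages of each visual-grade level.

    ``grades`` holds one row per mouse with the grade columns
    ``echostructure``, ``echogenicity_vs_cortex`` and ``ascites`` plus the
    grouping columns. Percentages are over the group n; for an empty group
    they are returned as NaN (flagged undefined).
    """
    group_cols = list(group_cols)
    for col, levels in _GRADE_LEVELS.items():
        if col not in grades.columns:
            raise ValidationError(f"missing grade column {col!r}")
        bad = set(grades[col].dropna()) - set(levels)
        if bad:
            raise ValidationError(f"out-of-vocabulary {col} value(s): {sorted(bad)}")
    rows = []
    for key, sub in grades.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(sub)
        for col, levels in _GRADE_LEVELS.items():
            for level in levels:
                count = int((sub[col] == level).sum())
                pct = 100.0 * count / n if n else math.nan
                rows.append(
                    dict(zip(group_cols, key))
                    | {"grade": col, "level": level, "count": count, "n": n,
                       "percent": pct}
                )
    return pd.DataFrame(rows)
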