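"""Cavalieri-principle tissue and cavity volumetry from serial coronal sections.

The Cavalieri estimator of a solid's volume is the inter-section spacing
times the sum of cross-sectional areas measured on equally spaced parallel
sections: V = d * sum_i A_i.  Here areas come from pixel-counting on
color-classified HES brightfield images: stained tissue is separated from
the near-white slide in HSV space, and the lesion cavity is the background
region fully enclosed by tissue.  Technical replicates at a bregma level are
averaged before the sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import closing, disk, remove_small_objects

from .fixtures import DEFAULT_LEVELS_MM
from .image_io import SectionImage

__all__ = [
    "SectioningScheme",
    "AreaMeasurement",
    "VolumeEstimate",
    "classify_tissue",
    "find_cavity",
    "measure_areas",
    "cavalieri_volume",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SectioningScheme:
    """Equally spaced coronal sampling scheme in bregma coordinates (mm)."""

    levels_mm: tuple = DEFAULT_LEVELS_MM
    sections_per_level: int = 10

    def __post_init__(self) -> None:
        self.levels_mm = tuple(float(v) for v in self.levels_mm)
        if self.sections_per_level < 1:
            raise ValueError("sections_per_level must be >= 1")
        if len(self.levels_mm) > 1:
            diffs = np.diff(self.levels_mm)
            if not np.allclose(diffs, diffs[0], atol=1e-9) or diffs[0] >= 0:
                raise ValueError("levels must be strictly decreasing and equally spaced")

    @property
    def spacing_mm(self) -> float:
        if len(self.levels_mm) < 2:
            raise ValueError("spacing undefined for a single-level scheme")
        return float(abs(self.levels_mm[1] - self.levels_mm[0]))


@dataclass
class AreaMeasurement:
    """Tissue and cavity areas (mm^2) of one section at one bregma level."""

    level_mm: float
    tissue_area_mm2: float
    cavity_area_mm2: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for v in (self.tissue_area_mm2, self.cavity_area_mm2):
            if not np.isfinite(v) or v < 0:
                raise ValueError("areas must be finite and non-negative")


@dataclass
class VolumeEstimate:
    """Cavalieri volumes (mm^3) for one animal."""

    tissue_volume_mm3: float
    cavity_volume_mm3: float
    n_levels_used: int
    per_level_mean_areas: dict = field(default_factory=dict)


def classify_tissue(
    img: SectionImage,
    s_min: float = 0.08,
    v_min: float = 0.85,
    min_speck_px: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Split an RGB brightfield section into tissue and background masks.

    Background is the near-white slide: saturation below ``s_min`` AND
    brightness above ``v_min`` in HSV space.  Everything else is stained
    tissue, after connected specks smaller than ``min_speck_px`` are removed
    (returned to background).
    """
    if not img.is_rgb:
        raise ValueError("classify_tissue requires an RGB image")
    hsv = rgb2hsv(img.pixels)
    background = (hsv[..., 1] < s_min) & (hsv[..., 2] > v_min)
    tissue = ~background
    if min_speck_px > 0 and tissue.any():
        # max_size removes objects <= its value; "smaller than min_speck_px" = <= min_speck_px - 1
        tissue = remove_small_objects(tissue, max_size=min_speck_px - 1, connectivity=2)
    return tissue, ~tissue


def find_cavity(tissue_mask: np.ndarray, close_radius_px: int = 0) -> np.ndarray:
    """Background regions fully enclosed by tissue (the lesion cavity).

    A cavity is any background 8-connected component with no path to the
    raster border.  With ``close_radius_px > 0`` the tissue silhouette is
    morphologically closed first, so a cavity that breaches the tissue edge
    through a narrow channel is still captured; the returned cavity pixels
    are always disjoint from the original tissue mask.
    """
    tissue = np.asarray(tissue_mask, dtype=bool)
    silhouette = tissue
    if close_radius_px > 0:
        silhouette = closing(tissue, footprint=disk(close_radius_px))
    filled = ndimage.binary_fill_holes(silhouette, structure=_STRUCT8)
    return filled & ~tissue


def measure_areas(
    tissue_mask: np.ndarray,
    cavity_mask: np.ndarray,
    pixel_size_um: float | None,
    level_mm: float = 0.0,
    replicate: int = 1,
) -> AreaMeasurement:
    """Pixel-counting areas: area_mm2 = n_pixels * (pixel_size_um / 1000)^2."""
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be given and positive; never assumed")
    if tissue_mask.shape != cavity_mask.shape:
        raise ValueError("masks must share shape")
    if bool(np.any(np.asarray(tissue_mask, bool) & np.asarray(cavity_mask, bool))):
        raise ValueError("tissue and cavity masks must be disjoint")
    px_area = (pixel_size_um / 1000.0) ** 2
    return AreaMeasurement(
        level_mm=level_mm,
        tissue_area_mm2=float(np.count_nonzero(tissue_mask)) * px_area,
        cavity_area_mm2=float(np.count_nonzero(cavity_mask)) * px_area,
        replicate=replicate,
    )


def cavalieri_volume(
    measurements: list[AreaMeasurement], scheme: SectioningScheme
) -> VolumeEstimate:
    """Cavalieri estimate: spacing times the sum of per-level mean areas.

    Replicate sections at the same level are averaged first; tissue and
    cavity volumes are computed independently.  Every measured level must
    belong to the scheme.
    """
    if not measurements:
        raise ValueError("at least one area measurement is required")
    scheme_levels = set(scheme.levels_mm)
    by_level: dict = {}
    for m in measurements:
        lv = float(m.level_mm)
        if not any(abs(lv - s) < 1e-9 for s in scheme_levels):
            raise ValueError(f"level {lv} mm is not part of the sectioning scheme")
        by_level.setdefault(lv, []).append(m)
    d = scheme.spacing_mm
    per_level = {
        lv: (
            float(np.mean([m.tissue_area_mm2 for m in ms])),
            float(np.mean([m.cavity_area_mm2 for m in ms])),
        )
        for lv, ms in by_level.items()
    }
    tissue_v = d * sum(t for t, _ in per_level.values())
    cavity_v = d * sum(c for _, c in per_level.values())
    return VolumeEstimate(
        tissue_volume_mm3=tissue_v,
        cavity_volume_mm3=cavity_v,
        n_levels_used=len(per_level),
        per_level_mean_areas=per_level,
    )
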