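"""Synthetic phantoms and cohort designs with exact ground truth.

Every downstream stage (stitching, segmentation, volumetry, statistics) is
exercised on images generated here, where the true cell count, centroid set,
and tissue/cavity areas are known by construction.  Generators are pure
functions of their parameters and seed: reruns are bit-identical.

Fluorescence phantoms emulate nuclear/immunomarker stains as isotropic
Gaussian intensity blobs on a noisy background; HES phantoms emulate
eosin-pink tissue on a near-white slide with an optional enclosed lesion
cavity.  Neither attempts photorealism — they provide analytically known
truth, not texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import SectionImage

__all__ = [
    "FluorPhantom",
    "HesPhantom",
    "CohortDesign",
    "PlacementError",
    "make_fluor_phantom",
    "make_hes_phantom",
    "make_cohort",
    "write_phantom",
    "write_cohort",
    "DEFAULT_LEVELS_MM",
]

#: Default coronal sectioning span: six equally spaced bregma levels from
#: +1 mm anterior to -4 mm posterior, 1 mm apart.
DEFAULT_LEVELS_MM = (1.0, 0.0, -1.0, -2.0, -3.0, -4.0)

_GROUP_LABELS = ("B", "RvD1", "S")


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed at the requested
    separation inside the raster (capacity exceeded)."""


@dataclass
class FluorPhantom:
    """Synthetic single-channel fluorescence image with known nuclei."""

    image: SectionImage
    truth_centroids: list
    channel: str
    params: dict = field(default_factory=dict)

    @property
    def truth_count(self) -> int:
        return len(self.truth_centroids)

    def __post_init__(self) -> None:
        h, w = self.image.pixels.shape
        for r, c in self.truth_centroids:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"centroid ({r}, {c}) outside raster bounds {h}x{w}")


@dataclass
class HesPhantom:
    """Synthetic RGB brightfield section with known tissue and cavity areas.

    ``truth_*`` fields record the *rasterized* (pixel-counted) areas, not the
    analytic request — what a pixel-counting area measurement should recover
    exactly.
    """

    image: SectionImage
    truth_tissue_area_mm2: float
    truth_cavity_area_mm2: float
    pixel_size_um: float
    truth_tissue_px: int = 0
    truth_cavity_px: int = 0


@dataclass
class CohortDesign:
    """Study-design table: animals, groups, sectioning scheme, attrition."""

    animals: list  # of (animal_id, group) tuples
    levels: tuple = DEFAULT_LEVELS_MM
    sections_per_level: int = 10
    attrition: int = 0

    def __post_init__(self) -> None:
        if self.sections_per_level < 1:
            raise ValueError("sections_per_level must be >= 1")
        diffs = np.diff(self.levels)
        if len(self.levels) > 1 and not np.all(diffs < 0):
            raise ValueError("levels must be strictly decreasing anterior -> posterior")

    def group_sizes(self) -> dict:
        sizes: dict = {}
        for _, g in self.animals:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        """Long table with one row per (animal, level, replicate)."""
        rows = [
            {"animal_id": a, "group": g, "level_mm": lv, "replicate": rep}
            for a, g in self.animals
            for lv in self.levels
            for rep in range(1, self.sections_per_level + 1)
        ]
        return pd.DataFrame(rows)


def make_fluor_phantom(
    n_cells: int,
    min_separation_px: float = 24.0,
    overlap_fraction: float = 0.0,
    bit_depth: int = 12,
    noise_sd: float = 20.0,
    seed: int = 0,
    shape: tuple = (1024, 1024),
    blob_radius_px: float = 6.0,
    background: float | None = None,
    amplitude: float | None = None,
    channel: str = "nuclear",
    pixel_size_um: float = 0.65,
    poisson_noise: bool = False,
) -> FluorPhantom:
    """Generate a fluorescence phantom of Gaussian blobs on a noisy background.

    With ``overlap_fraction == 0`` every pairwise centroid distance is at
    least ``min_separation_px``; a positive fraction places that share of the
    cells deliberately close to (touching) an already-placed neighbour.  Blob
    amplitude defaults to 10x the noise SD above background so that
    well-separated blobs are exactly recoverable by thresholding.

    Raises
    ------
    PlacementError
        If the raster cannot hold ``n_cells`` at the requested separation
        (explicit capacity error, never silent truncation).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    vmax = 2**bit_depth - 1
    if background is None:
        background = 0.05 * vmax
    if amplitude is None:
        amplitude = max(10.0 * noise_sd, 0.4 * vmax)

    rng = np.random.default_rng(seed)
    h, w = shape
    margin = int(np.ceil(2 * blob_radius_px)) + 1
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError(f"raster {shape} too small for blob radius {blob_radius_px}")

    n_overlap = int(round(overlap_fraction * n_cells))
    n_separated = n_cells - n_overlap

    centroids: list = []
    max_attempts = 5000 * max(n_cells, 1)
    attempts = 0
    while len(centroids) < n_separated:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n_separated} cells at separation "
                f"{min_separation_px} px in a {h}x{w} raster"
            )
        attempts += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_separation_px**2 for rr, cc in centroids):
            centroids.append((r, c))

    # overlapping cells: drop each next to a random already-placed one,
    # roughly one blob radius away so the pair merges into one touching clump
    for _ in range(n_overlap):
        if not centroids:
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            centroids.append((r, c))
            continue
        anchor = centroids[rng.integers(len(centroids))]
        theta = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(1.0, 1.6) * blob_radius_px
        r = float(np.clip(anchor[0] + d * np.sin(theta), margin, h - margin))
        c = float(np.clip(anchor[1] + d * np.cos(theta), margin, w - margin))
        centroids.append((r, c))

    img = np.full(shape, float(background))
    sigma = blob_radius_px / 2.0
    half = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    for r, c in centroids:
        ri, ci = int(round(r)), int(round(c))
        dy, dx = r - ri, c - ci
        blob = amplitude * np.exp(-(((yy - dy) ** 2 + (xx - dx) ** 2) / (2 * sigma**2)))
        y0, y1 = max(0, ri - half), min(h, ri + half + 1)
        x0, x1 = max(0, ci - half), min(w, ci + half + 1)
        img[y0:y1, x0:x1] += blob[
            y0 - (ri - half) : y1 - (ri - half), x0 - (ci - half) : x1 - (ci - half)
        ]

    if poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(np.round(img), 0, vmax)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    section = SectionImage(
        pixels=img.astype(dtype),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        channel=channel,
    )
    params = {
        "n_cells": n_cells,
        "min_separation_px": min_separation_px,
        "overlap_fraction": overlap_fraction,
        "bit_depth": bit_depth,
        "noise_sd": noise_sd,
        "seed": seed,
        "blob_radius_px": blob_radius_px,
        "background": background,
        "amplitude": amplitude,
        "poisson_noise": poisson_noise,
    }
    return FluorPhantom(image=section, truth_centroids=centroids, channel=channel, params=params)


# HES phantom colors: eosin-pink tissue on a near-white slide
_TISSUE_RGB = (230, 120, 150)
_BACKGROUND_RGB = (248, 246, 244)


def make_hes_phantom(
    shape: str = "disk",
    tissue_area_mm2: float = 1.0,
    cavity_area_mm2: float = 0.0,
    pixel_size_um: float = 10.0,
    open_cavity: bool = False,
    raster_shape: tuple = (512, 512),
) -> HesPhantom:
    """Generate an RGB brightfield phantom with known tissue and cavity areas.

    ``shape`` selects the footprint: ``disk`` and ``cylinder-slice`` draw a
    filled disk (a cylinder's constant cross-section), ``annulus`` requires a
    positive cavity area and centres it as an enclosed hole.  With
    ``open_cavity`` the cavity is breached to the footprint edge by a thin
    channel, emulating a lesion that reaches the cortical surface.

    Truth areas are the rasterized pixel tallies converted to mm^2 — exactly
    what pixel counting on the image should return.
    """
    if tissue_area_mm2 < 0 or cavity_area_mm2 < 0:
        raise ValueError("areas must be non-negative")
    if shape not in ("disk", "annulus", "cylinder-slice"):
        raise ValueError(f"unknown shape {shape!r}")
    if shape == "annulus" and cavity_area_mm2 <= 0:
        raise ValueError("annulus requires a positive cavity area")
    if cavity_area_mm2 > 0 and cavity_area_mm2 >= tissue_area_mm2 + cavity_area_mm2:
        raise ValueError("cavity larger than the tissue footprint")

    px_mm = pixel_size_um / 1000.0
    px_area_mm2 = px_mm * px_mm
    footprint_mm2 = tissue_area_mm2 + cavity_area_mm2
    r_outer_px = np.sqrt(footprint_mm2 / np.pi) / px_mm
    r_inner_px = np.sqrt(cavity_area_mm2 / np.pi) / px_mm if cavity_area_mm2 > 0 else 0.0

    h, w = raster_shape
    if r_outer_px + 2 > min(h, w) / 2:
        raise ValueError(
            f"requested footprint ({footprint_mm2:.3g} mm^2 -> radius {r_outer_px:.0f} px) "
            f"does not fit a {h}x{w} raster at {pixel_size_um} um/px"
        )
    if cavity_area_mm2 > 0 and r_outer_px - r_inner_px < 2:
        raise ValueError("cavity leaves less than a 2-px tissue rim; enlarge the footprint")

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    footprint = d2 <= r_outer_px**2
    cavity = d2 <= r_inner_px**2 if r_inner_px > 0 else np.zeros_like(footprint)

    if open_cavity and cavity.any():
        # carve a 3-px channel from the cavity straight up through the rim
        ch_half = 1
        x0, x1 = int(cx) - ch_half, int(cx) + ch_half + 1
        top = int(np.ceil(cy - r_outer_px)) - 1
        cavity_top = int(np.ceil(cy - r_inner_px))
        cavity = cavity.copy()
        cavity[max(top, 0) : cavity_top, x0:x1] |= footprint[max(top, 0) : cavity_top, x0:x1]

    tissue = footprint & ~cavity
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[:] = _BACKGROUND_RGB
    rgb[tissue] = _TISSUE_RGB

    tissue_px = int(tissue.sum())
    cavity_px = int(cavity.sum())
    section = SectionImage(pixels=rgb, bit_depth=8, pixel_size_um=pixel_size_um, channel="HES")
    return HesPhantom(
        image=section,
        truth_tissue_area_mm2=tissue_px * px_area_mm2,
        truth_cavity_area_mm2=cavity_px * px_area_mm2,
        pixel_size_um=pixel_size_um,
        truth_tissue_px=tissue_px,
        truth_cavity_px=cavity_px,
    )


def make_cohort(
    n_operated: int = 25,
    n_deaths: int = 1,
    n_groups: int = 3,
    seed: int = 0,
    group_labels: tuple = _GROUP_LABELS,
    levels: tuple = DEFAULT_LEVELS_MM,
    sections_per_level: int = 10,
    equal_division: bool = True,
) -> CohortDesign:
    """Randomly divide surviving animals into treatment groups.

    Emulates the study design: operated animals minus surgical attrition are
    assigned exhaustively and disjointly to groups.  With ``equal_division``
    the survivor count must divide evenly (the default 25 - 1 = 24 animals
    into 3 groups of 8).
    """
    survivors = n_operated - n_deaths
    if survivors < n_groups:
        raise ValueError("fewer survivors than groups")
    if equal_division and survivors % n_groups != 0:
        raise ValueError(
            f"{survivors} survivors are not evenly divisible into {n_groups} groups"
        )
    if len(group_labels) < n_groups:
        group_labels = tuple(group_labels) + tuple(
            f"G{i}" for i in range(len(group_labels) + 1, n_groups + 1)
        )
    rng = np.random.default_rng(seed)
    ids = [f"A{i:02d}" for i in range(1, survivors + 1)]
    order = rng.permutation(survivors)
    per = survivors // n_groups
    extra = survivors % n_groups
    animals = []
    pos = 0
    for gi in range(n_groups):
        size = per + (1 if gi < extra else 0)
        for k in order[pos : pos + size]:
            animals.append((ids[k], group_labels[gi]))
        pos += size
    animals.sort()
    return CohortDesign(
        animals=animals,
        levels=tuple(levels),
        sections_per_level=sections_per_level,
        attrition=n_deaths,
    )


def write_phantom(phantom, out_dir, stem: str) -> tuple:
    """Write a phantom as TIFF plus a sidecar ground-truth CSV.

    Fluorescence phantoms get one truth row per object (centroids);
    HES phantoms get one row with tissue/cavity areas.
    """
    from .image_io import write_tiff

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = write_tiff(phantom.image, out_dir / f"{stem}.tif")
    csv_path = out_dir / f"{stem}_truth.csv"
    if isinstance(phantom, FluorPhantom):
        pd.DataFrame(
            [{"object": i + 1, "row": r, "col": c} for i, (r, c) in enumerate(phantom.truth_centroids)]
        ).to_csv(csv_path, index=False)
    else:
        pd.DataFrame(
            [
                {
                    "tissue_area_mm2": phantom.truth_tissue_area_mm2,
                    "cavity_area_mm2": phantom.truth_cavity_area_mm2,
                    "pixel_size_um": phantom.pixel_size_um,
                }
            ]
        ).to_csv(csv_path, index=False)
    return tiff_path, csv_path


def write_cohort(design: CohortDesign, path) -> Path:
    """Write the cohort as CSV (animal_id, group, level, replicate)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    design.to_frame().to_csv(path, index=False)
    return path
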