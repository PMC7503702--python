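"""Nuclei detection: threshold, binarize, and extract particle centroids.

Mirrors the common fluorescence workflow of thresholding a nuclei channel
and running a particle analyzer on the binary mask: connected components,
an area filter, and per-particle centroids in physical units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .geometry import BinaryImage, FieldGeometry, PointPattern

__all__ = ["DetectionParams", "DetectionResult", "binarize", "detect_particles"]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholding and particle-filter settings.

    Defaults: Otsu threshold, 8-connectivity (the particle-analysis
    convention), no area filter, border-touching particles kept (tiled
    whole-substrate imaging means discarding them would bias counts).
    """

    threshold_method: str = "otsu"
    fixed_threshold: float = 0.5
    min_area: float = 0.0  # µm²
    max_area: float = np.inf  # µm²
    connectivity: int = 8
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.threshold_method not in {"otsu", "fixed"}:
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if not (0.0 <= self.fixed_threshold <= 1.0):
            raise ValueError("fixed_threshold must lie in [0, 1]")
        if self.min_area > self.max_area:
            raise ValueError("min_area must not exceed max_area")
        if self.connectivity not in {4, 8}:
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class DetectionResult:
    """Detected nuclei: centroid pattern, particle areas, summary density."""

    pattern: PointPattern
    particle_areas: np.ndarray  # µm² per particle
    n_cells: int
    mean_density: float  # cells per mm²

    def to_csv(self, path: str | Path) -> None:
        df = self.pattern.to_dataframe()
        df["area_um2"] = self.particle_areas
        df.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {"n_cells": self.n_cells, "mean_density_per_mm2": self.mean_density}

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2))


def binarize(image: np.ndarray, params: DetectionParams, pixel_size: float = 1.0) -> BinaryImage:
    """Threshold a grayscale image (values in [0, 1]) to a binary mask.

    With ``method='otsu'`` the threshold is computed from the image
    histogram; a constant image has no foreground/background split and
    yields an all-false mask with a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    if params.threshold_method == "otsu":
        if np.ptp(image) == 0:
            warnings.warn("constant image: Otsu threshold undefined, no foreground")
            return BinaryImage(np.zeros_like(image, dtype=bool), pixel_size)
        thr = threshold_otsu(image)
        # Otsu returns a value strictly between the two modes of a
        # two-level image; >= keeps the upper mode as foreground.
        mask = image >= thr
        if params.fixed_threshold is not None and not mask.any():
            mask = image > thr
    else:
        mask = image >= params.fixed_threshold
    return BinaryImage(mask, pixel_size)


def detect_particles(mask: BinaryImage, params: DetectionParams | None = None) -> DetectionResult:
    """Connected-component particle analysis of a binary nuclei mask.

    Components are found under the configured connectivity, filtered by
    area in µm², and reduced to centroids (arithmetic mean of member pixel
    centres, converted to µm).  An empty mask yields zero particles.
    """
    params = params or DetectionParams()
    ps = mask.pixel_size
    lab = label(mask.pixels, connectivity=1 if params.connectivity == 4 else 2)
    centroids = []
    areas = []
    ny, nx = mask.pixels.shape
    for region in regionprops(lab):
        area_um2 = region.area * ps**2
        if not (params.min_area <= area_um2 <= params.max_area):
            continue
        if params.exclude_border:
            r0, c0, r1, c1 = region.bbox
            if r0 == 0 or c0 == 0 or r1 == ny or c1 == nx:
                continue
        ci, cj = region.centroid  # row, col in pixel indices
        centroids.append(((cj + 0.5) * ps, (ci + 0.5) * ps))
        areas.append(area_um2)
    field = mask.field()
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    # pixel-centre convention can place a centroid marginally past the
    # field edge for border-touching particles; clamp to the field
    if len(pts):
        pts[:, 0] = np.clip(pts[:, 0], 0.0, field.width)
        pts[:, 1] = np.clip(pts[:, 1], 0.0, field.height)
    pattern = PointPattern(pts, field)
    n = len(pts)
    return DetectionResult(
        pattern=pattern,
        particle_areas=np.asarray(areas, dtype=float),
        n_cells=n,
        mean_density=n / field.area_mm2,
    )
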