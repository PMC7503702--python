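"""Core spatial containers: field geometry, point patterns, binary rasters.

Coordinates are continuous micrometres with the origin at the top-left
corner of the field, x increasing rightward and y downward (image
convention).  Raster pixel (i, j) — row i, column j, 0-based — has its
centre at ((j + 0.5) * pixel_size, (i + 0.5) * pixel_size).  One stated
convention prevents half-pixel drift between modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FieldGeometry:
    """Rectangular observation field in physical units.

    Parameters
    ----------
    width, height : float
        Field extent in µm; must be positive.
    pixel_size : float
        Edge length of a raster pixel in µm; must be positive.
    """

    width: float
    height: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field width and height must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster grid shape (rows, cols) covering the field."""
        return (
            math.ceil(self.height / self.pixel_size),
            math.ceil(self.width / self.pixel_size),
        )

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6


@dataclass
class PointPattern:
    """Positions of cell nuclei within a field.

    Attributes
    ----------
    points : (n, 2) float array
        (x, y) coordinates in µm, inside ``[0, width] × [0, height]``.
    field : FieldGeometry
    labels : (n,) int array, optional
        Ground-truth cluster id per point (synthetic patterns only).
    """

    points: np.ndarray
    field: FieldGeometry
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
            if len(self.labels) != len(self.points):
                raise ValueError("labels must match points in length")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (
                x.min() < 0
                or y.min() < 0
                or x.max() > self.field.width
                or y.max() > self.field.height
            ):
                raise ValueError("points must lie inside the field")

    @property
    def n(self) -> int:
        return len(self.points)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["x_um", "y_um"])
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, field: FieldGeometry | None = None) -> "PointPattern":
        """Read a ``x_um,y_um[,label]`` CSV.

        When *field* is omitted, a bounding field with 1 µm pixels is
        inferred from the coordinate extent.
        """
        df = pd.read_csv(path)
        if not {"x_um", "y_um"} <= set(df.columns):
            raise ValueError("CSV must have x_um and y_um columns")
        pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if field is None:
            w = float(pts[:, 0].max()) if len(pts) else 1.0
            h = float(pts[:, 1].max()) if len(pts) else 1.0
            field = FieldGeometry(max(w, 1e-9), max(h, 1e-9), 1.0)
        labels = df["label"].to_numpy(dtype=int) if "label" in df.columns else None
        return cls(pts, field, labels)


@dataclass
class BinaryImage:
    """2-D boolean raster with physical pixel size (row 0 = top)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def fill_fraction(self) -> float:
        """Fraction of foreground (true) pixels, in [0, 1]."""
        return float(self.pixels.mean())

    def field(self) -> FieldGeometry:
        ny, nx = self.pixels.shape
        return FieldGeometry(nx * self.pixel_size, ny * self.pixel_size, self.pixel_size)

    def save(self, path: str | Path) -> None:
        """Write as single-channel 8-bit (0/255) TIFF or PNG by extension."""
        arr = (self.pixels.astype(np.uint8)) * 255
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            tifffile.imwrite(path, arr)
        else:
            from PIL import Image

            Image.fromarray(arr, mode="L").save(path)

    @classmethod
    def load(cls, path: str | Path, pixel_size: float, threshold: float = 0.5) -> "BinaryImage":
        arr = read_grayscale(path)
        return cls(arr >= threshold, pixel_size)


def read_grayscale(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit single-channel TIFF/PNG as floats in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse an accidental channel axis
        arr = arr[..., 0]
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return arr
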