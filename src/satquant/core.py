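"""Shared containers and error types.

Conventions used throughout the package:

* Images are 2D rasters indexed ``[row, col]``. Physical coordinates are
  continuous micrometres with the origin at the image corner; the centre of
  pixel ``(i, j)`` sits at ``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)``
  expressed as ``(x, y)``.
* All object centroids, track positions and distances are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile


class SatquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SatquantError, ValueError):
    """A parameter value violates a precondition."""


class InvalidGeometryError(SatquantError, ValueError):
    """An ROI or mask does not fit the image geometry."""


class InsufficientDataError(SatquantError, ValueError):
    """Not enough data points to perform the requested computation."""


class UndefinedCorrelationError(SatquantError, ValueError):
    """Correlation undefined because one channel has zero variance."""


class NormalizationError(SatquantError, ValueError):
    """Sample pair overlap too small for mode normalization."""


class ImputationError(SatquantError, ValueError):
    """Imputation impossible (no or constant observed values)."""


@dataclass
class PixelImage:
    """2D intensity raster with a physical pixel size.

    Parameters
    ----------
    values : ndarray
        Intensity raster, shape ``(rows, cols)``; finite floats.
    pixel_size_um : float
        Edge length of one pixel in micrometres (> 0).
    channel_name : str
        Free-text channel label.
    """

    values: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidParameterError("image raster must be non-empty and 2D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("image intensities must be finite")
        if not self.pixel_size_um > 0:
            raise InvalidParameterError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def size_um(self) -> tuple[float, float]:
        """Physical extent as ``(width_x, height_y)`` in micrometres."""
        rows, cols = self.values.shape
        return (cols * self.pixel_size_um, rows * self.pixel_size_um)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` grids of pixel-centre coordinates in µm."""
        rows, cols = self.values.shape
        x = (np.arange(cols) + 0.5) * self.pixel_size_um
        y = (np.arange(rows) + 0.5) * self.pixel_size_um
        return np.meshgrid(x, y)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            self.values.astype(np.float32),
            metadata={"pixel_size_um": self.pixel_size_um,
                      "channel_name": self.channel_name},
        )

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float | None = None,
                  channel_name: str = "") -> "PixelImage":
        with tifffile.TiffFile(path) as tf:
            values = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if pixel_size_um is None:
            pixel_size_um = float(meta.get("pixel_size_um", 0.0))
        if not channel_name:
            channel_name = str(meta.get("channel_name", ""))
        return cls(np.asarray(values, dtype=float), pixel_size_um, channel_name)


#: Column order of the object table carried by :class:`LabeledObjects`.
OBJECT_COLUMNS = [
    "id",
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "mean_intensity",
    "equivalent_diameter_um",
]


@dataclass
class LabeledObjects:
    """Measured punctate objects from one channel.

    ``table`` has one row per object with columns ``id`` (unique int),
    ``centroid_x_um``, ``centroid_y_um``, ``area_um2``, ``mean_intensity``
    and ``equivalent_diameter_um``. ``label_raster`` (optional) is the
    integer label image the objects were segmented from, used for
    footprint-aware background measurements.
    """

    table: pd.DataFrame
    source_channel: str = ""
    label_raster: np.ndarray | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in OBJECT_COLUMNS if c not in self.table.columns]
        if missing:
            raise InvalidParameterError(f"object table missing columns {missing}")
        ids = self.table["id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise InvalidParameterError("object ids must be unique")
        if len(self.table) and not (self.table["area_um2"] > 0).all():
            raise InvalidParameterError("object areas must be positive")

    def __len__(self) -> int:
        return len(self.table)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of object centroids as ``(x, y)`` µm."""
        return self.table[["centroid_x_um", "centroid_y_um"]].to_numpy(float)

    @classmethod
    def from_centroids(cls, centroids_um, source_channel: str = "",
                       area_um2: float = 0.01,
                       mean_intensity: float = 1.0) -> "LabeledObjects":
        """Build a point-like object set (for proximity-style analyses)."""
        pts = np.atleast_2d(np.asarray(centroids_um, dtype=float))
        n = len(pts) if pts.size else 0
        table = pd.DataFrame({
            "id": np.arange(n),
            "centroid_x_um": pts[:, 0] if n else [],
            "centroid_y_um": pts[:, 1] if n else [],
            "area_um2": np.full(n, area_um2),
            "mean_intensity": np.full(n, mean_intensity),
            "equivalent_diameter_um": np.full(n, 2.0 * np.sqrt(area_um2 / np.pi)),
        })
        return cls(table, source_channel=source_channel)


@dataclass
class CellMask:
    """Binary cell region with optional exclusion zones (nucleus, mitotics).

    ``region`` and ``excluded`` are boolean rasters on the same grid as the
    image; ``excluded`` must be a subset of ``region``.
    """

    cell_id: int
    region: np.ndarray
    pixel_size_um: float
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        if not self.region.any():
            raise InvalidGeometryError("cell mask region is empty")
        if not self.pixel_size_um > 0:
            raise InvalidParameterError("pixel_size_um must be > 0")
        if self.excluded is not None:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != self.region.shape:
                raise InvalidGeometryError("excluded raster shape mismatch")
            if np.any(self.excluded & ~self.region):
                raise InvalidGeometryError("excluded regions must lie inside the cell")

    def usable(self) -> np.ndarray:
        """Region minus exclusions."""
        if self.excluded is None:
            return self.region
        return self.region & ~self.excluded

    def contains(self, points_um: np.ndarray, include_excluded: bool = False) -> np.ndarray:
        """Boolean membership of (n, 2) ``(x, y)`` µm points in the mask."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        cols = np.floor(pts[:, 0] / self.pixel_size_um).astype(int)
        rows = np.floor(pts[:, 1] / self.pixel_size_um).astype(int)
        raster = self.region if include_excluded else self.usable()
        ok = (
            (rows >= 0) & (rows < raster.shape[0])
            & (cols >= 0) & (cols < raster.shape[1])
        )
        out = np.zeros(len(pts), dtype=bool)
        out[ok] = raster[rows[ok], cols[ok]]
        return out


def rect_to_rect_mask(shape: tuple[int, int], pixel_size_um: float,
                      x0_um: float, y0_um: float, x1_um: float, y1_um: float) -> np.ndarray:
    """Boolean raster of pixels whose centres fall inside a µm rectangle."""
    rows, cols = shape
    xc = (np.arange(cols) + 0.5) * pixel_size_um
    yc = (np.arange(rows) + 0.5) * pixel_size_um
    inx = (xc >= x0_um) & (xc < x1_um)
    iny = (yc >= y0_um) & (yc < y1_um)
    return np.outer(iny, inx)
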