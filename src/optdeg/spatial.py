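"""Horizontal gridding of sparse sensor values for contour-style output.

Each sensor plane (height stratum) is interpolated independently onto a
regular grid over the greenhouse floor.  The default interpolant is
piecewise-linear on the Delaunay triangulation of the sensor positions:
deterministic, exact at the sensors and free of overshoot (grid values stay
within the range of the inputs).  Inverse-distance weighting (power 2) is
available as an alternative; cells outside the convex hull of the sensors
are masked unless ``extrapolate=True`` fills them by nearest neighbour.

Fields export to long-format CSV (x, y, value) and to ESRI ASCII grid
(.asc) with the mask encoded as the standard no-data value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

__all__ = ["GridSpec", "GridField", "interpolate_grid", "field_summary"]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular horizontal grid: node coordinates are ``nx`` x ``ny``
    linspaces over [x_min, x_max] x [y_min, y_max] (metres)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int
    ny: int

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("grid extents must be non-degenerate")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("nx and ny must be >= 2")

    @classmethod
    def from_bounds(cls, x_min, x_max, y_min, y_max,
                    resolution: float = 1.0) -> "GridSpec":
        """Grid over a bounding box at approximately ``resolution`` metres."""
        nx = max(2, int(round((x_max - x_min) / resolution)) + 1)
        ny = max(2, int(round((y_max - y_min) / resolution)) + 1)
        return cls(x_min, x_max, y_min, y_max, nx, ny)

    @classmethod
    def from_layout(cls, layout: pd.DataFrame,
                    resolution: float = 1.0) -> "GridSpec":
        """Grid over the sensor-layout bounding box (1 m default)."""
        return cls.from_bounds(layout["x"].min(), layout["x"].max(),
                               layout["y"].min(), layout["y"].max(),
                               resolution)

    def nodes(self):
        x = np.linspace(self.x_min, self.x_max, self.nx)
        y = np.linspace(self.y_min, self.y_max, self.ny)
        return np.meshgrid(x, y)  # each (ny, nx)


@dataclass
class GridField:
    """An interpolated quantity on one horizontal plane at one hour.

    ``values`` is (ny, nx) with NaN where ``mask`` is False (outside the
    sensor hull, unless extrapolated).
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray
    variable: str = ""
    height: float = float("nan")
    hour_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Long-format (x, y, value) table of the unmasked cells."""
        xx, yy = self.spec.nodes()
        m = self.mask
        return pd.DataFrame({"x": xx[m], "y": yy[m], "value": self.values[m]})

    def to_ascii_grid(self, path) -> None:
        """Write as ESRI ASCII grid; masked cells get the NODATA value.

        The format requires square cells, so the grid spacing must match
        in x and y.
        """
        dx = (self.spec.x_max - self.spec.x_min) / (self.spec.nx - 1)
        dy = (self.spec.y_max - self.spec.y_min) / (self.spec.ny - 1)
        if not np.isclose(dx, dy, rtol=1e-6):
            raise ValueError(
                f".asc export needs square cells (dx={dx:g}, dy={dy:g})")
        vals = np.where(self.mask, self.values, NODATA)
        with open(path, "w") as fh:
            fh.write(f"ncols {self.spec.nx}\n")
            fh.write(f"nrows {self.spec.ny}\n")
            fh.write(f"xllcorner {self.spec.x_min - dx / 2:.6f}\n")
            fh.write(f"yllcorner {self.spec.y_min - dy / 2:.6f}\n")
            fh.write(f"cellsize {dx:.6f}\n")
            fh.write(f"NODATA_value {NODATA:g}\n")
            for row in vals[::-1]:  # .asc rows run north -> south
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _idw(points, values, xi, power=2.0):
    d2 = ((xi[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    exact = d2 < 1e-24
    w = 1.0 / np.maximum(d2, 1e-24) ** (power / 2.0)
    out = (w * values[None, :]).sum(axis=1) / w.sum(axis=1)
    hit = exact.any(axis=1)
    if hit.any():
        out[hit] = values[exact.argmax(axis=1)[hit]]
    return out


def interpolate_grid(points, spec: GridSpec, method: str = "linear",
                     extrapolate: bool = False, variable: str = "",
                     height: float = float("nan"),
                     hour_label: str = "") -> GridField:
    """Interpolate sparse (x, y, value) samples onto the grid.

    ``method`` is "linear" (triangulated piecewise-linear, the default),
    "nearest" or "idw" (inverse distance, power 2).  The linear method
    needs >= 3 non-collinear points and falls back to nearest neighbour
    with a warning otherwise.  Cells outside the convex hull are masked,
    or filled by nearest neighbour when ``extrapolate`` is true.
    """
    pts = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    vals = np.asarray([p[2] for p in points], dtype=float)
    if len(pts) == 0:
        raise ValueError("no input points")
    xx, yy = spec.nodes()
    xi = np.column_stack([xx.ravel(), yy.ravel()])

    if method == "linear":
        try:
            interp = LinearNDInterpolator(pts, vals)
            grid = interp(xi)
        except (QhullError, ValueError):
            warnings.warn("fewer than 3 non-collinear points; "
                          "falling back to nearest-neighbour interpolation")
            method = "nearest"
    if method == "nearest":
        grid = NearestNDInterpolator(pts, vals)(xi)
    elif method == "idw":
        grid = _idw(pts, vals, xi)
    elif method != "linear":
        raise ValueError(f"unknown method {method!r}")

    grid = grid.reshape(xx.shape)
    mask = np.isfinite(grid)
    if extrapolate and not mask.all():
        fill = NearestNDInterpolator(pts, vals)(xi).reshape(xx.shape)
        grid = np.where(mask, grid, fill)
        mask = np.ones_like(mask)
    grid = np.where(mask, grid, np.nan)
    return GridField(spec=spec, values=grid, mask=mask, variable=variable,
                     height=height, hour_label=hour_label)


def field_summary(field: GridField, threshold: float):
    """Fraction of the unmasked area with value < threshold.

    Cells are weighted equally.  Returns None for a fully masked field
    (the statistic is undefined there).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    m = field.mask
    if not m.any():
        return None
    return float((field.values[m] < threshold).mean())
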