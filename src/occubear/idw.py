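"""Inverse distance weighting of per-site values onto a regular grid.

Reproduces the construction of a detection-probability surface from
camera-trap sites: each pixel centre takes the distance-decay weighted
average of the site values, w_i = d_i^{-k} with Euclidean distance d_i and
power k (default 2, the common GIS default).  A pixel coinciding with a
site (d < 1e-9 m) takes that site's value exactly.  All sites contribute by
default; an optional radius restricts the neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["GridSpec", "DetectionSurface", "idw_interpolate"]

_EXACT_EPS = 1e-9  # metres


@dataclass
class GridSpec:
    """Regular grid over a projected bounding box (metres).

    ``bounds`` is (x_min, y_min, x_max, y_max); pixel centres start half a
    pixel in from the lower-left corner.
    """

    bounds: tuple[float, float, float, float]
    pixel_size: float = 1000.0
    power: float = 2.0
    radius: float | None = None

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bounds
        if not (x1 > x0 and y1 > y0):
            raise ValueError("bounds must enclose positive area")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.power <= 0:
            raise ValueError("power must be > 0")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be > 0 when given")

    @classmethod
    def covering(cls, coords: np.ndarray, pixel_size: float = 1000.0,
                 power: float = 2.0, pad: float = 0.0, **kw) -> "GridSpec":
        """Smallest grid covering all sample points, optionally padded."""
        x0, y0 = coords.min(axis=0) - pad
        x1, y1 = coords.max(axis=0) + pad
        # widen degenerate extents so at least one pixel exists
        if x1 <= x0:
            x0, x1 = x0 - pixel_size / 2, x1 + pixel_size / 2
        if y1 <= y0:
            y0, y1 = y0 - pixel_size / 2, y1 + pixel_size / 2
        return cls(bounds=(x0, y0, x1, y1), pixel_size=pixel_size, power=power, **kw)

    @property
    def shape(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.bounds
        nx = int(np.ceil((x1 - x0) / self.pixel_size))
        ny = int(np.ceil((y1 - y0) / self.pixel_size))
        return ny, nx

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinate vectors (xs ascending, ys ascending)."""
        ny, nx = self.shape
        x0, y0, _, _ = self.bounds
        xs = x0 + (np.arange(nx) + 0.5) * self.pixel_size
        ys = y0 + (np.arange(ny) + 0.5) * self.pixel_size
        return xs, ys


@dataclass
class DetectionSurface:
    """Interpolated raster; row 0 is the *northernmost* row (map order)."""

    values: np.ndarray
    grid: GridSpec

    def to_long_frame(self) -> pd.DataFrame:
        xs, ys = self.grid.centers()
        xx, yy = np.meshgrid(xs, ys[::-1])
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "value": self.values.ravel()}
        )

    def write_csv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.to_long_frame().to_csv(fh, index=False)

    def write_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        """ESRI ASCII grid (.asc): plain-text raster with georeferencing."""
        ny, nx = self.values.shape
        x0, y0, _, _ = self.grid.bounds
        vals = np.where(np.isfinite(self.values), self.values, nodata)
        with open(path, "w") as fh:
            fh.write(
                f"ncols {nx}\nnrows {ny}\nxllcorner {x0}\nyllcorner {y0}\n"
                f"cellsize {self.grid.pixel_size}\nnodata_value {nodata}\n"
            )
            np.savetxt(fh, vals, fmt="%.6g")


def idw_interpolate(
    coords: np.ndarray, values: np.ndarray, grid: GridSpec
) -> DetectionSurface:
    """IDW surface of ``values`` sampled at ``coords`` (n x 2, metres)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float).ravel()
    if coords.shape[0] == 0:
        raise ValueError("need at least one sample point")
    if coords.shape[0] != values.shape[0]:
        raise ValueError("coords and values disagree in length")
    if not np.all(np.isfinite(coords)) or not np.all(np.isfinite(values)):
        raise ValueError("coords and values must be finite")
    _check_duplicates(coords, values)

    xs, ys = grid.centers()
    xx, yy = np.meshgrid(xs, ys[::-1])  # map order: north row first
    pix = np.column_stack([xx.ravel(), yy.ravel()])
    d = cdist(pix, coords)

    out = np.empty(pix.shape[0])
    exact = d < _EXACT_EPS
    has_exact = exact.any(axis=1)
    if has_exact.any():
        first = np.argmax(exact[has_exact], axis=1)
        out[has_exact] = values[first]

    rest = ~has_exact
    if rest.any():
        w = d[rest] ** (-grid.power)
        if grid.radius is not None:
            w[d[rest] > grid.radius] = 0.0
        denom = w.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = w @ values / denom
        vals[denom == 0] = np.nan  # outside every neighbourhood
        out[rest] = vals

    return DetectionSurface(values=out.reshape(xx.shape), grid=grid)


def _check_duplicates(coords: np.ndarray, values: np.ndarray) -> None:
    dd = cdist(coords, coords)
    iu = np.triu_indices_from(dd, k=1)
    close = dd[iu] < _EXACT_EPS
    if close.any():
        i, j = iu[0][close], iu[1][close]
        conflict = values[i] != values[j]
        if conflict.any():
            pairs = list(zip(i[conflict].tolist(), j[conflict].tolist()))
            raise ValueError(
                f"duplicate sample locations with conflicting values at index pairs {pairs}"
            )
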