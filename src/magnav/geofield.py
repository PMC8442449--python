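"""Dated geomagnetic cue grids on a planar raster.

The simulation experiment consumes three geomagnetic quantities per
calendar day: total intensity F (nT), inclination I (degrees) and the
horizontal component H = F*cos(I) (nT), each as a single-band raster on
a shared planar grid in metres.  This module provides the grid
containers, GeoTIFF reading/writing, derived quantities and point
queries.

Conventions
-----------
* ``origin_x, origin_y`` are the coordinates of the CENTRE of cell
  ``[0, 0]``; the row index increases with *decreasing* y (raster
  convention), the column index with increasing x.
* All coordinates are planar metres; the package never reprojects.
  The projection used upstream is carried only as ``crs_label`` text.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import tifffile

Cue = Literal["F", "I", "H"]

#: Valid cue identifiers, in the order used throughout the package.
CUES: tuple[str, ...] = ("F", "I", "H")

# GeoTIFF tag codes (GeoTIFF 1.1 spec)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


class FieldValidationError(ValueError):
    """A grid violates a cue-specific invariant (range, finiteness)."""


class BoundsError(ValueError):
    """A point query fell outside the grid extent."""


@dataclass(frozen=True)
class GridGeometry:
    """Affine geometry of a square-celled planar raster.

    Parameters
    ----------
    origin_x, origin_y
        Centre of cell ``[0, 0]`` in metres.
    cell_size
        Edge length of the square cells in metres (default 5 km, the
        working resolution of the daily geomagnetic model grids).
    n_rows, n_cols
        Grid shape; row 0 is the northernmost (largest y).
    crs_label
        Free-text description of the projected CRS; metadata only.
    """

    origin_x: float
    origin_y: float
    cell_size: float = 5000.0
    n_rows: int = 2
    n_cols: int = 2
    crs_label: str = "planar-metres"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError(
                f"grid must be at least 2x2, got {self.n_rows}x{self.n_cols}"
            )

    # -- coordinate helpers -------------------------------------------------

    def cell_center(self, row, col):
        """(x, y) of the centre of cell ``[row, col]`` (arrays allowed)."""
        x = self.origin_x + np.asarray(col) * self.cell_size
        y = self.origin_y - np.asarray(row) * self.cell_size
        return x, y

    def x_coords(self) -> np.ndarray:
        return self.origin_x + np.arange(self.n_cols) * self.cell_size

    def y_coords(self) -> np.ndarray:
        return self.origin_y - np.arange(self.n_rows) * self.cell_size

    @property
    def x_min(self) -> float:
        return self.origin_x

    @property
    def x_max(self) -> float:
        return self.origin_x + (self.n_cols - 1) * self.cell_size

    @property
    def y_min(self) -> float:
        return self.origin_y - (self.n_rows - 1) * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin_y

    def contains(self, x: float, y: float) -> bool:
        """True if (x, y) lies within the envelope of cell centres."""
        return (self.x_min <= x <= self.x_max) and (self.y_min <= y <= self.y_max)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell whose centre is nearest to (x, y)."""
        col = int(round((x - self.origin_x) / self.cell_size))
        row = int(round((self.origin_y - y) / self.cell_size))
        return row, col


def _validate_values(cue: str, values: np.ndarray) -> None:
    if cue not in CUES:
        raise ValueError(f"unknown cue {cue!r}; expected one of {CUES}")
    if not np.all(np.isfinite(values)):
        raise FieldValidationError(f"cue {cue}: grid contains non-finite values")
    if cue == "I":
        lo, hi = float(values.min()), float(values.max())
        if lo < -90.0 or hi > 90.0:
            raise FieldValidationError(
                f"cue I: inclination values must lie in [-90, 90] degrees, "
                f"found range [{lo:g}, {hi:g}]"
            )
    else:
        lo = float(values.min())
        if lo < 0.0:
            raise FieldValidationError(
                f"cue {cue}: field strength must be >= 0 nT, found minimum {lo:g}"
            )


@dataclass(frozen=True)
class FieldGrid:
    """One dated raster of one geomagnetic cue.

    ``values`` has shape ``(n_rows, n_cols)``; units are nT for F and H
    and degrees for I.
    """

    cue: str
    date: _dt.date
    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"values shape {values.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        object.__setattr__(self, "values", values)
        _validate_values(self.cue, values)

    @property
    def vmin(self) -> float:
        return float(self.values.min())

    @property
    def vmax(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class FieldStack:
    """The three cue grids for one day on one shared geometry."""

    grids: Mapping[str, FieldGrid]

    def __post_init__(self) -> None:
        missing = [c for c in CUES if c not in self.grids]
        if missing:
            raise ValueError(f"field stack missing cue grids: {missing}")
        ref = self.grids["F"]
        for cue in CUES:
            g = self.grids[cue]
            if g.geometry != ref.geometry:
                raise ValueError(f"cue {cue} geometry differs from cue F")
            if g.date != ref.date:
                raise ValueError(f"cue {cue} date differs from cue F")

    def __getitem__(self, cue: str) -> FieldGrid:
        return self.grids[cue]

    @property
    def date(self) -> _dt.date:
        return self.grids["F"].date

    @property
    def geometry(self) -> GridGeometry:
        return self.grids["F"].geometry

    def check_consistency(self, rtol: float = 1e-6) -> None:
        """Verify |H - F*cos(I)| <= rtol*F cellwise (for derived H)."""
        F = self.grids["F"].values
        I = self.grids["I"].values
        H = self.grids["H"].values
        err = np.abs(H - F * np.cos(np.deg2rad(I)))
        if not np.all(err <= rtol * np.maximum(F, 1.0)):
            raise FieldValidationError(
                "H grid is inconsistent with F*cos(I) beyond tolerance "
                f"(max error {err.max():g} nT)"
            )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_field_grid(grid: FieldGrid, path) -> Path:
    """Write a FieldGrid as a single-band float32 GeoTIFF.

    The affine is encoded with ModelPixelScale / ModelTiepoint tags
    (tiepoint at the upper-left *corner* of cell [0, 0], per GeoTIFF
    convention); cue, date and CRS label go into ImageDescription JSON.
    """
    path = Path(path)
    geo = grid.geometry
    half = geo.cell_size / 2.0
    desc = json.dumps(
        {
            "cue": grid.cue,
            "date": grid.date.isoformat(),
            "crs_label": geo.crs_label,
        }
    )
    tifffile.imwrite(
        path,
        grid.values.astype(np.float32),
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (geo.cell_size, geo.cell_size, 0.0)),
            (
                _TAG_TIEPOINT,
                "d",
                6,
                (0.0, 0.0, 0.0, geo.origin_x - half, geo.origin_y + half, 0.0),
            ),
        ],
        description=desc,
    )
    return path


def write_raster(values: np.ndarray, geometry: GridGeometry, path,
                 description: str = "") -> Path:
    """Write an arbitrary single-band raster (e.g. a probability
    surface) with the same GeoTIFF tags as a cue grid."""
    path = Path(path)
    half = geometry.cell_size / 2.0
    tifffile.imwrite(
        path,
        np.asarray(values, dtype=np.float32),
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3,
             (geometry.cell_size, geometry.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6,
             (0.0, 0.0, 0.0, geometry.origin_x - half,
              geometry.origin_y + half, 0.0)),
        ],
        description=description,
    )
    return path


def read_field_grid(path, cue: str, date: _dt.date | str | None = None) -> FieldGrid:
    """Read a single-band GeoTIFF raster as a :class:`FieldGrid`.

    Parameters
    ----------
    path
        Raster file.  Must be single band with square cells and carry
        ModelPixelScale / ModelTiepoint geo-tags.
    cue
        Which quantity the file holds ("F", "I" or "H"); cue-specific
        value invariants are validated on read.
    date
        Calendar day of the grid.  If omitted, taken from the file's
        ImageDescription metadata (and required to be present there).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise FieldValidationError(
                f"{path.name}: expected a single-band 2-D raster, "
                f"got shape {values.shape}"
            )
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise FieldValidationError(
                f"{path.name}: missing GeoTIFF pixel-scale/tiepoint tags"
            )
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        meta: dict = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (ValueError, TypeError):
                meta = {}
    if not np.isclose(sx, sy, rtol=1e-9):
        raise FieldValidationError(
            f"{path.name}: cells are not square (scale {sx:g} x {sy:g})"
        )
    if date is None:
        if "date" not in meta:
            raise ValueError(f"{path.name}: no date given and none in metadata")
        date = meta["date"]
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    # tiepoint (i, j) -> (X, Y) maps the raster point to world; with the
    # customary (0, 0) raster point this is the upper-left corner.
    i, j, _, X, Y, _ = tie[:6]
    ul_x = X - j * sx
    ul_y = Y + i * sy
    geometry = GridGeometry(
        origin_x=ul_x + sx / 2.0,
        origin_y=ul_y - sy / 2.0,
        cell_size=float(sx),
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        crs_label=str(meta.get("crs_label", "unknown")),
    )
    return FieldGrid(cue=cue, date=date, geometry=geometry, values=values)


def field_filename(cue: str, date: _dt.date) -> str:
    """Canonical file name ``<cue>_<YYYY-MM-DD>.tif``."""
    return f"{cue}_{date.isoformat()}.tif"


def write_field_stack(stack: FieldStack, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [
        write_field_grid(stack[cue], directory / field_filename(cue, stack.date))
        for cue in CUES
    ]


def read_field_stack(directory, date: _dt.date) -> FieldStack:
    directory = Path(directory)
    return FieldStack(
        {
            cue: read_field_grid(directory / field_filename(cue, date), cue, date)
            for cue in CUES
        }
    )


def read_field_series(directory, dates: Iterable[_dt.date]) -> list[FieldStack]:
    return [read_field_stack(directory, d) for d in dates]


# ---------------------------------------------------------------------------
# Derived grids and queries
# ---------------------------------------------------------------------------

def derive_horizontal(F_grid: FieldGrid, I_grid: FieldGrid) -> FieldGrid:
    """Horizontal component H = F*cos(I) on the shared geometry.

    F is the total field strength and I the dip angle in degrees; the
    horizontal component is the projection of the field vector onto the
    local horizontal plane.
    """
    if F_grid.geometry != I_grid.geometry:
        raise ValueError("F and I grids have mismatched geometry")
    if F_grid.date != I_grid.date:
        raise ValueError("F and I grids have mismatched dates")
    H = F_grid.values * np.cos(np.deg2rad(I_grid.values))
    # cos can go epsilon-negative at |I| ~ 90 degrees
    H = np.clip(H, 0.0, None)
    return FieldGrid(cue="H", date=F_grid.date, geometry=F_grid.geometry, values=H)


def make_stack(F_grid: FieldGrid, I_grid: FieldGrid,
               H_grid: FieldGrid | None = None) -> FieldStack:
    if H_grid is None:
        H_grid = derive_horizontal(F_grid, I_grid)
    return FieldStack({"F": F_grid, "I": I_grid, "H": H_grid})


def value_at(grid: FieldGrid, x, y, method: str = "bilinear"):
    """Cue value at planar point(s) (x, y).

    Bilinear interpolation between the four surrounding cell centres by
    default; ``method="nearest"`` snaps to the nearest centre.  Scalar
    or array inputs; out-of-bounds queries raise :class:`BoundsError`.
    """
    geo = grid.geometry
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    eps = 1e-9 * geo.cell_size
    bad = (
        (x < geo.x_min - eps) | (x > geo.x_max + eps)
        | (y < geo.y_min - eps) | (y > geo.y_max + eps)
    )
    if np.any(bad):
        i = int(np.argmax(bad))
        raise BoundsError(
            f"point ({x[i]:g}, {y[i]:g}) outside grid extent "
            f"x:[{geo.x_min:g}, {geo.x_max:g}] y:[{geo.y_min:g}, {geo.y_max:g}]"
        )
    cf = np.clip((x - geo.origin_x) / geo.cell_size, 0, geo.n_cols - 1)
    rf = np.clip((geo.origin_y - y) / geo.cell_size, 0, geo.n_rows - 1)
    if method == "nearest":
        out = grid.values[np.round(rf).astype(int), np.round(cf).astype(int)]
    elif method == "bilinear":
        r0 = np.clip(np.floor(rf).astype(int), 0, geo.n_rows - 2)
        c0 = np.clip(np.floor(cf).astype(int), 0, geo.n_cols - 2)
        tr = rf - r0
        tc = cf - c0
        v = grid.values
        out = (
            v[r0, c0] * (1 - tr) * (1 - tc)
            + v[r0, c0 + 1] * (1 - tr) * tc
            + v[r0 + 1, c0] * tr * (1 - tc)
            + v[r0 + 1, c0 + 1] * tr * tc
        )
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return float(out[0]) if scalar else out


def extremum_location(grid: FieldGrid, which: str) -> tuple[float, float, float]:
    """(x, y, value) of the grid's global minimum or maximum cell centre.

    Ties are broken by the smallest (row, col) in row-major order, which
    is what ``argmin``/``argmax`` on the flattened matrix return.
    """
    if which not in ("min", "max"):
        raise ValueError(f"which must be 'min' or 'max', got {which!r}")
    flat = int(grid.values.argmin() if which == "min" else grid.values.argmax())
    row, col = divmod(flat, grid.geometry.n_cols)
    x, y = grid.geometry.cell_center(row, col)
    return float(x), float(y), float(grid.values[row, col])
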