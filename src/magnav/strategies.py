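"""Navigational-strategy bias surfaces over geomagnetic grids.

Five candidate strategies are modelled, each as a per-cell probability
raster in [0, 1] that later multiplies into the step-sampling
distribution of the random-walk engines:

* ``no_bias`` — control, uniform 1.
* ``taxis`` — gradient following: the day's global cue minimum gets
  probability 1 and the maximum 0, linear in the cue value (autumn
  migration runs from high to low geomagnetic values; invert for
  spring).
* ``constant_heading`` — compass-like: hold the angle, measured at the
  bird between the direction to the cue grid's global extreme and the
  direction of travel, near a reference angle theta* calibrated once a
  day from the straight line bird -> target.
* ``bigradient`` — two-cue map positioning: per cue, probability falls
  linearly with deviation from the cue value at the target, scaled by
  the raster's daily range; the two single-cue rasters multiply.
* ``combination`` — single-cue map raster (first cue) times a
  constant-heading raster (second cue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geofield import CUES, FieldGrid, FieldStack, GridGeometry, extremum_location

NO_BIAS = "no_bias"
TAXIS = "taxis"
CONSTANT_HEADING = "constant_heading"
BIGRADIENT = "bigradient"
COMBINATION = "combination"

STRATEGIES = (NO_BIAS, TAXIS, CONSTANT_HEADING, BIGRADIENT, COMBINATION)

#: cue arity of each strategy
_ARITY = {NO_BIAS: 0, TAXIS: 1, CONSTANT_HEADING: 1, BIGRADIENT: 2, COMBINATION: 2}


class DegenerateGeometryError(ValueError):
    """Raised when a surface is requested for degenerate geometry
    (constant grid, bird at the target or at the extreme)."""


@dataclass(frozen=True)
class StrategySpec:
    """One model configuration: a strategy with its cue assignment.

    ``extreme`` ("min"/"max") applies only to constant heading, which
    is run once against each of the grid's global extremes.
    """

    strategy: str
    cues: tuple[str, ...] = ()
    extreme: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        cues = tuple(self.cues)
        if len(cues) != _ARITY[self.strategy]:
            raise ValueError(
                f"{self.strategy} takes {_ARITY[self.strategy]} cue(s), "
                f"got {cues}"
            )
        for c in cues:
            if c not in CUES:
                raise ValueError(f"unknown cue {c!r}")
        if len(set(cues)) != len(cues):
            raise ValueError(f"{self.strategy} cues must be distinct, got {cues}")
        if self.strategy == CONSTANT_HEADING:
            if self.extreme not in ("min", "max"):
                raise ValueError("constant heading needs extreme 'min' or 'max'")
        elif self.extreme is not None:
            raise ValueError(f"{self.strategy} takes no extreme flag")
        object.__setattr__(self, "cues", cues)
        if not self.label:
            object.__setattr__(self, "label", default_label(self))


def default_label(spec: StrategySpec) -> str:
    if spec.strategy == NO_BIAS:
        return NO_BIAS
    if spec.strategy == CONSTANT_HEADING:
        return f"{CONSTANT_HEADING}-{spec.extreme}{spec.cues[0]}"
    return f"{spec.strategy}-{''.join(spec.cues)}"


@dataclass(frozen=True)
class TargetInfo:
    """End point of the matched empirical trajectory and the cue values
    there (on the relevant date)."""

    target_xy: tuple[float, float]
    target_values: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ProbabilitySurface:
    """Per-cell probabilities in [0, 1] on a grid geometry."""

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def to_geotiff(self, path, description: str = "probability-surface"):
        """Export for visual inspection (same geo-tags as cue grids)."""
        from .geofield import write_raster

        return write_raster(self.values, self.geometry, path, description)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError("surface shape does not match geometry")
        if np.any(v < -1e-12) or np.any(v > 1.0 + 1e-12):
            raise ValueError(
                f"surface values outside [0, 1]: range "
                f"[{v.min():g}, {v.max():g}]"
            )
        if not np.any(v > 0):
            raise ValueError("surface has no strictly positive cell")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Per-value helpers (vectorised over arbitrary cell-value / coordinate
# arrays; the full-grid ops below and the simulator's windowed
# evaluation share these)
# ---------------------------------------------------------------------------

def taxis_values(v, vmin: float, vmax: float, invert: bool = False):
    """Linear scaling of cue values to probabilities: min -> 1, max -> 0
    (autumn).  ``invert=True`` flips the gradient for spring."""
    if vmax <= vmin:
        raise DegenerateGeometryError("constant grid: taxis undefined (zero range)")
    p = (vmax - np.asarray(v, dtype=float)) / (vmax - vmin)
    return 1.0 - p if invert else p


def gradient_to_target_values(v, v_target: float, vmin: float, vmax: float):
    """Single-cue map raster: 1 at the target's cue value, falling
    linearly with deviation over the raster's full daily range."""
    if vmax <= vmin:
        raise DegenerateGeometryError("constant grid: map raster undefined")
    p = 1.0 - np.abs(np.asarray(v, dtype=float) - v_target) / (vmax - vmin)
    return np.clip(p, 0.0, 1.0)


def vertex_angle_deg(current_xy, ref_xy, px, py):
    """Unsigned angle (degrees, [0, 180]) at vertex ``current_xy``
    between the rays current->ref and current->(px, py).

    Zero-length rays (a queried point equal to the current position)
    get angle 0 by convention.
    """
    cx, cy = current_xy
    rx, ry = ref_xy[0] - cx, ref_xy[1] - cy
    if rx == 0.0 and ry == 0.0:
        raise DegenerateGeometryError("current position coincides with the extreme")
    px = np.asarray(px, dtype=float) - cx
    py = np.asarray(py, dtype=float) - cy
    ang_ref = np.arctan2(ry, rx)
    ang_p = np.arctan2(py, px)
    d = np.abs(np.mod(ang_p - ang_ref + np.pi, 2 * np.pi) - np.pi)
    d = np.where((px == 0) & (py == 0), np.abs(ang_ref) * 0.0, d)
    return np.degrees(d)


def constant_heading_theta(grid: FieldGrid, current_xy, target_xy,
                           extreme: str) -> float:
    """Daily calibration angle theta* (degrees).

    Mean, over points sampled at cell_size spacing on the straight
    segment current -> target (excluding the current position itself),
    of the unsigned angle at the bird between the direction to the cue
    grid's global ``extreme`` and the direction to the sample point.
    """
    ex, ey, _ = extremum_location(grid, extreme)
    cx, cy = current_xy
    tx, ty = target_xy
    dist = float(np.hypot(tx - cx, ty - cy))
    if dist <= 0.0:
        raise DegenerateGeometryError("current position coincides with the target")
    n = max(int(np.ceil(dist / grid.geometry.cell_size)), 1)
    # fractions (0, 1]; the current position itself is excluded
    f = np.arange(1, n + 1) / n
    px = cx + f * (tx - cx)
    py = cy + f * (ty - cy)
    angles = vertex_angle_deg((cx, cy), (ex, ey), px, py)
    return float(angles.mean())


def constant_heading_values(current_xy, extreme_xy, theta_star: float, px, py):
    """Probability of a cell under constant heading: 1 at the
    calibrated angle theta*, falling linearly to 0 at 180 deg away."""
    ang = vertex_angle_deg(current_xy, extreme_xy, px, py)
    return 1.0 - np.abs(ang - theta_star) / 180.0


# ---------------------------------------------------------------------------
# Full-grid surface operations
# ---------------------------------------------------------------------------

def _cell_coords(geometry: GridGeometry):
    xs = geometry.x_coords()
    ys = geometry.y_coords()
    return np.meshgrid(xs, ys)


def no_bias_surface(geometry: GridGeometry) -> ProbabilitySurface:
    """Uniform control surface (all cells 1)."""
    return ProbabilitySurface(geometry, np.ones((geometry.n_rows,
                                                 geometry.n_cols)))


def taxis_surface(grid: FieldGrid, invert: bool = False) -> ProbabilitySurface:
    """Gradient-following surface: day's minimum -> 1, maximum -> 0."""
    p = taxis_values(grid.values, grid.vmin, grid.vmax, invert=invert)
    return ProbabilitySurface(grid.geometry, p)


def constant_heading_surface(grid: FieldGrid, current_xy, target_xy,
                             extreme: str,
                             theta_star: float | None = None
                             ) -> ProbabilitySurface:
    """Constant-heading surface from the current position.

    ``theta_star`` may be passed explicitly (the daily calibration is
    computed once per simulated day); if omitted it is computed from
    the current position.
    """
    ex, ey, _ = extremum_location(grid, extreme)
    if theta_star is None:
        theta_star = constant_heading_theta(grid, current_xy, target_xy, extreme)
    X, Y = _cell_coords(grid.geometry)
    p = constant_heading_values(current_xy, (ex, ey), theta_star, X, Y)
    return ProbabilitySurface(grid.geometry, p)


def bigradient_surface(grid1: FieldGrid, grid2: FieldGrid,
                       target_values: Mapping[str, float]) -> ProbabilitySurface:
    """Two-cue map surface: product of the single-cue gradient-to-target
    rasters of the two grids."""
    if grid1.geometry != grid2.geometry:
        raise ValueError("bigradient grids have mismatched geometry")
    p = np.ones_like(grid1.values)
    for g in (grid1, grid2):
        if g.cue not in target_values:
            raise ValueError(f"target value for cue {g.cue} missing")
        p = p * gradient_to_target_values(
            g.values, float(target_values[g.cue]), g.vmin, g.vmax
        )
    return ProbabilitySurface(grid1.geometry, p)


def combination_surface(map_cue_grid: FieldGrid, heading_cue_grid: FieldGrid,
                        current_xy, target_xy,
                        target_values: Mapping[str, float],
                        extreme: str = "min",
                        theta_star: float | None = None) -> ProbabilitySurface:
    """Map navigation on the first cue times constant heading on the
    second cue."""
    if map_cue_grid.geometry != heading_cue_grid.geometry:
        raise ValueError("combination grids have mismatched geometry")
    if map_cue_grid.cue not in target_values:
        raise ValueError(f"target value for cue {map_cue_grid.cue} missing")
    p_map = gradient_to_target_values(
        map_cue_grid.values,
        float(target_values[map_cue_grid.cue]),
        map_cue_grid.vmin,
        map_cue_grid.vmax,
    )
    p_head = constant_heading_surface(
        heading_cue_grid, current_xy, target_xy, extreme, theta_star=theta_star
    ).values
    return ProbabilitySurface(map_cue_grid.geometry, p_map * p_head)


# ---------------------------------------------------------------------------
# Windowed bias evaluation for the simulation engines
# ---------------------------------------------------------------------------

class BiasModel:
    """Evaluates one strategy's bias on arbitrary cells, with the daily
    calibration (extreme location, cue ranges, theta*) cached.

    Construct once per simulated day (``calibrate``), then call
    :meth:`at_cells` every step with the walker's current position.
    """

    def __init__(self, spec: StrategySpec, stack: FieldStack,
                 target: TargetInfo, invert_taxis: bool = False,
                 combination_extreme: str = "min") -> None:
        self.spec = spec
        self.stack = stack
        self.target = target
        self.invert_taxis = invert_taxis
        self.combination_extreme = combination_extreme
        self.theta_star: float | None = None
        self._extreme_xy: tuple[float, float] | None = None
        s = spec.strategy
        if s in (CONSTANT_HEADING, COMBINATION):
            which = spec.extreme if s == CONSTANT_HEADING else combination_extreme
            cue = spec.cues[0] if s == CONSTANT_HEADING else spec.cues[1]
            ex, ey, _ = extremum_location(stack[cue], which)
            self._extreme_xy = (ex, ey)

    def calibrate(self, day_start_xy) -> None:
        """Daily recalibration of theta* from the day-start position
        (no-op for strategies without a heading component)."""
        s = self.spec.strategy
        if s == CONSTANT_HEADING:
            cue, which = self.spec.cues[0], self.spec.extreme
        elif s == COMBINATION:
            cue, which = self.spec.cues[1], self.combination_extreme
        else:
            return
        self.theta_star = constant_heading_theta(
            self.stack[cue], day_start_xy, self.target.target_xy, which
        )

    def at_cells(self, rows, cols, current_xy) -> np.ndarray:
        """Bias probabilities at the given cells (arrays of row/col)."""
        s = self.spec.strategy
        stack = self.stack
        if s == NO_BIAS:
            return np.ones(np.shape(rows), dtype=float)
        if s == TAXIS:
            g = stack[self.spec.cues[0]]
            return taxis_values(g.values[rows, cols], g.vmin, g.vmax,
                                invert=self.invert_taxis)
        if s == BIGRADIENT:
            p = 1.0
            for cue in self.spec.cues:
                g = stack[cue]
                p = p * gradient_to_target_values(
                    g.values[rows, cols],
                    float(self.target.target_values[cue]),
                    g.vmin, g.vmax,
                )
            return p
        # heading component shared by CONSTANT_HEADING and COMBINATION
        if self.theta_star is None:
            self.calibrate(current_xy)
        geo = stack.geometry
        px, py = geo.cell_center(rows, cols)
        p_head = constant_heading_values(
            current_xy, self._extreme_xy, self.theta_star, px, py
        )
        if s == CONSTANT_HEADING:
            return p_head
        g = stack[self.spec.cues[0]]
        p_map = gradient_to_target_values(
            g.values[rows, cols],
            float(self.target.target_values[g.cue]),
            g.vmin, g.vmax,
        )
        return p_map * p_head

    def surface(self, current_xy) -> ProbabilitySurface:
        """Full-grid surface (for export / inspection)."""
        geo = self.stack.geometry
        rows, cols = np.meshgrid(np.arange(geo.n_rows), np.arange(geo.n_cols),
                                 indexing="ij")
        return ProbabilitySurface(geo, self.at_cells(rows, cols, current_xy))


# ---------------------------------------------------------------------------
# The experiment's model configurations
# ---------------------------------------------------------------------------

def enumerate_model_configs() -> list[StrategySpec]:
    """The 19 strategy/cue configurations of the experiment.

    1 no-bias control; taxis for each of F, H, I; constant heading
    against the global max and min of each cue (6); bi-gradient maps on
    the 3 unordered cue pairs; combination models on the 6 ordered cue
    pairs (first cue -> map raster, second cue -> heading raster).
    """
    specs: list[StrategySpec] = [StrategySpec(NO_BIAS)]
    specs += [StrategySpec(TAXIS, (c,)) for c in ("F", "H", "I")]
    specs += [
        StrategySpec(CONSTANT_HEADING, (c,), extreme=e)
        for e in ("max", "min")
        for c in ("F", "H", "I")
    ]
    specs += [StrategySpec(BIGRADIENT, p) for p in
              (("F", "H"), ("F", "I"), ("I", "H"))]
    specs += [StrategySpec(COMBINATION, p) for p in
              (("F", "H"), ("F", "I"), ("H", "F"),
               ("H", "I"), ("I", "F"), ("I", "H"))]
    assert len(specs) == 19 and len({s.label for s in specs}) == 19
    return specs
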