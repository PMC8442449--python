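"""Correlated random walk (CRW) and correlated random bridge (CRB)
engines over geomagnetic bias surfaces.

Each step the engine builds, on the window of grid cells reachable from
the walker's position (radius = the kernel's largest observed step),

* a movement surface from the empirical kernel — the probability per
  unit area of a step ending in each cell, given the previous step's
  length and turning angle;
* the strategy's bias surface on the same cells (rebuilt every step
  from the current day's grids; the constant-heading calibration angle
  is refreshed once per simulated day);
* for CRB, a pull-to-target weight encoding the feasibility of still
  reaching the fixed end point in the remaining steps,

multiplies them as movement**alpha * bias**beta (* pull), normalises,
samples one cell and jitters the position uniformly inside it.  The
default weighting (alpha=0.5, beta=1) takes the square root of the
movement surface against the full-strength bias, deliberately
over-weighting the geomagnetic signal relative to movement persistence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geofield import FieldStack, GridGeometry
from .movekernel import MovementKernel
from .strategies import (
    BiasModel,
    ProbabilitySurface,
    StrategySpec,
    TargetInfo,
)
from .tracks import Trajectory, wrap_angle

log = logging.getLogger(__name__)


class SimulationAbort(RuntimeError):
    """A replicate could not complete (no sampleable step after retries,
    or an infeasible bridge configuration)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Engine parameters for one batch.

    alpha, beta
        Exponents on the movement and bias surfaces (defaults 0.5 and
        1.0: square-rooted movement raster times full bias raster).
    heading_error
        Half-width (radians) of the error applied to the initial
        optimum heading; default pi/12.
    steps_per_day
        Hourly steps per simulated day (24); field grids and the
        constant-heading angle advance on day boundaries.
    """

    mode: str = "CRW"
    n_steps: int = 24
    start_xy: tuple[float, float] = (0.0, 0.0)
    target_xy: tuple[float, float] = (0.0, 0.0)
    alpha: float = 0.5
    beta: float = 1.0
    heading_error: float = np.pi / 12
    steps_per_day: int = 24
    n_replicates: int = 100
    seed: int = 0
    cell_mode: str = "jitter"            # "jitter" | "center"
    heading_error_dist: str = "uniform"  # "uniform" | "wrapped_normal"
    invert_taxis: bool = False
    combination_extreme: str = "min"

    def __post_init__(self) -> None:
        if self.mode not in ("CRW", "CRB"):
            raise ValueError(f"mode must be CRW or CRB, got {self.mode!r}")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not (0 <= self.heading_error <= np.pi):
            raise ValueError("heading_error must lie in [0, pi]")
        if self.cell_mode not in ("jitter", "center"):
            raise ValueError("cell_mode must be 'jitter' or 'center'")


@dataclass(frozen=True)
class SimulatedTrack:
    """One replicate: n_steps+1 positions plus the per-step (L, phi) log."""

    animal_id: str
    label: str
    replicate: int
    positions: np.ndarray          # (n_steps+1, 2)
    step_lengths: np.ndarray
    turning_angles: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1


# ---------------------------------------------------------------------------
# Window machinery
# ---------------------------------------------------------------------------

class _Window:
    """Precomputed relative cell offsets within one step's reach."""

    def __init__(self, geometry: GridGeometry, L_max: float) -> None:
        self.geometry = geometry
        self.radius_m = L_max
        rad = int(np.ceil(L_max / geometry.cell_size))
        dr, dc = np.meshgrid(np.arange(-rad, rad + 1),
                             np.arange(-rad, rad + 1), indexing="ij")
        keep = np.hypot(dr, dc) * geometry.cell_size <= L_max + geometry.cell_size
        self.dr = dr[keep].ravel()
        self.dc = dc[keep].ravel()

    def cells_around(self, x: float, y: float):
        """In-grid (rows, cols, cx, cy) of candidate cells around (x, y)."""
        geo = self.geometry
        r0, c0 = geo.cell_of(x, y)
        rows = r0 + self.dr
        cols = c0 + self.dc
        ok = (rows >= 0) & (rows < geo.n_rows) & (cols >= 0) & (cols < geo.n_cols)
        rows, cols = rows[ok], cols[ok]
        cx = geo.origin_x + cols * geo.cell_size
        cy = geo.origin_y - rows * geo.cell_size
        return rows, cols, cx, cy


def _movement_weights(kernel: MovementKernel, dist, phi, prev_L, prev_phi,
                      cell_size: float):
    """Area-density movement weights at candidate cells.

    step_density divided by the step length (floored at half a cell)
    converts the per-(L, phi) mass into a probability per unit area, so
    that sampling cells reproduces the kernel's (L, phi) law.
    """
    dens = kernel.step_density(dist, phi, prev_L, prev_phi)
    return dens / np.maximum(dist, cell_size / 2.0)


def movement_surface(kernel: MovementKernel, current_xy, prev_heading: float,
                     prev_L: float, prev_phi: float,
                     geometry: GridGeometry) -> ProbabilitySurface:
    """Full-grid movement surface around ``current_xy`` (zeros outside
    one step's reach; maximum rescaled to 1)."""
    x, y = current_xy
    if not geometry.contains(x, y):
        raise ValueError(f"current position ({x:g}, {y:g}) outside the grid")
    win = _Window(geometry, kernel.L_max)
    rows, cols, cx, cy = win.cells_around(x, y)
    if len(rows) == 0:
        raise ValueError("empty movement window")
    dist = np.hypot(cx - x, cy - y)
    phi = wrap_angle(np.arctan2(cy - y, cx - x) - prev_heading)
    w = _movement_weights(kernel, dist, phi, prev_L, prev_phi,
                          geometry.cell_size)
    w[dist > kernel.L_max] = 0.0
    if w.max() <= 0:
        raise ValueError("movement surface is zero everywhere in the window")
    values = np.zeros((geometry.n_rows, geometry.n_cols))
    values[rows, cols] = w / w.max()
    return ProbabilitySurface(geometry, values)


def combine_surfaces(movement: ProbabilitySurface, bias: ProbabilitySurface,
                     alpha: float = 0.5, beta: float = 1.0
                     ) -> ProbabilitySurface:
    """movement**alpha * bias**beta, normalised to sum 1 over the
    movement window.  If the bias annihilates the whole window the
    combination falls back to the movement surface alone (logged)."""
    if movement.geometry != bias.geometry:
        raise ValueError("movement and bias surfaces on different geometries")
    m = movement.values
    w = np.power(m, alpha) * np.power(bias.values, beta)
    if w.sum() <= 0:
        if np.power(m, alpha).sum() <= 0:
            raise ValueError("movement surface all-zero; nothing to sample")
        log.warning("bias annihilated the movement window; "
                    "falling back to movement alone")
        w = np.power(m, alpha)
    return ProbabilitySurface(movement.geometry, w / w.sum())


def crb_pull_surface(kernel: MovementKernel, current_xy, target_xy,
                     steps_remaining: int,
                     geometry: GridGeometry) -> ProbabilitySurface:
    """Feasibility-of-return weight for the bridge, on the window of
    cells reachable from the current position.

    With k = steps_remaining, a cell at distance d from the target is
    weighted by the normal density of the required mean per-step
    progress d/(k-1) under the kernel's step-length mean and a
    sqrt(k-1)-shrunk sd; cells needing more than (k-1)*L_max are
    infeasible (weight 0).  At k = 1 all mass sits on the target cell.
    """
    if steps_remaining < 1:
        raise ValueError("steps_remaining must be >= 1")
    x, y = current_xy
    win = _Window(geometry, kernel.L_max)
    rows, cols, cx, cy = win.cells_around(x, y)
    w = _pull_weights(kernel, np.hypot(cx - target_xy[0], cy - target_xy[1]),
                      steps_remaining)
    if steps_remaining == 1:
        tr, tc = geometry.cell_of(*target_xy)
        w = ((rows == tr) & (cols == tc)).astype(float)
    if w.max() <= 0:
        raise SimulationAbort(
            f"no feasible cell with {steps_remaining} steps remaining: "
            "n_steps too small for the distance to target"
        )
    values = np.zeros((geometry.n_rows, geometry.n_cols))
    values[rows, cols] = w / w.max()
    return ProbabilitySurface(geometry, values)


def _pull_weights(kernel: MovementKernel, dist_to_target, steps_remaining: int,
                  margin: float = 0.0):
    """Feasibility weights; ``margin`` shrinks the hard feasibility
    radius (the engine uses half a cell diagonal so that within-cell
    jitter can never break the bridge's distance budget)."""
    k = steps_remaining
    d = np.asarray(dist_to_target, dtype=float)
    if k == 1:
        # handled by the caller via the exact target cell; as a weight
        # function, concentrate on (numerically) zero distance
        return (d <= 1e-9).astype(float)
    need = d / (k - 1)
    sd = max(kernel.sd_L / np.sqrt(k - 1), 1e-2 * max(kernel.L_max, 1.0))
    feasible = d <= (k - 1) * kernel.L_max - margin
    # log-space with max-shift: relative weights survive even when the
    # raw normal densities all underflow (near-degenerate kernels)
    z = -0.5 * ((need - kernel.mean_L) / sd) ** 2
    z[~feasible] = -np.inf
    if not np.any(feasible):
        return np.zeros_like(d)
    w = np.exp(z - z[feasible].max())
    w[~feasible] = 0.0
    return w


def initial_heading(bias: ProbabilitySurface, start_xy, L_ref: float,
                    heading_error: float, rng: np.random.Generator,
                    target_xy=None, error_dist: str = "uniform") -> float:
    """Navigation-specific initial heading with a turning error.

    The optimum is the bearing from start to the highest-valued bias
    cell within L_ref (ties: nearest cell, then row-major order).  If
    no cell is strictly positive, or the bias is flat (uninformative),
    falls back to the bearing to ``target_xy``.  The returned heading
    is optimum + eps with eps ~ Uniform(-heading_error, heading_error)
    (or wrapped normal with sd heading_error).
    """
    geo = bias.geometry
    x, y = start_xy
    win = _Window(geo, L_ref)
    rows, cols, cx, cy = win.cells_around(x, y)
    dist = np.hypot(cx - x, cy - y)
    ok = (dist > 0) & (dist <= L_ref)
    vals = bias.values[rows, cols]
    optimum = _optimum_heading(vals[ok], dist[ok], cx[ok] - x, cy[ok] - y)
    if optimum is None:
        if target_xy is None:
            raise ValueError("flat/zero bias and no target to fall back to")
        optimum = float(np.arctan2(target_xy[1] - y, target_xy[0] - x))
    if error_dist == "uniform":
        eps = rng.uniform(-heading_error, heading_error)
    elif error_dist == "wrapped_normal":
        eps = rng.normal(0.0, heading_error)
    else:
        raise ValueError(f"unknown heading error distribution {error_dist!r}")
    return float(wrap_angle(optimum + eps))


def _optimum_heading(vals, dist, dx, dy):
    """Bearing to the best (highest, then nearest, then row-major) bias
    cell; None when the bias is non-positive or flat."""
    if len(vals) == 0 or vals.max() <= 0 or vals.max() - vals.min() < 1e-12:
        return None
    best = np.flatnonzero(vals >= vals.max() - 1e-15)
    i = best[np.argmin(dist[best])]  # row-major tie-break via stable argmin
    return float(np.arctan2(dy[i], dx[i]))


# ---------------------------------------------------------------------------
# The engines
# ---------------------------------------------------------------------------

class _Engine:
    """Shared per-replicate stepping machinery (CRW; CRB adds pull)."""

    def __init__(self, kernel: MovementKernel, spec: StrategySpec,
                 fields: Sequence[FieldStack], cfg: SimulationConfig,
                 target: TargetInfo) -> None:
        self.kernel = kernel
        self.spec = spec
        self.fields = list(fields)
        self.cfg = cfg
        self.target = target
        self.geometry = self.fields[0].geometry
        self.window = _Window(self.geometry, kernel.L_max)
        # flat locals for the hot loop
        k = kernel
        self._lw = k.len_bin_width
        self._aw = k.ang_bin_width
        self._dw = k.dL_bin_width
        self._nl = k.n_len_bins
        self._na = k.n_ang_bins
        self._nd = len(k.dL_hist)
        self._cap = k.L_max + k.len_bin_width

    def _stack_for_step(self, step: int) -> FieldStack:
        day = step // self.cfg.steps_per_day
        return self.fields[min(day, len(self.fields) - 1)]

    def _density(self, dist, phi, prev_L, prev_phi):
        """Inline step_density * area correction (hot path).

        Matches MovementKernel.step_density bin-for-bin (closed top
        bins; zero outside support) but avoids its per-call overhead.
        """
        k = self.kernel
        dL = dist - prev_L
        bad = (dist > k.L_max) | (dL < -k.L_max) | (dL > k.L_max)
        # +1e-9 matches the histogram's left-closed edges at round-off
        li = np.clip((dist / self._lw + 1e-9).astype(int), 0, self._nl - 1)
        ai = np.clip(((phi + np.pi) / self._aw + 1e-9).astype(int),
                     0, self._na - 1)
        di = np.clip(((dL + k.L_max) / self._dw + 1e-9).astype(int),
                     0, self._nd - 1)
        dphi = wrap_angle(phi - prev_phi)
        pi_ = np.clip(((dphi + np.pi) / self._aw + 1e-9).astype(int),
                      0, self._na - 1)
        dens = (k.joint_hist[li, ai] * k.dL_hist[di] * k.dPhi_hist[pi_])
        dens[bad] = 0.0
        return dens / np.maximum(dist, self.geometry.cell_size / 2.0)

    def _sample_cell(self, w, rng):
        total = w.sum()
        p = np.cumsum(w)
        return int(np.searchsorted(p, rng.random() * total))

    def run(self, animal_id: str, replicate: int,
            rng: np.random.Generator, attempts: int = 10) -> SimulatedTrack:
        """One replicate; a stranded walk (e.g. a bridge that fell
        behind its distance budget on a coarse grid) is re-drawn from
        the same generator stream, so results stay seed-deterministic."""
        last: SimulationAbort | None = None
        for _ in range(attempts):
            try:
                return self._run_once(animal_id, replicate, rng)
            except SimulationAbort as exc:
                last = exc
        raise last

    def _run_once(self, animal_id: str, replicate: int,
                  rng: np.random.Generator) -> SimulatedTrack:
        cfg = self.cfg
        kernel = self.kernel
        geo = self.geometry
        crb = cfg.mode == "CRB"
        tx, ty = self.target.target_xy
        if crb:
            direct = float(np.hypot(tx - cfg.start_xy[0], ty - cfg.start_xy[1]))
            if cfg.n_steps * kernel.L_max < direct:
                raise SimulationAbort(
                    f"bridge infeasible: {cfg.n_steps} steps x L_max "
                    f"{kernel.L_max:g} m < distance {direct:g} m"
                )

        bias = BiasModel(self.spec, self.fields[0], self.target,
                         invert_taxis=cfg.invert_taxis,
                         combination_extreme=cfg.combination_extreme)
        bias.calibrate(cfg.start_xy)
        x, y = cfg.start_xy
        heading = self._initial_heading(bias, rng)
        prev_L = kernel.mean_L if kernel.mean_L > 0 else kernel.L_max / 2
        prev_phi = 0.0

        n = cfg.n_steps
        pos = np.empty((n + 1, 2))
        pos[0] = (x, y)
        Ls = np.empty(n)
        phis = np.empty(n)
        current_day = 0

        for step in range(n):
            day = step // cfg.steps_per_day
            if day != current_day:
                current_day = day
                bias = BiasModel(self.spec, self._stack_for_step(step),
                                 self.target, invert_taxis=cfg.invert_taxis,
                                 combination_extreme=cfg.combination_extreme)
                bias.calibrate((x, y))

            if crb and step == n - 1:
                # bridge endpoint: final position is the target, exactly
                nx, ny = tx, ty
            else:
                nx, ny = self._one_step(bias, x, y, heading, prev_L, prev_phi,
                                        step, rng)
            dx, dy = nx - x, ny - y
            L = float(np.hypot(dx, dy))
            new_heading = float(np.arctan2(dy, dx)) if L > 0 else heading
            phi = float(wrap_angle(new_heading - heading))
            Ls[step] = L
            phis[step] = phi
            prev_L, prev_phi, heading = L, phi, new_heading
            x, y = nx, ny
            pos[step + 1] = (x, y)

        return SimulatedTrack(animal_id=animal_id, label=self.spec.label,
                              replicate=replicate, positions=pos,
                              step_lengths=Ls, turning_angles=phis)

    def _initial_heading(self, bias: BiasModel, rng) -> float:
        cfg = self.cfg
        x, y = cfg.start_xy
        rows, cols, cx, cy = self.window.cells_around(x, y)
        dist = np.hypot(cx - x, cy - y)
        ok = (dist > 0) & (dist <= self.kernel.L_max)
        vals = bias.at_cells(rows[ok], cols[ok], (x, y))
        optimum = _optimum_heading(vals, dist[ok], cx[ok] - x, cy[ok] - y)
        if optimum is None:
            optimum = float(np.arctan2(cfg.target_xy[1] - y,
                                       cfg.target_xy[0] - x))
        if cfg.heading_error_dist == "uniform":
            eps = rng.uniform(-cfg.heading_error, cfg.heading_error)
        else:
            eps = rng.normal(0.0, cfg.heading_error)
        return float(wrap_angle(optimum + eps))

    def _one_step(self, bias: BiasModel, x, y, heading, prev_L, prev_phi,
                  step, rng) -> tuple[float, float]:
        cfg = self.cfg
        geo = self.geometry
        crb = cfg.mode == "CRB"
        rows, cols, cx, cy = self.window.cells_around(x, y)
        if len(rows) == 0:
            raise SimulationAbort(
                f"walker at ({x:g}, {y:g}) has no in-grid cells in reach"
            )
        dist = np.hypot(cx - x, cy - y)
        phi = wrap_angle(np.arctan2(cy - y, cx - x) - heading)
        m = self._density(dist, phi, prev_L, prev_phi)
        if m.max() <= 0:
            # disjoint lag-1 supports: fall back to the joint law alone
            m = self.kernel.joint_density(dist, phi)
            m = m / np.maximum(dist, geo.cell_size / 2.0)
        if m.max() <= 0:
            # clipped window left no kernel support (grid edge, reversed
            # heading): keep the walk defined, uniform over reach
            m = ((dist > 0) & (dist <= self.kernel.L_max)).astype(float)
        if m.max() > 0:
            m = m / m.max()
        b = np.clip(bias.at_cells(rows, cols, (x, y)), 0.0, 1.0)
        if b.max() > 0:
            # rescale to the window max before exponentiating: the
            # sampling distribution is unchanged (normalised below) and
            # beta-fold powers of small probabilities cannot underflow
            b = b / b.max()
        w = np.power(m, cfg.alpha) * np.power(b, cfg.beta)
        if w.sum() <= 0:
            # bias annihilated the window: movement alone
            w = np.power(m, cfg.alpha)
        if crb:
            steps_remaining = cfg.n_steps - step
            margin = geo.cell_size / np.sqrt(2.0) if cfg.cell_mode == "jitter" else 0.0
            pull = _pull_weights(
                self.kernel,
                np.hypot(cx - self.target.target_xy[0],
                         cy - self.target.target_xy[1]),
                steps_remaining,
                margin=margin,
            )
            w = w * pull
            if w.sum() <= 0:
                # keep the bridge feasible even where movement mass dies
                w = pull
        if w.sum() <= 0:
            raise SimulationAbort(
                f"no sampleable cell at step {step} from ({x:g}, {y:g})"
            )
        idx = self._sample_cell(w, rng)
        nx, ny = float(cx[idx]), float(cy[idx])
        if cfg.cell_mode == "jitter":
            half = geo.cell_size / 2.0
            nx += rng.uniform(-half, half)
            ny += rng.uniform(-half, half)
        # step-length cap: L_max + one length-bin width
        dxy = np.hypot(nx - x, ny - y)
        if dxy > self._cap:
            s = self._cap / dxy
            nx = x + (nx - x) * s
            ny = y + (ny - y) * s
        return nx, ny


def simulate_crw(kernel: MovementKernel, spec: StrategySpec,
                 fields: Sequence[FieldStack], cfg: SimulationConfig,
                 target: TargetInfo, rng: np.random.Generator,
                 animal_id: str = "sim", replicate: int = 0) -> SimulatedTrack:
    """One correlated-random-walk replicate (free end point)."""
    cfg = replace(cfg, mode="CRW")
    return _Engine(kernel, spec, fields, cfg, target).run(animal_id,
                                                          replicate, rng)


def simulate_crb(kernel: MovementKernel, spec: StrategySpec,
                 fields: Sequence[FieldStack], cfg: SimulationConfig,
                 target: TargetInfo, rng: np.random.Generator,
                 animal_id: str = "sim", replicate: int = 0) -> SimulatedTrack:
    """One correlated-random-bridge replicate (both end points fixed)."""
    cfg = replace(cfg, mode="CRB")
    return _Engine(kernel, spec, fields, cfg, target).run(animal_id,
                                                          replicate, rng)


# ---------------------------------------------------------------------------
# Batches
# ---------------------------------------------------------------------------

def run_batch(kernel: MovementKernel, specs: Sequence[StrategySpec],
              animals: Sequence[tuple[Trajectory, TargetInfo]],
              fields: Sequence[FieldStack] | dict,
              cfg: SimulationConfig,
              max_retries: int = 5) -> list[SimulatedTrack]:
    """|specs| x |animals| x n_replicates simulated tracks.

    Per animal, n_steps is that animal's hourly step count and
    start/target come from its empirical trajectory.  ``fields`` is
    either one FieldStack sequence shared by all animals or a dict
    animal_id -> sequence.  Replicate r of animal a under spec s uses
    an independent RNG substream derived from (seed, s, a, r), so any
    subset of the batch is reproducible in isolation.
    """
    out: list[SimulatedTrack] = []
    for s_idx, spec in enumerate(specs):
        for a_idx, (traj, target) in enumerate(animals):
            f = fields[traj.animal_id] if isinstance(fields, dict) else fields
            acfg = replace(
                cfg,
                n_steps=len(traj) - 1,
                start_xy=traj.start_xy,
                target_xy=target.target_xy,
            )
            engine = _Engine(kernel, spec, f, acfg, target)
            for rep in range(cfg.n_replicates):
                for retry in range(max_retries):
                    rng = np.random.default_rng(
                        np.random.SeedSequence(
                            [cfg.seed, s_idx, a_idx, rep, retry]
                        )
                    )
                    try:
                        out.append(engine.run(traj.animal_id, rep, rng))
                        break
                    except SimulationAbort as exc:
                        log.warning(
                            "replicate %d of %s/%s failed (%s); redrawing",
                            rep, spec.label, traj.animal_id, exc,
                        )
                else:
                    raise SimulationAbort(
                        f"replicate {rep} of {spec.label}/{traj.animal_id} "
                        f"failed {max_retries} times"
                    )
    return out


def batch_to_frame(tracks: Sequence[SimulatedTrack]) -> pd.DataFrame:
    """Long-format table (animal_id, label, replicate, step, x, y)."""
    frames = []
    for t in tracks:
        n = len(t.positions)
        frames.append(pd.DataFrame({
            "animal_id": t.animal_id,
            "label": t.label,
            "replicate": t.replicate,
            "step": np.arange(n),
            "x": t.positions[:, 0],
            "y": t.positions[:, 1],
        }))
    return pd.concat(frames, ignore_index=True)
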