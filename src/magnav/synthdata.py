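"""Synthetic geomagnetic field stacks and migration tracks.

The generator emulates the study conditions end to end without any
download: a planar monotone "pseudo-dipole" field (F, I and H all
decline smoothly with distance from a simulated pole corner, H =
F*cos(I) exactly, with optional daily drift and storm noise), and
autumn migration tracks — hourly fixes over up to three days covering
1500-3000 km — either as a noisy straight corridor or generated by the
package's own walk engine under a chosen navigational strategy.

The pseudo-dipole is deliberately not a physical dipole: it preserves
exactly the properties the strategies consume (smooth monotone
gradients, consistent F/I/H relations, daily dynamics) at trivial
cost.  Its default amplitude (63,000 nT at the pole to 24,000 nT at
the equatorward edge over the domain diagonal) reproduces a mean
intensity gradient of order 10 nT/km on a continental-scale domain.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .geofield import CUES, FieldGrid, FieldStack, GridGeometry, value_at
from .movekernel import MovementKernel, estimate_kernel
from .strategies import StrategySpec, TargetInfo, TAXIS
from .tracks import KM, Trajectory, to_steps

_EPOCH = _dt.date(2016, 9, 19)


@dataclass(frozen=True)
class SynthFieldParams:
    """Planar pseudo-dipole field parameters.

    F interpolates linearly from ``F_pole`` at ``pole_xy`` to
    ``F_equator`` at the farthest grid corner; I likewise; H is derived
    as F*cos(I).  ``daily_drift`` shifts F (and hence H) by a constant
    per day; ``storm_amplitude`` adds zero-mean cellwise noise to F
    (truncated at 3 sd), emulating daily disturbance of the field.
    """

    geometry: GridGeometry
    pole_xy: tuple[float, float] = (0.0, 0.0)
    F_pole: float = 63000.0
    F_equator: float = 24000.0
    I_pole: float = 90.0
    I_equator: float = 10.0
    daily_drift: float = 0.0       # nT/day on F
    storm_amplitude: float = 0.0   # nT sd on F
    pole_drift: tuple[float, float] = (0.0, 0.0)  # m/day pole wander
    profile_k: float = 0.0         # 0 = linear radial falloff; > 0 convex
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.F_pole > self.F_equator > 0):
            raise ValueError("need F_pole > F_equator > 0")
        if not (90 >= self.I_pole > self.I_equator >= 0):
            raise ValueError("need 90 >= I_pole > I_equator >= 0")


@dataclass(frozen=True)
class SynthTrackParams:
    """Synthetic autumn-migration track parameters.

    Corridor mode emits hourly fixes along ``corridor_heading`` at
    ``mean_speed`` with seeded heading and speed noise; strategy mode
    regenerates the tracks with the package's own CRW engine under
    ``generating_strategy`` at bias weight ``bias_beta``, plus
    positional jitter.  Defaults emulate 14 autumn migrations of
    1500-3000 km completed within 3 days at 1 h fixes.
    """

    n_animals: int = 14
    duration_h: int = 72
    mean_speed_kmh: float = 28.0
    corridor_heading: float = -np.pi / 4
    heading_noise_sd: float = 0.2
    speed_noise_cv: float = 0.15
    start_xy: tuple[float, float] = (100.0 * KM, -100.0 * KM)
    start_spacing_m: float = 30.0 * KM
    generating_strategy: StrategySpec | None = None
    bias_beta: float = 5.0
    position_jitter_m: float = 0.0
    min_length_km: float = 1500.0
    kernel_bins: tuple[int, int] = (30, 24)  # reference kernel (len, ang)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h > 72:
            raise ValueError("migrations are completed within 3 days (72 h)")
        if self.n_animals < 1:
            raise ValueError("need at least one animal")


def _radial_fraction(p: SynthFieldParams, pole_xy) -> np.ndarray:
    """Per-cell distance from the pole, as a fraction of the farthest
    grid corner (0 at the pole, 1 at the far corner)."""
    geo = p.geometry
    X, Y = np.meshgrid(geo.x_coords(), geo.y_coords())
    d = np.hypot(X - pole_xy[0], Y - pole_xy[1])
    corners = [
        (geo.x_min, geo.y_min), (geo.x_min, geo.y_max),
        (geo.x_max, geo.y_min), (geo.x_max, geo.y_max),
    ]
    d_max = max(np.hypot(cx - pole_xy[0], cy - pole_xy[1])
                for cx, cy in corners)
    return d / d_max


def _profile_shape(frac: np.ndarray, k: float) -> np.ndarray:
    """Monotone increasing shape s(frac): 0 at the pole, 1 at the far
    corner.  k = 0 is linear; k > 0 is convex (the cue falls slowly
    near the pole and steeply equatorward, dipole-like), so the
    *relative* gradient is roughly constant across the domain."""
    if k == 0.0:
        return frac
    return np.expm1(k * frac) / np.expm1(k)


def synth_field_stack(p: SynthFieldParams,
                      dates: list[_dt.date]) -> list[FieldStack]:
    """One FieldStack per date under drift, storm and pole-wander
    dynamics.  Each day is radially monotone from that day's pole."""
    out = []
    d0 = dates[0]
    for date in dates:
        k = (date - d0).days
        pole = (p.pole_xy[0] + k * p.pole_drift[0],
                p.pole_xy[1] + k * p.pole_drift[1])
        frac = _radial_fraction(p, pole)
        shape = _profile_shape(frac, p.profile_k)
        F0 = p.F_pole + (p.F_equator - p.F_pole) * shape
        I0 = p.I_pole + (p.I_equator - p.I_pole) * frac
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, k]))
        F = F0 + p.daily_drift * k
        if p.storm_amplitude > 0:
            noise = rng.normal(0.0, p.storm_amplitude, size=F.shape)
            np.clip(noise, -3 * p.storm_amplitude, 3 * p.storm_amplitude,
                    out=noise)
            F = F + noise
        F = np.clip(F, 0.0, None)
        I = np.clip(I0, 0.0, 90.0)
        H = F * np.cos(np.deg2rad(I))
        out.append(FieldStack({
            "F": FieldGrid("F", date, p.geometry, F),
            "I": FieldGrid("I", date, p.geometry, I),
            "H": FieldGrid("H", date, p.geometry, np.clip(H, 0.0, None)),
        }))
    return out


def _corridor_track(p: SynthTrackParams, animal_idx: int,
                    rng: np.random.Generator) -> Trajectory:
    n = p.duration_h
    # start points spread perpendicular-ish to the corridor (along +x)
    x = p.start_xy[0] + animal_idx * p.start_spacing_m
    y = p.start_xy[1]
    headings = p.corridor_heading + rng.normal(0.0, p.heading_noise_sd, n)
    speeds = p.mean_speed_kmh * np.exp(
        rng.normal(0.0, p.speed_noise_cv, n) - p.speed_noise_cv**2 / 2
    )
    speeds = np.clip(speeds, 7.0, None)  # stays above the 6 km/h filter
    dx = speeds * KM * np.cos(headings)
    dy = speeds * KM * np.sin(headings)
    xs = np.concatenate([[x], x + np.cumsum(dx)])
    ys = np.concatenate([[y], y + np.cumsum(dy)])
    t0 = np.datetime64(f"{_EPOCH.isoformat()}T00:00:00", "s")
    times = t0 + np.arange(n + 1) * np.timedelta64(3600, "s")
    return Trajectory(f"a{animal_idx + 1:02d}", times, xs, ys)


def synth_tracks(p: SynthTrackParams, fields: list[FieldStack],
                 kernel: MovementKernel | None = None,
                 max_retries: int = 10) -> list[Trajectory]:
    """Generate hourly migration tracks inside the field domain.

    Corridor mode (``generating_strategy is None``) draws noisy
    straight flights; strategy mode runs the CRW engine under the
    given strategy at ``bias_beta`` (estimating a reference kernel
    from corridor tracks unless one is passed) and adds positional
    jitter.  Tracks violating the minimum-length filter are redrawn
    from a fresh substream (bounded retries).
    """
    from .simulate import SimulationConfig, simulate_crw  # cycle guard

    geo = fields[0].geometry
    tracks: list[Trajectory] = []
    if p.generating_strategy is not None and kernel is None:
        corridor = synth_tracks(replace(p, generating_strategy=None), fields)
        kernel = estimate_kernel([to_steps(t) for t in corridor],
                                 n_len_bins=p.kernel_bins[0],
                                 n_ang_bins=p.kernel_bins[1])
    for i in range(p.n_animals):
        for retry in range(max_retries):
            rng = np.random.default_rng(
                np.random.SeedSequence([p.seed, 7, i, retry])
            )
            if p.generating_strategy is None:
                traj = _corridor_track(p, i, rng)
            else:
                traj = _strategy_track(p, i, fields, kernel, rng)
            inside = (
                (traj.x >= geo.x_min) & (traj.x <= geo.x_max)
                & (traj.y >= geo.y_min) & (traj.y <= geo.y_max)
            )
            if traj.path_length_km() > p.min_length_km and inside.all():
                tracks.append(traj)
                break
        else:
            raise RuntimeError(
                f"could not generate a valid track for animal {i} "
                f"in {max_retries} tries (length/bounds constraints)"
            )
    return tracks


def _strategy_track(p: SynthTrackParams, animal_idx: int,
                    fields: list[FieldStack], kernel: MovementKernel,
                    rng: np.random.Generator) -> Trajectory:
    from .simulate import SimulationConfig, simulate_crw

    start = (p.start_xy[0] + animal_idx * p.start_spacing_m, p.start_xy[1])
    # nominal target straight down the corridor (used only as a fallback
    # aim; the walk is free-ended)
    reach = p.duration_h * p.mean_speed_kmh * KM
    target = (start[0] + reach * np.cos(p.corridor_heading),
              start[1] + reach * np.sin(p.corridor_heading))
    cfg = SimulationConfig(
        mode="CRW", n_steps=p.duration_h, start_xy=start, target_xy=target,
        alpha=0.5, beta=p.bias_beta, n_replicates=1,
        seed=int(rng.integers(2**31 - 1)),
    )
    day_last = min((p.duration_h - 1) // 24, len(fields) - 1)
    tinfo = TargetInfo(target_xy=target, target_values={
        cue: value_at(fields[day_last][cue], *target) if
        fields[day_last].geometry.contains(*target) else
        float(fields[day_last][cue].values.min())
        for cue in CUES
    })
    sim = simulate_crw(kernel, p.generating_strategy, fields, cfg, tinfo, rng,
                       animal_id=f"a{animal_idx + 1:02d}")
    xs = sim.positions[:, 0].copy()
    ys = sim.positions[:, 1].copy()
    if p.position_jitter_m > 0:
        xs += rng.normal(0.0, p.position_jitter_m, len(xs))
        ys += rng.normal(0.0, p.position_jitter_m, len(ys))
    t0 = np.datetime64(f"{_EPOCH.isoformat()}T00:00:00", "s")
    times = t0 + np.arange(len(xs)) * np.timedelta64(3600, "s")
    return Trajectory(f"a{animal_idx + 1:02d}", times, xs, ys)


# ---------------------------------------------------------------------------
# Named fixture scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureBundle:
    """Everything one end-to-end run needs, fully reproducible."""

    name: str
    fields: list[FieldStack]
    trajectories: list[Trajectory]
    targets: dict            # animal_id -> TargetInfo
    kernel: MovementKernel
    field_params: SynthFieldParams
    track_params: SynthTrackParams

    @property
    def observed(self) -> dict:
        return {t.animal_id: t.positions for t in self.trajectories}

    @property
    def animals(self) -> list:
        return [(t, self.targets[t.animal_id]) for t in self.trajectories]


def _dates(n_days: int) -> list[_dt.date]:
    return [_EPOCH + _dt.timedelta(days=k) for k in range(n_days)]


def _targets_for(tracks: list[Trajectory],
                 fields: list[FieldStack]) -> dict:
    targets = {}
    for t in tracks:
        day = min((len(t) - 2) // 24, len(fields) - 1)
        stack = fields[day]
        tx, ty = t.end_xy
        targets[t.animal_id] = TargetInfo(
            target_xy=(tx, ty),
            target_values={cue: value_at(stack[cue], tx, ty) for cue in CUES},
        )
    return targets


_SCENARIOS = {
    "smoke": dict(
        geometry=GridGeometry(0.0, 0.0, 10 * KM, 60, 60, "synthetic-planar"),
        field=dict(seed=101),
        track=dict(n_animals=3, duration_h=24, mean_speed_kmh=22.0,
                   heading_noise_sd=0.25, start_xy=(60 * KM, -60 * KM),
                   start_spacing_m=20 * KM, min_length_km=400.0, seed=201),
    ),
    "study-scale": dict(
        geometry=GridGeometry(0.0, 0.0, 20 * KM, 100, 100, "synthetic-planar"),
        field=dict(daily_drift=20.0, storm_amplitude=30.0, seed=102),
        track=dict(n_animals=14, duration_h=72, mean_speed_kmh=28.0,
                   heading_noise_sd=0.2, start_xy=(100 * KM, -100 * KM),
                   start_spacing_m=30 * KM, min_length_km=1500.0, seed=202),
    ),
    # Parameter-recovery scenario.  The route has a hard day-boundary
    # dog-leg (the pole jumps between days, rotating the gradient ~100
    # degrees), the intensity profile is steeply convex so relative
    # gradients are strong along the whole corridor, and the raster is
    # fine relative to the hourly step so the bias can steer within the
    # movement cone.  Gradient-followers reproduce the dog-leg;
    # endpoint-pursuit strategies bisect it.
    "recovery-taxis": dict(
        geometry=GridGeometry(0.0, 0.0, 2.5 * KM, 320, 320,
                              "synthetic-planar"),
        field=dict(pole_drift=(650 * KM, -250 * KM), profile_k=35.0,
                   seed=103),
        track=dict(n_animals=6, duration_h=48, mean_speed_kmh=12.0,
                   heading_noise_sd=0.10, start_xy=(140 * KM, -140 * KM),
                   start_spacing_m=20 * KM, min_length_km=400.0,
                   generating_strategy=StrategySpec(TAXIS, ("F",)),
                   bias_beta=5.0, position_jitter_m=1000.0,
                   kernel_bins=(12, 4), seed=203),
    ),
}


def fixture_scenario(name: str) -> FixtureBundle:
    """Named, seeded, fully reproducible fixture bundles.

    * ``smoke`` — 3 animals, 24 hourly steps, 60x60 grid of 10 km
      cells: fast end-to-end wiring checks.
    * ``study-scale`` — 14 animals, 72 hourly steps, 100x100 grid of
      20 km cells with daily drift and storm noise: the study's batch
      bookkeeping at full animal/replicate counts.
    * ``recovery-taxis`` — 6 animals, 36 steps, 80x80 grid; tracks
      generated by the package's own CRW engine under intensity taxis
      at high bias weight: parameter-recovery experiments.
    """
    if name not in _SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}"
        )
    sc = _SCENARIOS[name]
    fp = SynthFieldParams(geometry=sc["geometry"], **sc["field"])
    tp = SynthTrackParams(**sc["track"])
    n_days = (tp.duration_h + 23) // 24
    fields = synth_field_stack(fp, _dates(n_days))
    tracks = synth_tracks(tp, fields)
    kernel = estimate_kernel([to_steps(t) for t in tracks],
                             n_len_bins=tp.kernel_bins[0],
                             n_ang_bins=tp.kernel_bins[1])
    return FixtureBundle(
        name=name,
        fields=fields,
        trajectories=tracks,
        targets=_targets_for(tracks, fields),
        kernel=kernel,
        field_params=fp,
        track_params=tp,
    )
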