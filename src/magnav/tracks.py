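"""GPS track ingest and migratory-flight preprocessing.

Implements the standard cleaning pipeline for hourly migration
modelling: exclusion zones around breeding/wintering areas, a ground
speed filter to keep only in-flight fixes, a minimum path-length filter,
and linear interpolation to a regular hourly interval, followed by
decomposition into step lengths, headings and turning angles.

Angles use the mathematical convention throughout: radians measured
counter-clockwise from the +x axis, wrapped to (-pi, pi].
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

KM = 1000.0


def wrap_angle(a):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PreprocessParams:
    """Preprocessing thresholds (defaults: autumn goose migration).

    speed_threshold
        Minimum ground speed in km/h for a fix to count as flying
        (default 6; slower fixes are stopovers).
    north_radius, southwest_radius
        Radii in km of the exclusion zones around the northernmost
        (breeding) and the southernmost/westernmost (wintering) fixes
        (defaults 500 and 700).
    min_track_length
        Minimum migratory path length in km (default 1500).
    interp_interval
        Regular fix interval in hours after interpolation (default 1).
    """

    speed_threshold: float = 6.0
    north_radius: float = 500.0
    southwest_radius: float = 700.0
    min_track_length: float = 1500.0
    interp_interval: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "speed_threshold",
            "north_radius",
            "southwest_radius",
            "min_track_length",
            "interp_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered projected fixes of one animal's migration.

    ``times`` is a datetime64[s] array, ``x``/``y`` planar metres.
    """

    animal_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype="datetime64[s]")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        n = len(times)
        if not (len(x) == len(y) == n):
            raise ValueError("times, x, y must have equal length")
        if n < 2:
            raise ValueError(
                f"trajectory {self.animal_id!r} needs >= 2 fixes, got {n}"
            )
        if not np.all(np.diff(times.astype("int64")) > 0):
            raise ValueError(
                f"trajectory {self.animal_id!r}: timestamps must be "
                "strictly increasing"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError(f"trajectory {self.animal_id!r}: non-finite coordinates")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def start_xy(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.y[0])

    @property
    def end_xy(self) -> tuple[float, float]:
        return float(self.x[-1]), float(self.y[-1])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of planar coordinates."""
        return np.column_stack([self.x, self.y])

    def path_length_km(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum() / KM)

    def segment_hours(self) -> np.ndarray:
        return np.diff(self.times.astype("int64")) / 3600.0

    def segment_speeds_kmh(self) -> np.ndarray:
        d_km = np.hypot(np.diff(self.x), np.diff(self.y)) / KM
        return d_km / self.segment_hours()

    def start_date(self) -> _dt.date:
        return pd.Timestamp(self.times[0]).date()


@dataclass(frozen=True)
class StepSeries:
    """Step decomposition of an (hourly) trajectory.

    ``headings`` are the directions of each displacement; the turning
    angle at step t is the wrapped heading change from step t-1.
    """

    step_lengths: np.ndarray
    headings: np.ndarray
    turning_angles: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.step_lengths, dtype=float)
        h = np.asarray(self.headings, dtype=float)
        phi = np.asarray(self.turning_angles, dtype=float)
        if len(h) != len(L):
            raise ValueError("headings and step_lengths must align")
        if len(phi) != max(len(L) - 1, 0):
            raise ValueError("need exactly len(step_lengths)-1 turning angles")
        if np.any(L < 0):
            raise ValueError("step lengths must be non-negative")
        object.__setattr__(self, "step_lengths", L)
        object.__setattr__(self, "headings", h)
        object.__setattr__(self, "turning_angles", phi)

    @property
    def n_steps(self) -> int:
        return len(self.step_lengths)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks(path) -> list[Trajectory]:
    """Read trajectories from a CSV with columns animal_id,timestamp,x,y.

    Timestamps are ISO-8601 (UTC assumed); rows may be unordered and are
    sorted per animal.  Duplicate (animal_id, timestamp) pairs raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"animal_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path.name}: malformed timestamp: {exc}") from exc
    df["timestamp"] = df["timestamp"].dt.tz_localize(None)
    out: list[Trajectory] = []
    for animal_id, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("timestamp")
        dup = g["timestamp"].duplicated()
        if dup.any():
            t = g.loc[dup.idxmax(), "timestamp"]
            raise ValueError(
                f"duplicate timestamp {t} for animal {animal_id!r}"
            )
        out.append(
            Trajectory(
                animal_id=str(animal_id),
                times=g["timestamp"].to_numpy(dtype="datetime64[s]"),
                x=g["x"].to_numpy(dtype=float),
                y=g["y"].to_numpy(dtype=float),
            )
        )
    return out


def write_tracks(trajectories: list[Trajectory], path) -> Path:
    """Write trajectories to the same CSV dialect read_tracks consumes."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "animal_id": t.animal_id,
                "timestamp": pd.to_datetime(t.times).strftime("%Y-%m-%dT%H:%M:%S"),
                "x": t.x,
                "y": t.y,
            }
        )
        for t in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def to_geojson(traj: Trajectory) -> dict:
    """GeoJSON LineString feature (planar coordinates) for one track."""
    return {
        "type": "Feature",
        "properties": {
            "animal_id": traj.animal_id,
            "start": str(pd.Timestamp(traj.times[0])),
            "end": str(pd.Timestamp(traj.times[-1])),
        },
        "geometry": {
            "type": "LineString",
            "coordinates": [[float(a), float(b)] for a, b in zip(traj.x, traj.y)],
        },
    }


# ---------------------------------------------------------------------------
# Preprocessing stages
# ---------------------------------------------------------------------------

def speed_filter(traj: Trajectory, threshold_kmh: float = 6.0) -> Trajectory | None:
    """Drop fixes whose adjacent ground speeds are all below threshold.

    A fix is retained iff max(incoming, outgoing segment speed) >=
    threshold; terminal fixes are judged by their single adjacent
    segment.  Removes stationary stopover clusters while keeping flight
    onset/offset fixes.  Returns None if fewer than 2 fixes survive
    (track unusable).
    """
    speeds = traj.segment_speeds_kmh()
    n = len(traj)
    keep = np.zeros(n, dtype=bool)
    keep[0] = speeds[0] >= threshold_kmh
    keep[-1] = speeds[-1] >= threshold_kmh
    if n > 2:
        keep[1:-1] = np.maximum(speeds[:-1], speeds[1:]) >= threshold_kmh
    if keep.sum() < 2:
        return None
    return Trajectory(traj.animal_id, traj.times[keep], traj.x[keep], traj.y[keep])


def exclusion_zones(traj: Trajectory, params: PreprocessParams) -> Trajectory | None:
    """Remove fixes inside the breeding/wintering exclusion circles.

    Circles are centred on the northernmost fix (radius north_radius)
    and on the southernmost and westernmost fixes (radius
    southwest_radius), with plain Euclidean distances.  Intended to be
    called once per animal per migration.  Returns None if < 2 fixes
    survive.
    """
    x, y = traj.x, traj.y
    anchors = [
        (int(np.argmax(y)), params.north_radius * KM),
        (int(np.argmin(y)), params.southwest_radius * KM),
        (int(np.argmin(x)), params.southwest_radius * KM),
    ]
    remove = np.zeros(len(traj), dtype=bool)
    for idx, radius in anchors:
        d = np.hypot(x - x[idx], y - y[idx])
        remove |= d < radius
    keep = ~remove
    if keep.sum() < 2:
        return None
    return Trajectory(traj.animal_id, traj.times[keep], x[keep], y[keep])


def length_filter(traj: Trajectory, min_km: float = 1500.0) -> bool:
    """Keep iff the summed segment (path) length exceeds min_km."""
    return traj.path_length_km() > min_km


def interpolate_hourly(traj: Trajectory, interval_h: float = 1.0) -> Trajectory:
    """Linearly interpolate fixes onto a regular time lattice.

    Output fixes sit at t0, t0+interval, ... up to (and never beyond)
    the last original timestamp; coordinates are linear in time between
    the bracketing originals.  Idempotent on already-regular tracks.
    """
    t = traj.times.astype("int64").astype(float)  # seconds
    step = interval_h * 3600.0
    n_out = int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    t_new = t[0] + step * np.arange(n_out)
    x_new = np.interp(t_new, t, traj.x)
    y_new = np.interp(t_new, t, traj.y)
    times_new = np.round(t_new).astype("int64").astype("datetime64[s]")
    return Trajectory(traj.animal_id, times_new, x_new, y_new)


def preprocess(traj: Trajectory, params: PreprocessParams | None = None
               ) -> Trajectory | None:
    """Full pipeline: exclusion zones -> speed filter -> length filter ->
    hourly interpolation.  Returns None for tracks that fail a filter."""
    params = params or PreprocessParams()
    out = exclusion_zones(traj, params)
    if out is None:
        return None
    out = speed_filter(out, params.speed_threshold)
    if out is None:
        return None
    if not length_filter(out, params.min_track_length):
        return None
    return interpolate_hourly(out, params.interp_interval)


def to_steps(traj: Trajectory) -> StepSeries:
    """Decompose into step lengths, headings and turning angles."""
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    L = np.hypot(dx, dy)
    headings = wrap_angle(np.arctan2(dy, dx))
    phi = wrap_angle(np.diff(headings))
    return StepSeries(step_lengths=L, headings=np.atleast_1d(headings),
                      turning_angles=np.atleast_1d(phi))
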