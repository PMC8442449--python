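"""Trajectory similarity: mean distance, dynamic time warping, and the
dynamic interaction index.

All three measures compare a simulated track against the matched
empirical track.  Mean distance and DI require equal point counts
(guaranteed in the experiment, where each simulation uses the animal's
own hourly step count); DTW aligns sequences of any lengths.

DTW here is the classic unnormalised dynamic-programming variant with
Euclidean local cost and unit-slope moves (match / insert / delete),
no window constraint: the accumulated cost of the cheapest monotone
warping path.  The dynamic interaction index follows the dyadic
movement-similarity statistic of Long & Nelson: per step, the cosine
of the heading difference times ``1 - (|d1 - d2|/(d1 + d2))**delta``,
averaged over steps; it lies in [-1, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

try:  # numba accelerates the DTW inner loop; plain Python works too
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


def _as_points(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {p.shape}")
    return p


def mean_distance(sim, obs) -> float:
    """Mean pointwise Euclidean distance between matched positions.

    Lower is more similar; 0 for identical sequences.
    """
    sim, obs = _as_points(sim), _as_points(obs)
    if len(sim) != len(obs):
        raise ValueError(
            f"point counts differ ({len(sim)} vs {len(obs)}); "
            "mean distance needs matched sequences"
        )
    return float(np.hypot(*(sim - obs).T).mean())


@_njit(cache=False)
def _dtw_cost(cost: np.ndarray) -> float:  # pragma: no cover - jitted
    n, m = cost.shape
    D = np.empty((n, m))
    D[0, 0] = cost[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost[i, j] + best
    return D[n - 1, m - 1]


def dtw_distance(sim, obs) -> float:
    """Accumulated cost of the optimal warping path (metres)."""
    sim, obs = _as_points(sim), _as_points(obs)
    if len(sim) == 0 or len(obs) == 0:
        raise ValueError("dtw_distance needs non-empty sequences")
    dx = sim[:, 0][:, None] - obs[:, 0][None, :]
    dy = sim[:, 1][:, None] - obs[:, 1][None, :]
    return float(_dtw_cost(np.hypot(dx, dy)))


def di_index(sim, obs, delta: float = 1.0) -> float:
    """Dynamic interaction index of the two matched tracks.

    Per step t the azimuthal component is cos(theta_sim - theta_obs)
    and the displacement component 1 - (|d_sim - d_obs|/(d_sim +
    d_obs))**delta; their product is averaged over steps.  When both
    displacements are zero the displacement component is 1 (and the
    angle difference taken as 0); when exactly one is zero it is 0.
    """
    sim, obs = _as_points(sim), _as_points(obs)
    if len(sim) != len(obs):
        raise ValueError(
            f"point counts differ ({len(sim)} vs {len(obs)}); "
            "DI needs matched sequences"
        )
    if len(sim) < 2:
        raise ValueError("DI needs at least 2 points")
    v1 = np.diff(sim, axis=0)
    v2 = np.diff(obs, axis=0)
    d1 = np.hypot(v1[:, 0], v1[:, 1])
    d2 = np.hypot(v2[:, 0], v2[:, 1])
    both_zero = (d1 == 0) & (d2 == 0)
    one_zero = ((d1 == 0) | (d2 == 0)) & ~both_zero
    theta1 = np.arctan2(v1[:, 1], v1[:, 0])
    theta2 = np.arctan2(v2[:, 1], v2[:, 0])
    az = np.cos(theta1 - theta2)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = 1.0 - (np.abs(d1 - d2) / (d1 + d2)) ** delta
    di_t = az * disp
    di_t[both_zero] = 1.0
    di_t[one_zero] = 0.0
    return float(di_t.mean())


def score_pair(sim, obs, delta: float = 1.0) -> dict:
    """All three measures for one simulated/observed pair."""
    return {
        "mean_distance": mean_distance(sim, obs),
        "dtw": dtw_distance(sim, obs),
        "di": di_index(sim, obs, delta=delta),
    }


def score_batch(tracks, observed: dict, strategy_of: dict | None = None,
                delta: float = 1.0) -> pd.DataFrame:
    """Score a batch of simulated tracks against their empirical tracks.

    Parameters
    ----------
    tracks
        Iterable of :class:`~magnav.simulate.SimulatedTrack`.
    observed
        Map animal_id -> (n, 2) empirical positions (hourly).
    strategy_of
        Optional map label -> strategy name, added as a column.

    Returns
    -------
    DataFrame with columns animal_id, label, strategy, replicate,
    mean_distance, dtw, di.
    """
    rows = []
    for t in tracks:
        obs = observed[t.animal_id]
        rec = {
            "animal_id": t.animal_id,
            "label": t.label,
            "replicate": t.replicate,
        }
        rec.update(score_pair(t.positions, obs, delta=delta))
        rows.append(rec)
    df = pd.DataFrame(rows)
    if strategy_of is not None:
        df.insert(2, "strategy", df["label"].map(strategy_of))
    return df
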