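"""Empirical movement kernel: joint (step length, turning angle)
distribution plus lag-1 auto-difference distributions.

The kernel is estimated from hourly steps pooled across animals.  The
joint histogram carries the marginal movement structure; the lag-1
difference histograms (L_{t+1} - L_t and wrapped phi_{t+1} - phi_t,
computed within animals only) carry short-range persistence of speed
and turning.  A step's probability is modelled as the product of the
three masses — the simplest composition that preserves both the
marginal structure and lag-1 autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tracks import StepSeries, wrap_angle

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


def _uniform_bin(values, lo: float, width: float, n_bins: int):
    """Index of uniform bin containing each value; -1 outside [lo, lo+n*w].

    Values exactly at the upper edge fall in the last bin (closed top).
    """
    v = np.asarray(values, dtype=float)
    # the 1e-9 nudge reproduces np.histogram's left-closed edges under
    # floating-point round-off (e.g. pi/(2*pi/24) = 11.999...)
    idx = np.floor((v - lo) / width + 1e-9).astype(int)
    hi = lo + width * n_bins
    idx = np.where((v >= hi) & (v <= hi + 1e-9 * width), n_bins - 1, idx)
    idx = np.where((idx < 0) | (idx >= n_bins), -1, idx)
    return idx


@dataclass(frozen=True)
class MovementKernel:
    """Histogram representation of the pooled empirical movement kernel.

    All histograms are probability masses summing to 1.  Bin layout:

    * step lengths: ``n_len_bins`` uniform bins over [0, L_max];
    * turning angles: ``n_ang_bins`` uniform bins over (-pi, pi];
    * length differences: uniform bins over [-L_max, L_max];
    * angle differences: wrapped to (-pi, pi], same angular bin layout.
    """

    joint_hist: np.ndarray          # (n_len_bins, n_ang_bins)
    dL_hist: np.ndarray             # (n_dL_bins,)
    dPhi_hist: np.ndarray           # (n_ang_bins,)
    len_edges: np.ndarray
    ang_edges: np.ndarray
    dL_edges: np.ndarray
    L_max: float
    mean_L: float = field(default=0.0)
    sd_L: float = field(default=0.0)

    def __post_init__(self) -> None:
        for name in ("joint_hist", "dL_hist", "dPhi_hist"):
            h = getattr(self, name)
            if abs(h.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {h.sum():.12f})")
            if np.any(h < 0):
                raise ValueError(f"{name} has negative mass")

    # -- bin helpers --------------------------------------------------------

    @property
    def n_len_bins(self) -> int:
        return len(self.len_edges) - 1

    @property
    def n_ang_bins(self) -> int:
        return len(self.ang_edges) - 1

    @property
    def len_bin_width(self) -> float:
        return float(self.len_edges[1] - self.len_edges[0])

    @property
    def ang_bin_width(self) -> float:
        return float(self.ang_edges[1] - self.ang_edges[0])

    @property
    def dL_bin_width(self) -> float:
        return float(self.dL_edges[1] - self.dL_edges[0])

    def len_bin(self, L):
        return _uniform_bin(L, 0.0, self.len_bin_width, self.n_len_bins)

    def ang_bin(self, phi):
        phi = wrap_angle(phi)
        return _uniform_bin(phi, -np.pi, self.ang_bin_width, self.n_ang_bins)

    def dL_bin(self, dL):
        return _uniform_bin(dL, -self.L_max, self.dL_bin_width,
                            len(self.dL_hist))

    # -- evaluation ---------------------------------------------------------

    def step_density(self, L, phi, prev_L, prev_phi):
        """Unnormalised probability mass of a step (L, phi) given the
        previous step's (prev_L, prev_phi).

        Product of the joint mass at (L, phi), the lag-1 length
        difference mass at L - prev_L and the lag-1 turning difference
        mass at wrap(phi - prev_phi).  Zero outside support.  Vectorised
        over L/phi.
        """
        L = np.asarray(L, dtype=float)
        phi = np.asarray(phi, dtype=float)
        scalar = L.ndim == 0
        L, phi = np.atleast_1d(L), np.atleast_1d(phi)
        li = self.len_bin(L)
        ai = self.ang_bin(phi)
        di = self.dL_bin(L - prev_L)
        pi_ = self.ang_bin(wrap_angle(phi - prev_phi))
        ok = (li >= 0) & (ai >= 0) & (di >= 0) & (pi_ >= 0)
        out = np.zeros(L.shape, dtype=float)
        if np.any(ok):
            out[ok] = (
                self.joint_hist[li[ok], ai[ok]]
                * self.dL_hist[di[ok]]
                * self.dPhi_hist[pi_[ok]]
            )
        return float(out[0]) if scalar else out

    def joint_density(self, L, phi):
        """Joint mass at (L, phi) alone (no lag-1 conditioning)."""
        L = np.atleast_1d(np.asarray(L, dtype=float))
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        li = self.len_bin(L)
        ai = self.ang_bin(phi)
        ok = (li >= 0) & (ai >= 0)
        out = np.zeros(L.shape, dtype=float)
        out[ok] = self.joint_hist[li[ok], ai[ok]]
        return out

    # -- sampling -----------------------------------------------------------

    def _bin_weights(self, prev_L, prev_phi) -> np.ndarray:
        """Per-(L,phi)-bin weights of step_density at bin centres."""
        Lc = 0.5 * (self.len_edges[:-1] + self.len_edges[1:])
        ac = 0.5 * (self.ang_edges[:-1] + self.ang_edges[1:])
        di = self.dL_bin(Lc - prev_L)
        w_dL = np.where(di >= 0, self.dL_hist[np.clip(di, 0, None)], 0.0)
        pi_ = self.ang_bin(wrap_angle(ac - prev_phi))
        w_dPhi = np.where(pi_ >= 0, self.dPhi_hist[np.clip(pi_, 0, None)], 0.0)
        return self.joint_hist * np.outer(w_dL, w_dPhi)

    def sample_step(self, prev_L: float, prev_phi: float,
                    rng: np.random.Generator) -> tuple[float, float]:
        """Draw one (L, phi) proportional to step_density over the bin
        grid, uniformly jittered within the chosen bin.

        If the lag-1 conditioning annihilates all mass (disjoint
        supports), falls back to the joint histogram alone (logged).
        """
        w = self._bin_weights(prev_L, prev_phi)
        total = w.sum()
        if total <= 0.0:
            log.debug("step_density all-zero; falling back to joint histogram")
            w = self.joint_hist
            total = w.sum()
        flat = rng.choice(w.size, p=(w / total).ravel())
        li, ai = divmod(flat, self.n_ang_bins)
        L = self.len_edges[li] + rng.uniform(0.0, self.len_bin_width)
        phi = wrap_angle(self.ang_edges[ai] + rng.uniform(0.0, self.ang_bin_width))
        return float(L), float(phi)


def estimate_kernel(steps: list[StepSeries], n_len_bins: int = 30,
                    n_ang_bins: int = 24) -> MovementKernel:
    """Estimate the movement kernel from per-animal step series.

    (L, phi) pairs are pooled across animals for the joint histogram;
    lag-1 differences are computed within each animal only, so that no
    artificial jump between animals enters the persistence structure.
    """
    if not steps:
        raise ValueError("no step series supplied")
    pairs_L, pairs_phi, dLs, dPhis = [], [], [], []
    for s in steps:
        if s.n_steps < 2:
            continue
        # turning angle t belongs to step t+1 (the step after the turn)
        pairs_L.append(s.step_lengths[1:])
        pairs_phi.append(s.turning_angles)
        dLs.append(np.diff(s.step_lengths))
        if len(s.turning_angles) >= 2:
            dPhis.append(wrap_angle(np.diff(s.turning_angles)))
    if not pairs_L:
        raise ValueError("pooled step sample is empty (tracks too short)")
    L = np.concatenate(pairs_L)
    phi = np.concatenate(pairs_phi)
    dL = np.concatenate(dLs)
    dPhi = np.concatenate(dPhis) if dPhis else np.zeros(1)
    if len(L) < 2:
        raise ValueError("need at least 2 pooled steps")
    all_L = np.concatenate([s.step_lengths for s in steps])
    L_max = float(all_L.max())
    if L_max <= 0:
        raise ValueError("all pooled steps have zero length")
    len_edges = np.linspace(0.0, L_max, n_len_bins + 1)
    ang_edges = np.linspace(-np.pi, np.pi, n_ang_bins + 1)
    dL_edges = np.linspace(-L_max, L_max, 2 * n_len_bins + 1)

    joint, _, _ = np.histogram2d(
        np.clip(L, 0, L_max), phi, bins=[len_edges, ang_edges]
    )
    # closed-top convention: phi == pi lands in the last bin via clip
    joint = joint / joint.sum()
    h_dL, _ = np.histogram(np.clip(dL, -L_max, L_max), bins=dL_edges)
    h_dL = h_dL / h_dL.sum()
    h_dPhi, _ = np.histogram(dPhi, bins=ang_edges)
    h_dPhi = h_dPhi / h_dPhi.sum()

    return MovementKernel(
        joint_hist=joint,
        dL_hist=h_dL,
        dPhi_hist=h_dPhi,
        len_edges=len_edges,
        ang_edges=ang_edges,
        dL_edges=dL_edges,
        L_max=L_max,
        mean_L=float(all_L.mean()),
        sd_L=float(all_L.std(ddof=1)) if len(all_L) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# Serialisation (YAML manifest + CSV mass tables)
# ---------------------------------------------------------------------------

def save_kernel(kernel: MovementKernel, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(kernel.joint_hist).to_csv(directory / "joint_hist.csv",
                                           index=False)
    pd.DataFrame({"dL": kernel.dL_hist}).to_csv(directory / "dL_hist.csv",
                                                index=False)
    pd.DataFrame({"dPhi": kernel.dPhi_hist}).to_csv(directory / "dPhi_hist.csv",
                                                    index=False)
    manifest = {
        "L_max": kernel.L_max,
        "mean_L": kernel.mean_L,
        "sd_L": kernel.sd_L,
        "len_edges": [float(v) for v in kernel.len_edges],
        "ang_edges": [float(v) for v in kernel.ang_edges],
        "dL_edges": [float(v) for v in kernel.dL_edges],
    }
    with open(directory / "kernel.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return directory


def load_kernel(directory) -> MovementKernel:
    directory = Path(directory)
    with open(directory / "kernel.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return MovementKernel(
        joint_hist=pd.read_csv(directory / "joint_hist.csv").to_numpy(float),
        dL_hist=pd.read_csv(directory / "dL_hist.csv")["dL"].to_numpy(float),
        dPhi_hist=pd.read_csv(directory / "dPhi_hist.csv")["dPhi"].to_numpy(float),
        len_edges=np.asarray(manifest["len_edges"], dtype=float),
        ang_edges=np.asarray(manifest["ang_edges"], dtype=float),
        dL_edges=np.asarray(manifest["dL_edges"], dtype=float),
        L_max=float(manifest["L_max"]),
        mean_L=float(manifest["mean_L"]),
        sd_L=float(manifest["sd_L"]),
    )
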