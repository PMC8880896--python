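"""Trajectory statistics: unwrapping, speed, MSD, diffusivity, adhesion
cluster sizes, front-rear adhesion distribution and K-S comparison.

The observables follow standard cell-track practice: centroid positions
are recorded every few MCS on the periodic lattice and unwrapped with the
minimal-image rule; instantaneous speed is a windowed displacement rate;
the ensemble MSD averages squared displacements from a single post-burn-in
origin over independent replicates (no time averaging, which would bias
non-stationary regimes); the diffusion coefficient is the late-lag MSD
slope divided by 4 (2D Einstein convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats

from .engine import SimulationResult

TRACK_COLUMNS = ["mcs", "x", "y", "speed", "adh_fraction", "replicate", "seed"]

DEFAULT_SPEED_WINDOW = 25  # MCS; matches the +/-25 MCS front-rear axis window
DEFAULT_SAMPLING = 5  # MCS between recorded centroid samples


@dataclass
class Trajectory:
    """Unwrapped centroid track of one replicate."""

    mcs: np.ndarray
    position: np.ndarray  # (n, 2) unwrapped, lattice units
    adhesion_fraction: np.ndarray
    replicate_id: int = 0
    seed: int = 0
    speed: np.ndarray | None = None  # aligned with mcs; NaN where undefined

    def __post_init__(self):
        self.mcs = np.asarray(self.mcs)
        self.position = np.asarray(self.position, dtype=float)
        self.adhesion_fraction = np.asarray(self.adhesion_fraction, dtype=float)
        if np.any(np.diff(self.mcs) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.adhesion_fraction.size and (
            np.nanmin(self.adhesion_fraction) < 0 or np.nanmax(self.adhesion_fraction) > 1
        ):
            raise ValueError("adhesion_fraction must lie in [0, 1]")

    @property
    def sampling_interval(self) -> int:
        return int(self.mcs[1] - self.mcs[0])


@dataclass
class MSDCurve:
    lag: np.ndarray  # MCS
    msd: np.ndarray  # squared lattice units
    n_replicates: int = 1

    def __post_init__(self):
        self.lag = np.asarray(self.lag)
        self.msd = np.asarray(self.msd, dtype=float)


@dataclass
class ClusterSizeDistribution:
    sizes: np.ndarray  # connected-component sizes, sites

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=int)

    @property
    def total(self) -> int:
        return int(self.sizes.sum())

    @property
    def max(self) -> int:
        return int(self.sizes.max()) if self.sizes.size else 0


@dataclass
class AxisProjection:
    """Adhesion positions projected on the front-rear axis (positive = front)."""

    projections: np.ndarray
    n_snapshots: int = 0
    n_skipped: int = 0  # snapshots with no net displacement over the axis window

    def __post_init__(self):
        self.projections = np.asarray(self.projections, dtype=float)


# -- geometry ---------------------------------------------------------------


def unwrap_centroid(raw: np.ndarray, lattice_dims) -> np.ndarray:
    """Remove periodic wrap jumps from a raw centroid series.

    Each successive displacement is mapped to its minimal image, which is
    only unambiguous while true per-sample displacements stay below half
    the lattice in each axis.
    """
    raw = np.asarray(raw, dtype=float)
    dims = np.asarray(lattice_dims, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != dims.size:
        raise ValueError("raw centroid series must be (n, ndim)")
    steps = np.diff(raw, axis=0)
    steps = (steps + dims / 2.0) % dims - dims / 2.0
    if np.any(np.abs(steps) >= dims / 2.0):
        raise ValueError("per-sample displacement of half the lattice is ambiguous")
    out = np.empty_like(raw)
    out[0] = raw[0]
    out[1:] = raw[0] + np.cumsum(steps, axis=0)
    return out


def instantaneous_speed(trajectory: Trajectory, window: int = DEFAULT_SPEED_WINDOW) -> np.ndarray:
    """|r(t + window) - r(t)| / window, assigned to the window midpoint.

    Returns a series aligned with ``trajectory.mcs`` (NaN where the window
    does not fit).  ``window`` must be a multiple of the sampling interval.
    """
    dt = trajectory.sampling_interval
    if window < dt or window % dt != 0:
        raise ValueError(f"window must be a positive multiple of the sampling interval {dt}")
    k = window // dt
    pos = trajectory.position
    n = len(pos)
    speed = np.full(n, np.nan)
    if n > k:
        disp = np.linalg.norm(pos[k:] - pos[:-k], axis=1) / window
        # value for [t, t+window] sits at t + window/2; with even k this is
        # half a sample off-grid, so assign to the nearest sample index
        mid = k // 2
        speed[mid : mid + disp.size] = disp
    return speed


def ensemble_msd(trajectories: list[Trajectory], burn_in: int = 1000) -> MSDCurve:
    """Ensemble MSD over replicates from the single origin at ``burn_in``."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    sq = []
    lag = None
    for tr in trajectories:
        i0 = int(np.searchsorted(tr.mcs, burn_in))
        if i0 >= len(tr.mcs) or tr.mcs[i0] != burn_in:
            raise ValueError(f"trajectory has no sample at burn_in={burn_in}")
        rel = tr.position[i0:] - tr.position[i0]
        d2 = (rel**2).sum(axis=1)
        this_lag = tr.mcs[i0:] - burn_in
        if lag is None:
            lag = this_lag
        else:
            m = min(len(lag), len(this_lag))
            if not np.array_equal(lag[:m], this_lag[:m]):
                raise ValueError("trajectories have incompatible sampling")
            lag = lag[:m]
        sq.append(d2)
    m = len(lag)
    msd = np.mean([d2[:m] for d2 in sq], axis=0)
    return MSDCurve(lag=lag, msd=msd, n_replicates=len(trajectories))


def diffusion_coefficient(curve: MSDCurve, window=(11500, 24000)) -> float:
    """Late-lag MSD slope / 4 (2D convention) over the given lag window."""
    lo, hi = window
    mask = (curve.lag >= lo) & (curve.lag <= hi)
    if mask.sum() < 2:
        raise ValueError(f"MSD curve does not span the window {window}")
    res = scipy.stats.linregress(curve.lag[mask], curve.msd[mask])
    return float(res.slope) / 4.0


# -- adhesion layer ---------------------------------------------------------


def adhesion_clusters(adh: np.ndarray, periodic: bool = True) -> ClusterSizeDistribution:
    """Sizes of Moore-connected components of the adhesion layer.

    Labels with scipy.ndimage, then merges components that touch across
    the periodic boundary via union-find.
    """
    adh = np.asarray(adh).astype(bool)
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndi.label(adh, structure=structure)
    if n == 0:
        return ClusterSizeDistribution(sizes=np.empty(0, dtype=int))
    sizes = np.bincount(labels.ravel())[1:].astype(np.int64)
    if not periodic:
        return ClusterSizeDistribution(sizes=sizes)
    parent = np.arange(n + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    h, w = adh.shape
    # stitch wrap-adjacent label pairs (rows, columns, and both diagonals)
    edges = []
    last_row, first_row = labels[-1, :], labels[0, :]
    for shift in (-1, 0, 1):
        edges.append((last_row, np.roll(first_row, -shift)))
    last_col, first_col = labels[:, -1], labels[:, 0]
    for shift in (-1, 0, 1):
        edges.append((last_col, np.roll(first_col, -shift)))
    for a, b in edges:
        both = (a > 0) & (b > 0)
        for i, j in zip(a[both], b[both]):
            union(i, j)
    roots = np.array([find(i) for i in range(n + 1)])
    merged = np.zeros(n + 1, dtype=np.int64)
    np.add.at(merged, roots[1:], sizes)
    merged = merged[merged > 0]
    return ClusterSizeDistribution(sizes=merged)


def front_rear_projection(
    snapshots: list[tuple[int, np.ndarray]],
    trajectory: Trajectory,
    lattice_dims,
    axis_half_window: int = 25,
) -> AxisProjection:
    """Project adhesion sites on the instantaneous front-rear axis.

    For a snapshot at time t the axis is the unit vector from the cell's
    position at t - axis_half_window to its position at t + axis_half_window;
    every adhesion site's minimal-image displacement from the centroid at t
    is projected onto it (positive = towards the front).  Snapshots with no
    net displacement over the axis window are skipped and counted.

    ``snapshots`` holds (mcs, flat adhesion-site indices) pairs; flat index
    = y * width + x.
    """
    w, h = int(lattice_dims[0]), int(lattice_dims[1])
    dims = np.array([w, h], dtype=float)
    mcs = trajectory.mcs
    pos = trajectory.position
    projections = []
    n_used = 0
    n_skipped = 0
    for t, sites in snapshots:
        ia = np.searchsorted(mcs, t - axis_half_window)
        ib = np.searchsorted(mcs, t + axis_half_window)
        ic = np.searchsorted(mcs, t)
        if (
            ib >= len(mcs)
            or mcs[ia] != t - axis_half_window
            or mcs[ib] != t + axis_half_window
            or mcs[ic] != t
        ):
            raise ValueError(f"trajectory does not cover +/-{axis_half_window} MCS around {t}")
        axis = pos[ib] - pos[ia]
        norm = np.linalg.norm(axis)
        if norm == 0.0:
            n_skipped += 1
            continue
        axis = axis / norm
        centroid = pos[ic] % dims
        sites = np.asarray(sites)
        if sites.size == 0:
            n_used += 1
            continue
        xy = np.stack([sites % w, sites // w], axis=1).astype(float)
        rel = (xy - centroid + dims / 2.0) % dims - dims / 2.0
        projections.append(rel @ axis)
        n_used += 1
    proj = np.concatenate(projections) if projections else np.empty(0)
    return AxisProjection(projections=proj, n_snapshots=n_used, n_skipped=n_skipped)


# -- scalar statistics ------------------------------------------------------


def ks_statistic(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(sample_a)
    b = np.asarray(sample_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def msld(speed_series, epsilon: float = 1e-6) -> float:
    """Mean squared logarithmic difference of successive speeds.

    Zero speeds are floored at ``epsilon`` before taking logs; the value is
    invariant under a global rescaling of the speeds.
    """
    v = np.asarray(speed_series, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2 or np.all(v == 0):
        raise ValueError("need at least two (not all zero) speed samples")
    v = np.maximum(v, epsilon)
    d = np.diff(np.log(v))
    return float(np.mean(d**2))


# -- track I/O --------------------------------------------------------------


def trajectory_from_result(res: SimulationResult, speed_window: int = DEFAULT_SPEED_WINDOW,
                           replicate_id: int = 0) -> Trajectory:
    tr = Trajectory(
        mcs=res.track["mcs"].to_numpy(),
        position=res.track[["x", "y"]].to_numpy(),
        adhesion_fraction=res.track["adh_fraction"].to_numpy(),
        replicate_id=replicate_id,
        seed=res.seed,
    )
    tr.speed = instantaneous_speed(tr, speed_window)
    return tr


def write_track_csv(path, trajectories: list[Trajectory], lattice_dims) -> None:
    """Write tracks in the interchange CSV format (wrapped coordinates)."""
    dims = np.asarray(lattice_dims, dtype=float)
    frames = []
    for tr in trajectories:
        wrapped = tr.position % dims
        frames.append(
            pd.DataFrame(
                {
                    "mcs": tr.mcs,
                    "x": wrapped[:, 0],
                    "y": wrapped[:, 1],
                    "speed": tr.speed if tr.speed is not None else np.nan,
                    "adh_fraction": tr.adhesion_fraction,
                    "replicate": tr.replicate_id,
                    "seed": tr.seed,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_track_csv(path, lattice_dims, speed_window: int = DEFAULT_SPEED_WINDOW) -> list[Trajectory]:
    """Read the interchange CSV, unwrapping positions per replicate."""
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV is missing columns: {sorted(missing)}")
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("mcs")
        pos = unwrap_centroid(grp[["x", "y"]].to_numpy(), lattice_dims)
        tr = Trajectory(
            mcs=grp["mcs"].to_numpy(),
            position=pos,
            adhesion_fraction=grp["adh_fraction"].to_numpy(),
            replicate_id=int(rep),
            seed=int(grp["seed"].iloc[0]),
        )
        tr.speed = instantaneous_speed(tr, speed_window)
        out.append(tr)
    return out
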