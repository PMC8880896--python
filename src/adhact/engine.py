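"""Monte Carlo engine: single copy attempts, whole MCS, full simulations.

The Cellular Potts dynamics proceed by Metropolis-accepted label-copy
attempts between Moore-adjacent sites with unlike labels.  The total
energy change of an attempt ``source -> target`` is

    dH_total = dH_CPM - dH_Act + dH_Adh

with the CPM part (contact + area + perimeter constraints), the Act
protrusion bias (subtracted; scaled by the adhesion feedback prefactor
``f``), and the adhesion rupture cost paid on retraction from an adhered
site.  One MCS consists of (1) the sigma-sweep, calibrated so each lattice
site receives one attempt on average, (2) the asynchronous adhesion sweep,
(3) the Act decay (every positive value drops by 1).

All stochastic decisions of the kernel draw from one numba RNG stream per
process; seed it with :func:`seed_rng` (done automatically per replicate
by :func:`run_simulation`), so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel as K
from .lattice import LatticeState, params_vector
from .params import ModelParams

__all__ = [
    "CellVanishedError",
    "seed_rng",
    "delta_hamiltonian",
    "geometric_mean_act",
    "delta_act",
    "delta_adhesion",
    "metropolis_accept",
    "attempt_copy",
    "run_mcs",
    "run_simulation",
    "SimulationResult",
]


class CellVanishedError(RuntimeError):
    """The cell lost all its sites; the simulation cannot continue."""


def seed_rng(seed: int) -> None:
    """Seed the kernel RNG stream (one stream per process)."""
    K.seed_rng(int(seed))


def _site_index(state: LatticeState, site) -> int:
    if np.isscalar(site):
        idx = int(site)
    else:
        x, y = site
        idx = int(y) * state.width + int(x)
    if not 0 <= idx < state.width * state.height:
        raise IndexError(f"site {site} outside the lattice")
    return idx


def _check_pair(state: LatticeState, source, target) -> tuple[int, int]:
    s = _site_index(state, source)
    t = _site_index(state, target)
    if t not in state.nbr[s]:
        raise ValueError("source and target must be Moore-adjacent")
    if state.sigma_flat[s] == state.sigma_flat[t]:
        raise ValueError("copy attempt requires unlike labels")
    return s, t


def delta_hamiltonian(state: LatticeState, params: ModelParams, source, target) -> float:
    """Energy change of copying sigma(source) into target: contact + area
    + perimeter constraint terms, computed incrementally."""
    s, t = _check_pair(state, source, target)
    pv = params_vector(params)
    dh, _ = K.delta_cpm(
        state.sigma_flat, state.nbr, s, t,
        state.ibook[K.IB_AREA], state.ibook[K.IB_PERIM], pv,
    )
    return float(dh)


def geometric_mean_act(state: LatticeState, site) -> float:
    """Geometric mean of Act over the same-label Moore neighbourhood
    (including the site itself); 0 for medium sites."""
    x = _site_index(state, site)
    return float(K.gm_act(state.sigma_flat, state.act_flat, state.nbr, x))


def delta_act(state: LatticeState, params: ModelParams, source, target, f: float = 1.0) -> float:
    """Act protrusion bias f * (lambda_Act/Max_Act) * (GM(source) - GM(target)).

    The caller subtracts this value from the total energy change."""
    s = _site_index(state, source)
    t = _site_index(state, target)
    pv = params_vector(params)
    return float(K.delta_act(state.sigma_flat, state.act_flat, state.nbr, s, t, f, pv))


def delta_adhesion(state: LatticeState, params: ModelParams, source, target) -> float:
    """Rupture cost lambda_adh * Adh(target) when the copy retracts the cell."""
    s = _site_index(state, source)
    t = _site_index(state, target)
    pv = params_vector(params)
    return float(K.delta_adhesion(state.sigma_flat, state.adh_flat, s, t, pv))


def metropolis_accept(delta_h_total: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability 1 for negative energies, exp(-dH/T) otherwise."""
    if T <= 0:
        raise ValueError("T must be positive")
    if delta_h_total < 0:
        return True
    return rng.random() < np.exp(-delta_h_total / T)


def attempt_copy(
    state: LatticeState,
    params: ModelParams,
    source,
    target,
    rng: np.random.Generator,
    f: float = 1.0,
) -> bool:
    """One Metropolis copy attempt with full incremental bookkeeping.

    On an accepted extension the new site gets Act = Max_Act and no
    adhesion; on an accepted retraction the lost site's Act is zeroed and
    its adhesion bond (if any) is ruptured."""
    s, t = _check_pair(state, source, target)
    dh = delta_hamiltonian(state, params, source, target)
    dh -= delta_act(state, params, source, target, f)
    dh += delta_adhesion(state, params, source, target)
    if not metropolis_accept(dh, params.T, rng):
        return False
    pv = params_vector(params)
    _, dp = K.delta_cpm(
        state.sigma_flat, state.nbr, s, t,
        state.ibook[K.IB_AREA], state.ibook[K.IB_PERIM], pv,
    )
    K.apply_flip(
        state.sigma_flat, state.act_flat, state.adh_flat, state.nbr,
        state.ibook, state.fbook, state.cell_list, state.cell_pos,
        state.ux, state.uy, state.edge_list, state.edge_pos,
        t, state.sigma_flat[s], dp, params.max_act, state.width,
    )
    return True


def run_mcs(state: LatticeState, params: ModelParams, naive: bool = False) -> LatticeState:
    """Advance the state by one MCS in place (kernel RNG; see seed_rng)."""
    pv = params_vector(params)
    K.run_mcs_kernel(
        state.sigma_flat, state.act_flat, state.adh_flat, state.nbr,
        state.ibook, state.fbook, state.cell_list, state.cell_pos,
        state.ux, state.uy, state.edge_list, state.edge_pos, state.order,
        pv, state.width, naive,
    )
    state.mcs += 1
    if state.aborted:
        raise CellVanishedError(f"cell vanished at MCS {state.mcs}")
    return state


@dataclass
class SimulationResult:
    """Output of one replicate: sampled track plus adhesion snapshots."""

    params: ModelParams
    seed: int
    track: pd.DataFrame  # columns: mcs, x, y (unwrapped), area, adh_area, adh_fraction
    snapshots: list = field(default_factory=list)  # (mcs, flat adhesion-site indices)
    final_state: LatticeState | None = None

    @property
    def width(self) -> int:
        return self.params.width

    @property
    def height(self) -> int:
        return self.params.height

    def snapshot_layers(self) -> list[tuple[int, np.ndarray]]:
        """Densify snapshots into (mcs, 2D boolean adhesion layer) pairs."""
        out = []
        for mcs, sites in self.snapshots:
            layer = np.zeros(self.height * self.width, dtype=bool)
            layer[sites] = True
            out.append((mcs, layer.reshape(self.height, self.width)))
        return out


def run_simulation(
    params: ModelParams,
    seed: int | None = None,
    record_interval: int = 5,
    snapshot_interval: int = 0,
    snapshot_start: int | None = None,
    naive: bool = False,
    keep_state: bool = False,
) -> SimulationResult:
    """Run one replicate of ``params.duration_mcs`` steps.

    Parameters
    ----------
    seed : RNG seed for this replicate (defaults to ``params.seed``).
    record_interval : centroid/area sampling interval in MCS (0 = off).
    snapshot_interval : adhesion-layer snapshot interval in MCS (0 = off);
        snapshots start after ``snapshot_start`` (defaults to burn-in).
    naive : use the classic |lattice|-attempt sampler instead of the
        rejection-free scheme (for equivalence checks).
    """
    params.validate()
    if seed is None:
        seed = params.seed
    seed_rng(seed)
    state = LatticeState.initialize(params)
    n_mcs = params.duration_mcs
    if snapshot_start is None:
        snapshot_start = params.burn_in_mcs
    n_rec = (n_mcs // record_interval + 1) if record_interval > 0 else 1
    rec_mcs = np.zeros(n_rec, dtype=np.int64)
    rec_x = np.zeros(n_rec, dtype=np.float64)
    rec_y = np.zeros(n_rec, dtype=np.float64)
    rec_area = np.zeros(n_rec, dtype=np.int64)
    rec_adh = np.zeros(n_rec, dtype=np.int64)
    n_snap = (n_mcs // snapshot_interval + 1) if snapshot_interval > 0 else 0
    cap = int(4 * params.A_target) if n_snap else 0
    snap_mcs = np.zeros(n_snap, dtype=np.int64)
    snap_count = np.zeros(n_snap, dtype=np.int32)
    snap_sites = np.zeros((n_snap, cap), dtype=np.int32)
    counters = np.zeros(2, dtype=np.int64)
    # initial sample at MCS 0
    if record_interval > 0:
        c = state.centroid
        rec_x[0], rec_y[0] = c
        rec_area[0] = state.area
        rec_adh[0] = state.adh_area
        counters[0] = 1
    K.run_kernel(
        state.sigma_flat, state.act_flat, state.adh_flat, state.nbr,
        state.ibook, state.fbook, state.cell_list, state.cell_pos,
        state.ux, state.uy, state.edge_list, state.edge_pos, state.order,
        params_vector(params), state.width, naive, n_mcs, 0,
        record_interval, rec_mcs, rec_x, rec_y, rec_area, rec_adh,
        snapshot_interval, snapshot_start, snap_mcs, snap_count, snap_sites,
        counters,
    )
    state.mcs = n_mcs
    if state.aborted:
        raise CellVanishedError("cell vanished during the simulation")
    m = int(counters[0])
    track = pd.DataFrame(
        {
            "mcs": rec_mcs[:m],
            "x": rec_x[:m],
            "y": rec_y[:m],
            "area": rec_area[:m],
            "adh_area": rec_adh[:m],
        }
    )
    track["adh_fraction"] = track["adh_area"] / track["area"]
    snapshots = [
        (int(snap_mcs[j]), snap_sites[j, : snap_count[j]].copy())
        for j in range(int(counters[1]))
    ]
    return SimulationResult(
        params=params,
        seed=seed,
        track=track,
        snapshots=snapshots,
        final_state=state if keep_state else None,
    )
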