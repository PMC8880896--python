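"""Lattice state for a single cell on a periodic torus.

Three layers are carried per site: the cell label ``sigma`` (0 = medium,
1 = cell), the integer Act value in [0, Max_Act] (recent protrusive
activity), and the adhesion bit (bound to the substrate or not).  The
class also owns all incremental bookkeeping used by the Monte Carlo
kernel; :meth:`rebuild_bookkeeping` recomputes it from scratch and the
``compute_*`` module functions are independent (vectorised numpy)
recomputations used to validate the incremental path.
"""

from __future__ import annotations

import numpy as np

from . import _kernel as K
from .params import ModelParams


def params_vector(params: ModelParams) -> np.ndarray:
    """Pack ModelParams into the kernel's float64 parameter vector."""
    pv = np.zeros(K.PV_LEN, dtype=np.float64)
    pv[K.PV_T] = params.T
    pv[K.PV_AT] = params.A_target
    pv[K.PV_LA] = params.lambda_A
    pv[K.PV_PT] = params.P_target
    pv[K.PV_LP] = params.lambda_P
    pv[K.PV_JCM] = params.J_cell_medium
    pv[K.PV_LACT] = params.lambda_act
    pv[K.PV_MAXACT] = params.max_act
    pv[K.PV_THRESH] = params.act_threshold_fraction * params.max_act
    pv[K.PV_LADH] = params.lambda_adh
    pv[K.PV_PS] = params.p_s
    pv[K.PV_PE] = params.p_e
    pv[K.PV_PD] = params.p_d
    pv[K.PV_FBE] = 1.0 if params.feedback.enabled else 0.0
    pv[K.PV_FBB] = params.feedback.b
    pv[K.PV_FBS] = params.feedback.s
    return pv


class LatticeState:
    """State of the periodic lattice plus exact incremental bookkeeping."""

    def __init__(self, width: int, height: int):
        if width < 3 or height < 3:
            raise ValueError("lattice must be at least 3x3")
        self.width = width
        self.height = height
        n = width * height
        self.sigma_flat = np.zeros(n, dtype=np.int8)
        self.act_flat = np.zeros(n, dtype=np.int32)
        self.adh_flat = np.zeros(n, dtype=np.uint8)
        self.nbr = K.build_neighbor_table(width, height)
        self.ibook = np.zeros(6, dtype=np.int64)
        self.fbook = np.zeros(2, dtype=np.float64)
        self.cell_list = np.zeros(n, dtype=np.int32)
        self.cell_pos = np.full(n, -1, dtype=np.int32)
        self.ux = np.zeros(n, dtype=np.float64)
        self.uy = np.zeros(n, dtype=np.float64)
        self.edge_list = np.zeros(8 * n, dtype=np.int64)
        self.edge_pos = np.full(8 * n, -1, dtype=np.int32)
        self.order = np.zeros(n, dtype=np.int32)
        self.mcs = 0

    # -- 2D views ---------------------------------------------------------

    @property
    def sigma(self) -> np.ndarray:
        return self.sigma_flat.reshape(self.height, self.width)

    @property
    def act(self) -> np.ndarray:
        return self.act_flat.reshape(self.height, self.width)

    @property
    def adh(self) -> np.ndarray:
        return self.adh_flat.reshape(self.height, self.width)

    # -- bookkept observables ----------------------------------------------

    @property
    def area(self) -> int:
        return int(self.ibook[K.IB_AREA])

    @property
    def perimeter(self) -> int:
        return int(self.ibook[K.IB_PERIM])

    @property
    def adh_area(self) -> int:
        return int(self.ibook[K.IB_ADH])

    @property
    def centroid(self) -> np.ndarray:
        """Unwrapped (x, y) centroid; continuous across the torus seam."""
        a = self.ibook[K.IB_AREA]
        if a == 0:
            raise ValueError("cell has no sites")
        return np.array([self.fbook[K.FB_SX] / a, self.fbook[K.FB_SY] / a])

    @property
    def aborted(self) -> bool:
        return bool(self.ibook[K.IB_ABORT])

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(cls, params: ModelParams) -> "LatticeState":
        """Seed the cell as a filled disc of roughly the target area,
        centred on the lattice, with Act and adhesion layers all zero."""
        params.validate()
        state = cls(params.width, params.height)
        r = np.sqrt(params.A_target / np.pi)
        cy, cx = params.height / 2.0, params.width / 2.0
        yy, xx = np.mgrid[0 : params.height, 0 : params.width]
        disc = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r * r
        if not disc.any():
            raise ValueError("target area too small to seed a cell")
        state.sigma[...] = disc.astype(np.int8)
        state.rebuild_bookkeeping()
        return state

    def rebuild_bookkeeping(self) -> None:
        """Recompute all incremental bookkeeping from the layers."""
        sig = self.sigma
        n = self.width * self.height
        cells = np.flatnonzero(self.sigma_flat == 1).astype(np.int32)
        self.ibook[K.IB_AREA] = cells.size
        self.ibook[K.IB_PERIM] = compute_perimeter(sig)
        self.ibook[K.IB_ADH] = int(self.adh_flat.sum())
        self.ibook[K.IB_ABORT] = 0
        self.cell_pos[:] = -1
        self.cell_list[: cells.size] = cells
        self.cell_pos[cells] = np.arange(cells.size, dtype=np.int32)
        self.ibook[K.IB_NCELL] = cells.size
        xs = (cells % self.width).astype(np.float64)
        ys = (cells // self.width).astype(np.float64)
        self.ux[cells] = xs
        self.uy[cells] = ys
        self.fbook[K.FB_SX] = xs.sum()
        self.fbook[K.FB_SY] = ys.sum()
        # directed unlike Moore pairs
        self.edge_pos[:] = -1
        unlike = self.sigma_flat[:, None] != self.sigma_flat[self.nbr]
        eids = np.flatnonzero(unlike.reshape(-1)).astype(np.int64)
        self.edge_list[: eids.size] = eids
        self.edge_pos[eids] = np.arange(eids.size, dtype=np.int32)
        self.ibook[K.IB_NEDGE] = eids.size

    def copy(self) -> "LatticeState":
        new = LatticeState(self.width, self.height)
        for name in (
            "sigma_flat", "act_flat", "adh_flat", "ibook", "fbook",
            "cell_list", "cell_pos", "ux", "uy", "edge_list", "edge_pos",
        ):
            getattr(new, name)[...] = getattr(self, name)
        new.mcs = self.mcs
        return new

    # -- invariants ---------------------------------------------------------

    def check_invariants(self) -> None:
        """Raise AssertionError if a layer invariant is violated."""
        sig = self.sigma_flat
        if np.any((self.adh_flat == 1) & (sig == 0)):
            raise AssertionError("adhesion outside the cell")
        if np.any((self.act_flat != 0) & (sig == 0)):
            raise AssertionError("Act value on a medium site")
        if self.act_flat.min() < 0:
            raise AssertionError("negative Act value")

    # -- snapshot I/O --------------------------------------------------------

    def save_snapshot(self, path) -> None:
        np.savez_compressed(
            path, sigma=self.sigma, act=self.act, adh=self.adh, mcs=self.mcs
        )

    @classmethod
    def load_snapshot(cls, path) -> "LatticeState":
        with np.load(path) as data:
            sigma = data["sigma"]
            state = cls(sigma.shape[1], sigma.shape[0])
            state.sigma[...] = sigma
            state.act[...] = data["act"]
            state.adh[...] = data["adh"]
            state.mcs = int(data["mcs"])
        state.rebuild_bookkeeping()
        state.check_invariants()
        return state


def render_snapshot(state: LatticeState, path, dpi: int = 120) -> None:
    """Render the lattice to PNG: medium white, cell shaded red-to-yellow
    by its Act value, adhered sites darkened."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    act = state.act.astype(float)
    sigma = state.sigma
    adh = state.adh
    img = np.ones(sigma.shape + (3,))
    cmap = LinearSegmentedColormap.from_list("act", ["#8b0000", "#ff4500", "#ffd700"])
    maxact = max(act.max(), 1.0)
    cell = sigma == 1
    img[cell] = cmap(act[cell] / maxact)[:, :3]
    img[(adh == 1)] *= 0.45  # adhesions darker
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img, origin="lower", interpolation="nearest")
    ax.set_title(f"MCS {state.mcs}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


# -- independent, vectorised recomputations (oracles for the bookkeeping) ---


def _moore_shifts():
    return [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


def compute_area(sigma: np.ndarray) -> int:
    return int((sigma == 1).sum())


def compute_perimeter(sigma: np.ndarray) -> int:
    """Directed Moore pairs (cell site, non-cell neighbour), periodic."""
    cell = sigma == 1
    p = 0
    for dy, dx in _moore_shifts():
        p += int((cell & ~np.roll(cell, (dy, dx), axis=(0, 1))).sum())
    return p


def compute_adh_area(adh: np.ndarray) -> int:
    return int((adh == 1).sum())


def compute_centroid(sigma: np.ndarray, reference=None) -> np.ndarray:
    """(x, y) centroid using minimal-image offsets around ``reference``
    (defaults to the first cell site)."""
    ys, xs = np.nonzero(sigma == 1)
    if xs.size == 0:
        raise ValueError("cell has no sites")
    h, w = sigma.shape
    if reference is None:
        reference = (float(xs[0]), float(ys[0]))
    rx, ry = reference
    dx = (xs - rx + w / 2.0) % w - w / 2.0
    dy = (ys - ry + h / 2.0) % h - h / 2.0
    return np.array([rx + dx.mean(), ry + dy.mean()])


def hamiltonian(state: LatticeState, params: ModelParams) -> float:
    """Full-lattice Hamiltonian: contact + area + perimeter constraints.

    The contact sum runs over unordered Moore-adjacent unlike pairs."""
    sig = state.sigma
    unlike = 0
    # half of the 8 shifts covers each unordered pair exactly once
    for dy, dx in [(-1, -1), (-1, 0), (-1, 1), (0, -1)]:
        unlike += int((sig != np.roll(sig, (dy, dx), axis=(0, 1))).sum())
    h = params.J_cell_medium * unlike
    a = compute_area(sig)
    p = compute_perimeter(sig)
    h += params.lambda_A * (a - params.A_target) ** 2
    h += params.lambda_P * (p - params.P_target) ** 2
    return float(h)
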