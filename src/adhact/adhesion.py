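"""Cell-substrate adhesion dynamics.

Four stochastic processes act on the binary adhesion layer once per MCS,
in an asynchronous sweep over the cell sites in fresh random order:

* de novo formation: an empty site whose same-cell geometric mean of Act
  values reaches ``0.75 * Max_Act`` gains an adhesion with probability
  ``p_s`` (adhesions nucleate where the actin front is established);
* Eden patch expansion: an adhered site picks one random Moore neighbour;
  if that neighbour is inside the cell and empty it becomes adhered with
  probability ``p_e`` (radial colony-like patch growth);
* spontaneous unbinding: an adhered site detaches with probability
  ``p_d * (k/8)^2`` where k counts its non-adherent Moore neighbours, so
  patches shrink from their edges;
* rupture by retraction: handled in the Monte Carlo energy (cost
  ``lambda_adh`` per adhesion lost when the cell retracts).

The adhesion area feeds back on protrusion through the prefactor ``f``
(:func:`feedback_factor`) multiplying the Act weight.
"""

from __future__ import annotations

import numpy as np

from . import _kernel as K
from .lattice import LatticeState, params_vector
from .params import FeedbackParams, ModelParams

__all__ = [
    "formation_probability",
    "eden_expansion",
    "unbinding_probability",
    "adhesion_sweep",
    "feedback_factor",
]


def formation_probability(state: LatticeState, params: ModelParams, site) -> float:
    """Probability that ``site`` gains a de novo adhesion this sweep.

    ``p_s`` if the site is empty and the same-cell geometric mean of Act
    values (including the site) reaches 0.75 Max_Act, else 0.
    """
    from .engine import _site_index

    x = _site_index(state, site)
    if state.sigma_flat[x] != 1:
        raise ValueError("formation is defined only for cell sites")
    if state.adh_flat[x] == 1:
        return 0.0
    threshold = params.act_threshold_fraction * params.max_act
    if K.formation_eligible(state.sigma_flat, state.act_flat, state.nbr, x, threshold):
        return params.p_s
    return 0.0


def eden_expansion(state: LatticeState, params: ModelParams, site,
                   rng: np.random.Generator) -> bool:
    """One Eden growth trial from an adhered site.

    Picks one uniformly random Moore neighbour; if it lies inside the cell
    and carries no adhesion, it becomes adhered with probability ``p_e``.
    Returns whether the layer changed.
    """
    from .engine import _site_index

    x = _site_index(state, site)
    if state.adh_flat[x] != 1:
        raise ValueError("Eden expansion starts from an adhered site")
    u = state.nbr[x, rng.integers(8)]
    if state.sigma_flat[u] == 1 and state.adh_flat[u] == 0:
        if rng.random() < params.p_e:
            state.adh_flat[u] = 1
            state.ibook[K.IB_ADH] += 1
            return True
    return False


def unbinding_probability(state: LatticeState, params: ModelParams, site) -> float:
    """Spontaneous unbinding probability ``p_d * (k/8)^2`` with k the number
    of Moore neighbours (excluding the site) without an adhesion."""
    from .engine import _site_index

    x = _site_index(state, site)
    if state.adh_flat[x] != 1:
        raise ValueError("unbinding is defined only for adhered sites")
    k = int((state.adh_flat[state.nbr[x]] == 0).sum())
    return params.p_d * (k / 8.0) ** 2


def adhesion_sweep(state: LatticeState, params: ModelParams) -> LatticeState:
    """Run one asynchronous adhesion sweep in place (kernel RNG).

    Visits all current cell sites in a fresh random order; empty sites may
    form, adhered sites first try Eden expansion then unbinding, always
    reading the live (already modified) layer.
    """
    pv = params_vector(params)
    K.adhesion_sweep(
        state.sigma_flat, state.act_flat, state.adh_flat, state.nbr,
        state.ibook, state.cell_list, state.order, pv,
    )
    return state


def feedback_factor(adh_area: float, area: float, feedback: FeedbackParams) -> float:
    """Protrusion prefactor f: b at zero adhesion, rising linearly to 1 at
    the saturation adhesion-area fraction s, and 1 above it."""
    if area <= 0:
        raise ValueError("cell area must be positive")
    if not (0 <= adh_area <= area):
        raise ValueError("adhesion area must lie in [0, area]")
    if not feedback.enabled:
        return 1.0
    ratio = adh_area / area
    if ratio > feedback.s:
        return 1.0
    return feedback.b + (1.0 - feedback.b) / feedback.s * ratio
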