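"""Model parameters for the adhesion-extended Act Cellular Potts model.

All energies are in units of the fluctuation amplitude scale (arbitrary
units), lengths in lattice sites and times in Monte Carlo steps (MCS).
Defaults are the constants used throughout the study conditions: a single
cell of target area 1000 sites on a 300x300 periodic lattice, simulated
for 25000 MCS.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping


@dataclass
class FeedbackParams:
    """Adhesion -> protrusion feedback (prefactor ``f`` on the Act weight).

    ``f`` rises linearly from the baseline ``b`` (no adhesions) to 1 at the
    saturation adhesion-area fraction ``s`` and stays 1 above it.
    """

    enabled: bool = False
    b: float = 0.5
    s: float = 0.12

    def validate(self) -> None:
        if not (0.0 < self.b <= 1.0):
            raise ValueError(f"feedback baseline b must be in (0, 1], got {self.b}")
        if not (0.0 < self.s <= 1.0):
            raise ValueError(f"feedback saturation s must be in (0, 1], got {self.s}")


@dataclass
class ModelParams:
    """Full parameter set: CPM Hamiltonian, Act extension, adhesion dynamics.

    Attributes
    ----------
    T : float
        Fluctuation amplitude (Metropolis temperature).
    A_target, lambda_A : float
        Target cell area (sites) and area-constraint weight.
    P_target, lambda_P : float
        Target perimeter (directed unlike Moore-pair count) and weight.
    J_cell_medium, J_medium_medium : float
        Contact energies per unlike Moore pair.
    lambda_act, max_act : float / int
        Weight of the protrusive Act term (maximum protrusive force) and the
        maximum Act value (actin lifetime in MCS).
    act_threshold_fraction : float
        Fraction of ``max_act`` the local geometric mean of Act values must
        reach before a de novo adhesion may form.
    lambda_adh : float
        Energy paid to rupture one adhesion site on retraction.
    p_s, p_e, p_d : float
        Per-site per-MCS probabilities of de novo adhesion formation, Eden
        patch expansion, and (base rate of) spontaneous unbinding.
    feedback : FeedbackParams
        Adhesion->protrusion feedback settings.
    width, height : int
        Lattice dimensions (periodic torus).
    duration_mcs, burn_in_mcs : int
        Total simulated time and the initial stretch excluded from analysis.
    seed : int
        Base RNG seed; replicate ``i`` uses ``seed + i``.
    """

    # Hamiltonian (kept constant across all study conditions)
    T: float = 30.0
    A_target: float = 1000.0
    lambda_A: float = 50.0
    P_target: float = 350.0
    lambda_P: float = 4.0
    J_cell_medium: float = 35.0
    J_medium_medium: float = 0.0

    # Act extension
    lambda_act: float = 240.0
    max_act: int = 120

    # Adhesion dynamics
    act_threshold_fraction: float = 0.75
    lambda_adh: float = 0.0
    p_s: float = 0.0
    p_e: float = 0.0
    p_d: float = 0.0
    feedback: FeedbackParams = field(default_factory=FeedbackParams)

    # Lattice / schedule
    width: int = 300
    height: int = 300
    duration_mcs: int = 25000
    burn_in_mcs: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_s", "p_e", "p_d"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"rate {name} must be in [0, 1], got {v}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.max_act < 0:
            raise ValueError(f"max_act must be >= 0, got {self.max_act}")
        if not (0.0 <= self.act_threshold_fraction <= 1.0):
            raise ValueError("act_threshold_fraction must be in [0, 1]")
        if self.width < 3 or self.height < 3:
            raise ValueError("lattice must be at least 3x3")
        if self.duration_mcs < 0 or self.burn_in_mcs < 0:
            raise ValueError("durations must be non-negative")
        self.feedback.validate()

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        d = dict(d)
        fb = d.pop("feedback", None)
        params = cls(**d)
        if fb is not None:
            params.feedback = FeedbackParams(**fb) if isinstance(fb, Mapping) else fb
        params.validate()
        return params

    def replace(self, **kwargs: Any) -> "ModelParams":
        fb_kwargs = {k: kwargs.pop(k) for k in ("enabled", "b", "s") if k in kwargs}
        new = dataclasses.replace(self, **kwargs)
        if fb_kwargs:
            new.feedback = dataclasses.replace(self.feedback, **fb_kwargs)
        return new
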