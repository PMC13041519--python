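"""Phase two: place the animal in the trajectory plane and score the strike.

Once phase one has decided that a collision is possible, the model tracks the
animal's lateral position inside the trajectory until the vehicle arrives:

* ``d_initial = d_width - d_min`` -- starting x-position, anchored so that an
  animal just inside the far edge (``d_min = d_width``) starts at 0;
* ``d_collision = d_initial + sin(theta) * sa * t_v`` -- the window midpoint
  when the vehicle reaches the animal's plane, after drifting for the whole
  time-available interval.  The default drift uses the escape speed's
  cross-trajectory component ``sin(theta)`` -- the same component that clears
  the width in phase one, so the animal always drifts toward its exit edge;
  ``lateral_term="cos"`` switches to an along-track variant in which
  toward-angles drift forward and away-angles drift backward;
* the probability of collision is the occupied fraction of the silhouette's
  collision window centered at ``d_collision`` (see
  :func:`avistrike.silhouette.window_probability`).

``d_collision`` may leave ``[0, d_width]``; the window-overlap rule then
credits only the in-bounds part, so the probability tapers to 0 at both
edges.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kinematics import AnimalParams, PhaseOneResult, VehicleParams
from .silhouette import window_probability

__all__ = [
    "PhaseTwoResult",
    "initial_position",
    "position_at_arrival",
    "collision_probability",
]


@dataclasses.dataclass(frozen=True)
class PhaseTwoResult:
    d_initial: float
    d_collision: float
    p_collision: float


def initial_position(a: AnimalParams, v: VehicleParams) -> float:
    """Starting x-position within the trajectory: ``d_width - d_min``."""
    if a.d_min > v.d_width:
        raise ValueError("d_min cannot exceed the trajectory width")
    return v.d_width - a.d_min


def _lateral_component(theta_deg, lateral_term: str):
    if lateral_term == "cos":
        return np.cos(np.radians(theta_deg))
    if lateral_term == "sin":
        return np.sin(np.radians(theta_deg))
    raise ValueError("lateral_term must be 'cos' or 'sin'")


def position_at_arrival(
    a: AnimalParams,
    v: VehicleParams,
    t_v: float,
    lateral_term: str = "sin",
) -> float:
    """Window midpoint at vehicle arrival (meters; may lie outside the grid)."""
    if t_v < 0:
        raise ValueError("t_v must be >= 0")
    drift = float(_lateral_component(a.theta, lateral_term)) * a.sa * t_v
    return initial_position(a, v) + drift


def collision_probability(
    a: AnimalParams,
    v: VehicleParams,
    p1: PhaseOneResult,
    lateral_term: str = "sin",
) -> PhaseTwoResult:
    """Full phase-two evaluation given a phase-one result.

    If phase one reported an escape the probability is exactly 0 (the animal
    is assumed to hold course and speed).  Otherwise the silhouette's
    collision-window occupancy at the arrival position is returned.
    """
    d_init = initial_position(a, v)
    d_coll = position_at_arrival(a, v, p1.t_v, lateral_term=lateral_term)
    if not p1.collision_possible:
        return PhaseTwoResult(d_initial=d_init, d_collision=d_coll, p_collision=0.0)
    if v.silhouette is None:
        raise ValueError("vehicle has no silhouette attached")
    p = window_probability(v.silhouette, d_coll, a.l)
    return PhaseTwoResult(d_initial=d_init, d_collision=d_coll, p_collision=float(p))
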