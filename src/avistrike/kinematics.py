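"""Phase one of the collision model: can the animal clear the trajectory?

An animal standing inside (or at the edge of) an approaching vehicle's swept
trajectory initiates escape when the vehicle is ``d_fid`` meters away.  It
must cross its remaining lateral distance to safety -- the distance to the
trajectory edge plus its own body length -- before the vehicle arrives.  Two
clocks race:

``t_a``
    time the animal needs: ``(d_min + l) / (sin(theta) * s_a) + delta``,
    where ``theta`` is the escape angle (0 deg = straight at the vehicle,
    180 deg = straight away; only the perpendicular component ``sin(theta)``
    contributes to clearing the width) and ``delta`` is the sensory-motor
    delay spent reorienting before effective motion.

``t_v``
    time available: ``d_fid / (s_v + cos(theta) * s_a)`` -- the closing
    speed grows when the animal flees toward the vehicle (``theta`` < 90)
    and shrinks when it flees away.

A collision is *possible* iff ``t_a >= t_v`` (ties included); otherwise the
interaction ends with probability exactly 0 and phase two never runs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Union

import numpy as np

__all__ = [
    "AnimalParams",
    "VehicleParams",
    "PhaseOneResult",
    "distance_to_safety",
    "time_needed",
    "time_available",
    "phase_one",
    "threshold_angle",
]

ArrayLike = Union[float, np.ndarray]


@dataclasses.dataclass(frozen=True)
class AnimalParams:
    """Escape-response parameters of the animal.

    l : body length (m); sa : escape speed (m/s); delta : sensory-motor
    delay (s); d_fid : flight-initiation distance (m); theta : escape angle
    (degrees, exclusive of 0 and 180); d_min : lateral distance to the
    nearest trajectory edge (m).
    """

    l: float
    sa: float
    delta: float
    d_fid: float
    theta: float
    d_min: float

    def __post_init__(self) -> None:
        if not self.l > 0:
            raise ValueError("body length l must be > 0")
        if self.sa < 0:
            raise ValueError("escape speed sa must be >= 0")
        if self.delta < 0:
            raise ValueError("sensory-motor delay must be >= 0")
        if self.d_fid < 0:
            raise ValueError("flight-initiation distance must be >= 0")
        if not 0 < self.theta < 180:
            raise ValueError("escape angle must lie strictly inside (0, 180) degrees")
        if not self.d_min > 0:
            raise ValueError("distance to safety d_min must be > 0")


@dataclasses.dataclass(frozen=True)
class VehicleParams:
    """Approach parameters of the vehicle.

    sv : approach speed (m/s); d_width / d_height : swept-trajectory extent
    (m); silhouette : optional FrontalSilhouette whose physical extents must
    match d_width / d_height.
    """

    sv: float
    d_width: float
    d_height: float
    silhouette: Optional[object] = None

    def __post_init__(self) -> None:
        if not self.sv > 0:
            raise ValueError("approach speed sv must be > 0")
        if not (self.d_width > 0 and self.d_height > 0):
            raise ValueError("trajectory extents must be > 0")
        s = self.silhouette
        if s is not None:
            if not (
                math.isclose(s.width_m, self.d_width, rel_tol=1e-9)
                and math.isclose(s.height_m, self.d_height, rel_tol=1e-3)
            ):
                raise ValueError(
                    "silhouette physical extents do not match d_width/d_height"
                )

    @classmethod
    def from_silhouette(cls, sv: float, silhouette) -> "VehicleParams":
        return cls(
            sv=sv,
            d_width=silhouette.width_m,
            d_height=silhouette.height_m,
            silhouette=silhouette,
        )


@dataclasses.dataclass(frozen=True)
class PhaseOneResult:
    d_safe: float
    t_a: float
    t_v: float
    collision_possible: bool


# -- array-friendly cores (shared with the sweep engine) --------------------

def time_needed_arrays(
    d_min: ArrayLike, l: ArrayLike, sa: ArrayLike, delta: ArrayLike,
    theta_deg: ArrayLike,
) -> ArrayLike:
    """Vectorized ``t_a``; +inf where the lateral speed component vanishes."""
    lateral = np.sin(np.radians(theta_deg)) * sa
    with np.errstate(divide="ignore"):
        return np.where(lateral > 0, (d_min + l) / np.where(lateral > 0, lateral, 1.0), np.inf) + delta


def time_available_arrays(
    d_fid: ArrayLike, sv: ArrayLike, sa: ArrayLike, theta_deg: ArrayLike
) -> ArrayLike:
    """Vectorized ``t_v``; requires a positive closing speed."""
    closing = sv + np.cos(np.radians(theta_deg)) * sa
    if np.any(closing <= 0):
        raise ValueError(
            "non-positive closing speed: vehicle slower than the animal's "
            "along-track retreat (sv + cos(theta) * sa <= 0)"
        )
    return d_fid / closing


# -- scalar API -------------------------------------------------------------

def distance_to_safety(a: AnimalParams) -> float:
    """Total lateral distance to clear: ``d_min + l``."""
    return a.d_min + a.l


def time_needed(a: AnimalParams) -> float:
    """Time the animal needs to clear the trajectory (``t_a``), seconds.

    Returns ``inf`` when the animal has no lateral speed (sa = 0), which by
    construction compares >= any finite time available.
    """
    return float(time_needed_arrays(a.d_min, a.l, a.sa, a.delta, a.theta))


def time_available(a: AnimalParams, v: VehicleParams) -> float:
    """Time until the vehicle reaches the animal's line (``t_v``), seconds."""
    return float(time_available_arrays(a.d_fid, v.sv, a.sa, a.theta))


def phase_one(a: AnimalParams, v: VehicleParams) -> PhaseOneResult:
    """Run the phase-one race; ties (``t_a == t_v``) count as possible."""
    if a.d_min > v.d_width:
        raise ValueError("d_min cannot exceed the trajectory width")
    t_a = time_needed(a)
    t_v = time_available(a, v)
    return PhaseOneResult(
        d_safe=distance_to_safety(a),
        t_a=t_a,
        t_v=t_v,
        collision_possible=bool(t_a >= t_v),
    )


def threshold_angle(d_mid: float, d_half: float, l: float) -> float:
    """Vehicle approach angle (degrees) separating direct from indirect paths.

    ``arcsin((d_half + l) / d_mid)`` where ``d_mid`` is the distance from the
    vehicle's centerline to the animal, ``d_half`` half the vehicle's maximum
    width and ``l`` the animal's body length.  Approach angles at or below
    the threshold intersect the animal's position (a collision is possible if
    no escape is made); larger angles bypass it.
    """
    if not d_mid > 0:
        raise ValueError("d_mid must be > 0")
    if d_half < 0:
        raise ValueError("d_half must be >= 0")
    if not l > 0:
        raise ValueError("body length must be > 0")
    ratio = (d_half + l) / d_mid
    if ratio > 1:
        raise ValueError(
            "(d_half + l) / d_mid > 1: the animal lies inside the swept width "
            "at every approach angle"
        )
    return math.degrees(math.asin(ratio))
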