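"""Stochastic behavioral inputs under no-light / blue-light / red-light scenarios.

Two escape-response variables are drawn per model run:

* escape angle ``theta`` -- a mixture of two uniform distributions,
  "toward" (0.01-89.99 deg) and "away" (90.01-179.99 deg).  The mixing
  weight ``p_away`` is scenario-specific: 0.42 for a dark aircraft (Canada
  goose reactions mined from strike-report remarks), 0.65 under a 483-nm
  blue onboard light (mild avoidance) and 0.11 under a 631-nm red light
  (attraction).

* flight-initiation distance ``d_fid`` -- for a dark aircraft, or for a lit
  aircraft when the draw came from the toward distribution (attraction to
  the light pairs with short FIDs), a normal with mean 56.2 m and SD 16.5 m
  truncated at 0.  For a lit aircraft when the draw came from the away
  distribution, the earlier alert afforded by the light expands the usable
  range: uniform on [0, speed x beta], where ``beta`` (s) is the light's
  temporal benefit and the speed is the vehicle's approach speed by default
  (``alert_speed="animal"`` switches to the animal's escape speed).

All draws go through a caller-supplied :class:`numpy.random.Generator`, so a
fixed seed reproduces the stream bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "LightScenario",
    "BehaviorSample",
    "TOWARD_RANGE",
    "AWAY_RANGE",
    "sample_angle",
    "sample_fid",
    "sample_behavior",
    "max_alert_distance",
]

#: Inclusive bounds of the two uniform escape-angle distributions (degrees).
TOWARD_RANGE = (0.01, 89.99)
AWAY_RANGE = (90.01, 179.99)

#: Baseline flight-initiation-distance distribution (m): goose responses to
#: direct ground-vehicle approaches.
DEFAULT_FID_MEAN = 56.2
DEFAULT_FID_SD = 16.5

_DEFAULT_P_AWAY = {"none": 0.42, "blue": 0.65, "red": 0.11}


@dataclasses.dataclass(frozen=True)
class LightScenario:
    """One onboard-light condition and its behavioral consequences."""

    kind: str  # "none", "blue" or "red"
    p_away: float
    beta: float = 4.1  # temporal benefit of the light (s); unused for "none"
    fid_mean: float = DEFAULT_FID_MEAN
    fid_sd: float = DEFAULT_FID_SD

    def __post_init__(self) -> None:
        if self.kind not in _DEFAULT_P_AWAY:
            raise ValueError("scenario kind must be 'none', 'blue' or 'red'")
        if not 0 <= self.p_away <= 1:
            raise ValueError("p_away must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not self.fid_sd > 0:
            raise ValueError("fid_sd must be > 0")

    @classmethod
    def default(cls, kind: str, **overrides) -> "LightScenario":
        """Scenario with the field defaults for ``kind``."""
        return cls(kind=kind, p_away=_DEFAULT_P_AWAY[kind], **overrides)

    @property
    def lit(self) -> bool:
        return self.kind != "none"


@dataclasses.dataclass(frozen=True)
class BehaviorSample:
    theta: float
    d_fid: float
    away: bool


def max_alert_distance(sv: float, beta: float) -> float:
    """Farthest distance at which the light can trigger escape: ``sv * beta``."""
    if not sv > 0:
        raise ValueError("speed must be > 0")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return sv * beta


def sample_angle(
    sc: LightScenario, rng: np.random.Generator, size: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw escape angles; returns ``(theta_deg, away)`` arrays (or scalars)."""
    n = 1 if size is None else size
    away = rng.random(n) < sc.p_away
    u = rng.random(n)
    lo_t, hi_t = TOWARD_RANGE
    lo_a, hi_a = AWAY_RANGE
    theta = np.where(away, lo_a + u * (hi_a - lo_a), lo_t + u * (hi_t - lo_t))
    if size is None:
        return float(theta[0]), bool(away[0])
    return theta, away


def _truncated_normal(
    mean: float, sd: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Normal(mean, sd) with negative draws resampled (truncation at 0)."""
    out = rng.normal(mean, sd, n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def sample_fid(
    sc: LightScenario,
    away,
    speed: float,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> np.ndarray:
    """Draw flight-initiation distances paired with the given away flags.

    ``speed`` (m/s) converts the light's temporal benefit into the maximum
    alert distance for away-draws under a lit scenario; pass the vehicle's
    approach speed (default convention) or the animal's escape speed.
    """
    n = 1 if size is None else size
    away_arr = np.broadcast_to(np.asarray(away, dtype=bool), (n,))
    out = np.empty(n, dtype=float)
    if sc.lit:
        uniform_part = away_arr
    else:
        uniform_part = np.zeros(n, dtype=bool)
    n_unif = int(uniform_part.sum())
    if n_unif:
        upper = max_alert_distance(speed, sc.beta) if sc.beta > 0 else 0.0
        out[uniform_part] = rng.random(n_unif) * upper
    n_norm = n - n_unif
    if n_norm:
        out[~uniform_part] = _truncated_normal(sc.fid_mean, sc.fid_sd, rng, n_norm)
    if size is None:
        return float(out[0])
    return out


def sample_behavior(
    sc: LightScenario,
    speed: float,
    rng: np.random.Generator,
    size: Optional[int] = None,
):
    """Joint draw of (theta, d_fid, away) honoring the pairing rule."""
    if size is None:
        theta, away = sample_angle(sc, rng)
        d_fid = sample_fid(sc, away, speed, rng)
        return BehaviorSample(theta=theta, d_fid=d_fid, away=away)
    theta, away = sample_angle(sc, rng, size=size)
    d_fid = sample_fid(sc, away, speed, rng, size=size)
    return theta, d_fid, away
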