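"""Definitions of the three running-based exercise protocols.

Each protocol lasts roughly 10 min and is designed to stress primarily one
energy system:

* ``continuous_shuttles`` — 20 m shuttle runs at a mean speed of 8 km/h for
  10 min (aerobic).
* ``repeated_accelerations`` — 6 x (5 + 5) m maximal runs with a 180-degree
  turn and 2 min passive recoveries (anaerobic alactic).
* ``repeated_sprints`` — 3 x 4 x (20 + 20) m maximal sprints with a
  180-degree turn, 20 s recovery between sprints and 3 min between sets
  (anaerobic lactic).

Every shuttle leg is modelled as a symmetric accelerate–cruise–decelerate
profile with a full stop at each 180-degree turn; peak accelerations are
kept at or below 4.5 m/s^2, the validity ceiling of the equivalent-slope
model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROTOCOL_NAMES = ("continuous_shuttles", "repeated_accelerations", "repeated_sprints")


@dataclass(frozen=True)
class Effort:
    """One effort: ``legs`` shuttle legs of ``leg_distance`` m each.

    ``peak_speed`` is the cruise speed of the trapezoid profile; consecutive
    legs are separated by a full stop (the 180-degree turn).
    """

    legs: int
    leg_distance: float
    peak_speed: float

    @property
    def distance(self) -> float:
        return self.legs * self.leg_distance


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered efforts and the passive recovery after each one (s)."""

    name: str
    segments: tuple[tuple[Effort, float], ...]  # (effort, recovery after it)
    accel: float = 4.25  # peak forward acceleration, m/s^2
    decel: float = 4.5  # peak deceleration magnitude, m/s^2

    def __post_init__(self) -> None:
        if self.accel <= 0 or self.decel <= 0:
            raise ValueError("acceleration limits must be positive")
        for eff, rec in self.segments:
            if rec < 0:
                raise ValueError("recovery duration must be non-negative")
            ramp = eff.peak_speed**2 / 2 * (1 / self.accel + 1 / self.decel)
            if ramp > eff.leg_distance + 1e-9:
                raise ValueError(
                    f"protocol {self.name!r}: leg of {eff.leg_distance} m cannot "
                    f"reach {eff.peak_speed} m/s within the acceleration limits"
                )

    @property
    def total_effort_distance(self) -> float:
        return sum(eff.distance for eff, _ in self.segments)

    @property
    def n_efforts(self) -> int:
        return len(self.segments)


def _cruise_speed_for_leg_time(distance: float, leg_time: float, accel: float,
                               decel: float) -> float:
    """Cruise speed of a 0->v->0 trapezoid covering ``distance`` in ``leg_time``.

    Solves d = v T - v^2/2 (1/a_up + 1/a_down) for the smaller root.
    """
    k = 0.5 * (1 / accel + 1 / decel)
    disc = leg_time**2 - 4 * k * distance
    if disc < 0:
        raise ValueError("leg time too short for the distance at these limits")
    return (leg_time - np.sqrt(disc)) / (2 * k)


def continuous_shuttles(duration_s: float = 600.0, shuttle_m: float = 20.0,
                        mean_speed: float = 8 / 3.6) -> ProtocolSpec:
    """Continuous 20 m shuttles at a mean of 8 km/h, one ~10 min effort."""
    leg_time = shuttle_m / mean_speed  # 9 s at the defaults
    legs = int(round(duration_s / leg_time))
    accel = decel = 1.5  # gentle ramps for submaximal shuttles
    v = _cruise_speed_for_leg_time(shuttle_m, leg_time, accel, decel)
    eff = Effort(legs=legs, leg_distance=shuttle_m, peak_speed=v)
    return ProtocolSpec("continuous_shuttles", ((eff, 0.0),), accel=accel, decel=decel)


def repeated_accelerations(n: int = 6, leg_m: float = 5.0,
                           recovery_s: float = 120.0) -> ProtocolSpec:
    """6 x (5 + 5) m maximal accelerations with 180-degree turn, 2 min rest."""
    accel, decel = 4.25, 4.5
    # highest speed reachable with a full stop inside a 5 m leg
    v = np.sqrt(2 * leg_m / (1 / accel + 1 / decel)) * 0.999
    eff = Effort(legs=2, leg_distance=leg_m, peak_speed=float(v))
    segs = tuple((eff, recovery_s if i < n - 1 else 0.0) for i in range(n))
    return ProtocolSpec("repeated_accelerations", segs, accel=accel, decel=decel)


def repeated_sprints(sets: int = 3, sprints_per_set: int = 4, leg_m: float = 20.0,
                     intra_recovery_s: float = 20.0,
                     inter_recovery_s: float = 180.0) -> ProtocolSpec:
    """3 x 4 x (20 + 20) m sprints; 20 s between sprints, 3 min between sets."""
    eff = Effort(legs=2, leg_distance=leg_m, peak_speed=7.0)
    segs = []
    for s in range(sets):
        for j in range(sprints_per_set):
            last_in_set = j == sprints_per_set - 1
            last_overall = last_in_set and s == sets - 1
            rec = 0.0 if last_overall else (inter_recovery_s if last_in_set
                                            else intra_recovery_s)
            segs.append((eff, rec))
    return ProtocolSpec("repeated_sprints", tuple(segs))


_FACTORIES = {
    "continuous_shuttles": continuous_shuttles,
    "repeated_accelerations": repeated_accelerations,
    "repeated_sprints": repeated_sprints,
    # CLI-friendly aliases
    "continuous": continuous_shuttles,
    "accelerations": repeated_accelerations,
    "sprints": repeated_sprints,
}


def get_protocol(name: str) -> ProtocolSpec:
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")
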