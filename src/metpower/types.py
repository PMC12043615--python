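"""Core domain containers shared across the pipeline.

Canonical internal units: time s, speed m/s, acceleration m/s^2, metabolic
power W/kg, oxygen uptake ml/kg/min (net, per-kg series) or ml/min (gross,
absolute breath data), energy kJ, lactate mmol/L.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Fixed energy equivalent of oxygen assumed by the metabolic power model.
FIXED_EE_KJ_PER_L = 20.9

#: Conversion: 1 W/kg of metabolic power expressed as net oxygen uptake,
#: derived solely from the fixed equivalent (60 s/min / 20.9 kJ/L, with
#: 1 J = 1 mJ/g handled by the ml scale).
WKG_TO_MLKGMIN = 60.0 / FIXED_EE_KJ_PER_L

#: Oxygen equivalent of blood lactate accumulation, L O2 per kg body mass
#: per mmol/L.
LACTATE_O2_L_PER_KG_PER_MMOL = 0.003

PHASE_EFFORT = "effort"
PHASE_BREAK = "break"
PHASE_POST = "post"


@dataclass(frozen=True)
class AthleteProfile:
    """Anthropometric and physiological parameters of one athlete.

    vo2max and vo2rest are net and gross maximal/resting uptakes in
    ml/kg/min respectively; vo2rest is the seated resting uptake that the
    three-component model subtracts to obtain net aerobic supply.
    """

    mass: float
    vo2max: float
    vo2rest: float = 4.5
    hrmax: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not 0 < self.vo2rest < self.vo2max:
            raise ValueError(
                f"need 0 < vo2rest < vo2max, got {self.vo2rest}, {self.vo2max}"
            )

    @property
    def vo2rest_ml_min(self) -> float:
        return self.vo2rest * self.mass

    @property
    def vo2max_ml_min(self) -> float:
        return self.vo2max * self.mass


@dataclass
class SpeedTrace:
    """Uniform 20 Hz speed series with per-sample phase labels."""

    t: np.ndarray
    v: np.ndarray
    phase: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if self.t.size < 2:
            raise ValueError("speed trace needs at least two samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("speed trace must be uniformly sampled")
        if np.any(self.v < 0):
            raise ValueError("speed must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def effort_windows(self) -> list[tuple[float, float]]:
        """Contiguous [start, end) time windows labelled as effort."""
        return _phase_windows(self.t, self.phase, PHASE_EFFORT, self.dt)

    def break_windows(self) -> list[tuple[float, float]]:
        return _phase_windows(self.t, self.phase, PHASE_BREAK, self.dt)


def _phase_windows(t, phase, label, dt) -> list[tuple[float, float]]:
    mask = np.asarray(phase) == label
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = [0] if mask[0] else []
    starts += [int(i) + 1 for i in edges if not mask[i] and mask[i + 1]]
    ends = [int(i) + 1 for i in edges if mask[i] and not mask[i + 1]]
    if mask[-1]:
        ends.append(len(mask))
    # half-open sample intervals [t, t + dt)
    return [(float(t[s]), float(t[e - 1]) + dt) for s, e in zip(starts, ends)]


@dataclass
class MetabolicPowerSeries:
    """Per-sample output of the speed -> energy-cost -> power chain."""

    t: np.ndarray
    v: np.ndarray
    a: np.ndarray
    es: np.ndarray
    em: np.ndarray
    ec: np.ndarray
    p: np.ndarray
    phase: np.ndarray
    mass: float
    vo2sim: Optional[np.ndarray] = None
    n_es_out_of_range: int = 0

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class MpmEnergyResult:
    """Energy partition of the metabolic power model, kJ."""

    w_aer: float
    w_ana: float
    w_aer_breaks: float
    vo2_accumulated: float  # L, net simulated uptake over the session
    breaks_excluded: bool = False
    summary: dict = field(default_factory=dict)

    @property
    def w_tot(self) -> float:
        return self.w_aer + self.w_ana


@dataclass
class BreathSeries:
    """Breath-by-breath gas exchange; vo2/vco2 are gross ml/min."""

    t: np.ndarray
    vo2: np.ndarray
    vco2: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.t.size == 0:
            raise ValueError("empty breath series")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("breath times must be strictly increasing")
        if np.any(self.vo2 < 0):
            raise ValueError("VO2 must be non-negative")
        if self.vco2 is not None:
            self.vco2 = np.asarray(self.vco2, dtype=float)


@dataclass(frozen=True)
class LactateSamples:
    """Capillary lactate: pre-exercise plus post-exercise minutes 1/3/5/7."""

    pre: float
    post: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if self.pre <= 0 or any(v <= 0 for _, v in self.post):
            raise ValueError("lactate concentrations must be positive")
        allowed = {1, 3, 5, 7}
        if any(m not in allowed for m, _ in self.post):
            raise ValueError("post-exercise minutes must be in {1, 3, 5, 7}")

    @property
    def peak(self) -> float:
        if not self.post:
            raise ValueError("no post-exercise lactate samples")
        return max(v for _, v in self.post)


@dataclass
class EpocFit:
    """Biexponential fit of excess post-exercise oxygen consumption.

    vo2(t) = a exp(-t/tau_a) + b exp(-t/tau_b) + c, amplitudes ml/min.
    """

    a: float
    tau_a: float
    b: float
    tau_b: float
    c: float
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged:
            if not self.tau_a < self.tau_b:
                raise ValueError("fast time constant must be below slow one")
            if self.a < 0 or self.b < 0 or self.c < 0:
                raise ValueError("amplitudes and offset must be non-negative")


@dataclass(frozen=True)
class EnergyEquivalent:
    mode: str  # "fixed" | "individual"
    value: float  # kJ/L O2
    rer_used: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode == "fixed" and self.value != FIXED_EE_KJ_PER_L:
            raise ValueError("fixed mode must carry 20.9 kJ/L")
        if self.mode not in ("fixed", "individual"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class TcmEnergyResult:
    """Three-component (PCr-LA-O2) energy supplies, kJ."""

    w_aer_incl: float
    w_aer_excl: float
    w_alactic: float
    w_lactic: float
    vo2_net_incl: float  # L
    vo2_net_excl: float  # L
    ee: EnergyEquivalent
    epoc: Optional[EpocFit] = None
    delta_lactate: float = float("nan")
    summary: dict = field(default_factory=dict)

    @property
    def w_ana(self) -> float:
        return self.w_alactic + self.w_lactic

    @property
    def w_tot_incl(self) -> float:
        return self.w_aer_incl + self.w_ana

    @property
    def w_tot_excl(self) -> float:
        return self.w_aer_excl + self.w_ana


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
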