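"""Synthetic sessions for the three running protocols with known energy truth.

A session is generated in a physiologically ordered chain:

1. a 20 Hz speed trace realizes the protocol geometry (trapezoid legs with a
   full stop at every 180-degree turn) plus multiplicative device noise;
2. the noiseless trace defines the metabolic power demand via the
   energy-cost model, and the true oxygen-uptake response follows first-order
   onset kinetics toward that demand, capped at VO2max;
3. the aerobic truth is the response integral over the effort windows; the
   anaerobic truth is the demand integral over the efforts minus the aerobic
   truth, split into alactic and lactic parts by ``lactic_fraction``;
4. the breath-by-breath series samples the response at irregular breath
   times (faster breathing at higher uptake) and decays biexponentially
   after the last effort, with the fast EPOC amplitude derived from the
   alactic truth (inverse of the 2*tau_a fast-component integral);
5. the lactate samples rise above baseline by the amount implied by the
   lactic truth (inverse of the 3 ml O2/kg per mmol/L mapping).

By construction aerobic + alactic + lactic truth equals the effort-window
demand integral, and a consistent estimator can recover each component.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import mpm
from .protocols import ProtocolSpec, get_protocol
from .types import (
    FIXED_EE_KJ_PER_L,
    LACTATE_O2_L_PER_KG_PER_MMOL,
    PHASE_BREAK,
    PHASE_EFFORT,
    PHASE_POST,
    AthleteProfile,
    BreathSeries,
    LactateSamples,
    MetabolicPowerSeries,
    SpeedTrace,
)

DT = 0.05  # 20 Hz
POST_WINDOW_S = 450.0  # 7.5 min of seated recovery after the last effort


@dataclass(frozen=True)
class KineticsParams:
    """Oxygen-kinetics and noise parameters of the generator.

    Time constants in s; EPOC amplitudes in L/min; ``lactate_gain`` in
    mmol/L per kJ of lactic supply (None = physiological inverse of the
    3 ml O2/kg mapping); noise SDs are relative (fractions).
    """

    tau_on: float = 20.0
    a_fast: float = 1.5
    tau_a: float = 30.0
    b_slow: float = 0.4
    tau_b: float = 300.0
    lactate_gain: Optional[float] = None
    lactic_fraction: float = 0.5
    noise_sd_speed: float = 0.023
    noise_sd_vo2: float = 0.04
    breath_interval_jitter: float = 0.25
    lactate_noise_sd: float = 0.1
    lactate_baseline: float = 1.6

    def __post_init__(self) -> None:
        if not 0 < self.tau_a < self.tau_b:
            raise ValueError("need 0 < tau_a < tau_b")
        if self.tau_on <= 0:
            raise ValueError("tau_on must be positive")
        if self.a_fast < 0 or self.b_slow < 0:
            raise ValueError("EPOC amplitudes must be non-negative")
        if not 0 <= self.lactic_fraction <= 1:
            raise ValueError("lactic_fraction must be in [0, 1]")

    def noiseless(self) -> "KineticsParams":
        return replace(self, noise_sd_speed=0.0, noise_sd_vo2=0.0,
                       breath_interval_jitter=0.0, lactate_noise_sd=0.0)


def default_kinetics(protocol_name: str) -> KineticsParams:
    """Protocol-tuned defaults for the anaerobic split.

    The lactic share of the anaerobic deficit is set once per protocol to
    match the energy system each exercise is designed to stress: mostly
    alactic for the short accelerations, mostly lactic for the repeated
    sprints, a small lactic share for the continuous shuttles.
    """
    frac = {"continuous_shuttles": 0.15, "continuous": 0.15,
            "repeated_accelerations": 0.4, "accelerations": 0.4,
            "repeated_sprints": 0.9, "sprints": 0.9}.get(protocol_name, 0.5)
    return KineticsParams(lactic_fraction=frac)


@dataclass(frozen=True)
class EnergyTruth:
    """Ground-truth energy supplies of a synthetic session, kJ."""

    aerobic: float
    alactic: float
    lactic: float

    @property
    def total(self) -> float:
        return self.aerobic + self.alactic + self.lactic


@dataclass
class SyntheticSession:
    trace: SpeedTrace
    breaths: BreathSeries
    lactate: LactateSamples
    truth: EnergyTruth
    seed: int
    protocol: ProtocolSpec
    athlete: AthleteProfile
    kin: KineticsParams


def _leg_speed(tloc: np.ndarray, v: float, a_up: float, a_dn: float,
               leg_time: float) -> np.ndarray:
    t1 = v / a_up
    t3 = v / a_dn
    t2_end = leg_time - t3
    out = np.where(tloc < t1, a_up * tloc, v)
    dec = v - a_dn * (tloc - t2_end)
    out = np.where(tloc > t2_end, np.maximum(dec, 0.0), out)
    return out


def generate_speed_trace(protocol: ProtocolSpec, athlete: AthleteProfile,
                         seed: int | np.random.Generator = 0,
                         noise_sd: float = 0.0,
                         post_window_s: float = POST_WINDOW_S) -> SpeedTrace:
    """Realize the protocol as a 20 Hz speed trace with phase labels.

    Each shuttle leg is a trapezoid 0 -> peak -> 0; recoveries and the
    trailing post window are stationary. Multiplicative Gaussian noise of
    relative SD ``noise_sd`` is applied to moving samples and the result is
    clipped at zero.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # segment plan: (duration, phase, profile params or None)
    plan: list[tuple[float, str, tuple | None]] = []
    for eff, recovery in protocol.segments:
        ramp = eff.peak_speed**2 / 2 * (1 / protocol.accel + 1 / protocol.decel)
        if ramp > eff.leg_distance + 1e-9:
            raise ValueError("infeasible leg: cannot cover the distance "
                             "within the acceleration limits")
        cruise = (eff.leg_distance - ramp) / eff.peak_speed
        leg_time = eff.peak_speed / protocol.accel + cruise + eff.peak_speed / protocol.decel
        for _ in range(eff.legs):
            plan.append((leg_time, PHASE_EFFORT,
                         (eff.peak_speed, protocol.accel, protocol.decel, leg_time)))
        if recovery > 0:
            plan.append((recovery, PHASE_BREAK, None))
    plan.append((post_window_s, PHASE_POST, None))

    total = sum(d for d, _, _ in plan)
    n = int(np.floor(total / DT)) + 1
    t = np.arange(n) * DT
    v = np.zeros(n)
    phase = np.full(n, PHASE_POST, dtype=object)
    cursor = 0.0
    for dur, ph, params in plan:
        i0 = int(np.ceil(cursor / DT - 1e-9))
        i1 = min(int(np.ceil((cursor + dur) / DT - 1e-9)), n)
        phase[i0:i1] = ph
        if params is not None:
            pk, a_up, a_dn, leg_time = params
            v[i0:i1] = _leg_speed(t[i0:i1] - cursor, pk, a_up, a_dn, leg_time)
        cursor += dur
    if noise_sd > 0:
        v = v * (1.0 + noise_sd * rng.standard_normal(n))
        v = np.clip(v, 0.0, None)
    return SpeedTrace(t=t, v=v, phase=phase, mass=athlete.mass)


def _effort_strip_mask(phase: np.ndarray) -> np.ndarray:
    return np.asarray(phase[:-1]) == PHASE_EFFORT


def _vo2_response(demand: MetabolicPowerSeries, athlete: AthleteProfile,
                  kin: KineticsParams) -> np.ndarray:
    """True net oxygen-uptake response, ml/kg/min on the demand grid."""
    return mpm.simulate_vo2(demand, tau=kin.tau_on, vo2max=athlete.vo2max)


def aerobic_truth_kj(demand: MetabolicPowerSeries, vo2_net: np.ndarray,
                     mass: float) -> float:
    """Effort-window integral of the net uptake response, kJ at 20.9 kJ/L."""
    strips = 0.5 * demand.dt * (vo2_net[:-1] + vo2_net[1:])
    litres = strips[_effort_strip_mask(demand.phase)].sum() / 60.0 * mass / 1000.0
    return float(litres * FIXED_EE_KJ_PER_L)


def effort_demand_kj(demand: MetabolicPowerSeries, mass: float) -> float:
    """Effort-window integral of the metabolic power demand, kJ."""
    strips = 0.5 * demand.dt * (demand.p[:-1] + demand.p[1:])
    return float(strips[_effort_strip_mask(demand.phase)].sum() * mass / 1000.0)


def generate_breath_series(demand: MetabolicPowerSeries, athlete: AthleteProfile,
                           kin: KineticsParams,
                           seed: int | np.random.Generator = 0
                           ) -> tuple[BreathSeries, dict]:
    """Breath-by-breath gas exchange emulating a portable analyzer.

    During exercise the gross VO2 follows the first-order response to the
    demand (capped at VO2max) plus resting uptake; after the last effort it
    decays biexponentially with amplitudes (a_fast, b_slow) above the
    resting offset. Breath intervals shorten with uptake (3 s at rest down
    to 1.5 s at VO2max, log-normal jitter); VO2 carries multiplicative
    noise. Returns the series and the ground-truth aerobic/alactic
    integrals in kJ.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    phases = np.asarray(demand.phase)
    eff_idx = np.flatnonzero(phases == PHASE_EFFORT)
    if eff_idx.size == 0:
        raise ValueError("demand contains no effort samples")
    t_end = demand.t[eff_idx[-1]] + demand.dt
    if demand.t[-1] - t_end < 420.0:
        raise ValueError("demand must cover >= 7 min after the last effort")

    vo2_net = _vo2_response(demand, athlete, kin)
    truth_aer = aerobic_truth_kj(demand, vo2_net, athlete.mass)
    truth_alactic = (kin.a_fast * kin.tau_a / 60.0 * (1 - np.exp(-2.0))
                     * FIXED_EE_KJ_PER_L)

    a_ml = kin.a_fast * 1000.0
    b_ml = kin.b_slow * 1000.0
    rest_ml = athlete.vo2rest_ml_min
    net_abs = vo2_net * athlete.mass  # ml/min
    post = demand.t >= t_end
    dt_post = demand.t[post] - t_end
    net_abs[post] = (a_ml * np.exp(-dt_post / kin.tau_a)
                     + b_ml * np.exp(-dt_post / kin.tau_b))
    gross = net_abs + rest_ml

    # breath timestamps: interval driven by the current relative uptake
    times = []
    t_cur = float(demand.t[0])
    t_max = float(demand.t[-1])
    vo2max_ml = athlete.vo2max_ml_min
    sigma = kin.breath_interval_jitter
    while t_cur < t_max:
        rel = min(np.interp(t_cur, demand.t, net_abs) / vo2max_ml, 1.0)
        mean_int = 3.0 - 1.5 * rel
        if sigma > 0:
            interval = mean_int * rng.lognormal(-0.5 * sigma**2, sigma)
        else:
            interval = mean_int
        t_cur += max(interval, 0.3)
        if t_cur < t_max:
            times.append(t_cur)
    tb = np.asarray(times)
    vo2_b = np.interp(tb, demand.t, gross)
    if kin.noise_sd_vo2 > 0:
        vo2_b = vo2_b * (1.0 + kin.noise_sd_vo2 * rng.standard_normal(tb.size))
        vo2_b = np.clip(vo2_b, 0.0, None)
    rer = 0.84 + 0.16 * np.clip(np.interp(tb, demand.t, net_abs) / vo2max_ml, 0, 1)
    vco2_b = vo2_b * rer
    phase_b = np.where(tb < t_end, "exercise", "post").astype(object)
    series = BreathSeries(t=tb, vo2=vo2_b, vco2=vco2_b, phase=phase_b)
    truth = {"aerobic_kj": truth_aer, "alactic_kj": truth_alactic}
    return series, truth


#: Post-exercise lactate time course relative to the peak rise
#: (appearance then clearance; peak in the 3rd minute).
_LACTATE_SHAPE = {1: 0.70, 3: 1.0, 5: 0.93, 7: 0.84}


def generate_lactate_samples(lactic_energy: float, kin: KineticsParams,
                             athlete: AthleteProfile,
                             seed: int | np.random.Generator = 0
                             ) -> tuple[LactateSamples, float]:
    """Capillary lactate samples implied by a lactic energy supply.

    The peak post-exercise rise above baseline is
    lactic_energy * gain where the default gain inverts the
    1 mmol/L = 3 ml O2/kg mapping at the fixed 20.9 kJ/L equivalent.
    Returns the samples and the exact rise (mmol/L) as truth.
    """
    if lactic_energy < 0:
        raise ValueError("lactic energy must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    gain = kin.lactate_gain
    if gain is None:
        gain = 1.0 / (LACTATE_O2_L_PER_KG_PER_MMOL * athlete.mass * FIXED_EE_KJ_PER_L)
    delta = lactic_energy * gain
    sd = kin.lactate_noise_sd
    pre = kin.lactate_baseline + (sd * rng.standard_normal() if sd > 0 else 0.0)
    pre = max(pre, 0.2)
    post = []
    for minute, shape in sorted(_LACTATE_SHAPE.items()):
        val = kin.lactate_baseline + shape * delta
        if sd > 0:
            val += sd * rng.standard_normal()
        post.append((minute, max(val, 0.2)))
    return LactateSamples(pre=pre, post=tuple(post)), delta


def generate_session(protocol: ProtocolSpec | str, athlete: AthleteProfile,
                     kin: KineticsParams | None = None, seed: int = 0,
                     smoothing_window: float = 0.25) -> SyntheticSession:
    """Generate one complete synthetic session with ground truth.

    All randomness flows from ``seed`` through named sub-streams (speed
    noise, breath signal, lactate), so identical inputs reproduce the
    session bit-for-bit.
    """
    if isinstance(protocol, str):
        protocol = get_protocol(protocol)
    if kin is None:
        kin = default_kinetics(protocol.name)
    ss = np.random.SeedSequence(seed)
    rng_speed, rng_breath, rng_lact = (np.random.default_rng(c)
                                       for c in ss.spawn(3))

    clean = generate_speed_trace(protocol, athlete, noise_sd=0.0)
    with warnings.catch_warnings():
        # maximal efforts intentionally brush the fitted slope range; the
        # extrapolation warning is meant for analysts, not the generator
        warnings.filterwarnings("ignore", message=".*equivalent-slope range.*")
        demand = mpm.power_series(clean, smoothing_window=smoothing_window)
    vo2_net = _vo2_response(demand, athlete, kin)
    truth_aer = aerobic_truth_kj(demand, vo2_net, athlete.mass)
    w_eff = effort_demand_kj(demand, athlete.mass)
    deficit = max(w_eff - truth_aer, 0.0)
    truth_lactic = kin.lactic_fraction * deficit
    truth_alactic = deficit - truth_lactic

    # derive the fast EPOC amplitude carrying exactly the alactic truth
    a_fast = truth_alactic / (FIXED_EE_KJ_PER_L * (kin.tau_a / 60.0)
                              * (1 - np.exp(-2.0)))
    kin_derived = replace(kin, a_fast=a_fast)

    noisy = clean
    if kin.noise_sd_speed > 0:
        v = clean.v * (1.0 + kin.noise_sd_speed * rng_speed.standard_normal(clean.v.size))
        noisy = SpeedTrace(t=clean.t, v=np.clip(v, 0.0, None),
                           phase=clean.phase, mass=clean.mass)
    breaths, _ = generate_breath_series(demand, athlete, kin_derived, rng_breath)
    lactate, _ = generate_lactate_samples(truth_lactic, kin, athlete, rng_lact)
    truth = EnergyTruth(aerobic=truth_aer, alactic=truth_alactic,
                        lactic=truth_lactic)
    return SyntheticSession(trace=noisy, breaths=breaths, lactate=lactate,
                            truth=truth, seed=seed, protocol=protocol,
                            athlete=athlete, kin=kin)
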