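"""Metabolic power model: speed -> energy cost -> power -> simulated VO2.

The model treats accelerated running on flat ground as equivalent to uphill
running at constant speed. From the forward acceleration a it derives an
equivalent slope ES = a/g and equivalent mass EM = sqrt(ES^2 + 1), evaluates
the fifth-order energy-cost polynomial

    EC = (155.4 ES^5 - 30.4 ES^4 - 43.3 ES^3 + 46.3 ES^2 + 19.5 ES + 3.6) EM

in J/kg/m, and multiplies by speed to obtain metabolic power P = EC * v in
W/kg. Net oxygen uptake is then simulated as a first-order response to the
oxygen-equivalent power demand with time constant tau (default 20 s),
capped at VO2max; aerobic supply is the part of the power demand covered by
the simulated uptake, anaerobic supply the excess above it.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

from .types import (
    FIXED_EE_KJ_PER_L,
    PHASE_BREAK,
    PHASE_EFFORT,
    WKG_TO_MLKGMIN,
    MetabolicPowerSeries,
    MpmEnergyResult,
    SpeedTrace,
    warn,
)

G = 9.81  # m/s^2

#: Energy-cost polynomial, highest order first (J/kg/m at EM = 1).
EC_COEFFS = (155.4, -30.4, -43.3, 46.3, 19.5, 3.6)

#: The equivalent-slope model was developed up to |ES| = 0.45 (about
#: 4.5 m/s^2); beyond it the polynomial is extrapolated.
ES_VALID_RANGE = 0.45


def compute_acceleration(trace: SpeedTrace, smoothing_window: float = 0.25) -> np.ndarray:
    """Forward acceleration by central finite differences, optionally smoothed.

    ``smoothing_window`` is a moving-average width in seconds (0 disables
    smoothing). One-sided differences are used at the ends so the output has
    the same length as the input.
    """
    if trace.v.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    a = np.gradient(trace.v, trace.dt)
    if smoothing_window and smoothing_window > 0:
        n = max(1, int(round(smoothing_window / trace.dt)))
        if n > 1:
            a = uniform_filter1d(a, size=n, mode="nearest")
    return a


def equivalent_slope_and_mass(a: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """ES = a/g and EM = sqrt(ES^2 + 1) from forward acceleration."""
    es = np.asarray(a, dtype=float) / G
    em = np.sqrt(es**2 + 1.0)
    return es, em


def energy_cost(es, em):
    """Energy cost of accelerated running, J/kg/m (3.6 at ES=0, EM=1)."""
    return np.polyval(EC_COEFFS, np.asarray(es, dtype=float)) * np.asarray(em, dtype=float)


def metabolic_power(ec, v):
    """P = EC * v in W/kg; zero when stationary."""
    ec = np.asarray(ec, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be non-negative")
    return ec * v


def power_series(trace: SpeedTrace, smoothing_window: float = 0.25) -> MetabolicPowerSeries:
    """Run the full speed -> EC -> P chain on a trace."""
    a = compute_acceleration(trace, smoothing_window)
    es, em = equivalent_slope_and_mass(a)
    n_out = int(np.count_nonzero(np.abs(es) > ES_VALID_RANGE))
    if n_out:
        warn(f"{n_out} samples exceed the fitted equivalent-slope range "
             f"|ES| <= {ES_VALID_RANGE}; polynomial extrapolated")
    ec = energy_cost(es, em)
    p = metabolic_power(ec, trace.v)
    return MetabolicPowerSeries(t=trace.t, v=trace.v, a=a, es=es, em=em, ec=ec,
                                p=p, phase=trace.phase, mass=trace.mass,
                                n_es_out_of_range=n_out)


def simulate_vo2(p_series: MetabolicPowerSeries, tau: float = 20.0,
                 vo2max: float | None = None) -> np.ndarray:
    """Simulated net oxygen uptake (ml/kg/min) from the power demand.

    Within each 0.05 s sample the oxygen-equivalent demand E_n is constant
    and the uptake relaxes exponentially from its value at the sample onset
    toward E_n — a discrete first-order filter

        vo2[i] = E[i] + (vo2[i-1] - E[i]) * exp(-dt/tau)

    starting from 0 (net). The measured VO2max acts as a cut-off: the
    response is capped and each following step starts from the capped value.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    demand = p_series.p * WKG_TO_MLKGMIN  # ml/kg/min
    decay = np.exp(-p_series.dt / tau)
    out = np.empty_like(demand)
    level = 0.0
    for i, e in enumerate(demand):
        level = e + (level - e) * decay
        if vo2max is not None and level > vo2max:
            level = vo2max
        out[i] = level
    return out


def _strip_sums(y: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid strip integrals dt*(y[i]+y[i+1])/2 for each sample interval."""
    return 0.5 * dt * (y[:-1] + y[1:])


def partition_energy(p_series: MetabolicPowerSeries, vo2sim: np.ndarray,
                     mass: float | None = None) -> MpmEnergyResult:
    """Partition the power demand into aerobic and anaerobic supply, kJ.

    Per sample the aerobic rate is min(P, P_vo2sim) and the anaerobic rate
    max(P - P_vo2sim, 0) with the simulated uptake converted to W/kg through
    the fixed 20.9 kJ/L equivalent; time integrals are trapezoidal, with each
    sample strip assigned to the phase of its left sample so that window
    integrals add up exactly to the total.
    """
    if mass is None:
        mass = p_series.mass
    if len(vo2sim) != len(p_series.p):
        raise ValueError("power and simulated-VO2 series are misaligned")
    p = p_series.p
    p_vo2 = np.asarray(vo2sim) / WKG_TO_MLKGMIN  # W/kg
    aer_rate = np.minimum(p, p_vo2)
    ana_rate = p - aer_rate  # == max(p - p_vo2, 0), >= 0
    dt = p_series.dt
    aer_strips = _strip_sums(aer_rate, dt)
    ana_strips = _strip_sums(ana_rate, dt)
    break_mask = np.asarray(p_series.phase[:-1]) == PHASE_BREAK
    to_kj = mass / 1000.0
    w_aer = float(aer_strips.sum() * to_kj)
    w_ana = float(ana_strips.sum() * to_kj)
    w_aer_breaks = float(aer_strips[break_mask].sum() * to_kj)
    vo2_acc = float(_strip_sums(np.asarray(vo2sim), dt).sum() / 60.0 * mass / 1000.0)
    eff = np.asarray(p_series.phase) != "post"
    summary = {
        "v_peak": float(p_series.v[eff].max()),
        "acc_peak": float(p_series.a[eff].max()),
        "dec_peak": float(p_series.a[eff].min()),
        "p_peak": float(p[eff].max()),
        "p_mean": float(p[eff].mean()),
        "vo2sim_peak": float(np.max(np.asarray(vo2sim)[eff])),
        "vo2sim_mean": float(np.mean(np.asarray(vo2sim)[eff])),
    }
    return MpmEnergyResult(w_aer=w_aer, w_ana=w_ana, w_aer_breaks=w_aer_breaks,
                           vo2_accumulated=vo2_acc, summary=summary)


def exclude_breaks(result: MpmEnergyResult) -> MpmEnergyResult:
    """Subtract the aerobic supply accrued during passive breaks.

    Only the aerobic side can be corrected — the anaerobic supply has no
    per-break attribution in this model — so w_ana is unchanged and w_tot
    is recomputed as the new sum.
    """
    return MpmEnergyResult(
        w_aer=result.w_aer - result.w_aer_breaks,
        w_ana=result.w_ana,
        w_aer_breaks=result.w_aer_breaks,
        vo2_accumulated=result.vo2_accumulated,
        breaks_excluded=True,
        summary=dict(result.summary),
    )


def analyze_trace(trace: SpeedTrace, vo2max: float, tau: float = 20.0,
                  smoothing_window: float = 0.25) -> tuple[MetabolicPowerSeries, MpmEnergyResult, MpmEnergyResult]:
    """Full metabolic power analysis of one session.

    Returns the per-sample series plus the energy partition including and
    excluding passive breaks.
    """
    ps = power_series(trace, smoothing_window)
    ps.vo2sim = simulate_vo2(ps, tau=tau, vo2max=vo2max)
    incl = partition_energy(ps, ps.vo2sim)
    return ps, incl, exclude_breaks(incl)
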