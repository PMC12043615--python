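"""Three-component (PCr-LA-O2) model of energy supply.

Aerobic supply: accumulated breath-by-breath VO2 over the exercise minus
resting uptake times duration, converted with an energy equivalent of
oxygen. Anaerobic alactic supply: fast component of the biexponential EPOC
fit, integrated up to the 2*tau_a cut-off. Anaerobic lactic supply: net
lactate rise (peak post minus pre) at 3 ml O2/kg per mmol/L.

The energy equivalent is either fixed at 20.9 kJ/L O2 or individual, read
off the nonprotein caloric-equivalent table at the peak respiratory
exchange ratio of the exercise.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .types import (
    FIXED_EE_KJ_PER_L,
    LACTATE_O2_L_PER_KG_PER_MMOL,
    AthleteProfile,
    BreathSeries,
    EnergyEquivalent,
    EpocFit,
    LactateSamples,
    TcmEnergyResult,
    warn,
)

#: Nonprotein caloric equivalents of oxygen by respiratory quotient
#: (Lusk's classical table, kcal/L converted at 4.184 kJ/kcal).
RER_EE_TABLE = (
    (0.70, 19.61),
    (0.75, 19.83),
    (0.80, 20.09),
    (0.85, 20.34),
    (0.90, 20.60),
    (0.95, 20.86),
    (1.00, 21.12),
)


def moving_average_breaths(series: BreathSeries, n_breaths: int = 10) -> BreathSeries:
    """Centered moving average over ``n_breaths`` breaths.

    Length is preserved; windows shrink at the edges. ``n_breaths = 1`` is
    the identity.
    """
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    if series.t.size == 0:
        raise ValueError("empty breath series")

    def _smooth(x):
        return (pd.Series(x).rolling(n_breaths, center=True, min_periods=1)
                .mean().to_numpy())

    return BreathSeries(
        t=series.t.copy(),
        vo2=_smooth(series.vo2),
        vco2=None if series.vco2 is None else _smooth(series.vco2),
        phase=None if series.phase is None else series.phase.copy(),
    )


def _windowed_integral_l(t: np.ndarray, flow_ml_min: np.ndarray,
                         windows: list[tuple[float, float]]) -> float:
    """Integral of a ml/min flow over time windows, in litres.

    Uses a shape-preserving monotone cubic (PCHIP) interpolant of the
    breath samples. Window edges rarely coincide with breath timestamps and
    the uptake curve has sharp on-/off-kinetic transitions at effort
    boundaries; a straddling linear chord systematically overshoots those
    kinks, whereas the monotone interpolant hugs them.
    """
    interp = PchipInterpolator(t, flow_ml_min)
    total = 0.0
    for (t0, t1) in windows:
        if t1 <= t[0] or t0 >= t[-1]:
            raise ValueError(f"window ({t0}, {t1}) outside breath data span")
        total += float(interp.integrate(max(t0, t[0]), min(t1, t[-1])))
    return total / 1000.0 / 60.0  # ml/min * s -> L


def net_aerobic_supply(series: BreathSeries, vo2rest_ml_min: float,
                       window: tuple[float, float],
                       ee: EnergyEquivalent) -> tuple[float, float]:
    """Net aerobic energy over an exercise window.

    Returns (w_aer kJ, net accumulated VO2 L): the gross VO2 integral minus
    resting uptake times duration, multiplied by the energy equivalent.
    Negative net uptake is clipped to zero with a warning.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    gross_l = _windowed_integral_l(series.t, series.vo2, [window])
    rest_l = vo2rest_ml_min / 1000.0 * (t1 - t0) / 60.0
    net = gross_l - rest_l
    if net < 0:
        warn(f"net accumulated VO2 negative ({net:.3f} L); clipped to 0")
        net = 0.0
    return net * ee.value, net


def fit_epoc(post_series: BreathSeries, vo2rest_ml_min: float | None = None,
             min_duration_s: float = 360.0) -> EpocFit:
    """Fit vo2(t) = a exp(-t/tau_a) + b exp(-t/tau_b) + c to post-exercise data.

    Times are taken relative to the first post-exercise breath. Nonlinear
    least squares with non-negative amplitudes and multi-start
    initialization over a grid of time-constant pairs; the two exponentials
    are reordered afterwards so tau_a < tau_b. The offset c starts at the
    measured resting uptake when provided (bounded to +-50% of it), else at
    the mean of the final minute.
    """
    t = post_series.t - post_series.t[0]
    y = post_series.vo2
    if t[-1] < min_duration_s:
        raise ValueError(
            f"need >= {min_duration_s:.0f} s of post-exercise data, got {t[-1]:.0f} s")
    c0 = (vo2rest_ml_min if vo2rest_ml_min is not None
          else float(np.mean(y[t >= t[-1] - 60.0])))
    c_lo, c_hi = 0.5 * c0, 1.5 * c0
    amp0 = max(float(y[:3].mean()) - c0, 10.0)

    def resid(p):
        a, ta, b, tb, c = p
        return a * np.exp(-t / ta) + b * np.exp(-t / tb) + c - y

    best = None
    lb = [0.0, 5.0, 0.0, 30.0, c_lo]
    ub = [np.inf, 600.0, np.inf, 3000.0, c_hi]
    for ta0 in (15.0, 30.0, 60.0):
        for tb0 in (120.0, 300.0, 900.0):
            x0 = [0.75 * amp0, ta0, 0.25 * amp0, tb0, c0]
            try:
                sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                    x_scale=[max(amp0, 1), 30, max(amp0, 1), 300,
                                             max(c0, 1)])
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        raise RuntimeError("EPOC fit failed to converge from every start")
    rss, sol = best
    a, ta, b, tb, c = sol.x
    if ta > tb:  # reorder so the fast component comes first
        a, ta, b, tb = b, tb, a, ta
    return EpocFit(a=float(a), tau_a=float(ta), b=float(b), tau_b=float(tb),
                   c=float(c), rss=rss, converged=bool(sol.success))


def alactic_supply(fit: EpocFit, ee: EnergyEquivalent) -> float:
    """Fast-component EPOC energy up to the 2*tau_a cut-off, kJ.

    integral_0^{2 tau_a} a exp(-t/tau_a) dt = a tau_a (1 - e^-2), with the
    amplitude in L/min and the time constant in minutes.
    """
    if not fit.converged:
        raise ValueError("EPOC fit did not converge")
    litres = (fit.a / 1000.0) * (fit.tau_a / 60.0) * (1.0 - np.exp(-2.0))
    return litres * ee.value


def delta_lactate(samples: LactateSamples) -> float:
    """Net lactate: highest post-exercise minus pre-exercise, mmol/L."""
    d = samples.peak - samples.pre
    if d < 0:
        warn(f"negative net lactate ({d:.2f} mmol/L)")
    return d


def lactic_supply(delta_la: float, mass: float, ee: EnergyEquivalent) -> float:
    """Lactic energy from net lactate at 3 ml O2/kg per mmol/L, kJ."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if delta_la < 0:
        warn("negative net lactate treated as zero lactic supply")
    return max(delta_la, 0.0) * LACTATE_O2_L_PER_KG_PER_MMOL * mass * ee.value


def individual_equivalent(peak_rer: float) -> EnergyEquivalent:
    """Individual energy equivalent from the peak RER of the exercise.

    Linear interpolation in the bundled caloric-equivalent table; RER is
    clamped to [0.70, 1.00] with a warning outside that range.
    """
    if peak_rer <= 0:
        raise ValueError("RER must be positive")
    rers = np.array([r for r, _ in RER_EE_TABLE])
    vals = np.array([v for _, v in RER_EE_TABLE])
    if peak_rer < rers[0] or peak_rer > rers[-1]:
        warn(f"RER {peak_rer:.2f} outside [{rers[0]}, {rers[-1]}]; clamped")
        peak_rer = float(np.clip(peak_rer, rers[0], rers[-1]))
    return EnergyEquivalent(mode="individual",
                            value=float(np.interp(peak_rer, rers, vals)),
                            rer_used=peak_rer)


def fixed_equivalent() -> EnergyEquivalent:
    return EnergyEquivalent(mode="fixed", value=FIXED_EE_KJ_PER_L)


def break_aerobic_correction(series: BreathSeries, break_windows,
                             vo2rest_ml_min: float,
                             ee: EnergyEquivalent) -> tuple[float, float]:
    """Net aerobic energy accrued during passive breaks, for subtraction.

    Returns (kJ, L). Windows must be disjoint.
    """
    wins = sorted(break_windows)
    for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
        if b0 < a1:
            raise ValueError("break windows overlap")
    if not wins:
        return 0.0, 0.0
    gross_l = _windowed_integral_l(series.t, series.vo2, wins)
    dur = sum(t1 - t0 for t0, t1 in wins)
    net = gross_l - vo2rest_ml_min / 1000.0 * dur / 60.0
    return net * ee.value, net


def peak_rer(series: BreathSeries, window: tuple[float, float]) -> float:
    """Highest VCO2/VO2 ratio within a time window (after smoothing)."""
    if series.vco2 is None:
        raise ValueError("VCO2 required to compute RER")
    m = (series.t >= window[0]) & (series.t <= window[1]) & (series.vo2 > 0)
    if not m.any():
        raise ValueError("no breaths within the exercise window")
    return float(np.max(series.vco2[m] / series.vo2[m]))


def assemble_tcm(series: BreathSeries, samples: LactateSamples,
                 athlete: AthleteProfile,
                 effort_windows: list[tuple[float, float]],
                 break_windows: list[tuple[float, float]] | None = None,
                 ee_mode: str = "fixed", n_breaths: int = 10) -> TcmEnergyResult:
    """Run the complete three-component analysis of one session.

    ``effort_windows`` delimit the efforts; the exercise window spans the
    first effort start to the last effort end, and ``break_windows``
    (defaulting to the gaps between efforts) are used for the excl.-breaks
    variant. Post-exercise breaths (after the last effort) feed the EPOC fit.

    The ``n_breaths`` moving average is used where a smooth curve is wanted
    (peak RER, peak/mean uptake). Windowed accumulated-uptake integrals and
    the EPOC fit use the raw breaths: a centered 10-breath average has a
    transition width of roughly 20 s, which redistributes flux across the
    boundaries of few-second effort windows and inflates the fitted fast
    EPOC amplitude, whereas trapezoidal integration and least squares
    already average breath-level noise.
    """
    if not effort_windows:
        raise ValueError("need at least one effort window")
    smoothed = moving_average_breaths(series, n_breaths)
    exercise = (effort_windows[0][0], effort_windows[-1][1])
    if break_windows is None:
        break_windows = [(a1, b0) for (_, a1), (b0, _) in
                         zip(effort_windows, effort_windows[1:])]
    if ee_mode == "fixed":
        ee = fixed_equivalent()
    elif ee_mode == "individual":
        ee = individual_equivalent(peak_rer(smoothed, exercise))
    else:
        raise ValueError(f"unknown ee_mode {ee_mode!r}")

    w_aer_incl, vo2_net_incl = net_aerobic_supply(
        series, athlete.vo2rest_ml_min, exercise, ee)
    w_break, vo2_break = break_aerobic_correction(
        series, break_windows, athlete.vo2rest_ml_min, ee)
    w_aer_excl = max(w_aer_incl - w_break, 0.0)
    vo2_net_excl = max(vo2_net_incl - vo2_break, 0.0)

    post_mask = series.t >= exercise[1]
    post = BreathSeries(t=series.t[post_mask], vo2=series.vo2[post_mask])
    fit = fit_epoc(post, vo2rest_ml_min=athlete.vo2rest_ml_min)
    w_alactic = alactic_supply(fit, ee)

    dla = delta_lactate(samples)
    w_lactic = lactic_supply(dla, athlete.mass, ee)

    ex_mask = (smoothed.t >= exercise[0]) & (smoothed.t <= exercise[1])
    return TcmEnergyResult(
        w_aer_incl=w_aer_incl, w_aer_excl=w_aer_excl, w_alactic=w_alactic,
        w_lactic=w_lactic, vo2_net_incl=vo2_net_incl, vo2_net_excl=vo2_net_excl,
        ee=ee, epoc=fit, delta_lactate=dla,
        summary={
            "la_pre": samples.pre,
            "la_peak": samples.peak,
            "vo2_peak_ml_min": float(smoothed.vo2[ex_mask].max()),
            "vo2_mean_ml_min": float(smoothed.vo2[ex_mask].mean()),
        },
    )
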