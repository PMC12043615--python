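"""File formats, run configuration and the end-to-end pipeline.

CSV schemas (comma separated, dot decimal, UTF-8, header row):

* speed trace   — ``t_s,speed_mps,phase``
* breath series — ``t_s,vo2_ml_min,vco2_ml_min[,phase]``
* lactate       — ``label,minute,mmol_l`` (label ``pre`` or ``post``)

Each synthetic session additionally gets a JSON sidecar with the ground
truth and seed. Time coordinates are seconds from session start; sample
intervals are half-open [t, t + dt).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import mpm, stats, synth, tcm
from .protocols import get_protocol
from .types import (
    AthleteProfile,
    BreathSeries,
    LactateSamples,
    MpmEnergyResult,
    SpeedTrace,
    TcmEnergyResult,
    warn,
)

log = logging.getLogger("metpower")


class FormatError(ValueError):
    """Malformed input file."""


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    extra = set(df.columns) - required - {"phase", "vco2_ml_min"}
    if extra:
        warn(f"{path}: ignoring unknown columns {sorted(extra)}")
    bad = df[list(required)].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad) + 2)[:5].tolist()  # 1-based + header
        raise FormatError(f"{path}: malformed rows at lines {lines}")
    return df


def read_speed_csv(path, mass: float) -> SpeedTrace:
    df = _read_csv(path, {"t_s", "speed_mps"})
    t = df["t_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time not strictly increasing")
    v = df["speed_mps"].to_numpy(float)
    if np.any(v < 0):
        raise FormatError(f"{path}: negative speed")
    phase = (df["phase"].to_numpy(object) if "phase" in df.columns
             else np.full(len(df), "effort", dtype=object))
    return SpeedTrace(t=t, v=v, phase=phase, mass=mass)


def write_speed_csv(path, trace: SpeedTrace) -> None:
    pd.DataFrame({"t_s": trace.t, "speed_mps": trace.v,
                  "phase": trace.phase}).to_csv(path, index=False)


def read_breath_csv(path) -> BreathSeries:
    df = _read_csv(path, {"t_s", "vo2_ml_min"})
    t = df["t_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time not strictly increasing")
    return BreathSeries(
        t=t, vo2=df["vo2_ml_min"].to_numpy(float),
        vco2=(df["vco2_ml_min"].to_numpy(float)
              if "vco2_ml_min" in df.columns else None),
        phase=(df["phase"].to_numpy(object) if "phase" in df.columns else None),
    )


def write_breath_csv(path, series: BreathSeries) -> None:
    d = {"t_s": series.t, "vo2_ml_min": series.vo2}
    if series.vco2 is not None:
        d["vco2_ml_min"] = series.vco2
    if series.phase is not None:
        d["phase"] = series.phase
    pd.DataFrame(d).to_csv(path, index=False)


def read_lactate_csv(path) -> LactateSamples:
    df = _read_csv(path, {"label", "minute", "mmol_l"})
    pre = df[df["label"] == "pre"]
    if len(pre) != 1:
        raise FormatError(f"{path}: expected exactly one pre-exercise sample")
    post = [(int(r.minute), float(r.mmol_l))
            for r in df[df["label"] == "post"].itertuples()]
    return LactateSamples(pre=float(pre["mmol_l"].iloc[0]), post=tuple(post))


def write_lactate_csv(path, samples: LactateSamples) -> None:
    rows = [{"label": "pre", "minute": 0, "mmol_l": samples.pre}]
    rows += [{"label": "post", "minute": m, "mmol_l": v}
             for m, v in samples.post]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_session(outdir, session: synth.SyntheticSession) -> None:
    """Write one synthetic session (3 CSVs + truth sidecar) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_speed_csv(outdir / "speed.csv", session.trace)
    write_breath_csv(outdir / "breaths.csv", session.breaths)
    write_lactate_csv(outdir / "lactate.csv", session.lactate)
    sidecar = {
        "seed": session.seed,
        "protocol": session.protocol.name,
        "athlete": dataclasses.asdict(session.athlete),
        "truth_kj": {"aerobic": session.truth.aerobic,
                     "alactic": session.truth.alactic,
                     "lactic": session.truth.lactic},
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2))


def result_to_dict(res) -> dict:
    if isinstance(res, MpmEnergyResult):
        return {"w_tot": res.w_tot, "w_aer": res.w_aer, "w_ana": res.w_ana,
                "w_aer_breaks": res.w_aer_breaks,
                "vo2_accumulated_l": res.vo2_accumulated,
                "breaks_excluded": res.breaks_excluded,
                "summary": res.summary}
    if isinstance(res, TcmEnergyResult):
        return {"w_tot_incl": res.w_tot_incl, "w_tot_excl": res.w_tot_excl,
                "w_aer_incl": res.w_aer_incl, "w_aer_excl": res.w_aer_excl,
                "w_alactic": res.w_alactic, "w_lactic": res.w_lactic,
                "w_ana": res.w_ana, "vo2_net_incl_l": res.vo2_net_incl,
                "vo2_net_excl_l": res.vo2_net_excl,
                "delta_lactate": res.delta_lactate,
                "ee": {"mode": res.ee.mode, "value": res.ee.value,
                       "rer_used": res.ee.rer_used},
                "epoc": None if res.epoc is None else dataclasses.asdict(res.epoc),
                "summary": res.summary}
    raise TypeError(type(res))


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    protocols: tuple[str, ...] = ("continuous_shuttles",
                                  "repeated_accelerations",
                                  "repeated_sprints")
    n_subjects: int = 12
    seed: int = 0
    mass_mean: float = 81.2
    mass_sd: float = 11.1
    vo2max_mean: float = 64.8
    vo2max_sd: float = 4.9
    vo2rest: float = 4.5
    tau: float = 20.0
    smoothing_window: float = 0.25
    out_dir: str = "metpower_run"
    zero_noise: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "protocols" in raw:
            raw["protocols"] = tuple(raw["protocols"])
        return cls(**raw)


def sample_cohort(config: RunConfig) -> list[AthleteProfile]:
    """Cohort mirroring the study: truncated-normal mass and VO2max."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    out = []
    while len(out) < config.n_subjects:
        mass = rng.normal(config.mass_mean, config.mass_sd)
        vo2max = rng.normal(config.vo2max_mean, config.vo2max_sd)
        if mass > 40 and vo2max > config.vo2rest + 10:
            out.append(AthleteProfile(mass=mass, vo2max=vo2max,
                                      vo2rest=config.vo2rest))
    return out


def analyze_session(session: synth.SyntheticSession, tau: float = 20.0,
                    smoothing_window: float = 0.25) -> dict:
    """Run both models on one session; returns results per arm."""
    trace, ath = session.trace, session.athlete
    _, mpm_incl, mpm_excl = mpm.analyze_trace(
        trace, ath.vo2max, tau=tau, smoothing_window=smoothing_window)
    ew, bw = trace.effort_windows(), trace.break_windows()
    tcm_ind = tcm.assemble_tcm(session.breaths, session.lactate, ath, ew, bw,
                               ee_mode="individual")
    tcm_fix = tcm.assemble_tcm(session.breaths, session.lactate, ath, ew, bw,
                               ee_mode="fixed")
    return {"mpm_incl": mpm_incl, "mpm_excl": mpm_excl,
            "tcm_ind": tcm_ind, "tcm_fix": tcm_fix}


def run_pipeline(config: RunConfig) -> Path:
    """simulate -> both models -> comparison for every subject and protocol.

    Deterministic given the config seed. Writes per-session inputs and
    result JSONs plus one comparison table CSV and Bland-Altman point CSVs
    per protocol; returns the report directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = sample_cohort(config)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_subjects * len(config.protocols)) % (2**31)
    config.to_yaml(out / "config.yaml")
    k = 0
    for proto_name in config.protocols:
        proto = get_protocol(proto_name)
        results = {"mpm": [], "tcm_ind": [], "tcm_fix": []}
        pdir = out / proto.name
        for i, ath in enumerate(cohort):
            kin = synth.default_kinetics(proto.name)
            if config.zero_noise:
                kin = kin.noiseless()
            session = synth.generate_session(proto, ath, kin, seed=int(seeds[k]))
            k += 1
            sdir = pdir / f"subject_{i:02d}"
            write_session(sdir, session)
            res = analyze_session(session, tau=config.tau,
                                  smoothing_window=config.smoothing_window)
            log.info("%s subject %d: mpm w_tot=%.1f kJ, tcm(fix) w_tot=%.1f kJ",
                     proto.name, i, res["mpm_excl"].w_tot,
                     res["tcm_fix"].w_tot_excl)
            (sdir / "results.json").write_text(json.dumps(
                {arm: result_to_dict(r) for arm, r in res.items()}, indent=2))
            results["mpm"].append(res["mpm_excl"])
            results["tcm_ind"].append(res["tcm_ind"])
            results["tcm_fix"].append(res["tcm_fix"])
        report = stats.compare_models(results["mpm"], results["tcm_ind"],
                                      results["tcm_fix"])
        report["table"].to_csv(pdir / "comparison.csv")
        for var in ("w_tot", "w_aer", "w_ana", "vo2_accumulated"):
            ba = report[var]["bland_altman"]
            pd.DataFrame({"mean": ba.means, "difference": ba.differences}
                         ).to_csv(pdir / f"bland_altman_{var}.csv", index=False)
        log.info("%s: report written to %s", proto.name, pdir)
    return out
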