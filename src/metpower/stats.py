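"""Agreement and repeated-measures statistics for the model comparison.

Each metric is gated by Shapiro–Wilk normality (per condition) and Levene
variance homogeneity: if both pass, a one-way repeated-measures ANOVA with
generalized eta-squared and paired t-tests; otherwise a Friedman test with
Kendall's W and Wilcoxon signed-rank tests. Post-hoc p-values are
Bonferroni-corrected; pairwise effect sizes are Cohen's d on the paired
differences. Agreement between the two energy models is summarized by
absolute and relative biases and Bland-Altman 95% limits of agreement.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

GATE_ALPHA = 0.05


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    effect: float
    effect_label: str
    detail: dict = field(default_factory=dict)


@dataclass
class AgreementReport:
    bias: float
    bias_sd: float
    loa_low: float
    loa_high: float
    relative_bias: float
    relative_bias_sd: float
    differences: np.ndarray
    means: np.ndarray
    n_excluded_relative: int = 0


def _as_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("design must be a subjects x conditions matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if np.isnan(x).any():
        raise ValueError("design must contain complete cases only")
    return x


def eta_squared_label(v: float) -> str:
    if v >= 0.138:
        return "large"
    if v >= 0.059:
        return "moderate"
    if v >= 0.01:
        return "small"
    return "trivial"


def kendall_w_label(v: float) -> str:
    if v >= 0.5:
        return "large"
    if v >= 0.3:
        return "moderate"
    return "small"


def cohen_d_label(v: float) -> str:
    v = abs(v)
    if v >= 0.8:
        return "large"
    if v >= 0.5:
        return "moderate"
    if v >= 0.2:
        return "small"
    return "trivial"


def choose_test(design, alpha: float = GATE_ALPHA) -> tuple[str, dict]:
    """Parametric vs nonparametric branch from the normality/variance gate.

    Parametric iff every condition passes Shapiro–Wilk and Levene's test
    passes, all at ``alpha``. Degenerate (constant) conditions fail the
    gate by convention. Returns the branch and the gate p-values.
    """
    x = _as_matrix(design)
    gate: dict = {"alpha": alpha, "shapiro_p": [], "levene_p": np.nan}
    ok = True
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            gate["shapiro_p"].append(np.nan)
            ok = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = sps.shapiro(col).pvalue
        gate["shapiro_p"].append(float(p))
        ok &= p >= alpha
    if ok:
        lev = sps.levene(*(x[:, j] for j in range(x.shape[1])))
        gate["levene_p"] = float(lev.pvalue)
        ok &= lev.pvalue >= alpha
    branch = "parametric" if ok else "nonparametric"
    return branch, gate


def rm_anova(design) -> TestResult:
    """One-way repeated-measures ANOVA with generalized eta-squared.

    For this single within-subject factor design
    eta_g^2 = SS_effect / (SS_effect + SS_subjects + SS_error).
    """
    x = _as_matrix(design)
    n, k = x.shape
    gm = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - gm) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - gm) ** 2)
    ss_tot = np.sum((x - gm) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df2
    f = (ss_cond / df1) / ms_err if ms_err > 0 else 0.0
    p = float(sps.f.sf(f, df1, df2)) if ms_err > 0 else 1.0
    eta_g = ss_cond / (ss_cond + ss_subj + ss_err) if ss_tot > 0 else 0.0
    return TestResult("rm_anova", float(f), p, float(eta_g),
                      eta_squared_label(eta_g),
                      {"df1": df1, "df2": df2, "ss_cond": ss_cond,
                       "ss_subj": ss_subj, "ss_err": ss_err})


def friedman(design) -> TestResult:
    """Friedman test with Kendall's W = chi2 / (n (k - 1))."""
    x = _as_matrix(design)
    n, k = x.shape
    if np.allclose(x, x[:, [0]]):
        return TestResult("friedman", 0.0, 1.0, 0.0, kendall_w_label(0.0))
    chi2, p = sps.friedmanchisquare(*(x[:, j] for j in range(k)))
    w = chi2 / (n * (k - 1))
    return TestResult("friedman", float(chi2), float(p), float(w),
                      kendall_w_label(w))


def global_test(design, branch: str) -> TestResult:
    if branch == "parametric":
        return rm_anova(design)
    if branch == "nonparametric":
        return friedman(design)
    raise ValueError(f"unknown branch {branch!r}")


def cohen_d_paired(a, b) -> float:
    """Cohen's d for paired data: mean difference / SD of differences."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    sd = d.std(ddof=1)
    return float(d.mean() / sd) if sd > 0 else 0.0


def posthoc(design, branch: str, labels=None) -> list[TestResult]:
    """All pairwise paired comparisons with Bonferroni correction.

    Parametric branch: paired t-tests; nonparametric: Wilcoxon signed-rank
    (exact p for n <= 25, zero differences dropped). p-values are
    multiplied by the number of pairs and capped at 1.
    """
    x = _as_matrix(design)
    k = x.shape[1]
    if labels is None:
        labels = [f"c{j}" for j in range(k)]
    pairs = list(itertools.combinations(range(k), 2))
    out = []
    for i, j in pairs:
        a, b = x[:, i], x[:, j]
        diff = a - b
        if branch == "parametric":
            stat, p = sps.ttest_rel(a, b)
            name = "t_paired"
        else:
            nz = diff[diff != 0]
            if nz.size == 0:
                stat, p = 0.0, 1.0
            else:
                mode = "exact" if nz.size <= 25 else "approx"
                stat, p = sps.wilcoxon(nz, mode=mode)
            name = "wilcoxon"
        d = cohen_d_paired(a, b)
        out.append(TestResult(name, float(stat), min(float(p) * len(pairs), 1.0),
                              d, cohen_d_label(d),
                              {"pair": (labels[i], labels[j]),
                               "p_uncorrected": float(p),
                               "bonferroni_factor": len(pairs)}))
    return out


def gated_comparison(design, alpha: float = GATE_ALPHA, labels=None):
    """Gate, global test and post-hocs for one metric."""
    branch, gate = choose_test(design, alpha)
    g = global_test(design, branch)
    g.detail["branch"] = branch
    g.detail["gate"] = gate
    return g, posthoc(design, branch, labels)


def bland_altman(model, reference) -> AgreementReport:
    """Bias, SD and 95% limits of agreement of model minus reference.

    The relative bias is the mean of per-subject percentage differences
    with respect to the reference; subjects with a zero reference are
    excluded from the relative bias (flagged in the report).
    """
    m = np.asarray(model, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("model and reference must be equal-length vectors")
    if m.size < 3:
        raise ValueError("need at least 3 paired values")
    diff = m - r
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    nz = r != 0
    rel = (m[nz] - r[nz]) / r[nz] * 100.0
    n_excluded = int((~nz).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} subjects with zero reference excluded "
                      "from the relative bias", stacklevel=2)
    return AgreementReport(
        bias=bias, bias_sd=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        relative_bias=float(rel.mean()) if rel.size else float("nan"),
        relative_bias_sd=float(rel.std(ddof=1)) if rel.size > 1 else 0.0,
        differences=diff, means=(m + r) / 2.0,
        n_excluded_relative=n_excluded,
    )


#: Variables compared between the two models, as (label, mpm getter, tcm getter).
_VARIABLES = {
    "w_tot": (lambda m: m.w_tot, lambda t: t.w_tot_excl),
    "w_aer": (lambda m: m.w_aer, lambda t: t.w_aer_excl),
    "w_ana": (lambda m: m.w_ana, lambda t: t.w_ana),
    "vo2_accumulated": (lambda m: m.vo2_accumulated,
                        lambda t: t.vo2_net_incl),
}


def compare_models(mpm_results, tcm_ind_results, tcm_fix_results,
                   variables=None, alpha: float = GATE_ALPHA) -> dict:
    """Full agreement report between the two models over one cohort.

    Inputs are per-subject result lists for one exercise condition (the
    metabolic power model plus the three-component model with individual
    and fixed energy equivalents). For each variable the three arms are
    compared with the gated global test and post-hocs, and the metabolic
    power model is assessed against the fixed-equivalent three-component
    arm by bias and Bland-Altman limits of agreement.
    """
    if not (len(mpm_results) == len(tcm_ind_results) == len(tcm_fix_results)):
        raise ValueError("unmatched sessions across arms")
    if variables is None:
        variables = list(_VARIABLES)
    report: dict = {}
    rows = []
    for var in variables:
        get_m, get_t = _VARIABLES[var]
        arm_m = np.array([get_m(r) for r in mpm_results])
        arm_i = np.array([get_t(r) for r in tcm_ind_results])
        arm_f = np.array([get_t(r) for r in tcm_fix_results])
        design = np.column_stack([arm_m, arm_i, arm_f])
        glob, pairs = gated_comparison(design, alpha,
                                       labels=["mpm", "tcm_ind", "tcm_fix"])
        ba = bland_altman(arm_m, arm_f)
        report[var] = {"global": glob, "posthoc": pairs, "bland_altman": ba,
                       "arms": {"mpm": arm_m, "tcm_ind": arm_i,
                                "tcm_fix": arm_f}}
        rows.append({
            "variable": var,
            "mpm_mean": arm_m.mean(), "mpm_sd": arm_m.std(ddof=1),
            "tcm_ind_mean": arm_i.mean(), "tcm_ind_sd": arm_i.std(ddof=1),
            "tcm_fix_mean": arm_f.mean(), "tcm_fix_sd": arm_f.std(ddof=1),
            "branch": glob.detail.get("branch"),
            "global_p": glob.p, "global_effect": glob.effect,
            "effect_label": glob.effect_label,
            "bias": ba.bias, "bias_sd": ba.bias_sd,
            "relative_bias_pct": ba.relative_bias,
            "relative_bias_sd_pct": ba.relative_bias_sd,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high,
        })
    report["table"] = pd.DataFrame(rows).set_index("variable")
    return report


def aerobic_share_pct(w_aer: float, w_tot: float) -> float:
    """Relative aerobic contribution, percent of total energy."""
    if w_tot <= 0:
        raise ValueError("total energy must be positive")
    return 100.0 * w_aer / w_tot
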