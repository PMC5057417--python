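"""Non-inferiority trial design and CI-based analysis for a binary endpoint.

The primary endpoint is 30-day mortality, assumed equal in both arms at
the design stage (p0 = 4.2%).  Non-inferiority of the new triage model is
declared when the lower bound of the two-sided Wald confidence interval
for d = p_dept - p_cta (positive favors CTA) lies above -delta
(delta = 0.5 percentage points absolute); superiority is then tested
hierarchically (gatekeeping) by asking whether the same lower bound
exceeds 0.

Two confidence levels coexist deliberately: the sample-size formula uses
a one-sided alpha of 0.05 (equivalently a 90% two-sided CI), which
reproduces the published requirement of ~39,820 patients, while the trial
analysis defaults to the conventional two-sided 95% interval.  Both are
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialDesign",
    "TrialResult",
    "ni_sample_size",
    "analytic_power_ni",
    "analytic_power_superiority",
    "analyze_trial",
    "analyze_secondary",
]


@dataclass(frozen=True)
class TrialDesign:
    """Design parameters of the non-inferiority comparison.

    p0: assumed 30-day mortality in both arms; delta: non-inferiority
    margin (absolute risk difference); alpha_one_sided: one-sided type-I
    error of the design; power: target probability of declaring
    non-inferiority when the arms are truly equal; 1:1 allocation.
    """

    p0: float = 0.042
    delta: float = 0.005
    alpha_one_sided: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        if self.delta <= 0.0:
            raise ValueError("delta must be positive")
        if not 0.0 < self.alpha_one_sided < 0.5:
            raise ValueError("alpha_one_sided must be in (0, 0.5)")
        if not 0.5 < self.power < 1.0:
            raise ValueError("power must be in (0.5, 1)")

    @property
    def ci_level(self) -> float:
        """Two-sided CI level matching the one-sided design alpha."""
        return 1.0 - 2.0 * self.alpha_one_sided


@dataclass(frozen=True)
class TrialResult:
    p_cta: float
    p_dept: float
    d: float                      # p_dept - p_cta; positive favors CTA
    ci: tuple[float, float]
    ci_level: float
    noninferior: bool
    superior: bool
    n_cta: int
    n_dept: int

    def __post_init__(self) -> None:
        if self.superior and not self.noninferior:
            raise ValueError("superiority requires non-inferiority (gatekeeping)")


def ni_sample_size(design: TrialDesign = TrialDesign()) -> dict[str, int]:
    """Per-arm and total sample size for the non-inferiority comparison.

    Normal approximation with equal variance p0(1-p0) in both arms under
    the design assumption of truly equal mortality:

        n/arm = ceil[ (z_{1-a} + z_{power})^2 * 2 p0 (1-p0) / delta^2 ]
    """
    z_a = stats.norm.ppf(1.0 - design.alpha_one_sided)
    z_b = stats.norm.ppf(design.power)
    per_arm = math.ceil(
        (z_a + z_b) ** 2 * 2.0 * design.p0 * (1.0 - design.p0) / design.delta ** 2
    )
    return {"per_arm": per_arm, "total": 2 * per_arm}


def analytic_power_ni(
    p_cta: float,
    p_dept: float,
    delta: float,
    n_per_arm: int,
    alpha_one_sided: float = 0.05,
) -> float:
    """Closed-form power of the non-inferiority test at a given truth.

    d_true = p_dept - p_cta; power = Phi((d_true + delta)/SE - z_{1-a})
    with the unpooled binomial SE at the true proportions.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    d_true = p_dept - p_cta
    se = math.sqrt(p_cta * (1 - p_cta) / n_per_arm + p_dept * (1 - p_dept) / n_per_arm)
    z_a = stats.norm.ppf(1.0 - alpha_one_sided)
    return float(stats.norm.cdf((d_true + delta) / se - z_a))


def analytic_power_superiority(
    p_cta: float,
    p_dept: float,
    n_per_arm: int,
    alpha_two_sided: float = 0.05,
) -> float:
    """Closed-form power to show CTA superiority (lower CI bound above 0)."""
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    d_true = p_dept - p_cta
    se = math.sqrt(p_cta * (1 - p_cta) / n_per_arm + p_dept * (1 - p_dept) / n_per_arm)
    z_a = stats.norm.ppf(1.0 - alpha_two_sided / 2.0)
    return float(stats.norm.cdf(d_true / se - z_a))


def _wald_diff_ci(x_cta: int, n_cta: int, x_dept: int, n_dept: int,
                  ci_level: float):
    p_c = x_cta / n_cta
    p_d = x_dept / n_dept
    d = p_d - p_c
    se = math.sqrt(p_c * (1 - p_c) / n_cta + p_d * (1 - p_d) / n_dept)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return p_c, p_d, d, (d - z * se, d + z * se)


def analyze_trial(
    cohort: pd.DataFrame,
    design: TrialDesign = TrialDesign(),
    ci_level: float = 0.95,
    outcome: str = "died30",
) -> TrialResult:
    """CI-based non-inferiority / hierarchical superiority analysis.

    Expects an ``arm`` column with values "cta"/"dept".  Non-inferiority:
    lower Wald bound of p_dept - p_cta above -delta; superiority is
    evaluated only when non-inferiority holds, and requires the same
    lower bound above 0.
    """
    arms = cohort["arm"].astype(str).str.lower()
    cta = cohort.loc[arms == "cta", outcome].astype(int)
    dept = cohort.loc[arms == "dept", outcome].astype(int)
    if len(cta) == 0 or len(dept) == 0:
        raise ValueError("both arms must contain at least one encounter")
    p_c, p_d, d, ci = _wald_diff_ci(int(cta.sum()), len(cta),
                                    int(dept.sum()), len(dept), ci_level)
    noninf = ci[0] > -design.delta
    sup = bool(noninf and ci[0] > 0.0)
    return TrialResult(p_cta=p_c, p_dept=p_d, d=d, ci=ci, ci_level=ci_level,
                       noninferior=noninf, superior=sup,
                       n_cta=len(cta), n_dept=len(dept))


def analyze_trial_counts(
    deaths_cta: int, n_cta: int, deaths_dept: int, n_dept: int,
    design: TrialDesign = TrialDesign(), ci_level: float = 0.95,
) -> TrialResult:
    """Count-level variant of `analyze_trial` (used by the simulator)."""
    if n_cta == 0 or n_dept == 0:
        raise ValueError("both arms must contain at least one encounter")
    p_c, p_d, d, ci = _wald_diff_ci(deaths_cta, n_cta, deaths_dept, n_dept,
                                    ci_level)
    noninf = ci[0] > -design.delta
    sup = bool(noninf and ci[0] > 0.0)
    return TrialResult(p_cta=p_c, p_dept=p_d, d=d, ci=ci, ci_level=ci_level,
                       noninferior=noninf, superior=sup,
                       n_cta=n_cta, n_dept=n_dept)


def analyze_secondary(cohort: pd.DataFrame, ci_level: float = 0.95) -> dict:
    """Secondary-endpoint comparisons between arms.

    Length of stay is log-transformed and compared by a two-sample t-test;
    the reported effect is the back-transformed geometric-mean ratio
    (CTA / DEPT) with its CI.  ICU admission and 30-day readmission are
    compared as proportion differences (dept - cta) with Wald CIs.
    """
    arms = cohort["arm"].astype(str).str.lower()
    out: dict = {}

    if "los_days" in cohort.columns:
        los_c = cohort.loc[arms == "cta", "los_days"].to_numpy(dtype=float)
        los_d = cohort.loc[arms == "dept", "los_days"].to_numpy(dtype=float)
        if np.any(los_c <= 0) or np.any(los_d <= 0):
            raise ValueError("length of stay must be positive")
        lc, ld = np.log(los_c), np.log(los_d)
        t, p = stats.ttest_ind(lc, ld, equal_var=False)
        diff = lc.mean() - ld.mean()
        se = math.sqrt(lc.var(ddof=1) / lc.size + ld.var(ddof=1) / ld.size)
        df = (lc.var(ddof=1) / lc.size + ld.var(ddof=1) / ld.size) ** 2 / (
            (lc.var(ddof=1) / lc.size) ** 2 / (lc.size - 1)
            + (ld.var(ddof=1) / ld.size) ** 2 / (ld.size - 1)
        )
        tq = stats.t.ppf(0.5 + ci_level / 2.0, df)
        out["los_ratio"] = {
            "ratio": float(math.exp(diff)),
            "ci": (float(math.exp(diff - tq * se)), float(math.exp(diff + tq * se))),
            "p": float(p),
        }

    for col, key in (("icu", "icu_diff"), ("readmit30", "readmit_diff")):
        if col in cohort.columns:
            x_c = cohort.loc[arms == "cta", col].astype(int)
            x_d = cohort.loc[arms == "dept", col].astype(int)
            _, _, d, ci = _wald_diff_ci(int(x_c.sum()), len(x_c),
                                        int(x_d.sum()), len(x_d), ci_level)
            out[key] = {"diff": d, "ci": ci}

    if "time_to_treatment" in cohort.columns:
        tt_c = np.log(cohort.loc[arms == "cta", "time_to_treatment"].to_numpy(float))
        tt_d = np.log(cohort.loc[arms == "dept", "time_to_treatment"].to_numpy(float))
        t, p = stats.ttest_ind(tt_c, tt_d, equal_var=False)
        out["time_to_treatment_ratio"] = {
            "ratio": float(math.exp(tt_c.mean() - tt_d.mean())), "p": float(p),
        }
    return out
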