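"""Cluster-randomized cross-over trial simulation and operating characteristics.

The trial layout follows the study design: two centers, each using one
triage model during the first half of the inclusions and the other during
the second half, so that each arm accrues exactly half of the total
encounters and every center contributes to both arms.  The CTA arm can
carry a mortality effect expressed as an odds multiplier on each
encounter's latent death risk (1.0 = no effect, the non-inferiority
null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import GeneratorConfig, generate_cohort
from .design import TrialDesign, analyze_trial_counts

__all__ = [
    "TrialSimConfig",
    "simulate_trial",
    "split_encounters",
    "operating_characteristics",
]


@dataclass
class TrialSimConfig:
    """One simulated trial: cohort spec plus arm structure and effect."""

    total_n: int = 40_000
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cta_mortality_multiplier: float = 1.0  # odds multiplier in the CTA arm
    first_cta_center: str = "A"
    seed: int = 0
    center_mortality_offset: float = 0.0   # log-odds added at center B

    def __post_init__(self) -> None:
        if self.total_n % 2 != 0:
            raise ValueError("total_n must be even (1:1 allocation)")
        if self.cta_mortality_multiplier < 0:
            raise ValueError("cta_mortality_multiplier must be >= 0")


def simulate_trial(config: TrialSimConfig) -> pd.DataFrame:
    """Simulate one full trial; returns the cohort with an ``arm`` column.

    Period switches after total_n/2 inclusions; the arm is determined by
    (center, period) with cross-over, so each arm holds exactly total_n/2
    encounters.  Deaths are drawn after applying the CTA odds multiplier
    (and any center offset) to each encounter's latent log-odds.
    """
    gen = GeneratorConfig(**{**config.generator.to_dict(),
                             "n": config.total_n,
                             "seed": config.seed,
                             "crossover_at": config.total_n // 2})
    rng = np.random.default_rng(config.seed)
    table = generate_cohort(gen, rng=rng, include_linear_predictor=True)

    first = config.first_cta_center
    is_cta = (table["center"] == first) == (table["period"] == 1)
    table["arm"] = np.where(is_cta, "cta", "dept")

    lp = table.pop("_lp").to_numpy().copy()
    if config.center_mortality_offset:
        lp = lp + config.center_mortality_offset * (
            table["center"] == config.generator.centers[1]
        ).to_numpy()
    if config.cta_mortality_multiplier != 1.0:
        if config.cta_mortality_multiplier == 0.0:
            lp = np.where(is_cta, -np.inf, lp)
        else:
            lp = lp + math.log(config.cta_mortality_multiplier) * is_cta.to_numpy()
    table["died30"] = rng.random(len(table)) < expit(lp)
    return table


def split_encounters(records: pd.DataFrame) -> pd.DataFrame:
    """Turn per-admission records into analysis encounters.

    ``records`` needs patient_id, admit_day and discharge_day columns
    (days on any common scale), ordered or orderable per patient.  A
    readmission more than 30 days after the previous discharge opens a new
    encounter; a readmission within 30 days is folded into the index
    encounter, setting its readmit30 flag, and extends the discharge used
    for subsequent gap comparisons.
    """
    required = {"patient_id", "admit_day", "discharge_day"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (records["discharge_day"] < records["admit_day"]).any():
        bad = records.index[records["discharge_day"] < records["admit_day"]][0]
        raise ValueError(f"discharge before admission at row {bad}")

    rows = []
    for pid, grp in records.groupby("patient_id", sort=False):
        grp = grp.sort_values("admit_day")
        current = None
        for rec in grp.itertuples(index=False):
            if current is None or rec.admit_day - current["discharge_day"] > 30:
                if current is not None:
                    rows.append(current)
                current = {"patient_id": pid,
                           "admit_day": rec.admit_day,
                           "discharge_day": rec.discharge_day,
                           "readmit30": False}
            else:
                current["readmit30"] = True
                current["discharge_day"] = max(current["discharge_day"],
                                               rec.discharge_day)
        if current is not None:
            rows.append(current)
    return pd.DataFrame(rows).reset_index(drop=True)


def _arm_probability(p_dept: float, multiplier: float) -> float:
    if multiplier == 0.0:
        return 0.0
    return float(expit(logit(p_dept) + math.log(multiplier)))


def operating_characteristics(
    config: TrialSimConfig,
    reps: int = 2000,
    design: TrialDesign = TrialDesign(),
    ci_level: Optional[float] = None,
    vitals: bool = False,
    margin_reps: Optional[int] = None,
) -> dict:
    """Monte-Carlo operating characteristics of the trial decision rule.

    Estimates the probability of declaring non-inferiority and (gatekept)
    superiority under the configured truth, plus the type-I error when the
    CTA arm is exactly delta worse than the DEPT arm.  The default path
    draws per-arm deaths as Bernoulli at the arm's marginal mortality,
    which matches the patient-level analysis exactly when no covariate
    structure enters the decision rule; ``vitals=True`` instead runs the
    full vitals-level simulator per replicate (use smaller reps/total_n).

    ``ci_level`` defaults to the design-consistent two-sided level
    1 - 2*alpha_one_sided.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if ci_level is None:
        ci_level = design.ci_level
    n_arm = config.total_n // 2
    rng = np.random.default_rng(config.seed)

    def run(p_cta: float, p_dept: float, nreps: int):
        ni = sup = 0
        if vitals:
            for r in range(nreps):
                cfg = TrialSimConfig(
                    total_n=config.total_n,
                    generator=config.generator,
                    cta_mortality_multiplier=config.cta_mortality_multiplier,
                    first_cta_center=rng.choice(["A", "B"]),
                    seed=int(rng.integers(2**31 - 1)),
                )
                tab = simulate_trial(cfg)
                res = analyze_trial_counts(
                    int(tab.loc[tab.arm == "cta", "died30"].sum()), n_arm,
                    int(tab.loc[tab.arm == "dept", "died30"].sum()), n_arm,
                    design, ci_level)
                ni += res.noninferior
                sup += res.superior
        else:
            deaths_c = rng.binomial(n_arm, p_cta, size=nreps)
            deaths_d = rng.binomial(n_arm, p_dept, size=nreps)
            for dc, dd in zip(deaths_c, deaths_d):
                res = analyze_trial_counts(int(dc), n_arm, int(dd), n_arm,
                                           design, ci_level)
                ni += res.noninferior
                sup += res.superior
        return ni / nreps, sup / nreps

    p_dept = config.generator.target_mortality
    p_cta = _arm_probability(p_dept, config.cta_mortality_multiplier)
    power_ni, power_sup = run(p_cta, p_dept, reps)

    m_reps = margin_reps if margin_reps is not None else reps
    type1, _ = run(p_dept + design.delta, p_dept, m_reps)

    def mc_se(p: float, k: int) -> float:
        return math.sqrt(max(p * (1 - p), 1e-12) / k)

    return {
        "power_ni": power_ni, "se_ni": mc_se(power_ni, reps),
        "power_sup": power_sup, "se_sup": mc_se(power_sup, reps),
        "type1_at_margin": type1, "se_type1": mc_se(type1, m_reps),
        "n_per_arm": n_arm, "reps": reps, "ci_level": ci_level,
        "p_cta": p_cta, "p_dept": p_dept,
    }
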