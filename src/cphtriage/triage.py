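"""Deterministic CTA triage scoring.

The Copenhagen Triage Algorithm (CTA) assigns emergency-department patients
to an acuity category in two steps: an integer score computed from vital
signs (each abnormal vital contributes a fixed integer weight), mapped to a
category through increasing score thresholds, followed by a nurse
clinical-assessment override that may move the category at most two steps up
or one step down.  Patients presenting with minor injuries or complaints are
triaged BLUE directly and are exempt from both scoring and override.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

__all__ = [
    "TriageCategory",
    "VitalSigns",
    "Predictor",
    "ScoreChart",
    "TriageResult",
    "compute_score",
    "score_to_category",
    "apply_override",
    "triage_patient",
    "default_cta_chart",
    "ChartScorer",
]


class TriageCategory(enum.Enum):
    """Five-level acuity scale.

    GREEN < YELLOW < ORANGE < RED form an ordered ladder; BLUE (minor
    injuries and complaints) sits outside the ladder and is never produced
    by the score nor altered by override.
    """

    BLUE = "blue"
    GREEN = "green"
    YELLOW = "yellow"
    ORANGE = "orange"
    RED = "red"

    @property
    def rank(self) -> Optional[int]:
        """Position on the ordered ladder (GREEN=0 .. RED=3); None for BLUE."""
        return _LADDER_RANK.get(self)

    @classmethod
    def from_rank(cls, rank: int) -> "TriageCategory":
        return _LADDER[rank]


_LADDER = (
    TriageCategory.GREEN,
    TriageCategory.YELLOW,
    TriageCategory.ORANGE,
    TriageCategory.RED,
)
_LADDER_RANK = {c: i for i, c in enumerate(_LADDER)}


@dataclass(frozen=True)
class VitalSigns:
    """One encounter's physiological measurements.

    Parameters
    ----------
    sbp : float
        Systolic blood pressure, mmHg; must lie in (0, 400).
    hr : float
        Heart rate, beats/min; must lie in (0, 350).
    rr : float
        Respiratory rate, breaths/min; must lie in (0, 120).
    spo2 : float
        Arterial oxygen saturation, percent; must lie in (0, 100].
    oxygen_treatment : bool
        True when the patient receives supplemental oxygen.
    """

    sbp: float
    hr: float
    rr: float
    spo2: float
    oxygen_treatment: bool

    _BOUNDS = {
        "sbp": (0.0, 400.0),
        "hr": (0.0, 350.0),
        "rr": (0.0, 120.0),
        "spo2": (0.0, 100.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._BOUNDS.items():
            value = getattr(self, name)
            if value is None or not isinstance(value, (int, float)):
                raise ValueError(f"vital sign {name!r} is missing or non-numeric")
            if not math.isfinite(value):
                raise ValueError(f"vital sign {name!r} is not finite: {value!r}")
            if not (lo < value <= hi if name == "spo2" else lo < value < hi):
                raise ValueError(
                    f"vital sign {name!r}={value} outside physiological range "
                    f"({lo}, {hi}{']' if name == 'spo2' else ')'}"
                )
        if not isinstance(self.oxygen_treatment, bool):
            raise ValueError("oxygen_treatment must be a boolean")


@dataclass(frozen=True)
class Predictor:
    """One scored item of the chart.

    ``direction`` is "below" (abnormal when value < cutoff), "above"
    (abnormal when value > cutoff) or "flag" (abnormal when the boolean
    field is true).  Comparisons are strict: a value exactly at the cutoff
    is normal.
    """

    name: str
    field: str
    direction: str
    weight: int
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in ("below", "above", "flag"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction != "flag" and self.cutoff is None:
            raise ValueError(f"predictor {self.name!r} needs a cutoff")
        if not (isinstance(self.weight, int) and self.weight >= 1):
            raise ValueError(f"predictor {self.name!r} weight must be an integer >= 1")

    def is_abnormal(self, vitals: VitalSigns) -> bool:
        value = getattr(vitals, self.field)
        if self.direction == "flag":
            return bool(value)
        if self.direction == "below":
            return value < self.cutoff
        return value > self.cutoff


@dataclass(frozen=True)
class ScoreChart:
    """Deployable CTA chart: weighted predictors plus category thresholds.

    ``thresholds = (t_yellow, t_orange, t_red)`` is a strictly increasing
    integer triple with ``t_yellow >= 1``: scores below t_yellow map to
    GREEN, scores at or above t_red to RED.
    """

    predictors: tuple[Predictor, ...]
    thresholds: tuple[int, int, int]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) != 3 or not all(isinstance(x, int) for x in t):
            raise ValueError("thresholds must be an integer triple")
        if not (1 <= t[0] < t[1] < t[2]):
            raise ValueError("thresholds must be strictly increasing with t_yellow >= 1")
        if t[2] > self.max_score:
            raise ValueError("t_red exceeds the maximum attainable score")

    @property
    def max_score(self) -> int:
        return sum(p.weight for p in self.predictors)

    def to_json(self) -> str:
        obj = {
            "predictors": [
                {
                    "name": p.name,
                    "field": p.field,
                    "cutoff": p.cutoff,
                    "direction": p.direction,
                    "weight": p.weight,
                }
                for p in self.predictors
            ],
            "thresholds": list(self.thresholds),
        }
        if self.meta:
            obj["meta"] = self.meta
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScoreChart":
        obj = json.loads(text)
        preds = tuple(
            Predictor(
                name=p["name"],
                field=p.get("field", p["name"]),
                direction=p["direction"],
                weight=int(p["weight"]),
                cutoff=p.get("cutoff"),
            )
            for p in obj["predictors"]
        )
        return cls(
            predictors=preds,
            thresholds=tuple(int(t) for t in obj["thresholds"]),
            meta=obj.get("meta", {}),
        )


@dataclass(frozen=True)
class TriageResult:
    """Outcome of triaging one encounter."""

    score: Optional[int]
    base_category: TriageCategory
    final_category: TriageCategory
    override_applied: bool = False
    override_clamped: bool = False


def compute_score(vitals: VitalSigns, chart: ScoreChart) -> int:
    """Sum the weights of chart predictors whose abnormality condition holds.

    Cutoff comparisons are strict, so a vital exactly at its cutoff does not
    score.  Missing or non-finite vitals raise at `VitalSigns` construction;
    no imputation is performed.
    """
    return sum(p.weight for p in chart.predictors if p.is_abnormal(vitals))


def score_to_category(score: int, chart: ScoreChart) -> TriageCategory:
    """Map an integer score to its acuity category (never BLUE)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    t_yellow, t_orange, t_red = chart.thresholds
    if score < t_yellow:
        return TriageCategory.GREEN
    if score < t_orange:
        return TriageCategory.YELLOW
    if score < t_red:
        return TriageCategory.ORANGE
    return TriageCategory.RED


def apply_override(
    base: TriageCategory, requested: TriageCategory
) -> tuple[TriageCategory, bool]:
    """Apply the nurse override: at most two categories up, one down.

    Returns ``(final_category, clamped)``.  A BLUE base is never
    reclassified; requesting BLUE from a non-BLUE base is an error (BLUE is
    an intake route, not an override target).  Requests outside the allowed
    window are clamped to the nearest permitted category rather than
    rejected, so triage always yields a category.
    """
    if base is TriageCategory.BLUE:
        return TriageCategory.BLUE, requested is not TriageCategory.BLUE
    if requested is TriageCategory.BLUE:
        raise ValueError("cannot override a scored category to BLUE")
    lo = max(base.rank - 1, 0)
    hi = min(base.rank + 2, len(_LADDER) - 1)
    final_rank = min(max(requested.rank, lo), hi)
    final = TriageCategory.from_rank(final_rank)
    return final, final is not requested


def triage_patient(
    vitals: Optional[VitalSigns],
    chart: ScoreChart,
    minor_injury: bool = False,
    requested: Optional[TriageCategory] = None,
) -> TriageResult:
    """Full two-step CTA triage of one encounter.

    Minor-injury presentations go straight to BLUE with no score.  Otherwise
    the vital-sign score determines the base category and the optional nurse
    request is applied under the override constraints.
    """
    if minor_injury:
        return TriageResult(None, TriageCategory.BLUE, TriageCategory.BLUE)
    if vitals is None:
        raise ValueError("vitals are required for non-minor-injury encounters")
    score = compute_score(vitals, chart)
    base = score_to_category(score, chart)
    if requested is None:
        return TriageResult(score, base, base)
    final, clamped = apply_override(base, requested)
    return TriageResult(score, base, final, override_applied=final is not base,
                        override_clamped=clamped)


def default_cta_chart() -> ScoreChart:
    """The packaged default CTA chart.

    Predictors and integer weights follow the published multivariate model
    (odds ratios rounded to the nearest integer): oxygen treatment 4,
    SBP < 100 mmHg 3, RR > 22 /min 3, HR > 110 bpm 2, SpO2 < 94% 2.
    Category thresholds come from mortality-band calibration on the default
    synthetic cohort; the generating seed is recorded in the chart metadata.
    """
    text = resources.files("cphtriage.data").joinpath("default_chart.json").read_text()
    return ScoreChart.from_json(text)


class ChartScorer:
    """sklearn-style transformer applying a fixed `ScoreChart` to a cohort.

    `fit` only validates the input schema; `transform` returns the integer
    scores and `predict` the category names for each row of a DataFrame with
    columns sbp, hr, rr, spo2, oxygen_treatment.
    """

    _VITAL_COLS = ("sbp", "hr", "rr", "spo2", "oxygen_treatment")

    def __init__(self, chart: Optional[ScoreChart] = None):
        self.chart = chart

    def get_params(self, deep: bool = True) -> dict:
        return {"chart": self.chart}

    def set_params(self, **params) -> "ChartScorer":
        for k, v in params.items():
            if k != "chart":
                raise ValueError(f"unknown parameter {k!r}")
            self.chart = v
        return self

    def fit(self, X, y=None) -> "ChartScorer":
        self._validate(X)
        self.chart_ = self.chart if self.chart is not None else default_cta_chart()
        return self

    def _validate(self, X) -> None:
        missing = [c for c in self._VITAL_COLS if c not in X.columns]
        if missing:
            raise ValueError(f"missing vital-sign columns: {missing}")

    def transform(self, X):
        """Integer CTA scores, one per row."""
        import numpy as np

        self._check_fitted()
        self._validate(X)
        scores = np.zeros(len(X), dtype=int)
        for p in self.chart_.predictors:
            col = X[p.field].to_numpy()
            if np.any(~np.isfinite(col.astype(float))):
                bad = int(np.flatnonzero(~np.isfinite(col.astype(float)))[0])
                raise ValueError(f"non-finite value in column {p.field!r} at row {bad}")
            if p.direction == "flag":
                hit = col.astype(bool)
            elif p.direction == "below":
                hit = col < p.cutoff
            else:
                hit = col > p.cutoff
            scores += p.weight * hit.astype(int)
        return scores

    def predict(self, X) -> list[str]:
        """Category name ("green".."red") per row, before any override."""
        return [score_to_category(int(s), self.chart_).value for s in self.transform(X)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "chart_"):
            raise RuntimeError("ChartScorer is not fitted; call fit first")
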