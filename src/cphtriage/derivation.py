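"""Score-construction pipeline: from a cohort table to a deployable chart.

The pipeline mirrors how integer clinical risk scores are classically
derived from a registry cohort:

1. dichotomize each vital at its 10% abnormal tail (nearest-rank
   percentile; the abnormal side is the clinically dangerous tail),
2. screen each candidate flag by univariate logistic regression on 30-day
   death,
3. fit the retained flags jointly and backward-eliminate until every
   remaining flag has Wald p below alpha,
4. round the multivariate odds ratios to the nearest integer to obtain
   the score weights, and
5. calibrate the score-to-category thresholds so that observed category
   mortality matches the target bands (green < 2.5%, yellow 2.5-7.5%,
   orange 7.5-15%, red > 15%).

`TriageScoreDeriver` wraps the whole pipeline as an sklearn-style
estimator; the module-level functions expose the individual steps.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .triage import ChartScorer, Predictor, ScoreChart

__all__ = [
    "PredictorSpec",
    "RegressionResult",
    "CalibrationBands",
    "ThresholdCalibration",
    "default_predictor_specs",
    "percentile_cutoff",
    "fit_logistic",
    "univariate_screen",
    "backward_eliminate",
    "round_weights",
    "calibrate_thresholds",
    "derive_chart",
    "TriageScoreDeriver",
]

logger = logging.getLogger(__name__)

VITAL_COLUMNS = ("sbp", "hr", "rr", "spo2", "oxygen_treatment")


@dataclass
class PredictorSpec:
    """A candidate predictor before/after cutoff assignment.

    direction: "below" — abnormal tail is low values; "above" — high
    values; "flag" — the column is already boolean.
    """

    name: str
    field: str
    direction: str
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in ("below", "above", "flag"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def flags(self, table: pd.DataFrame) -> np.ndarray:
        col = table[self.field].to_numpy()
        if self.direction == "flag":
            return col.astype(bool).astype(int)
        if self.cutoff is None:
            raise ValueError(f"predictor {self.name!r} has no cutoff assigned")
        if self.direction == "below":
            return (col < self.cutoff).astype(int)
        return (col > self.cutoff).astype(int)


def default_predictor_specs() -> list[PredictorSpec]:
    """The five candidate predictors of the CTA chart."""
    return [
        PredictorSpec("oxygen_treatment", "oxygen_treatment", "flag"),
        PredictorSpec("sbp_low", "sbp", "below"),
        PredictorSpec("hr_high", "hr", "above"),
        PredictorSpec("rr_high", "rr", "above"),
        PredictorSpec("spo2_low", "spo2", "below"),
    ]


@dataclass(frozen=True)
class RegressionResult:
    """Fitted logistic model: per-predictor ORs with Wald inference."""

    names: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    intercept: float

    @property
    def odds_ratios(self) -> dict[str, float]:
        return {k: math.exp(v) for k, v in self.coef.items()}


@dataclass(frozen=True)
class CalibrationBands:
    """Target per-category 30-day mortality intervals, in percent.

    Defaults: green [0, 2.5), yellow [2.5, 7.5), orange [7.5, 15),
    red (15, 100].  ``references`` are the band midpoints (red: its lower
    edge) used as tie-break anchors in threshold calibration.
    """

    edges: tuple[float, float, float] = (2.5, 7.5, 15.0)
    references: tuple[float, float, float, float] = (1.25, 5.0, 11.25, 15.0)

    def in_band(self, category_index: int, mortality_pct: float) -> bool:
        lo = 0.0 if category_index == 0 else self.edges[category_index - 1]
        hi = self.edges[category_index] if category_index < 3 else 100.0
        if category_index == 3:
            return mortality_pct > lo
        return lo <= mortality_pct < hi if category_index > 0 else mortality_pct < hi


@dataclass(frozen=True)
class ThresholdCalibration:
    thresholds: tuple[int, int, int]
    mortality_pct: tuple[float, ...]  # observed per-category mortality, % (nan if empty)
    n_in_band: int
    counts: tuple[int, ...]


def percentile_cutoff(
    values: Sequence[float], direction: str, fraction: float = 0.10
) -> float:
    """Nearest-rank percentile cutoff for a 10%-tail dichotomization.

    For ``direction="above"`` returns the (1-fraction) nearest-rank
    percentile (abnormal = strictly greater); for ``"below"`` the
    ``fraction`` percentile (abnormal = strictly less).  With ties the
    realized abnormal fraction can only shrink, never exceed ``fraction``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_cutoff: empty input")
    if not np.all(np.isfinite(arr)):
        raise ValueError("percentile_cutoff: non-finite values")
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    if direction not in ("above", "below"):
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    q = 1.0 - fraction if direction == "above" else fraction
    srt = np.sort(arr)
    rank = max(1, math.ceil(q * arr.size))  # 1-based nearest rank
    return float(srt[rank - 1])


def _binary_design(table: pd.DataFrame, specs: Sequence[PredictorSpec]) -> pd.DataFrame:
    return pd.DataFrame({s.name: s.flags(table) for s in specs}, index=table.index)


def fit_logistic(X: pd.DataFrame, y: Sequence[int]) -> RegressionResult:
    """Maximum-likelihood logistic regression with Wald inference.

    ``X`` holds binary predictor columns (no constant; one is added).
    Raises on perfect separation, naming the offending predictor, and on
    non-convergence.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    for name in X.columns:
        if X[name].nunique() < 2:
            raise ValueError(f"predictor {name!r} is constant")
    _check_separation(X, y)
    design = sm.add_constant(X.astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")
    coef = {name: float(fit.params[name]) for name in X.columns}
    se = {name: float(fit.bse[name]) for name in X.columns}
    pvals = {name: float(fit.pvalues[name]) for name in X.columns}
    return RegressionResult(
        names=tuple(X.columns),
        coef=coef,
        se=se,
        pvalues=pvals,
        intercept=float(fit.params["const"]),
    )


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    # a zero cell in the 2x2 predictor/outcome table makes the Wald fit blow up
    for name in X.columns:
        x = np.asarray(X[name], dtype=float)
        cells = [
            np.sum((x == 1) & (y == 1)),
            np.sum((x == 1) & (y == 0)),
            np.sum((x == 0) & (y == 1)),
            np.sum((x == 0) & (y == 0)),
        ]
        if min(cells) == 0:
            raise ValueError(f"perfect separation on predictor {name!r}")


def univariate_screen(
    table: pd.DataFrame,
    specs: Sequence[PredictorSpec],
    alpha: float = 0.05,
    outcome: str = "died30",
) -> list[PredictorSpec]:
    """Retain predictors whose univariate Wald p-value is below alpha."""
    y = table[outcome].to_numpy()
    kept = []
    for spec in specs:
        X = _binary_design(table, [spec])
        result = fit_logistic(X, y)
        if result.pvalues[spec.name] < alpha:
            kept.append(spec)
    return kept


def backward_eliminate(
    table: pd.DataFrame,
    specs: Sequence[PredictorSpec],
    alpha: float = 0.05,
    outcome: str = "died30",
    trace: Optional[list] = None,
) -> RegressionResult:
    """Joint fit with stepwise removal of the least significant predictor.

    Refits after each removal; stops when every remaining Wald p < alpha.
    Raises when no predictor survives.
    """
    remaining = list(specs)
    if not remaining:
        raise ValueError("no predictor survives elimination")
    y = table[outcome].to_numpy()
    while True:
        X = _binary_design(table, remaining)
        result = fit_logistic(X, y)
        worst = max(result.names, key=lambda n: result.pvalues[n])
        if result.pvalues[worst] < alpha:
            return result
        if trace is not None:
            trace.append({"removed": worst, "p": result.pvalues[worst]})
        remaining = [s for s in remaining if s.name != worst]
        if not remaining:
            raise ValueError("no predictor survives elimination")


def round_weights(result: RegressionResult) -> dict[str, int]:
    """Round each multivariate odds ratio half-up to its integer weight.

    Predictors whose OR rounds to zero carry no score information and are
    dropped with a warning.
    """
    weights: dict[str, int] = {}
    for name, odds in result.odds_ratios.items():
        if odds <= 0:
            raise ValueError(f"non-positive odds ratio for {name!r}")
        w = math.floor(odds + 0.5)  # round half up
        if w == 0:
            logger.warning("predictor %r rounds to weight 0 and is dropped", name)
            continue
        weights[name] = w
    return weights


def calibrate_thresholds(
    scores: Sequence[int],
    died30: Sequence[int],
    bands: Optional[CalibrationBands] = None,
) -> ThresholdCalibration:
    """Exhaustive search for the score thresholds matching the mortality bands.

    Enumerates every strictly increasing integer triple within the observed
    score range and keeps the triple placing the most categories inside
    their band (observed mortality within the band interval); ties are
    broken by the smallest total absolute deviation from the band reference
    points, with an empty category contributing a fixed 100-point penalty.
    Row order cannot matter: only the score->(n, deaths) table enters.
    """
    bands = bands or CalibrationBands()
    s = np.asarray(scores, dtype=int)
    d = np.asarray(died30, dtype=int)
    if s.size != d.size or s.size == 0:
        raise ValueError("scores and died30 must be equal-length and non-empty")
    if d.sum() == 0 or d.sum() == d.size:
        raise ValueError("need at least one death and one survivor")
    levels = np.unique(s)
    if levels.size < 4:
        raise ValueError("need at least 4 distinct score values to calibrate")

    # per-score-level counts; cumulative from the top make category sums O(1)
    max_s = int(levels.max())
    n_by = np.bincount(s, minlength=max_s + 1)
    dth_by = np.bincount(s, weights=d, minlength=max_s + 1)

    def category_stats(t: tuple[int, int, int]):
        cuts = [0, t[0], t[1], t[2], max_s + 1]
        ns, ds = [], []
        for i in range(4):
            sl = slice(cuts[i], cuts[i + 1])
            ns.append(int(n_by[sl].sum()))
            ds.append(float(dth_by[sl].sum()))
        return ns, ds

    best = None
    lo, hi = max(1, int(levels.min()) + 1), max_s
    for t in itertools.combinations(range(lo, hi + 1), 3):
        ns, ds = category_stats(t)
        mort = [100.0 * ds[i] / ns[i] if ns[i] else math.nan for i in range(4)]
        n_in = sum(
            1 for i in range(4) if ns[i] and bands.in_band(i, mort[i])
        )
        dev = sum(
            abs(mort[i] - bands.references[i]) if ns[i] else 100.0 for i in range(4)
        )
        key = (-n_in, dev, t)
        if best is None or key < best[0]:
            best = (key, t, mort, ns, n_in)
    if best is None:
        raise ValueError("no admissible threshold triple in the score range")
    _, t, mort, ns, n_in = best
    return ThresholdCalibration(
        thresholds=tuple(int(x) for x in t),
        mortality_pct=tuple(mort),
        n_in_band=n_in,
        counts=tuple(ns),
    )


class TriageScoreDeriver:
    """End-to-end chart derivation as an sklearn-style estimator.

    fit(X, y) runs the full pipeline (percentile cutoffs, univariate
    screen, backward elimination, weight rounding, threshold calibration)
    on a vitals DataFrame ``X`` and a 0/1 30-day-death vector ``y``.
    Afterwards ``transform`` yields integer scores and ``predict`` category
    names under the derived chart.

    Parameters
    ----------
    fraction : float, default 0.10
        Abnormal-tail fraction for the percentile cutoffs.
    alpha : float, default 0.05
        Two-sided Wald significance level for screening and elimination.
    bands : CalibrationBands, optional
        Target mortality bands for threshold calibration.
    specs : list of PredictorSpec, optional
        Candidate predictors; defaults to the five CTA vitals.

    Attributes
    ----------
    cutoffs_ : dict mapping predictor name to dichotomization cutoff
    univariate_ : dict mapping predictor name to univariate OR and p
    model_ : RegressionResult of the final multivariate fit
    weights_ : dict mapping retained predictor to integer weight
    calibration_ : ThresholdCalibration
    chart_ : ScoreChart — the deployable result
    report_ : dict — JSON-serializable derivation report
    """

    def __init__(
        self,
        fraction: float = 0.10,
        alpha: float = 0.05,
        bands: Optional[CalibrationBands] = None,
        specs: Optional[list[PredictorSpec]] = None,
    ):
        self.fraction = fraction
        self.alpha = alpha
        self.bands = bands
        self.specs = specs

    def get_params(self, deep: bool = True) -> dict:
        return {
            "fraction": self.fraction,
            "alpha": self.alpha,
            "bands": self.bands,
            "specs": self.specs,
        }

    def set_params(self, **params) -> "TriageScoreDeriver":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "TriageScoreDeriver":
        table = X.copy()
        y = np.asarray(y, dtype=int)
        if len(table) != len(y):
            raise ValueError("X and y length mismatch")
        if len(table) < 1:
            raise ValueError("empty cohort")
        table = table.assign(died30=y)

        specs = [
            PredictorSpec(s.name, s.field, s.direction, s.cutoff)
            for s in (self.specs or default_predictor_specs())
        ]
        for spec in specs:
            if spec.direction != "flag" and spec.cutoff is None:
                spec.cutoff = percentile_cutoff(
                    table[spec.field], spec.direction, self.fraction
                )
        self.cutoffs_ = {s.name: s.cutoff for s in specs}

        y_arr = table["died30"].to_numpy()
        self.univariate_ = {}
        for spec in specs:
            res = fit_logistic(_binary_design(table, [spec]), y_arr)
            self.univariate_[spec.name] = {
                "or": res.odds_ratios[spec.name],
                "p": res.pvalues[spec.name],
            }
        kept = univariate_screen(table, specs, self.alpha)
        trace: list = []
        self.model_ = backward_eliminate(table, kept, self.alpha, trace=trace)
        self.elimination_trace_ = trace
        self.weights_ = round_weights(self.model_)
        surviving = [s for s in specs if s.name in self.weights_]

        predictors = tuple(
            Predictor(
                name=s.name,
                field=s.field,
                direction=s.direction,
                weight=self.weights_[s.name],
                cutoff=s.cutoff,
            )
            for s in surviving
        )
        scores = sum(
            self.weights_[s.name] * s.flags(table) for s in surviving
        )
        self.calibration_ = calibrate_thresholds(scores, y_arr, self.bands)
        self.chart_ = ScoreChart(
            predictors=predictors,
            thresholds=self.calibration_.thresholds,
            meta={"derived_from_n": int(len(table))},
        )
        self.report_ = {
            "cutoffs": self.cutoffs_,
            "univariate": self.univariate_,
            "elimination_trace": trace,
            "final_model": {
                "odds_ratios": self.model_.odds_ratios,
                "coefficients": self.model_.coef,
                "se": self.model_.se,
                "p": self.model_.pvalues,
                "intercept": self.model_.intercept,
            },
            "weights": self.weights_,
            "thresholds": list(self.calibration_.thresholds),
            "category_mortality_pct": [
                None if math.isnan(m) else m for m in self.calibration_.mortality_pct
            ],
        }
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return ChartScorer(self.chart_).fit(X).transform(X)

    def predict(self, X: pd.DataFrame) -> list[str]:
        self._check_fitted()
        return ChartScorer(self.chart_).fit(X).predict(X)

    def _check_fitted(self) -> None:
        if not hasattr(self, "chart_"):
            raise RuntimeError("TriageScoreDeriver is not fitted; call fit first")


def derive_chart(
    table: pd.DataFrame,
    specs: Optional[list[PredictorSpec]] = None,
    fraction: float = 0.10,
    alpha: float = 0.05,
    bands: Optional[CalibrationBands] = None,
) -> ScoreChart:
    """Run the full derivation pipeline on a cohort table; returns the chart.

    Thin functional wrapper over `TriageScoreDeriver`.
    """
    deriver = TriageScoreDeriver(fraction=fraction, alpha=alpha, bands=bands, specs=specs)
    deriver.fit(table[list(VITAL_COLUMNS)], table["died30"])
    return deriver.chart_
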