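"""Score-derivation pipeline: cutoffs, logistic fits, elimination,
rounding and threshold calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cphtriage.cohort import GeneratorConfig, generate_cohort
from cphtriage.derivation import (
    CalibrationBands,
    PredictorSpec,
    TriageScoreDeriver,
    VITAL_COLUMNS,
    backward_eliminate,
    calibrate_thresholds,
    default_predictor_specs,
    derive_chart,
    fit_logistic,
    percentile_cutoff,
    round_weights,
    univariate_screen,
)


class TestPercentileCutoff:
    def test_uniform_grid_above(self):
        values = list(range(1, 101))
        cut = percentile_cutoff(values, "above", 0.10)
        assert cut == 90
        assert sum(v > cut for v in values) == 10

    def test_uniform_grid_below(self):
        values = list(range(1, 101))
        cut = percentile_cutoff(values, "below", 0.10)
        assert cut == 10
        assert sum(v < cut for v in values) == 9

    def test_degenerate_ties(self):
        values = [5.0] * 50
        cut = percentile_cutoff(values, "above", 0.10)
        assert cut == 5.0 and sum(v > cut for v in values) == 0

    def test_realized_fraction_never_exceeds_target(self, rng):
        values = rng.normal(size=1001)
        for direction in ("above", "below"):
            cut = percentile_cutoff(values, direction, 0.10)
            frac = np.mean(values > cut if direction == "above" else values < cut)
            assert frac <= 0.10 + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError):
            percentile_cutoff([], "above")
        with pytest.raises(ValueError):
            percentile_cutoff([1.0], "sideways")


def _loglik(beta0, beta1, x, y):
    lp = beta0 + beta1 * x
    return np.sum(y * lp - np.log1p(np.exp(lp)))


class TestFitLogistic:
    def test_saturated_2x2_equals_cross_product_ratio(self):
        # cells: (x=1,y=1)=12, (x=1,y=0)=30, (x=0,y=1)=9, (x=0,y=0)=60
        x = np.repeat([1, 1, 0, 0], [12, 30, 9, 60])
        y = np.repeat([1, 0, 1, 0], [12, 30, 9, 60])
        res = fit_logistic(pd.DataFrame({"f": x}), y)
        assert res.odds_ratios["f"] == pytest.approx((12 * 60) / (30 * 9), rel=1e-6)
        assert res.coef["f"] == pytest.approx(math.log(res.odds_ratios["f"]), abs=1e-9)

    def test_agrees_with_likelihood_grid_search(self):
        """Independent oracle: brute-force grid over (intercept, slope)."""
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, size=40)
        y = ((0.4 * x + rng.random(40)) > 0.7).astype(int)
        res = fit_logistic(pd.DataFrame({"f": x}), y)

        def grid_argmax(b0s, b1s):
            lp = b0s[:, None, None] + b1s[None, :, None] * x[None, None, :]
            ll = np.sum(y * lp - np.log1p(np.exp(lp)), axis=-1)
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            return b0s[i], b1s[j]

        b0, b1 = grid_argmax(np.linspace(-5, 5, 501), np.linspace(-5, 5, 501))
        b0, b1 = grid_argmax(np.linspace(b0 - 0.05, b0 + 0.05, 401),
                             np.linspace(b1 - 0.05, b1 + 0.05, 401))
        assert res.intercept == pytest.approx(b0, abs=1e-3)
        assert res.coef["f"] == pytest.approx(b1, abs=1e-3)

    def test_perfect_separation_names_predictor(self):
        x = np.array([0] * 10 + [1] * 10)
        y = x.copy()
        with pytest.raises(ValueError, match="f"):
            fit_logistic(pd.DataFrame({"f": x}), y)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"f": [0, 1, 0, 1]}), [0, 0, 0, 0])

    def test_null_pvalues_roughly_uniform(self, rng):
        """Type-I error of the Wald test near 5% under the null."""
        hits = 0
        n, reps = 400, 1000
        for _ in range(reps):
            x = rng.integers(0, 2, size=n)
            y = (rng.random(n) < 0.3).astype(int)
            try:
                res = fit_logistic(pd.DataFrame({"f": x}), y)
            except ValueError:
                continue
            hits += res.pvalues["f"] < 0.05
        assert abs(hits / reps - 0.05) < 0.02


class TestScreenAndEliminate:
    def test_empty_spec_list_screens_to_empty(self, small_cohort):
        assert univariate_screen(small_cohort, []) == []

    def test_strong_predictor_retained(self, small_cohort):
        specs = [PredictorSpec("oxygen_treatment", "oxygen_treatment", "flag")]
        assert len(univariate_screen(small_cohort, specs)) == 1

    def test_noise_predictor_eliminated(self, large_cohort, rng):
        table = large_cohort.head(50_000).copy()
        table["noise"] = rng.integers(0, 2, size=len(table)).astype(bool)
        specs = default_predictor_specs() + [PredictorSpec("noise", "noise", "flag")]
        for s in specs:
            if s.direction != "flag":
                s.cutoff = percentile_cutoff(table[s.field], s.direction)
        trace = []
        res = backward_eliminate(table, specs, trace=trace)
        assert "noise" not in res.names
        assert all(p < 0.05 for p in res.pvalues.values())

    def test_single_predictor_identical_to_univariate(self, small_cohort):
        specs = [PredictorSpec("oxygen_treatment", "oxygen_treatment", "flag")]
        uni = fit_logistic(
            pd.DataFrame({"oxygen_treatment": small_cohort.oxygen_treatment.astype(int)}),
            small_cohort.died30.astype(int))
        elim = backward_eliminate(small_cohort, specs)
        assert elim.coef == uni.coef

    def test_all_eliminated_raises(self, rng):
        n = 5000
        table = pd.DataFrame({
            "noise": rng.integers(0, 2, size=n).astype(bool),
            "died30": (rng.random(n) < 0.05).astype(int),
        })
        with pytest.raises(ValueError, match="no predictor survives"):
            backward_eliminate(table, [PredictorSpec("noise", "noise", "flag")])


class TestRoundWeights:
    @pytest.mark.parametrize("odds, weight", [
        (4.27, 4), (3.28, 3), (2.14, 2), (2.71, 3), (1.67, 2), (2.5, 3),
    ])
    def test_half_up_rounding(self, odds, weight):
        from cphtriage.derivation import RegressionResult
        res = RegressionResult(names=("f",), coef={"f": math.log(odds)},
                               se={"f": 0.1}, pvalues={"f": 0.001}, intercept=-3.0)
        assert round_weights(res) == {"f": weight}

    def test_zero_weight_dropped(self, caplog):
        from cphtriage.derivation import RegressionResult
        res = RegressionResult(names=("f",), coef={"f": math.log(0.4)},
                               se={"f": 0.1}, pvalues={"f": 0.001}, intercept=-3.0)
        assert round_weights(res) == {}

    def test_idempotent_on_integers(self):
        from cphtriage.derivation import RegressionResult
        for k in (1, 2, 3, 7):
            res = RegressionResult(names=("f",), coef={"f": math.log(k)},
                                   se={"f": 0.1}, pvalues={"f": 0.001},
                                   intercept=-3.0)
            assert round_weights(res) == {"f": k}


def _brute_force_thresholds(scores, deaths, bands):
    """Independent enumeration oracle for the calibration search."""
    scores = np.asarray(scores)
    deaths = np.asarray(deaths)
    max_s = scores.max()
    best = None
    for t in itertools.combinations(range(scores.min() + 1, max_s + 1), 3):
        edges = [-1, t[0] - 1, t[1] - 1, t[2] - 1, max_s]
        n_in, dev = 0, 0.0
        for i in range(4):
            mask = (scores > edges[i]) & (scores <= edges[i + 1])
            if mask.sum() == 0:
                dev += 100.0
                continue
            m = 100.0 * deaths[mask].mean()
            if bands.in_band(i, m):
                n_in += 1
            dev += abs(m - bands.references[i])
        key = (-n_in, dev, t)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


class TestCalibrateThresholds:
    def _table(self):
        # 6 score levels with mortality rising through every band edge
        scores, deaths = [], []
        for level, (n, rate) in enumerate(
            [(4000, 0.01), (2000, 0.04), (1000, 0.06), (500, 0.10),
             (300, 0.20), (200, 0.40)]
        ):
            scores += [level] * n
            d = int(round(n * rate))
            deaths += [1] * d + [0] * (n - d)
        return np.array(scores), np.array(deaths)

    def test_matches_brute_force_oracle(self):
        scores, deaths = self._table()
        bands = CalibrationBands()
        cal = calibrate_thresholds(scores, deaths, bands)
        assert cal.thresholds == _brute_force_thresholds(scores, deaths, bands)
        assert cal.n_in_band == 4

    def test_permutation_invariant(self, rng):
        scores, deaths = self._table()
        perm = rng.permutation(len(scores))
        cal1 = calibrate_thresholds(scores, deaths)
        cal2 = calibrate_thresholds(scores[perm], deaths[perm])
        assert cal1.thresholds == cal2.thresholds
        assert cal1.thresholds[0] < cal1.thresholds[1] < cal1.thresholds[2]

    def test_all_low_mortality_degenerate(self):
        rng = np.random.default_rng(2)
        scores = rng.integers(0, 6, size=20_000)
        deaths = (rng.random(20_000) < 0.01).astype(int)
        cal = calibrate_thresholds(scores, deaths)
        assert cal.thresholds[0] >= 1  # still a valid, deterministic triple

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([0, 1, 1, 0] * 10, [0, 1, 0, 1] * 10)


class TestDeriveChart:
    def test_recovers_published_weights(self, large_cohort):
        chart = derive_chart(large_cohort)
        weights = {p.name: p.weight for p in chart.predictors}
        assert weights == {"oxygen_treatment": 4, "sbp_low": 3, "hr_high": 2,
                           "rr_high": 3, "spo2_low": 2}

    def test_cutoffs_near_configured_tails(self, large_cohort):
        deriver = TriageScoreDeriver().fit(
            large_cohort[list(VITAL_COLUMNS)], large_cohort.died30.astype(int))
        assert deriver.cutoffs_["sbp_low"] == pytest.approx(100, abs=1.5)
        assert deriver.cutoffs_["hr_high"] == pytest.approx(110, abs=1.5)
        assert deriver.cutoffs_["rr_high"] == pytest.approx(22, abs=0.5)
        assert deriver.cutoffs_["spo2_low"] == pytest.approx(94, abs=0.5)

    def test_shuffled_outcome_kills_the_chart(self, small_cohort, rng):
        table = small_cohort.copy()
        table["died30"] = rng.permutation(table["died30"].to_numpy())
        with pytest.raises(ValueError, match="no predictor survives"):
            derive_chart(table)

    def test_deriver_transform_predict(self, large_cohort):
        deriver = TriageScoreDeriver().fit(
            large_cohort[list(VITAL_COLUMNS)], large_cohort.died30.astype(int))
        sub = large_cohort.head(100)
        scores = deriver.transform(sub)
        assert scores.min() >= 0 and scores.max() <= deriver.chart_.max_score
        assert set(deriver.predict(sub)) <= {"green", "yellow", "orange", "red"}

    def test_report_is_json_serializable(self, large_cohort):
        import json
        deriver = TriageScoreDeriver().fit(
            large_cohort[list(VITAL_COLUMNS)], large_cohort.died30.astype(int))
        json.dumps(deriver.report_)
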