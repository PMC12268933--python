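"""Per-timepoint and per-animal decision rules, checked against an
independently coded literal transcription of the rules."""

import math

import numpy as np
import pytest
from scipy import stats

from tumorclass.classify import (classify_animal, classify_timepoint,
                                 growth_rate_test, summarize_cohort)
from tumorclass.control import ControlBand
from tumorclass.growth import GrowthCurve, ResponseCall

from conftest import make_curve


def flat_band(lower=1.0, upper=2.0, days=(7, 10, 12, 14, 17)):
    mid = (lower + upper) / 2
    return ControlBand(day_grid=tuple(float(d) for d in days),
                       mean_log=(mid,) * len(days),
                       lower_log=(lower,) * len(days),
                       upper_log=(upper,) * len(days))


def curve_from_logs(animal_id, days, logs):
    return make_curve(animal_id, days, [10.0 ** v for v in logs])


class TestTimepoint:
    band = flat_band(lower=1.0, upper=2.0)

    def test_strictly_below_lower_is_responder(self):
        assert classify_timepoint(10, 0.99, self.band).is_responder_point

    def test_mean_is_non_responder(self):
        assert not classify_timepoint(10, 1.5, self.band).is_responder_point

    def test_exactly_on_lower_bound_is_non_responder(self):
        # boundary convention: the rule is strict inequality
        assert not classify_timepoint(10, 1.0, self.band).is_responder_point

    def test_above_band_is_non_responder(self):
        assert not classify_timepoint(10, 2.5, self.band).is_responder_point

    def test_interpolated_day(self):
        band = ControlBand(day_grid=(10.0, 12.0), mean_log=(1.5, 2.5),
                           lower_log=(1.0, 2.0), upper_log=(2.0, 3.0))
        assert classify_timepoint(11, 1.49, band).is_responder_point
        assert not classify_timepoint(11, 1.5, band).is_responder_point

    def test_day_before_band_errors(self):
        with pytest.raises(ValueError, match="precedes"):
            classify_timepoint(3, 1.5, self.band)


class TestGrowthRate:
    def test_matches_closed_form_ols(self):
        days = np.array([10, 12, 14, 17.0])
        logs = np.array([2.0, 1.8, 1.5, 1.1])
        slope, p = growth_rate_test(days, logs)
        x = days - days.mean()
        expected_slope = float((x * (logs - logs.mean())).sum() / (x * x).sum())
        assert slope == pytest.approx(expected_slope, rel=1e-12)
        assert p == pytest.approx(stats.linregress(days, logs).pvalue)

    def test_perfect_line_has_vanishing_p(self):
        days = [10, 12, 14, 17]
        slope, p = growth_rate_test(days, [2.0 - 0.1 * d for d in days])
        assert slope == pytest.approx(-0.1)
        assert p < 1e-12

    def test_flat_series_p_is_one(self):
        slope, p = growth_rate_test([10, 12, 14], [1.5, 1.5, 1.5])
        assert slope == 0.0 and p == 1.0


class TestClassifyAnimal:
    band = flat_band(lower=1.0, upper=2.0)

    def test_regressing_hand_case(self):
        # responder points at 10, 13, 17 (final); steep clean negative slope
        days = [10, 13, 15, 17]
        logs = [0.9 - 0.10 * (d - 10) + e
                for d, e in zip(days, [0.0, 0.001, -0.001, 0.0])]
        call = classify_animal(curve_from_logs("m", days, logs), self.band)
        assert call.label == "regressing"
        assert call.growth_rate < 0 and call.p_value < 0.05
        assert call.n_responder_points_from_day10 == 4

    def test_final_point_inside_band_is_non_responsive(self):
        # two responder points but the final day-17 point is inside the band
        call = classify_animal(
            curve_from_logs("m", [10, 13, 17], [0.8, 0.9, 1.5]), self.band)
        assert call.label == "non-responsive"
        assert call.n_responder_points_from_day10 == 2
        assert not call.final_point_is_responder

    def test_two_measurements_from_day10_unclassifiable(self):
        call = classify_animal(
            curve_from_logs("m", [7, 10, 13], [1.2, 0.8, 0.7]), self.band)
        assert not call.classifiable
        assert call.label == "unclassifiable"
        assert call.n_points_from_day10 == 2
        assert math.isnan(call.growth_rate)

    def test_flat_plateau_below_band_is_exhausted(self):
        call = classify_animal(
            curve_from_logs("m", [10, 12, 14, 17], [0.8] * 4), self.band)
        assert call.label == "exhausted"
        assert call.p_value == 1.0

    def test_single_responder_point_is_non_responsive(self):
        call = classify_animal(
            curve_from_logs("m", [10, 13, 17], [1.5, 1.4, 0.9]), self.band)
        assert call.label == "non-responsive"
        assert call.n_responder_points_from_day10 == 1

    def test_final_counts_within_the_two(self):
        # exactly two responder points, one of them the final measurement
        call = classify_animal(
            curve_from_logs("m", [10, 13, 17], [0.9, 1.5, 0.8]), self.band)
        assert call.label in ("regressing", "exhausted")

    def test_pre_threshold_points_ignored(self):
        # below-band excursions before day 10 must not count
        call = classify_animal(
            curve_from_logs("m", [7, 8, 10, 13, 17],
                            [0.5, 0.5, 1.5, 1.6, 1.7]), self.band)
        assert call.label == "non-responsive"
        assert call.n_points_from_day10 == 3
        assert call.n_responder_points_from_day10 == 0

    def test_monotonicity_lowering_points_moves_toward_responder(self):
        days = [10, 12, 14, 17]
        base = classify_animal(
            curve_from_logs("m", days, [1.5, 1.6, 1.7, 1.8]), self.band)
        assert base.label == "non-responsive"
        lowered = classify_animal(
            curve_from_logs("m", days, [0.5, 0.6, 0.7, 0.8]), self.band)
        assert lowered.label in ("regressing", "exhausted")


# --- literal transcription of the published decision rules (oracle) -------

def literal_rules_oracle(curve, band, day_threshold=10, alpha=0.05):
    """Independent plain transcription of the classification rules."""
    pts = [(d, la) for d, la in zip(curve.days, curve.log_areas)
           if d >= day_threshold]
    if len(pts) < 3:  # "A minimum of 3 measurements from day 10"
        return "unclassifiable"
    grid = np.asarray(band.day_grid)
    lower = np.asarray(band.lower_log)
    flags = [la < float(np.interp(d, grid, lower)) for d, la in pts]
    # "at least two data points from day 10 ... outside the control range
    # ... including the final measurement"
    responder = sum(flags) >= 2 and flags[-1]
    if not responder:
        return "non-responsive"
    days = np.array([d for d, _ in pts], dtype=float)
    logs = np.array([la for _, la in pts], dtype=float)
    xc = days - days.mean()
    slope = float((xc * (logs - logs.mean())).sum() / (xc * xc).sum())
    resid = logs - (logs.mean() + slope * xc)
    dof = len(pts) - 2
    s2 = float((resid ** 2).sum()) / dof
    if s2 == 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        se = math.sqrt(s2 / float((xc * xc).sum()))
        p = 2 * stats.t.sf(abs(slope / se), dof)
    # "negative growth rate ... p value <0.05 ... 'regressing' ...
    # the rest as 'exhausted'"
    return "regressing" if (slope < 0 and p < alpha) else "exhausted"


def random_curves(n, band, rng):
    """Curves spanning all rule branches, including unclassifiable ones."""
    curves = []
    for i in range(n):
        kind = rng.integers(0, 5)
        if kind == 0:  # too few points after day 10
            days = [7, 10, 13][: int(rng.integers(1, 3)) + 1]
        else:
            days = sorted(rng.choice([7, 10, 11, 12, 13, 14, 15, 16, 17],
                                     size=int(rng.integers(3, 7)),
                                     replace=False))
        logs = rng.uniform(0.2, 2.8, size=len(days))
        if kind == 2:  # clearly regressing shape
            logs = np.clip(2.0 - 0.15 * (np.asarray(days) - 7)
                           + rng.normal(0, 0.02, len(days)), 0.0, None)
        elif kind == 3:  # plateau below the band
            logs = np.full(len(days), 0.7) + rng.normal(0, 0.02, len(days))
        curves.append(curve_from_logs(f"r{i}", days, logs))
    return curves


def test_rule_oracle_agreement_on_1000_random_curves():
    band = flat_band(lower=1.0, upper=2.0)
    rng = np.random.default_rng(2024)
    for curve in random_curves(1000, band, rng):
        got = classify_animal(curve, band).label
        want = literal_rules_oracle(curve, band)
        assert got == want, f"{curve.animal_id}: {got} != {want}"


class TestSummarize:
    def _call(self, i, label):
        classifiable = label != "unclassifiable"
        return ResponseCall(f"m{i}", classifiable, label, 3 if classifiable else 1,
                            2, True, -0.1, 0.01) if label == "regressing" else \
            ResponseCall(f"m{i}", classifiable, label, 3 if classifiable else 1,
                         2 if classifiable else 0, classifiable,
                         0.0 if classifiable else float("nan"),
                         1.0 if classifiable else float("nan"))

    def test_proportions_hand_case(self):
        calls = [self._call(0, "regressing"), self._call(1, "regressing"),
                 self._call(2, "exhausted"), self._call(3, "non-responsive")]
        s = summarize_cohort(calls)
        assert s.proportions == {"regressing": 0.5, "exhausted": 0.25,
                                 "non-responsive": 0.25}
        assert sum(s.proportions.values()) == pytest.approx(1.0)

    def test_all_one_class(self):
        s = summarize_cohort([self._call(i, "exhausted") for i in range(3)])
        assert s.proportions["exhausted"] == 1.0
        assert s.proportions["regressing"] == 0.0

    def test_unclassifiable_counted_separately(self):
        calls = [self._call(0, "regressing"), self._call(1, "unclassifiable")]
        s = summarize_cohort(calls)
        assert s.n_unclassifiable == 1
        assert s.proportions["regressing"] == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no calls"):
            summarize_cohort([])
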