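"""Per-timepoint and per-animal response rules.

A measurement is a "responder point" when its log10 area falls strictly
below the control band's lower bound on that day. An animal with at least
three measurements from day 10 is a responder when at least two of those
measurements are responder points and the final measurement is itself a
responder point; otherwise it is non-responsive. Responders subdivide by
the post-day-10 growth rate (OLS slope of log10 area on day): a
significantly negative slope (two-sided t-test, p < 0.05) means the tumor
is regressing, the rest — tumors that shrank below control growth but then
stalled or regrew — are called exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .control import ControlBand
from .growth import GrowthCurve, ResponseCall

__all__ = [
    "TimepointCall",
    "classify_timepoint",
    "growth_rate_test",
    "classify_animal",
    "summarize_cohort",
    "CohortSummary",
]


@dataclass(frozen=True)
class TimepointCall:
    """One measurement judged against the control band."""

    day: float
    log_area: float
    is_responder_point: bool


def classify_timepoint(day: float, log_area: float,
                       band: ControlBand) -> TimepointCall:
    """Judge one (day, log10 area) point against the control band.

    A point is a responder point iff it lies strictly below the band's
    lower bound at that day; a point exactly on the bound, inside the
    band, or above it is a non-responder point (response means a smaller
    tumor than control growth, so high excursions do not count).
    """
    lower = band.lower_at(day)
    return TimepointCall(day=day, log_area=log_area,
                         is_responder_point=log_area < lower)


def growth_rate_test(days: Sequence[float],
                     log_areas: Sequence[float]) -> tuple[float, float]:
    """OLS slope of log10 area on day and its two-sided t-test p-value.

    The t statistic uses n − 2 degrees of freedom. A perfectly flat series
    (zero slope, zero residual) has no evidence against slope = 0 and gets
    p = 1; a non-zero slope with zero residual variance gets p = 0.
    """
    days = np.asarray(days, dtype=float)
    logs = np.asarray(log_areas, dtype=float)
    if days.size < 3:
        raise ValueError("slope test needs >= 3 points")
    res = stats.linregress(days, logs)
    slope = float(res.slope)
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0 if slope == 0.0 else 0.0
    return slope, p


def classify_animal(
    curve: GrowthCurve,
    band: ControlBand,
    day_threshold: float = 10,
    alpha: float = 0.05,
) -> ResponseCall:
    """Apply the full decision rule to one animal.

    Rules, in order:

    1. fewer than 3 measurements on/after ``day_threshold`` → unclassifiable;
    2. responder ⇔ ≥ 2 responder points among days ≥ ``day_threshold`` AND
       the final measurement is a responder point (it may be one of the two);
    3. non-responder → "non-responsive";
    4. responder → "regressing" if the post-threshold slope is negative with
       p < ``alpha``, else "exhausted".
    """
    sub = curve.points_from(day_threshold)
    n_from = 0 if sub is None else sub.n_points
    if sub is None or n_from < 3:
        return ResponseCall(
            animal_id=curve.animal_id,
            classifiable=False,
            label="unclassifiable",
            n_points_from_day10=n_from,
            n_responder_points_from_day10=0,
            final_point_is_responder=False,
            growth_rate=float("nan"),
            p_value=float("nan"),
        )

    log_areas = sub.log_areas
    flags = [classify_timepoint(d, la, band).is_responder_point
             for d, la in zip(sub.days, log_areas)]
    n_responder = int(sum(flags))
    final_is_responder = bool(flags[-1])
    is_responder = n_responder >= 2 and final_is_responder

    slope, p = growth_rate_test(sub.days, log_areas)

    if not is_responder:
        label = "non-responsive"
    elif slope < 0 and p < alpha:
        label = "regressing"
    else:
        label = "exhausted"

    return ResponseCall(
        animal_id=curve.animal_id,
        classifiable=True,
        label=label,
        n_points_from_day10=n_from,
        n_responder_points_from_day10=n_responder,
        final_point_is_responder=final_is_responder,
        growth_rate=slope,
        p_value=p,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Label counts and proportions over the classifiable animals."""

    counts: dict[str, int]
    proportions: dict[str, float]  # over classifiable animals, sums to 1
    n_classifiable: int
    n_unclassifiable: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"{lbl}: {self.counts.get(lbl, 0)} "
                 f"({100 * self.proportions.get(lbl, 0.0):.1f}%)"
                 for lbl in ("regressing", "exhausted", "non-responsive")]
        parts.append(f"unclassifiable: {self.n_unclassifiable}")
        return "; ".join(parts)


def summarize_cohort(calls: Sequence[ResponseCall]) -> CohortSummary:
    """Count labels; proportions are over classifiable animals only."""
    if not calls:
        raise ValueError("no calls to summarize")
    counts = {lbl: 0 for lbl in ("regressing", "exhausted", "non-responsive")}
    n_unclassifiable = 0
    for call in calls:
        if call.classifiable:
            counts[call.label] += 1
        else:
            n_unclassifiable += 1
    n_classifiable = sum(counts.values())
    if n_classifiable == 0:
        raise ValueError("no classifiable animals")
    proportions = {lbl: c / n_classifiable for lbl, c in counts.items()}
    return CohortSummary(counts=counts, proportions=proportions,
                         n_classifiable=n_classifiable,
                         n_unclassifiable=n_unclassifiable)
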