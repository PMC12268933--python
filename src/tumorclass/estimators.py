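"""scikit-learn style front end for the growth-response pipeline."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .classify import classify_animal, summarize_cohort
from .control import assign_pseudo_control, compute_auc, fit_control_band
from .growth import GrowthCurve, ResponseCall, curves_from_frame

__all__ = ["TumorResponseClassifier"]


def _as_curves(X) -> list[GrowthCurve]:
    if isinstance(X, pd.DataFrame):
        unit = "mm2" if "area_mm2" in X.columns else "cm2"
        area_col = "area_mm2" if unit == "mm2" else "area_cm2"
        curves, _ = curves_from_frame(X, area_col=area_col, area_unit=unit)
        return curves
    curves = list(X)
    if not all(isinstance(c, GrowthCurve) for c in curves):
        raise TypeError(
            "X must be a long-format DataFrame (animal_id, day, "
            "area_cm2/area_mm2) or a sequence of GrowthCurve")
    return curves


class TumorResponseClassifier(BaseEstimator):
    """Three-way tumor growth response classifier with a pseudo-control band.

    ``fit`` ranks the cohort by growth AUC, takes the top quartile as
    pseudo-control, and fits the central-75% control band up to
    ``day_cutoff``. ``predict`` applies the responder rules and returns one
    of ``{"regressing", "exhausted", "non-responsive", "unclassifiable"}``
    per animal. Pseudo-control animals are not excluded from prediction:
    cohort percentages are computed over all classifiable animals.

    Parameters
    ----------
    coverage_target : float, default 0.75
        Central fraction of control observations the band must contain.
    day_cutoff : float, default 17
        Last day modelled by the control band.
    day_threshold : float, default 10
        First day that counts toward the responder rules.
    alpha : float, default 0.05
        Significance level of the post-threshold growth-rate t-test.
    control_quantile : float, default 0.75
        AUC percentile above which animals become pseudo-control.
    epsilon : float, default 0.01
        Minimum band half-width in log10 units.

    Attributes
    ----------
    band_ : ControlBand
        Fitted control band.
    control_ids_, treated_ids_ : list of str
        The pseudo-control split.
    auc_ : dict
        Growth AUC (mm²·day) per animal used for the split.

    Examples
    --------
    >>> from tumorclass.simulate import simulate_cohort
    >>> cohort = simulate_cohort(n=80, seed=0)
    >>> clf = TumorResponseClassifier().fit(cohort.curves)
    >>> labels = clf.predict(cohort.curves)
    """

    def __init__(self, coverage_target: float = 0.75, day_cutoff: float = 17,
                 day_threshold: float = 10, alpha: float = 0.05,
                 control_quantile: float = 0.75, epsilon: float = 0.01):
        self.coverage_target = coverage_target
        self.day_cutoff = day_cutoff
        self.day_threshold = day_threshold
        self.alpha = alpha
        self.control_quantile = control_quantile
        self.epsilon = epsilon

    def fit(self, X, y=None) -> "TumorResponseClassifier":
        """Select pseudo-control animals and fit the control band."""
        curves = _as_curves(X)
        aucs = [compute_auc(c) for c in curves if c.n_points >= 2]
        if len(aucs) < 4:
            raise ValueError(
                "need >= 4 animals with >= 2 measurements to define the "
                "pseudo-control quartile")
        control_ids, treated_ids = assign_pseudo_control(
            aucs, quantile=self.control_quantile)
        control_set = set(control_ids)
        control_curves = [c for c in curves if c.animal_id in control_set]
        band = fit_control_band(
            control_curves, coverage_target=self.coverage_target,
            day_cutoff=self.day_cutoff, epsilon=self.epsilon)
        self.auc_ = {r.animal_id: r.auc for r in aucs}
        self.control_ids_ = control_ids
        self.treated_ids_ = treated_ids
        self.band_ = band
        return self

    def predict_calls(self, X) -> list[ResponseCall]:
        """Full per-animal classification records, in input order."""
        check_is_fitted(self, "band_")
        return [classify_animal(c, self.band_,
                                day_threshold=self.day_threshold,
                                alpha=self.alpha)
                for c in _as_curves(X)]

    def predict(self, X) -> np.ndarray:
        """Labels only, as an object array in input order."""
        return np.array([call.label for call in self.predict_calls(X)],
                        dtype=object)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)

    def summarize(self, X):
        """Cohort label counts/proportions (see ``summarize_cohort``)."""
        return summarize_cohort(self.predict_calls(X))
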