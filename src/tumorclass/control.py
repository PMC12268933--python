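"""Pseudo-control selection and the control growth band.

In an untreated cohort there is no designated control arm, so the fastest
growing quartile of tumors — ranked by area under the growth curve (AUC) —
stands in as the reference ("pseudo-control") population. A two-stage
procedure then summarises control growth on the log10 mm² scale:

stage 1
    a saturating (Gompertz-form) mean curve is fitted to the pooled control
    log10 areas up to a day cutoff, with a quadratic-in-day fallback when
    the non-linear fit does not converge;
stage 2
    lower/upper bounds are the empirical central-coverage quantiles of the
    pooled control residuals added to the mean curve, so the band contains
    the target fraction (default 75%) of control observations.

Tumors falling below the band's lower bound are the "responder" signal used
downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .growth import GrowthCurve

__all__ = [
    "AucRecord",
    "ControlBand",
    "compute_auc",
    "assign_pseudo_control",
    "fit_control_band",
]

#: Minimum band half-width, log10 units, to avoid degenerate zero-width
#: bands on noiseless input.
DEFAULT_EPSILON = 0.01


@dataclass(frozen=True)
class AucRecord:
    """Trapezoid area under one animal's day → area(mm²) curve."""

    animal_id: str
    auc: float  # mm²·day

    def __post_init__(self) -> None:
        if not np.isfinite(self.auc) or self.auc < 0:
            raise ValueError(f"invalid AUC {self.auc!r} for {self.animal_id!r}")


def compute_auc(curve: GrowthCurve) -> AucRecord:
    """Area under the growth curve on the raw mm² scale (trapezoid rule).

    Requires at least two measurements; a single point has no area.
    """
    if curve.n_points < 2:
        raise ValueError(
            f"AUC undefined for {curve.animal_id!r}: needs >= 2 points, "
            f"has {curve.n_points}")
    auc = float(np.trapezoid(np.asarray(curve.areas_mm2, dtype=float),
                             np.asarray(curve.days, dtype=float)))
    return AucRecord(animal_id=curve.animal_id, auc=auc)


def assign_pseudo_control(
    aucs: Iterable[AucRecord],
    *,
    quantile: float = 0.75,
) -> tuple[list[str], list[str]]:
    """Split animals into pseudo-control (top AUC quartile) and treated.

    Animals whose AUC is at or above the ``quantile`` percentile of all
    AUCs (linear-interpolation / type-7 quantile) form the control set —
    roughly the top ``1 - quantile`` fraction of the cohort. Ordering of
    the returned lists is deterministic: descending AUC, then animal id.

    Returns
    -------
    (control_ids, treated_ids)
    """
    records = sorted(aucs, key=lambda r: (-r.auc, r.animal_id))
    if len(records) < 4:
        raise ValueError(
            f"pseudo-control assignment needs >= 4 animals, got {len(records)}")
    values = np.array([r.auc for r in records], dtype=float)
    cut = float(np.quantile(values, quantile, method="linear"))
    control = [r.animal_id for r in records if r.auc >= cut]
    treated = [r.animal_id for r in records if r.auc < cut]
    return control, treated


@dataclass(frozen=True)
class ControlBand:
    """Expected control log10 growth with central-coverage bounds.

    Bounds are defined on ``day_grid``; between grid days the band is
    linearly interpolated, beyond the last grid day it extends flat, and
    before the first grid day it is undefined (no backward extrapolation).
    """

    day_grid: tuple[float, ...]
    mean_log: tuple[float, ...]
    lower_log: tuple[float, ...]
    upper_log: tuple[float, ...]
    coverage_target: float = 0.75
    day_cutoff: float = 17
    fit_diagnostics: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.day_grid, dtype=float)
        lo = np.asarray(self.lower_log, dtype=float)
        mid = np.asarray(self.mean_log, dtype=float)
        hi = np.asarray(self.upper_log, dtype=float)
        if not (len(g) == len(lo) == len(mid) == len(hi)):
            raise ValueError("band arrays must share a length")
        if len(g) == 0:
            raise ValueError("empty band")
        if np.any(np.diff(g) <= 0):
            raise ValueError("band day grid must be strictly increasing")
        if np.any(lo > mid) or np.any(mid > hi):
            raise ValueError("band must satisfy lower <= mean <= upper")
        if not 0 < self.coverage_target < 1:
            raise ValueError(f"coverage_target {self.coverage_target} not in (0,1)")

    def _eval(self, values: Sequence[float], day: float) -> float:
        g = np.asarray(self.day_grid, dtype=float)
        if day < g[0]:
            raise ValueError(
                f"day {day} precedes the first control day {g[0]:g}; "
                "the band does not extrapolate backward")
        # flat beyond the last grid day (and hence beyond day_cutoff)
        return float(np.interp(day, g, np.asarray(values, dtype=float)))

    def mean_at(self, day: float) -> float:
        return self._eval(self.mean_log, day)

    def lower_at(self, day: float) -> float:
        return self._eval(self.lower_log, day)

    def upper_at(self, day: float) -> float:
        return self._eval(self.upper_log, day)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.day_grid,
            "mean_log": self.mean_log,
            "lower_log": self.lower_log,
            "upper_log": self.upper_log,
        })

    def save(self, tsv_path: str | Path) -> None:
        """Write the band grid as TSV plus a JSON sidecar of fit metadata."""
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        meta = {
            "coverage_target": self.coverage_target,
            "day_cutoff": self.day_cutoff,
            "fit_diagnostics": dict(self.fit_diagnostics),
        }
        tsv_path.with_suffix(tsv_path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, default=float))

    @classmethod
    def load(cls, tsv_path: str | Path) -> "ControlBand":
        tsv_path = Path(tsv_path)
        df = pd.read_csv(tsv_path, sep="\t")
        meta_path = tsv_path.with_suffix(tsv_path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            day_grid=tuple(df["day"]),
            mean_log=tuple(df["mean_log"]),
            lower_log=tuple(df["lower_log"]),
            upper_log=tuple(df["upper_log"]),
            coverage_target=meta.get("coverage_target", 0.75),
            day_cutoff=meta.get("day_cutoff", 17),
            fit_diagnostics=meta.get("fit_diagnostics", {}),
        )


def _gompertz_log(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    # log10 area under Gompertz growth: saturates at `a`, depth `b`, rate `c`
    return a - b * np.exp(-c * t)


def _fit_mean_curve(days: np.ndarray, logs: np.ndarray) -> tuple[str, dict, callable]:
    """Stage 1: saturating mean curve, quadratic fallback."""
    a0 = float(logs.max()) + 0.5
    b0 = max(a0 - float(logs.min()), 0.5)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gompertz_log, days, logs, p0=(a0, b0, 0.1),
                bounds=([-np.inf, 0.0, 1e-4], [np.inf, np.inf, 2.0]),
                maxfev=20000)
        if not np.all(np.isfinite(popt)):
            raise RuntimeError("non-finite parameters")
        params = {"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])}
        return "gompertz_log10", params, lambda t: _gompertz_log(np.asarray(t, float), *popt)
    except Exception:
        pass
    try:
        coeffs = np.polyfit(days, logs, deg=min(2, len(np.unique(days)) - 1))
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"control mean-curve fit failed: {exc}") from exc
    poly = np.poly1d(coeffs)
    return ("quadratic_log10", {"coefficients": [float(c) for c in coeffs]},
            lambda t: poly(np.asarray(t, float)))


def fit_control_band(
    control_curves: Sequence[GrowthCurve],
    coverage_target: float = 0.75,
    day_cutoff: float = 17,
    *,
    epsilon: float = DEFAULT_EPSILON,
) -> ControlBand:
    """Fit the two-stage control growth band on pooled control points.

    Parameters
    ----------
    control_curves
        Pseudo-control animals' curves; needs ≥ 3 animals with
        observations at ≥ 3 distinct days ≤ ``day_cutoff``.
    coverage_target
        Central fraction of control observations the band should contain
        (default 0.75, i.e. bounds at the 12.5th/87.5th residual quantiles).
    day_cutoff
        Last day modelled (default 17); the band extends flat beyond it.
    epsilon
        Minimum half-width in log10 units.
    """
    if len(control_curves) < 3:
        raise ValueError(
            f"control band needs >= 3 control animals, got {len(control_curves)}")
    if not 0 < coverage_target < 1:
        raise ValueError(f"coverage_target {coverage_target} not in (0,1)")

    days, logs = [], []
    for curve in control_curves:
        la = curve.log_areas
        for i, d in enumerate(curve.days):
            if d <= day_cutoff:
                days.append(float(d))
                logs.append(float(la[i]))
    order = np.lexsort((logs, days))  # canonical order: fit is invariant
    days_arr = np.array(days)[order]
    logs_arr = np.array(logs)[order]
    distinct = np.unique(days_arr)
    if distinct.size < 3:
        raise ValueError(
            f"control band needs observations at >= 3 distinct days <= "
            f"{day_cutoff:g}, got {distinct.size}")

    model_name, params, mean_fn = _fit_mean_curve(days_arr, logs_arr)

    residuals = logs_arr - mean_fn(days_arr)
    tail = (1.0 - coverage_target) / 2.0
    lo_off, hi_off = np.quantile(residuals, [tail, 1.0 - tail])
    lo_off = min(float(lo_off), -epsilon)
    hi_off = max(float(hi_off), epsilon)

    grid = distinct
    mean = mean_fn(grid)
    lower = mean + lo_off
    upper = mean + hi_off

    lo_grid = np.interp(days_arr, grid, lower)
    hi_grid = np.interp(days_arr, grid, upper)
    inside = (logs_arr >= lo_grid) & (logs_arr <= hi_grid)
    achieved = float(inside.mean())

    diagnostics = {
        "model": model_name,
        "parameters": params,
        "coverage_target": coverage_target,
        "day_cutoff": day_cutoff,
        "achieved_coverage": achieved,
        "n_control_animals": len(control_curves),
        "n_control_points": int(len(days_arr)),
        "residual_offsets": {"lower": lo_off, "upper": hi_off},
    }
    if achieved < coverage_target - 0.05:
        warnings.warn(
            f"control band covers only {achieved:.3f} of control points "
            f"(target {coverage_target})", stacklevel=2)
    return ControlBand(
        day_grid=tuple(float(d) for d in grid),
        mean_log=tuple(float(v) for v in mean),
        lower_log=tuple(float(v) for v in lower),
        upper_log=tuple(float(v) for v in upper),
        coverage_target=coverage_target,
        day_cutoff=day_cutoff,
        fit_diagnostics=diagnostics,
    )
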