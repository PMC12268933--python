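"""Longitudinal tumor measurement containers and delimited-text I/O.

Caliper measurements arrive as tumor area in cm² (length × width). All
downstream modelling works on log10 of the area in mm², so areas are
converted on load (× 100) and undetectable tumors (recorded as 0 cm²) are
floored at 1 mm² so the log transform is always defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "ResponseCall",
    "ParseReport",
    "convert_area",
    "load_measurements",
    "curves_from_frame",
    "write_calls",
    "read_calls",
    "LABELS",
]

#: Closed label vocabulary for per-animal calls.
LABELS = ("regressing", "exhausted", "non-responsive", "unclassifiable")

#: Area assigned to an undetectable tumor, mm².
UNDETECTABLE_FLOOR_MM2 = 1.0


def convert_area(area_cm2: float, *, animal_id: str | None = None,
                 day: object = None) -> float:
    """Convert a tumor area from cm² to mm², flooring undetectable tumors.

    Parameters
    ----------
    area_cm2 : float
        Caliper tumor area (length × width) in cm². Must be finite and
        non-negative.
    animal_id, day : optional
        Context used only to make validation errors actionable.

    Returns
    -------
    float
        ``100 * area_cm2`` for a detectable tumor; ``1.0`` mm² when the
        tumor is undetectable (``area_cm2 == 0``) so that log10 is defined.
    """
    ctx = ""
    if animal_id is not None or day is not None:
        ctx = f" (animal={animal_id!r}, day={day!r})"
    if not math.isfinite(area_cm2):
        raise ValueError(f"non-finite tumor area {area_cm2!r}{ctx}")
    if area_cm2 < 0:
        raise ValueError(f"negative tumor area {area_cm2!r}{ctx}")
    if area_cm2 == 0:
        return UNDETECTABLE_FLOOR_MM2
    return 100.0 * area_cm2


@dataclass(frozen=True)
class GrowthCurve:
    """One animal's tumor-area series, ordered by day.

    ``days`` are strictly increasing; ``areas_mm2`` are ≥ 1 mm² (the
    undetectable floor), so ``log_areas`` is always ≥ 0.
    """

    animal_id: str
    days: tuple[float, ...]
    areas_mm2: tuple[float, ...]
    group: str | None = None
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise ValueError(f"curve for {self.animal_id!r} has no points")
        if len(self.days) != len(self.areas_mm2):
            raise ValueError(
                f"curve for {self.animal_id!r}: {len(self.days)} days vs "
                f"{len(self.areas_mm2)} areas")
        d = np.asarray(self.days, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError(
                f"curve for {self.animal_id!r}: days must be strictly "
                f"increasing, got {list(self.days)}")
        if d[0] < 0:
            raise ValueError(f"curve for {self.animal_id!r}: negative day")
        a = np.asarray(self.areas_mm2, dtype=float)
        if not np.all(np.isfinite(a)) or np.any(a < UNDETECTABLE_FLOOR_MM2):
            raise ValueError(
                f"curve for {self.animal_id!r}: areas must be finite and "
                f">= {UNDETECTABLE_FLOOR_MM2} mm2")

    @property
    def log_areas(self) -> np.ndarray:
        """log10 of the areas in mm² (non-negative by the floor rule)."""
        return np.log10(np.asarray(self.areas_mm2, dtype=float))

    @property
    def n_points(self) -> int:
        return len(self.days)

    @property
    def final_day(self) -> float:
        return self.days[-1]

    def points_from(self, day_threshold: float) -> "GrowthCurve | None":
        """Sub-curve restricted to days ≥ ``day_threshold`` (None if empty)."""
        keep = [i for i, d in enumerate(self.days) if d >= day_threshold]
        if not keep:
            return None
        return GrowthCurve(
            animal_id=self.animal_id,
            days=tuple(self.days[i] for i in keep),
            areas_mm2=tuple(self.areas_mm2[i] for i in keep),
            group=self.group,
            experiment_id=self.experiment_id,
        )


@dataclass(frozen=True)
class ResponseCall:
    """Per-animal classification record."""

    animal_id: str
    classifiable: bool
    label: str
    n_points_from_day10: int
    n_responder_points_from_day10: int
    final_point_is_responder: bool
    growth_rate: float  # log10 mm² per day, NaN when unclassifiable
    p_value: float      # two-sided slope t-test, NaN when unclassifiable

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.classifiable == (self.label == "unclassifiable"):
            raise ValueError(
                f"{self.animal_id!r}: classifiable flag inconsistent with "
                f"label {self.label!r}")


@dataclass
class ParseReport:
    """What the measurement loader saw, for logging."""

    n_animals: int = 0
    n_points: int = 0
    n_floored: int = 0
    n_dropped_missing: int = 0
    non_integer_days: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = (f"{self.n_animals} animals, {self.n_points} points, "
             f"{self.n_floored} undetectable values floored to 1 mm2, "
             f"{self.n_dropped_missing} missing values dropped")
        if self.non_integer_days:
            s += " [non-integer days present]"
        return s


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def load_measurements(
    path: str | Path,
    *,
    sep: str | None = None,
    animal_col: str = "animal_id",
    day_col: str = "day",
    area_col: str = "area_cm2",
    area_unit: str = "cm2",
    group_col: str | None = None,
) -> tuple[list[GrowthCurve], ParseReport]:
    """Read long-format measurements into one :class:`GrowthCurve` per animal.

    Parameters
    ----------
    path
        Comma- or tab-delimited file with a header row.
    sep
        Field separator; sniffed from the header when None.
    area_unit
        ``"cm2"`` (default, converted ×100 with the undetectable floor) or
        ``"mm2"`` for pre-converted input (floored at 1 mm²).

    Returns
    -------
    (curves, report)
        Curves sorted by animal id, points sorted by day, plus a
        :class:`ParseReport`.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={animal_col: str})
    missing_cols = {animal_col, day_col, area_col} - set(df.columns)
    if missing_cols:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing_cols)}")
    return curves_from_frame(
        df, animal_col=animal_col, day_col=day_col, area_col=area_col,
        area_unit=area_unit, group_col=group_col, source=str(path))


def curves_from_frame(
    df: pd.DataFrame,
    *,
    animal_col: str = "animal_id",
    day_col: str = "day",
    area_col: str = "area_cm2",
    area_unit: str = "cm2",
    group_col: str | None = None,
    source: str = "<frame>",
) -> tuple[list[GrowthCurve], ParseReport]:
    """Build curves from an in-memory long-format table (loader core)."""
    if area_unit not in ("cm2", "mm2"):
        raise ValueError(f"area_unit must be 'cm2' or 'mm2', got {area_unit!r}")
    report = ParseReport()

    days = pd.to_numeric(df[day_col], errors="coerce")
    bad_day = days.isna() & df[day_col].notna()
    if bad_day.any():
        line = int(df.index[bad_day][0]) + 2  # header + 1-based
        raise ValueError(
            f"{source}: unparseable day value {df.loc[bad_day, day_col].iloc[0]!r}"
            f" at line {line}")
    areas = pd.to_numeric(df[area_col], errors="coerce")
    bad_area = areas.isna() & df[area_col].notna()
    if bad_area.any():
        line = int(df.index[bad_area][0]) + 2
        raise ValueError(
            f"{source}: unparseable area value "
            f"{df.loc[bad_area, area_col].iloc[0]!r} at line {line}")

    work = pd.DataFrame({
        "animal_id": df[animal_col].astype(str),
        "day": days,
        "area": areas,
    })
    if group_col is not None and group_col in df.columns:
        work["group"] = df[group_col]

    n_missing = int(work["area"].isna().sum() + work["day"].isna().sum())
    if n_missing:
        warnings.warn(
            f"{source}: dropping {n_missing} row(s) with missing day/area",
            stacklevel=2)
        report.n_dropped_missing = n_missing
        work = work.dropna(subset=["day", "area"])

    dup = work.duplicated(subset=["animal_id", "day"], keep=False)
    if dup.any():
        offenders = (work.loc[dup, ["animal_id", "day"]]
                     .drop_duplicates().itertuples(index=False))
        listing = ", ".join(f"({a}, day {d:g})" for a, d in offenders)
        raise ValueError(f"{source}: duplicate (animal, day) rows: {listing}")

    if not np.allclose(work["day"], np.round(work["day"])):
        report.non_integer_days = True
        warnings.warn(f"{source}: non-integer measurement days present",
                      stacklevel=2)

    curves: list[GrowthCurve] = []
    for animal_id, sub in work.groupby("animal_id", sort=True):
        sub = sub.sort_values("day")
        areas_mm2 = []
        for day, raw in zip(sub["day"], sub["area"]):
            if area_unit == "cm2":
                mm2 = convert_area(float(raw), animal_id=animal_id, day=day)
                if raw == 0:
                    report.n_floored += 1
            else:
                if not math.isfinite(raw) or raw < 0:
                    raise ValueError(
                        f"{source}: invalid mm2 area {raw!r} "
                        f"(animal={animal_id!r}, day={day!r})")
                mm2 = max(float(raw), UNDETECTABLE_FLOOR_MM2)
                if raw < UNDETECTABLE_FLOOR_MM2:
                    report.n_floored += 1
            areas_mm2.append(mm2)
        group = sub["group"].iloc[0] if "group" in sub.columns else None
        curves.append(GrowthCurve(
            animal_id=str(animal_id),
            days=tuple(float(d) for d in sub["day"]),
            areas_mm2=tuple(areas_mm2),
            group=group,
        ))
        report.n_points += len(areas_mm2)
    report.n_animals = len(curves)
    return curves, report


_CALL_COLUMNS = [
    "animal_id", "label", "classifiable", "n_points_from_day10",
    "n_responder_points_from_day10", "final_point_is_responder",
    "growth_rate", "p_value",
]


def calls_to_frame(calls: Sequence[ResponseCall]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(call, c) for c in _CALL_COLUMNS}
                         for call in calls], columns=_CALL_COLUMNS)


def write_calls(calls: Sequence[ResponseCall], path: str | Path) -> None:
    """Write per-animal calls as TSV (fixed column order, lossless)."""
    if not calls:
        raise ValueError("no calls to write")
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[ResponseCall]:
    """Read back a calls TSV written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(ResponseCall(
            animal_id=str(row.animal_id),
            classifiable=bool(row.classifiable),
            label=str(row.label),
            n_points_from_day10=int(row.n_points_from_day10),
            n_responder_points_from_day10=int(row.n_responder_points_from_day10),
            final_point_is_responder=bool(row.final_point_is_responder),
            growth_rate=float(row.growth_rate),
            p_value=float(row.p_value),
        ))
    return out
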