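"""Shape descriptors for electron-microscopy quantification.

Circularity is ``4π · area / perimeter²``: 1.0 for a perfect circle and
smaller for elongated or irregular outlines. By the isoperimetric
inequality no simple closed shape exceeds 1, but discretised (pixelated)
perimeter estimates can overshoot slightly; values marginally above 1 are
clipped with a warning.
"""

from __future__ import annotations

import math
import warnings

import pandas as pd

__all__ = ["circularity", "circularity_table"]

#: Tolerance above 1.0 beyond which input is considered geometrically
#: inconsistent (clipped with a warning).
OVERSHOOT_TOL = 1e-6


def circularity(area: float, perimeter: float) -> float:
    """Circularity ``4π · area / perimeter²`` of a closed shape.

    Parameters
    ----------
    area : float
        Enclosed area, any squared length unit; must be ≥ 0.
    perimeter : float
        Outline length in the matching unit; must be > 0.

    Returns
    -------
    float
        Dimensionless circularity in [0, 1]; exactly 1.0 for a circle.
        Values above ``1 + 1e-6`` (possible with discretised perimeter
        estimates) are clipped to 1.0 with a warning.
    """
    if not (math.isfinite(area) and math.isfinite(perimeter)):
        raise ValueError(f"non-finite input: area={area!r}, perimeter={perimeter!r}")
    if perimeter <= 0:
        raise ValueError(f"perimeter must be positive, got {perimeter!r}")
    if area < 0:
        raise ValueError(f"area must be non-negative, got {area!r}")
    value = 4.0 * math.pi * area / (perimeter * perimeter)
    if value > 1.0 + OVERSHOOT_TOL:
        warnings.warn(
            f"circularity {value:.6g} exceeds 1: area/perimeter pair is "
            "geometrically inconsistent; clipping to 1.0", stacklevel=2)
        return 1.0
    return value


def circularity_table(df: pd.DataFrame, *, id_col: str = "object_id",
                      area_col: str = "area",
                      perimeter_col: str = "perimeter") -> pd.DataFrame:
    """Per-object circularity for a (object_id, area, perimeter) table."""
    missing = {id_col, area_col, perimeter_col} - set(df.columns)
    if missing:
        raise ValueError(f"shape table missing column(s) {sorted(missing)}")
    values = [circularity(a, p) for a, p in zip(df[area_col], df[perimeter_col])]
    return pd.DataFrame({"object_id": df[id_col], "circularity": values})
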