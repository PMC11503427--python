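"""Urinary-iodine status classification for pregnancy.

Spot urinary iodine (UI, μg/L) is the standard population-level proxy for
iodine intake.  Values are classified against the pregnancy thresholds
100, 150 and 250 μg/L: below 100 is deficient, 100-150 is below the minimum
recommended level, 150-250 (both ends inclusive) is optimal, and strictly
above 250 is high.  The four categories partition [0, ∞).
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd

from .data_model import Cohort


class UiCategory(enum.Enum):
    """Iodine-status tiers; boundaries: [0,100), [100,150), [150,250], (250,∞)."""

    DEFICIENT_LT100 = "deficient_lt100"
    BELOW_RECOMMENDED_100_150 = "below_recommended_100_150"
    OPTIMAL_150_250 = "optimal_150_250"
    ABOVE_250 = "above_250"


def classify_ui(ui: float) -> UiCategory:
    """Classify a single UI value (μg/L); 150 and 250 both count as optimal."""
    if not np.isfinite(ui) or ui < 0:
        raise ValueError(f"UI must be a finite non-negative concentration, got {ui!r}")
    if ui < 100:
        return UiCategory.DEFICIENT_LT100
    if ui < 150:
        return UiCategory.BELOW_RECOMMENDED_100_150
    if ui <= 250:
        return UiCategory.OPTIMAL_150_250
    return UiCategory.ABOVE_250


def classify_ui_array(ui) -> np.ndarray:
    """Vectorised :func:`classify_ui`; returns an object array of UiCategory."""
    v = np.asarray(ui, dtype=float)
    if (v[np.isfinite(v)] < 0).any():
        raise ValueError("negative UI value")
    return np.array([classify_ui(x) if np.isfinite(x) else None for x in v], dtype=object)


def ui_proportions(cohort: Cohort) -> pd.Series:
    """Proportion of measurements in each iodine-status tier, plus cumulative tiers.

    Returns a Series with one entry per :class:`UiCategory` value and two
    cumulative entries, ``below_100`` and ``below_150``; the four category
    proportions sum to 1.  Rows with missing UI are excluded from the
    denominator; the count used is exposed as ``series.attrs['n']``.
    """
    ui = cohort.data["ui"].dropna().to_numpy(dtype=float)
    if ui.size == 0:
        raise ValueError("no UI values to classify")
    cats = classify_ui_array(ui)
    n = ui.size
    props = {c.value: float((cats == c).sum()) / n for c in UiCategory}
    props["below_100"] = props[UiCategory.DEFICIENT_LT100.value]
    props["below_150"] = (
        props[UiCategory.DEFICIENT_LT100.value] + props[UiCategory.BELOW_RECOMMENDED_100_150.value]
    )
    out = pd.Series(props)
    out.attrs["n"] = n
    return out
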