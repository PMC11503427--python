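"""Tukey inter-quartile-range "fence" detection and removal of urinary-iodine outliers.

A value is an outlier when it falls strictly outside
``[Q1 - k*IQR, Q3 + k*IQR]`` with ``k = 1.5`` by convention; values exactly on
a fence are retained.  Fencing is applied to urinary iodine only, never to the
hormone measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Cohort, PERIOD_LABELS

QUARTILE_METHODS = ("linear_interpolation", "tukey_hinges")
SCOPES = ("pooled", "per_period")


@dataclass(frozen=True)
class FenceBounds:
    """Quartiles, IQR, multiplier and the resulting lower/upper fences."""

    q1: float
    q3: float
    iqr: float
    k: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.q3 < self.q1:
            raise ValueError("q3 < q1")
        if self.k <= 0:
            raise ValueError("fence multiplier k must be positive")

    def outlier_mask(self, values) -> np.ndarray:
        """Boolean mask of values strictly outside the fences (NaN → False)."""
        v = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            return (v < self.lower) | (v > self.upper)


@dataclass
class FilterResult:
    retained: Cohort
    removed: Cohort
    bounds: "FenceBounds | dict[str, FenceBounds]"

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def compute_quartiles(values, method: str = "linear_interpolation") -> tuple[float, float]:
    """First and third quartiles under a stated convention.

    ``linear_interpolation`` interpolates between order statistics (the common
    software default); ``tukey_hinges`` takes the medians of the lower and
    upper halves of the sorted data, including the overall median in both
    halves when n is odd.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("cannot compute quartiles of an empty collection")
    if method == "linear_interpolation":
        q1, q3 = np.percentile(v, [25, 75], method="linear")
        return float(q1), float(q3)
    if method == "tukey_hinges":
        s = np.sort(v)
        half = (s.size + 1) // 2  # include median in both halves when n odd
        return float(np.median(s[:half])), float(np.median(s[-half:]))
    raise ValueError(f"unknown quartile method {method!r}; choose from {QUARTILE_METHODS}")


def tukey_fence(values, k: float = 1.5, method: str = "linear_interpolation") -> FenceBounds:
    """Fence bounds for the given values; requires at least 4 finite values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError(
            f"only {v.size} finite values: too few for meaningful quartiles, no fencing applied"
        )
    if k <= 0:
        raise ValueError("fence multiplier k must be positive")
    q1, q3 = compute_quartiles(v, method)
    iqr = q3 - q1
    return FenceBounds(q1=q1, q3=q3, iqr=iqr, k=k, lower=q1 - k * iqr, upper=q3 + k * iqr)


def filter_ui_outliers(
    cohort: Cohort,
    k: float = 1.5,
    scope: str = "pooled",
    method: str = "linear_interpolation",
) -> FilterResult:
    """Partition a cohort into UI-inlier and UI-outlier rows.

    ``scope='pooled'`` fits one fence to all UI values together (default);
    ``'per_period'`` fits a fence within each gestational period.  Rows with
    missing UI cannot be judged and are always retained.  The retained
    cohort's provenance records bounds, ``k``, scope and removed count.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; choose from {SCOPES}")
    df = cohort.data
    ui = df["ui"].to_numpy(dtype=float)

    if scope == "pooled":
        bounds: FenceBounds | dict[str, FenceBounds] = tukey_fence(ui, k=k, method=method)
        outlier = bounds.outlier_mask(ui)
        desc = f"[{bounds.lower:.6g}, {bounds.upper:.6g}]"
    else:
        bounds = {}
        outlier = np.zeros(len(df), dtype=bool)
        for p in PERIOD_LABELS:
            in_p = (df["period"] == p).to_numpy()
            if not in_p.any():
                continue
            b = tukey_fence(ui[in_p], k=k, method=method)
            bounds[p] = b
            outlier[in_p] = b.outlier_mask(ui[in_p])
        desc = "; ".join(f"{p}: [{b.lower:.6g}, {b.upper:.6g}]" for p, b in bounds.items())

    note = (
        f"Tukey fence on UI (k={k}, scope={scope}, quartiles={method}): "
        f"bounds {desc}; removed {int(outlier.sum())} of {len(df)}"
    )
    retained = cohort.subset(~outlier, note)
    removed = cohort.subset(outlier, f"rows removed by: {note}")
    return FilterResult(retained=retained, removed=removed, bounds=bounds)
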