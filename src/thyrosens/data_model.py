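"""Cohort data model and delimited-table I/O.

A cohort is a flat table of thyroid-panel measurement occasions in pregnancy:
one row per blood/urine sampling session, carrying the gestational period
(first/second/third trimester or two-months postpartum), TSH (μIU/mL), free
thyroxine fT4 (ng/dL), anti-thyroid-peroxidase antibody level (U/mL) and/or
positivity flag, and spot urinary iodine (μg/L).  Repeated measurements from
the same woman are deliberately not linked: each row is treated as an
independent observation, so no subject identifier is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered gestational-period labels: trimesters 1-3 and two-months postpartum.
PERIOD_LABELS: tuple[str, ...] = ("T1", "T2", "T3", "PP")

PERIOD_DTYPE = pd.CategoricalDtype(categories=PERIOD_LABELS, ordered=True)

#: anti-TPO positivity cutoff, U/mL; positive means strictly above this level.
ANTI_TPO_CUTOFF: float = 34.0

#: Internal column order of a cohort table.
COLUMNS: tuple[str, ...] = (
    "sample_id", "period", "tsh", "ft4", "anti_tpo", "anti_tpo_positive", "ui",
)

#: Canonical on-disk column names (internal name -> CSV header).
DEFAULT_SCHEMA: dict[str, str] = {
    "sample_id": "sample_id",
    "period": "period",
    "gest_week": "gest_week",
    "tsh": "tsh_uIU_mL",
    "ft4": "ft4_ng_dL",
    "anti_tpo": "anti_tpo_U_mL",
    "anti_tpo_positive": "anti_tpo_pos",
    "ui": "ui_ug_L",
}

_NUMERIC_FIELDS = ("tsh", "ft4", "anti_tpo", "ui")

_TRUE_TOKENS = {"true", "1", "yes", "y", "pos", "positive"}
_FALSE_TOKENS = {"false", "0", "no", "n", "neg", "negative"}


class SchemaError(ValueError):
    """A required column is missing or the column mapping is invalid."""


class RowError(ValueError):
    """One or more rows hold values that cannot be parsed or are out of range."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


def period_from_week(week: int | float) -> str:
    """Map a gestational week to a trimester label.

    Weeks 0-13 are the first trimester, 14-26 the second, and 27 onward the
    third.  Postpartum rows cannot be expressed as a week; they must carry the
    ``PP`` label directly.
    """
    if not np.isfinite(week) or week < 0:
        raise ValueError(f"gestational week must be a non-negative number, got {week!r}")
    if week <= 13:
        return "T1"
    if week <= 26:
        return "T2"
    return "T3"


@dataclass(eq=False)
class Cohort:
    """A validated collection of measurement occasions plus an audit trail.

    ``data`` holds one row per sample with columns :data:`COLUMNS`; ``period``
    is an ordered categorical over :data:`PERIOD_LABELS`.  ``provenance`` is a
    free-text log of the filters and derivations applied so every downstream
    number can be traced back to the raw table.
    """

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def counts_by_period(self) -> pd.Series:
        return self.data["period"].value_counts().reindex(PERIOD_LABELS, fill_value=0)

    def with_provenance(self, note: str) -> "Cohort":
        return Cohort(self.data.copy(), [*self.provenance, note])

    def subset(self, mask, note: str | None = None) -> "Cohort":
        prov = list(self.provenance) + ([note] if note else [])
        return Cohort(self.data.loc[mask].reset_index(drop=True), prov)

    def equals(self, other: "Cohort", rtol: float = 1e-6) -> bool:
        """Field-for-field equality with numeric tolerance (missing == missing)."""
        a, b = self.data, other.data
        if len(a) != len(b):
            return False
        if not (a["sample_id"].to_numpy() == b["sample_id"].to_numpy()).all():
            return False
        if not (a["period"].astype(str).to_numpy() == b["period"].astype(str).to_numpy()).all():
            return False
        fa = a["anti_tpo_positive"]
        fb = b["anti_tpo_positive"]
        if not (fa.isna() == fb.isna()).all() or not (fa.dropna() == fb[fa.notna()]).all():
            return False
        for col in _NUMERIC_FIELDS:
            x, y = a[col].to_numpy(float), b[col].to_numpy(float)
            both_nan = np.isnan(x) & np.isnan(y)
            close = np.isclose(x, y, rtol=rtol, equal_nan=False)
            if not (both_nan | close).all():
                return False
        return True


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort frame missing columns: {missing}")
    df = df.loc[:, list(COLUMNS)].reset_index(drop=True)

    dup = df["sample_id"].duplicated()
    if dup.any():
        raise RowError(
            f"duplicate sample_id values: {sorted(df.loc[dup, 'sample_id'].unique())[:5]}",
            rows=list(np.flatnonzero(dup)),
        )

    df["period"] = df["period"].astype(str).astype(PERIOD_DTYPE)
    if df["period"].isna().any():
        bad = list(np.flatnonzero(df["period"].isna()))
        raise RowError(f"rows with unknown period label: {bad[:10]}", rows=bad)

    for col in _NUMERIC_FIELDS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    df["anti_tpo_positive"] = df["anti_tpo_positive"].astype("boolean")

    checks = {
        "tsh": df["tsh"] <= 0,
        "ft4": df["ft4"] <= 0,
        "ui": df["ui"] < 0,
        "anti_tpo": df["anti_tpo"] < 0,
    }
    for col, bad in checks.items():
        bad = bad.fillna(False)
        if bad.any():
            rows = list(np.flatnonzero(bad))
            raise RowError(f"out-of-range {col} values at rows {rows[:10]}", rows=rows)
    return df


def _parse_numeric(raw: pd.Series, name: str) -> pd.Series:
    coerced = pd.to_numeric(raw, errors="coerce")
    nonempty = raw.notna() & (raw.astype(str).str.strip() != "")
    bad = nonempty & coerced.isna()
    if bad.any():
        rows = list(np.flatnonzero(bad))
        raise RowError(
            f"non-numeric value(s) in column '{name}' at rows {rows[:10]} "
            f"(e.g. {raw[bad].iloc[0]!r})",
            rows=rows,
        )
    return coerced.astype(float)


def _parse_flag(raw: pd.Series, name: str) -> pd.Series:
    out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
    s = raw.astype(str).str.strip().str.lower()
    filled = raw.notna() & (s != "")
    out[filled & s.isin(_TRUE_TOKENS)] = True
    out[filled & s.isin(_FALSE_TOKENS)] = False
    bad = filled & ~s.isin(_TRUE_TOKENS | _FALSE_TOKENS)
    if bad.any():
        rows = list(np.flatnonzero(bad))
        raise RowError(f"unparseable boolean in '{name}' at rows {rows[:10]}", rows=rows)
    return out


def read_cohort(path: str | Path, schema: dict[str, str] | None = None) -> Cohort:
    """Read a cohort CSV, mapping columns via ``schema`` (internal -> header).

    The period may be given directly (labels ``T1``/``T2``/``T3``/``PP``) or
    via an integer gestational week, mapped week ≤ 13 → T1, 14-26 → T2,
    ≥ 27 → T3.  When both are present and disagree, the explicit label wins
    and a warning is logged.
    """
    path = Path(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)

    def col(name: str) -> pd.Series | None:
        header = colmap.get(name)
        return raw[header] if header in raw.columns else None

    required = ["sample_id", "tsh", "ft4", "ui"]
    missing = [colmap[c] for c in required if col(c) is None]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    if col("period") is None and col("gest_week") is None:
        raise SchemaError(
            f"{path.name}: need a '{colmap['period']}' or '{colmap['gest_week']}' column"
        )

    n = len(raw)
    period = pd.Series([None] * n, dtype=object)
    labels = col("period")
    if labels is not None:
        has_label = labels.notna() & (labels.astype(str).str.strip() != "")
        lab = labels.astype(str).str.strip().str.upper()
        unknown = has_label & ~lab.isin(PERIOD_LABELS)
        if unknown.any():
            rows = list(np.flatnonzero(unknown))
            raise RowError(
                f"unknown period label(s) {sorted(lab[unknown].unique())[:5]} at rows {rows[:10]}",
                rows=rows,
            )
        period[has_label] = lab[has_label]
    weeks = col("gest_week")
    if weeks is not None:
        wk = _parse_numeric(weeks, colmap["gest_week"])
        from_week = wk.dropna().map(period_from_week)
        for i, p_wk in from_week.items():
            if period[i] is None:
                period[i] = p_wk
            elif period[i] != p_wk and period[i] != "PP":
                logger.warning(
                    "row %d: period label %s conflicts with gest_week-derived %s; label wins",
                    i, period[i], p_wk,
                )
    if period.isna().any():
        rows = list(np.flatnonzero(period.isna()))
        raise RowError(f"rows with no period information: {rows[:10]}", rows=rows)

    def numeric_or_nan(name: str) -> pd.Series:
        c = col(name)
        return _parse_numeric(c, colmap[name]) if c is not None else pd.Series(np.nan, index=raw.index)

    flag_col = col("anti_tpo_positive")
    df = pd.DataFrame(
        {
            "sample_id": raw[colmap["sample_id"]].astype(str).str.strip(),
            "period": period,
            "tsh": _parse_numeric(raw[colmap["tsh"]], colmap["tsh"]),
            "ft4": _parse_numeric(raw[colmap["ft4"]], colmap["ft4"]),
            "anti_tpo": numeric_or_nan("anti_tpo"),
            "anti_tpo_positive": _parse_flag(flag_col, colmap["anti_tpo_positive"])
            if flag_col is not None
            else pd.Series(pd.NA, index=raw.index, dtype="boolean"),
            "ui": _parse_numeric(raw[colmap["ui"]], colmap["ui"]),
        }
    )
    return Cohort(df, [f"read {len(df)} rows from {path.name}"])


def derive_anti_tpo_positivity(cohort: Cohort, cutoff: float = ANTI_TPO_CUTOFF) -> Cohort:
    """Fill the anti-TPO positivity flag from the antibody level.

    Positivity means strictly above the cutoff (a level exactly at the cutoff
    is negative).  Rows that already carry a flag keep it unchanged; rows with
    neither a flag nor a level are an error.
    """
    df = cohort.data.copy()
    need = df["anti_tpo_positive"].isna()
    has_level = df["anti_tpo"].notna()
    orphan = need & ~has_level
    if orphan.any():
        rows = list(np.flatnonzero(orphan))
        raise RowError(
            f"rows with neither anti-TPO level nor positivity flag: {rows[:10]}", rows=rows
        )
    df.loc[need, "anti_tpo_positive"] = df.loc[need, "anti_tpo"] > cutoff
    n = int(need.sum())
    return Cohort(df, [*cohort.provenance, f"derived anti-TPO positivity (> {cutoff} U/mL) for {n} rows"])


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with canonical headers; missing values as empty cells.

    Numeric fields are written at 10 significant digits so that
    ``read_cohort(write_cohort(c))`` round-trips losslessly well past 6
    significant digits.
    """
    out = pd.DataFrame(
        {
            DEFAULT_SCHEMA["sample_id"]: cohort.data["sample_id"],
            DEFAULT_SCHEMA["period"]: cohort.data["period"].astype(str),
            DEFAULT_SCHEMA["tsh"]: cohort.data["tsh"],
            DEFAULT_SCHEMA["ft4"]: cohort.data["ft4"],
            DEFAULT_SCHEMA["anti_tpo"]: cohort.data["anti_tpo"],
            DEFAULT_SCHEMA["anti_tpo_positive"]: cohort.data["anti_tpo_positive"].map(
                {True: "true", False: "false"}, na_action="ignore"
            ),
            DEFAULT_SCHEMA["ui"]: cohort.data["ui"],
        }
    )
    out.to_csv(path, index=False, float_format="%.10g", na_rep="")
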