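"""Thyroid Feedback Quantile-based Index (TFQI).

The TFQI gauges central (hypothalamic-pituitary) sensitivity to thyroid
hormones from the joint position of a sample's fT4 and TSH within a reference
distribution:

    TFQI = cdf(fT4) - (1 - cdf(TSH))

Under intact negative feedback, a high fT4 quantile should be met by a low TSH
quantile, so the two terms cancel and the index sits near zero.  Positive
values mean TSH is higher than the fT4 quantile predicts — reduced central
sensitivity; negative values mean increased sensitivity.  The index lies in
[-1, 1] and, being quantile-based, is invariant to any strictly monotone
rescaling of either hormone.

Two empirical-CDF conventions are offered: ``ecdf_leq`` (proportion of the
reference at or below the value; the maximum maps to exactly 1) and ``hazen``
(mid-rank minus one-half over n; all values strictly inside (0, 1), mean TFQI
exactly 0 in tie-free finite samples).  A parametric Gaussian/log-Gaussian
variant is provided for scoring against published moments rather than a
reference sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Cohort, PERIOD_LABELS

CONVENTIONS = ("ecdf_leq", "hazen")
REFERENCE_SCOPES = ("pooled", "per_period")

#: ng/dL -> pmol/L for thyroxine (molar mass 776.87 g/mol: 10 / 776.87 mol/L per g/dL).
FT4_NGDL_TO_PMOL: float = 12.871


def ft4_ngdl_to_pmol(x) -> "float | np.ndarray":
    """Convert free thyroxine from ng/dL to pmol/L (factor 12.871)."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("fT4 concentration cannot be negative")
    out = arr * FT4_NGDL_TO_PMOL
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _cdf_against(reference_sorted: np.ndarray, x: np.ndarray, convention: str) -> np.ndarray:
    n = reference_sorted.size
    right = np.searchsorted(reference_sorted, x, side="right")
    if convention == "ecdf_leq":
        return right / n
    if convention == "hazen":
        left = np.searchsorted(reference_sorted, x, side="left")
        # mid-rank of x among the reference; reduces to (#below + #equal/2)/n
        return (left + (right - left) / 2.0) / n
    raise ValueError(f"unknown CDF convention {convention!r}; choose from {CONVENTIONS}")


def empirical_cdf(values, convention: str = "ecdf_leq") -> np.ndarray:
    """Per-value empirical CDF of a collection, ties sharing one CDF value.

    ``ecdf_leq``: F(x) = (#values <= x) / n.  ``hazen``: (midrank - 0.5) / n.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empirical CDF of an empty collection is undefined")
    if not np.isfinite(v).all():
        raise ValueError("empirical CDF requires finite values")
    return _cdf_against(np.sort(v), v, convention)


@dataclass
class EcdfReference:
    """A frozen empirical reference distribution for prospective TFQI scoring.

    Holds the sorted fT4 and TSH reference samples and the CDF convention, so
    new measurements can be placed within the distribution of an already
    analysed cohort (e.g. to score a new patient against a study population).
    """

    ft4: np.ndarray
    tsh: np.ndarray
    convention: str = "ecdf_leq"

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        self.ft4 = np.sort(np.asarray(self.ft4, dtype=float))
        self.tsh = np.sort(np.asarray(self.tsh, dtype=float))
        if self.ft4.size == 0 or self.tsh.size == 0:
            raise ValueError("empty reference distribution")

    def score(self, ft4, tsh) -> np.ndarray:
        """TFQI of new (ft4, tsh) pairs against this reference."""
        ft4 = np.atleast_1d(np.asarray(ft4, dtype=float))
        tsh = np.atleast_1d(np.asarray(tsh, dtype=float))
        cdf_ft4 = _cdf_against(self.ft4, ft4, self.convention)
        cdf_tsh = _cdf_against(self.tsh, tsh, self.convention)
        return cdf_ft4 - (1.0 - cdf_tsh)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "convention": self.convention,
                    "ft4": self.ft4.tolist(),
                    "tsh": self.tsh.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EcdfReference":
        d = json.loads(Path(path).read_text())
        return cls(ft4=np.asarray(d["ft4"]), tsh=np.asarray(d["tsh"]), convention=d["convention"])


@dataclass(frozen=True)
class ParametricReference:
    """Gaussian fT4 / log-Gaussian TSH moments for the parametric TFQI variant."""

    mu_ft4: float
    sigma_ft4: float
    mu_log_tsh: float
    sigma_log_tsh: float

    def __post_init__(self) -> None:
        if self.sigma_ft4 <= 0 or self.sigma_log_tsh <= 0:
            raise ValueError("reference standard deviations must be positive")


def parametric_tfqi(tsh, ft4, ref: ParametricReference) -> "float | np.ndarray":
    """TFQI with Gaussian fT4 and log-Gaussian TSH reference distributions.

    Returns Φ((ft4 − μ_fT4)/σ_fT4) − (1 − Φ((ln tsh − μ_lnTSH)/σ_lnTSH)).
    """
    tsh_arr = np.asarray(tsh, dtype=float)
    ft4_arr = np.asarray(ft4, dtype=float)
    if (tsh_arr <= 0).any():
        raise ValueError("TSH must be positive (log-Gaussian reference)")
    cdf_ft4 = stats.norm.cdf((ft4_arr - ref.mu_ft4) / ref.sigma_ft4)
    cdf_tsh = stats.norm.cdf((np.log(tsh_arr) - ref.mu_log_tsh) / ref.sigma_log_tsh)
    out = cdf_ft4 - (1.0 - cdf_tsh)
    return float(out) if out.ndim == 0 else out


def compute_tfqi(
    cohort: Cohort,
    convention: str = "ecdf_leq",
    reference_scope: str = "pooled",
) -> pd.DataFrame:
    """Per-sample CDF values and TFQI for a cohort.

    The CDFs of fT4 and TSH are taken over the chosen reference set: the whole
    cohort pooled across periods (default — the index is computed over all
    study samples together) or within each gestational period.  Returns a
    frame aligned with ``cohort.data`` holding ``cdf_ft4``, ``cdf_tsh`` and
    ``tfqi``; rows with a missing hormone value get NaN.  The convention and
    scope are recorded in ``DataFrame.attrs``.
    """
    if reference_scope not in REFERENCE_SCOPES:
        raise ValueError(f"unknown reference scope {reference_scope!r}")
    df = cohort.data
    if len(df) == 0:
        raise ValueError("cannot compute TFQI on an empty cohort")
    ft4 = df["ft4"].to_numpy(dtype=float)
    tsh = df["tsh"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {"cdf_ft4": np.nan, "cdf_tsh": np.nan, "tfqi": np.nan}, index=df.index, dtype=float
    )

    def fill(mask: np.ndarray) -> None:
        ok = mask & np.isfinite(ft4) & np.isfinite(tsh)
        if not ok.any():
            return
        cdf_f = empirical_cdf(ft4[ok], convention)
        cdf_t = empirical_cdf(tsh[ok], convention)
        out.loc[ok, "cdf_ft4"] = cdf_f
        out.loc[ok, "cdf_tsh"] = cdf_t
        out.loc[ok, "tfqi"] = cdf_f - (1.0 - cdf_t)

    if reference_scope == "pooled":
        fill(np.ones(len(df), dtype=bool))
    else:
        for p in PERIOD_LABELS:
            fill((df["period"] == p).to_numpy())

    if out["tfqi"].isna().all():
        raise ValueError("no rows with finite TSH and fT4: empty reference set")
    out.attrs["convention"] = convention
    out.attrs["reference_scope"] = reference_scope
    return out


def make_reference(cohort: Cohort, convention: str = "ecdf_leq") -> EcdfReference:
    """Freeze a cohort's finite fT4/TSH values as a scoring reference."""
    df = cohort.data
    ok = df["ft4"].notna() & df["tsh"].notna()
    return EcdfReference(
        ft4=df.loc[ok, "ft4"].to_numpy(), tsh=df.loc[ok, "tsh"].to_numpy(), convention=convention
    )
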