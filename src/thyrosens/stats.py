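"""Inferential toolkit: stratified Pearson correlation, pairs bootstrap,
one-/two-way ANOVA with Tukey-Kramer post hoc, chi-square independence, OLS.

Correlations between the TFQI (or a hormone) and urinary iodine are computed
per gestational period, optionally restricted to a UI stratum such as
"over 250 μg/L".  Strata with fewer than 3 complete pairs are reported as
not-estimable with their pair count rather than raised, mirroring how a sparse
postpartum stratum is handled in practice.  All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data_model import Cohort, PERIOD_LABELS

MIN_PAIRS = 3  # smallest stratum for which r and p are reported

SIDES = ("above_strict", "at_or_below")


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    period: str | None = None  # None = pooled
    stratum: str | None = None
    estimable: bool = True

    def __str__(self) -> str:
        where = f"{self.period or 'pooled'}" + (f", UI {self.stratum}" if self.stratum else "")
        if not self.estimable:
            return f"[{where}] not estimable (n={self.n})"
        return f"[{where}] r={self.r:+.3f}, n={self.n}, p={self.p:.3f}"


@dataclass
class BootstrapResult:
    point_r: float
    replicate_summary: float
    ci_low: float
    ci_high: float
    b: int
    seed: int | None
    n: int
    n_degenerate: int = 0
    summary: str = "mean"
    period: str | None = None
    stratum: str | None = None


@dataclass
class AnovaResult:
    design: str  # "oneway" | "twoway"
    effects: dict[str, dict[str, float]]  # effect -> {f, df_num, df_den, p}
    ss_type: str | None = None

    def f(self, effect: str) -> float:
        return self.effects[effect]["f"]

    def p(self, effect: str) -> float:
        return self.effects[effect]["p"]


@dataclass
class PosthocResult:
    comparisons: pd.DataFrame  # group1, group2, mean_diff, se, p_adj, ci_low, ci_high, reject
    alpha: float


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    observed: pd.DataFrame
    expected: pd.DataFrame


@dataclass
class OlsFit:
    slope: float
    intercept: float
    n: int
    period: str | None = None
    stratum: str | None = None
    estimable: bool = True


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson_r(x, y, period: str | None = None, stratum: str | None = None) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-based p (n − 2 df).

    Pairs with a missing value in either variable are dropped (pairwise
    deletion).  Raises on fewer than 3 complete pairs or zero variance.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} complete pairs, got {n}")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"variable {name} is constant; correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), n=n, p=float(res.pvalue), period=period, stratum=stratum
    )


def bootstrap_correlation(
    x,
    y,
    b: int = 1000,
    seed: int | None = None,
    summary: str = "mean",
    period: str | None = None,
    stratum: str | None = None,
) -> BootstrapResult:
    """Pairs (case) bootstrap of the Pearson correlation.

    Resamples whole (x, y) pairs with replacement ``b`` times, computes r per
    replicate, and reports the percentile 95% interval plus a replicate
    summary (mean by default, median optionally).  Replicates where either
    resampled variable is constant are discarded and counted in
    ``n_degenerate``.  Deterministic given ``seed``.
    """
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    if b < 1:
        raise ValueError("b must be >= 1")
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} complete pairs, got {n}")
    point = pearson_r(x, y).r

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b, n))
    xs, ys = x[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    good = (sx > 0) & (sy > 0)
    if not good.any():
        raise ValueError("all bootstrap replicates degenerate (zero variance)")
    r = (xc[good] * yc[good]).sum(axis=1) / (sx[good] * sy[good])
    r = np.clip(r, -1.0, 1.0)  # guard against rounding past the bound
    lo, hi = np.percentile(r, [2.5, 97.5])
    summ = float(np.mean(r)) if summary == "mean" else float(np.median(r))
    return BootstrapResult(
        point_r=point,
        replicate_summary=summ,
        ci_low=float(lo),
        ci_high=float(hi),
        b=b,
        seed=seed,
        n=n,
        n_degenerate=int(b - good.sum()),
        summary=summary,
        period=period,
        stratum=stratum,
    )


def stratified_correlation(
    df: pd.DataFrame,
    var_x: str = "tfqi",
    var_y: str = "ui",
    threshold: float = 250.0,
    side: str = "above_strict",
) -> list[CorrelationResult]:
    """Per-period correlation of ``var_x`` vs ``var_y`` within a UI stratum.

    ``df`` is a cohort table already joined with the TFQI columns (must hold
    ``period``, ``ui`` and ``var_x``).  ``side='above_strict'`` keeps rows
    with UI strictly over the threshold ("over 250 μg/L"); ``'at_or_below'``
    keeps the complement.  With ``threshold=0`` and ``above_strict`` this
    reduces to the plain per-period correlations.  Periods with fewer than 3
    qualifying pairs are returned as not-estimable with their n.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    stratum_label = (
        f"> {threshold:g} μg/L" if side == "above_strict" else f"<= {threshold:g} μg/L"
    )
    ui = df["ui"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        in_stratum = ui > threshold if side == "above_strict" else ui <= threshold
    results = []
    for p in PERIOD_LABELS:
        sel = (df["period"] == p).to_numpy() & in_stratum
        x, y = _complete_pairs(df.loc[sel, var_x], df.loc[sel, var_y])
        if x.size < MIN_PAIRS or np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(
                CorrelationResult(
                    r=np.nan, n=x.size, p=np.nan, period=p, stratum=stratum_label, estimable=False
                )
            )
        else:
            results.append(pearson_r(x, y, period=p, stratum=stratum_label))
    return results


def oneway_anova(values, groups) -> AnovaResult:
    """Classic fixed-effects one-way F test of a measurement across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    f, p = sps.f_oneway(*samples)
    k = len(samples)
    n = sum(s.size for s in samples)
    return AnovaResult(
        design="oneway",
        effects={"group": {"f": float(f), "df_num": k - 1, "df_den": n - k, "p": float(p)}},
    )


def tukey_kramer(values, groups, alpha: float = 0.05) -> PosthocResult:
    """All pairwise group comparisons with the Tukey-Kramer (unequal-n) adjustment."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 groups for post hoc comparisons")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    # statsmodels exposes a tidy summary; rebuild it as a typed frame
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    comparisons = pd.DataFrame(
        {
            "group1": frame["group1"].astype(str),
            "group2": frame["group2"].astype(str),
            "mean_diff": res.meandiffs,
            "se": res.std_pairs,
            "p_adj": res.pvalues,
            "ci_low": res.confint[:, 0],
            "ci_high": res.confint[:, 1],
            "reject": res.reject,
        }
    )
    return PosthocResult(comparisons=comparisons, alpha=alpha)


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r×c count table.

    No continuity correction (the designs here are wider than 2×2).  Warns
    when any expected count falls below 5.  Zero row/column margins are an
    error: drop the empty level before testing.
    """
    obs = pd.DataFrame(table)
    arr = obs.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row or column margin")
    stat, p, df, expected = sps.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} cell(s) with expected count < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p=float(p),
        observed=obs,
        expected=pd.DataFrame(expected, index=obs.index, columns=obs.columns),
    )


def twoway_anova(
    values,
    factor_a,
    factor_b,
    names: tuple[str, str] = ("factor_a", "factor_b"),
    interaction: bool = False,
) -> AnovaResult:
    """Two-way ANOVA with type II sums of squares (unbalanced designs allowed).

    Main effects only by default.  If an interaction is requested but some
    factor-level cell is empty, the interaction is inestimable: it is dropped
    with a warning and main effects are reported.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": np.asarray(factor_a), "b": np.asarray(factor_b)}
    ).dropna()
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("both factors need at least 2 observed levels")
    if interaction:
        cells = df.groupby(["a", "b"], observed=True).size()
        full = df["a"].nunique() * df["b"].nunique()
        if len(cells) < full:
            warnings.warn(
                "empty factor cells make the interaction inestimable; reporting main effects only",
                stacklevel=2,
            )
            interaction = False
    formula = "y ~ C(a) + C(b)" + (" + C(a):C(b)" if interaction else "")
    fit = ols(formula, data=df).fit()
    tbl = anova_lm(fit, typ=2)
    rename = {"C(a)": names[0], "C(b)": names[1], "C(a):C(b)": f"{names[0]}:{names[1]}"}
    effects = {}
    df_den = float(tbl.loc["Residual", "df"])
    for row, eff in rename.items():
        if row in tbl.index:
            effects[eff] = {
                "f": float(tbl.loc[row, "F"]),
                "df_num": float(tbl.loc[row, "df"]),
                "df_den": df_den,
                "p": float(tbl.loc[row, "PR(>F)"]),
            }
    return AnovaResult(design="twoway", effects=effects, ss_type="II")


def ols_fit(x, y, period: str | None = None, stratum: str | None = None) -> OlsFit:
    """Simple least-squares line; not-estimable (not an error) when n < 2 or x constant.

    A stratum holding a single observation cannot support a regression line,
    so such fits are reported with their n and ``estimable=False``.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        return OlsFit(
            slope=np.nan, intercept=np.nan, n=n, period=period, stratum=stratum, estimable=False
        )
    slope, intercept = np.polyfit(x, y, 1)
    return OlsFit(
        slope=float(slope), intercept=float(intercept), n=n, period=period, stratum=stratum
    )
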