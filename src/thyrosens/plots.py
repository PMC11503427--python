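"""Scatter plots of the TFQI against urinary iodine, split at the UI threshold.

Two panels — UI at or below the threshold and UI above it — with one colour
per gestational period and the per-stratum OLS line where it is estimable.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data_model import PERIOD_LABELS

_COLORS = {"T1": "tab:blue", "T2": "tab:orange", "T3": "tab:green", "PP": "tab:red"}


def plot_stratified_scatter(report, path: str | Path) -> Path:
    """Render the two-panel TFQI-vs-UI figure for a :class:`StudyReport`."""
    df = report.data
    if df is None:
        raise ValueError("report carries no analysed data frame")
    thr = report.config.threshold
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2), sharey=True)
    fits = {(f.period, f.stratum): f for f in report.ols}
    for ax, (title, mask, results) in zip(
        axes,
        [
            (f"UI ≤ {thr:g} μg/L", df["ui"] <= thr, report.stratified_below),
            (f"UI > {thr:g} μg/L", df["ui"] > thr, report.stratified_above),
        ],
    ):
        for p in PERIOD_LABELS:
            sel = mask & (df["period"] == p)
            if not sel.any():
                continue
            ax.scatter(df.loc[sel, "ui"], df.loc[sel, "tfqi"], s=12, alpha=0.5,
                       color=_COLORS[p], label=p)
            res = next(r for r in results if r.period == p)
            fit = fits.get((p, res.stratum))
            if fit is not None and fit.estimable:
                xs = np.linspace(df.loc[sel, "ui"].min(), df.loc[sel, "ui"].max(), 10)
                ax.plot(xs, fit.intercept + fit.slope * xs, color=_COLORS[p], lw=1.5)
        ax.set_title(title)
        ax.set_xlabel("urinary iodine (μg/L)")
    axes[0].set_ylabel("TFQI")
    axes[0].legend(title="period", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
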