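"""End-to-end analysis pipeline and report.

Stage order: read (or simulate) → anti-TPO positivity derivation → Tukey fence
on UI → TFQI → per-period summary (the study-table analog) → iodine-status
proportions → one-way ANOVAs with Tukey-Kramer post hoc → chi-square of
anti-TPO positivity by period → two-way ANOVA of UI by positivity and period →
per-period correlations of TSH/fT4/TFQI vs UI → threshold-stratified TFQI-UI
correlations (at-or-below and above) with OLS fits → pairs bootstrap of the
above-threshold TFQI-UI correlation per period.

The TFQI reference set is the post-fence cohort by default (exclusion precedes
index computation); set ``tfqi_prefence=True`` to compute it on the raw cohort
as a sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .data_model import Cohort, PERIOD_LABELS, derive_anti_tpo_positivity, read_cohort
from .iodine import ui_proportions
from .outliers import FilterResult, filter_ui_outliers
from .simulate import DEFAULT_PERIOD_SPECS, DependenceSpec, PeriodSpec, generate_cohort
from .tfqi import compute_tfqi, ft4_ngdl_to_pmol

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything needed to recompute a report: inputs, filters, seeds."""

    input: str | None = None  # CSV path; None → synthetic cohort
    seed: int | None = None
    outlier_k: float = 1.5
    outlier_method: str = "linear_interpolation"
    outlier_scope: str = "pooled"
    tfqi_convention: str = "ecdf_leq"
    tfqi_scope: str = "pooled"
    tfqi_prefence: bool = False
    threshold: float = 250.0
    bootstrap_b: int = 1000
    outdir: str | None = None
    make_plots: bool = False
    schema: dict | None = None
    period_specs: dict[str, PeriodSpec] | None = None  # synthetic input only
    dependence: DependenceSpec | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.bootstrap_b < 1:
            raise ValueError("bootstrap_b must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        specs = raw.pop("period_specs", None)
        dep = raw.pop("dependence", None)
        cfg = cls(**raw)
        if specs:
            cfg.period_specs = {p: PeriodSpec(**v) for p, v in specs.items()}
        if dep:
            if "copula_corr" in dep:
                dep["copula_corr"] = np.asarray(dep["copula_corr"], dtype=float)
            cfg.dependence = DependenceSpec(**dep)
        return cfg


@dataclass
class StudyReport:
    """All pipeline outputs; every number is recomputable from input + config."""

    config: AnalysisConfig
    summary: pd.DataFrame  # per-period analog of the study summary table
    iodine: pd.Series
    anova: dict[str, st.AnovaResult]
    posthoc: dict[str, st.PosthocResult]
    chi_square: st.ChiSquareResult | None
    twoway: st.AnovaResult | None
    correlations_ui: dict[str, list[st.CorrelationResult]]  # variable -> per-period results
    stratified_below: list[st.CorrelationResult]
    stratified_above: list[st.CorrelationResult]
    bootstrap: list[st.BootstrapResult]
    ols: list[st.OlsFit]
    n_input: int = 0
    n_removed: int = 0
    provenance: list[str] = field(default_factory=list)
    data: pd.DataFrame | None = None  # analysed (post-fence) table incl. tfqi

    def to_text(self) -> str:
        lines = [
            "Thyroid sensitivity / urinary iodine analysis report",
            "=" * 60,
            f"samples analysed: {self.n_input - self.n_removed} "
            f"({self.n_removed} UI outliers removed of {self.n_input})",
            "",
            "Per-period summary (mean ± SD):",
            self.summary.round(3).to_string(),
            "",
            "Iodine status (proportions of measurements):",
        ]
        for k, v in self.iodine.items():
            lines.append(f"  {k}: {100 * v:.1f}%")
        lines.append("")
        for var, res in self.anova.items():
            e = res.effects["group"]
            lines.append(
                f"one-way ANOVA {var} vs period: F({e['df_num']:.0f},{e['df_den']:.0f})"
                f" = {e['f']:.3f}, p = {e['p']:.4f}"
            )
        if self.chi_square is not None:
            c = self.chi_square
            lines.append(
                f"chi-square anti-TPO positivity x period: X2({c.df}) = {c.statistic:.3f}, "
                f"p = {c.p:.4f}"
            )
        if self.twoway is not None:
            for eff, e in self.twoway.effects.items():
                lines.append(
                    f"two-way ANOVA UI ~ {eff}: F({e['df_num']:.0f},{e['df_den']:.0f})"
                    f" = {e['f']:.3f}, p = {e['p']:.4f}"
                )
        lines.append("")
        lines.append("Per-period correlations vs UI (unstratified):")
        for var, results in self.correlations_ui.items():
            for r in results:
                lines.append(f"  {var:>4} vs UI {r}")
        lines.append(f"TFQI vs UI at or below {self.config.threshold:g} μg/L:")
        lines += [f"  {r}" for r in self.stratified_below]
        lines.append(f"TFQI vs UI above {self.config.threshold:g} μg/L:")
        lines += [f"  {r}" for r in self.stratified_above]
        lines.append("")
        lines.append(f"Pairs bootstrap (b={self.config.bootstrap_b}) of TFQI vs UI above threshold:")
        for b in self.bootstrap:
            lines.append(
                f"  [{b.period}] point r={b.point_r:+.3f}, replicate {b.summary}="
                f"{b.replicate_summary:+.3f}, 95% CI ({b.ci_low:+.3f}, {b.ci_high:+.3f}), n={b.n}"
            )
        lines.append("")
        lines.append("Provenance:")
        lines += [f"  - {p}" for p in self.provenance]
        return "\n".join(lines)

    def correlation_frame(self) -> pd.DataFrame:
        rows = []
        for var, results in self.correlations_ui.items():
            for r in results:
                rows.append({"variable": var, **dataclasses.asdict(r), "stratum": "all"})
        for r in self.stratified_below + self.stratified_above:
            rows.append({"variable": "tfqi", **dataclasses.asdict(r)})
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary_by_period.csv")
        self.iodine.rename("proportion").to_csv(out / "iodine_status.csv")
        self.correlation_frame().to_csv(out / "correlations.csv", index=False)
        pd.DataFrame([dataclasses.asdict(b) for b in self.bootstrap]).to_csv(
            out / "bootstrap.csv", index=False
        )
        pd.DataFrame([dataclasses.asdict(f) for f in self.ols]).to_csv(
            out / "ols_fits.csv", index=False
        )
        (out / "report.txt").write_text(self.to_text() + "\n")


def _summary_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for p in PERIOD_LABELS:
        sub = df[df["period"] == p]
        if len(sub) == 0:
            continue
        pos = sub["anti_tpo_positive"].dropna()
        rows[p] = {
            "n": len(sub),
            "tsh_mean": sub["tsh"].mean(),
            "tsh_sd": sub["tsh"].std(),
            "ft4_ngdl_mean": sub["ft4"].mean(),
            "ft4_ngdl_sd": sub["ft4"].std(),
            "ft4_pmol_mean": ft4_ngdl_to_pmol(sub["ft4"].mean()),
            "ft4_pmol_sd": ft4_ngdl_to_pmol(sub["ft4"].std()),
            "anti_tpo_pos_pct": 100.0 * pos.mean() if len(pos) else np.nan,
            "tfqi_mean": sub["tfqi"].mean(),
            "tfqi_sd": sub["tfqi"].std(),
            "ui_mean": sub["ui"].mean(),
            "ui_sd": sub["ui"].std(),
        }
    return pd.DataFrame(rows).T.rename_axis("period")


def run_analysis(cohort: Cohort, config: AnalysisConfig | None = None) -> StudyReport:
    """Run the full analysis on an already-loaded cohort."""
    config = config or AnalysisConfig()
    n_input = len(cohort)

    cohort = derive_anti_tpo_positivity(cohort)
    logger.info("stage anti-TPO derivation: %d rows", len(cohort))

    pre_fence = cohort
    result: FilterResult = filter_ui_outliers(
        cohort, k=config.outlier_k, scope=config.outlier_scope, method=config.outlier_method
    )
    cohort = result.retained
    logger.info("stage UI fence: removed %d, retained %d", result.n_removed, len(cohort))

    tfqi_source = pre_fence if config.tfqi_prefence else cohort
    tfqi_tbl = compute_tfqi(
        tfqi_source, convention=config.tfqi_convention, reference_scope=config.tfqi_scope
    )
    df = cohort.data.copy()
    if config.tfqi_prefence:
        by_id = pd.Series(tfqi_tbl["tfqi"].to_numpy(), index=pre_fence.data["sample_id"])
        df["tfqi"] = df["sample_id"].map(by_id).to_numpy()
    else:
        df["tfqi"] = tfqi_tbl["tfqi"].to_numpy()
    logger.info("stage TFQI: convention=%s scope=%s", config.tfqi_convention, config.tfqi_scope)

    summary = _summary_table(df)
    iodine = ui_proportions(cohort)

    anova, posthoc = {}, {}
    groups = df["period"].astype(str).to_numpy()
    multi = df["period"].nunique() >= 2
    if multi:
        for var in ("tsh", "ft4", "ui", "tfqi"):
            vals = df[var].to_numpy(dtype=float)
            anova[var] = st.oneway_anova(vals, groups)
            posthoc[var] = st.tukey_kramer(vals, groups)

    chi = None
    twoway = None
    if multi and df["anti_tpo_positive"].nunique() >= 2:
        table = pd.crosstab(df["anti_tpo_positive"].astype(bool), df["period"], dropna=True)
        table = table.loc[:, table.sum(axis=0) > 0]
        chi = st.chi_square_independence(table)
        twoway = st.twoway_anova(
            df["ui"], df["anti_tpo_positive"].astype(bool), df["period"].astype(str),
            names=("anti_tpo_pos", "period"),
        )

    correlations_ui = {
        var: st.stratified_correlation(df, var_x=var, threshold=0.0, side="above_strict")
        for var in ("tsh", "ft4", "tfqi")
    }
    below = st.stratified_correlation(df, var_x="tfqi", threshold=config.threshold,
                                      side="at_or_below")
    above = st.stratified_correlation(df, var_x="tfqi", threshold=config.threshold,
                                      side="above_strict")

    boots = []
    ols_fits = []
    with np.errstate(invalid="ignore"):
        hot = df["ui"].to_numpy(dtype=float) > config.threshold
    for i, p in enumerate(PERIOD_LABELS):
        for side_mask, res_list in (((~hot), below), (hot, above)):
            sel = (df["period"] == p).to_numpy() & side_mask
            ols_fits.append(
                st.ols_fit(df.loc[sel, "ui"], df.loc[sel, "tfqi"], period=p,
                           stratum=res_list[i].stratum)
            )
        if above[i].estimable:
            sel = (df["period"] == p).to_numpy() & hot
            boots.append(
                st.bootstrap_correlation(
                    df.loc[sel, "tfqi"], df.loc[sel, "ui"], b=config.bootstrap_b,
                    seed=config.seed, period=p, stratum=above[i].stratum,
                )
            )

    provenance = list(cohort.provenance)
    provenance.append(
        f"analysis config: threshold={config.threshold}, bootstrap_b={config.bootstrap_b}, "
        f"seed={config.seed}, tfqi={config.tfqi_convention}/{config.tfqi_scope}"
        f"{'/pre-fence' if config.tfqi_prefence else '/post-fence'}"
    )
    return StudyReport(
        config=config,
        summary=summary,
        iodine=iodine,
        anova=anova,
        posthoc=posthoc,
        chi_square=chi,
        twoway=twoway,
        correlations_ui=correlations_ui,
        stratified_below=below,
        stratified_above=above,
        bootstrap=boots,
        ols=ols_fits,
        n_input=n_input,
        n_removed=result.n_removed,
        provenance=provenance,
        data=df,
    )


def run(config: AnalysisConfig) -> StudyReport:
    """Load or simulate the input cohort, run the analysis, write outputs."""
    if config.input:
        cohort = read_cohort(config.input, schema=config.schema)
    else:
        cohort = generate_cohort(
            specs=config.period_specs or DEFAULT_PERIOD_SPECS,
            dep=config.dependence,
            seed=config.seed,
        )
    report = run_analysis(cohort, config)
    if config.outdir:
        report.write(config.outdir)
        if config.make_plots:
            from .plots import plot_stratified_scatter

            plot_stratified_scatter(report, Path(config.outdir) / "tfqi_vs_ui.png")
    return report
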