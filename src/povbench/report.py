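"""Publication-style tables and figures from run artifacts.

Renders the regression ladder as a text table with significance markers
(*** p<0.01, ** p<0.05, * p<0.10), the benchmark and SPL summary tables,
a histogram of SPL costs across countries, and a sorted per-country cost
bar chart.  Figures are written as SVG and PNG with metadata stripped so
reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import fe

COEF_LABELS = {
    "log_phe_lag": "Log government health spending (lagged)",
    "log_gdp": "Log GDP per capita",
    "gini": "Gini index",
}


def significance_marker(p: float) -> str:
    """Conventional significance stars: *** p<0.01, ** p<0.05, * p<0.10."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def regression_table(fits: dict[str, fe.FitResult], order: list[str] | None = None) -> str:
    """Text table, one column per specification, coefficients over SEs."""
    order = order or list(fits)
    cols = [name for name in order if name in fits]
    if not cols:
        return "(no fitted specifications)\n"
    coef_names = []
    for name in cols:
        for c in fits[name].params.index:
            if c not in coef_names:
                coef_names.append(c)

    width = 24
    lines = []
    header = "".ljust(42) + "".join(f"({i + 1})".rjust(width) for i in range(len(cols)))
    lines.append(header)
    lines.append("".ljust(42) + "".join(c.rjust(width) for c in cols))
    lines.append("-" * len(header))
    for coef in coef_names:
        vals, ses = [], []
        for name in cols:
            f = fits[name]
            if coef in f.params.index:
                star = significance_marker(float(f.p_values()[coef]))
                vals.append(f"{f.params[coef]:.3f}{star}".rjust(width))
                ses.append(f"({f.se[coef]:.3f})".rjust(width))
            else:
                vals.append("".rjust(width))
                ses.append("".rjust(width))
        lines.append(COEF_LABELS.get(coef, coef).ljust(42) + "".join(vals))
        lines.append("".ljust(42) + "".join(ses))
    lines.append("-" * len(header))

    def _row(label: str, fmt) -> str:
        return label.ljust(42) + "".join(fmt(fits[name]).rjust(width) for name in cols)

    lines.append(_row("Country fixed effects",
                      lambda f: "X" if f.spec.include_fixed_effects else ""))
    lines.append(_row("Observations", lambda f: str(f.n_obs)))
    lines.append(_row("R-squared", lambda f: f"{f.r_squared:.2f}"))
    lines.append(_row("# countries", lambda f: str(f.n_countries)))
    lines.append("")
    lines.append("Standard errors in parentheses. *** p<0.01, ** p<0.05, * p<0.10.")
    return "\n".join(lines) + "\n"


def _read_artifact_csv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _save_fig(fig, out: Path, stem: str) -> None:
    fig.savefig(out / f"{stem}.svg", metadata={"Date": None, "Creator": None})
    fig.savefig(out / f"{stem}.png", dpi=150, metadata={"Software": None})
    plt.close(fig)


def spl_cost_histogram(per_country: pd.DataFrame, out: Path) -> None:
    """Distribution of SPL costs per poverty case averted across countries."""
    costs = per_country["cost_per_case"].dropna() / 1000.0
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(costs, bins=min(20, max(5, len(costs) // 2)), color="#4878b0",
            edgecolor="white")
    ax.set_xlabel("Cost per poverty case averted (1,000 $)")
    ax.set_ylabel("Number of countries")
    ax.set_title("Distribution of SPL program costs per poverty case averted")
    fig.tight_layout()
    _save_fig(fig, out, "fig_spl_cost_distribution")


def spl_cost_bars(per_country: pd.DataFrame, out: Path) -> None:
    """Per-country costs, sorted descending."""
    df = per_country.dropna(subset=["cost_per_case"]).sort_values(
        "cost_per_case", ascending=False
    )
    fig, ax = plt.subplots(figsize=(max(7, 0.22 * len(df)), 5))
    colors = df["income_group"].map(
        {"low": "#d1605e", "lower_middle": "#4878b0"}
    ).fillna("#777777")
    ax.bar(df["country"], df["cost_per_case"] / 1000.0, color=colors)
    ax.set_ylabel("Cost per poverty case averted (1,000 $)")
    ax.set_title("Estimated country-specific SPL costs per poverty case averted")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    _save_fig(fig, out, "fig_spl_cost_by_country")


def format_display_table(df: pd.DataFrame, money_cols: tuple[str, ...]) -> pd.DataFrame:
    """Round dollar columns for display; empty groups render as an em dash."""
    out = df.copy()
    for col in money_cols:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "—" if pd.isna(v) else f"${v:,.0f}"
            )
    return out


def render_all(out: Path, config) -> None:
    """Render every table/figure whose inputs exist in the output directory."""
    out = Path(out)
    fits_raw = json.loads((out / "fits.json").read_text())
    fits = {k: fe.FitResult.from_dict(v) for k, v in fits_raw.items()}

    ladder = [k for k in ("bivariate", "fixed_effects", "fe_controls") if k in fits]
    (out / "table_regression_ladder.txt").write_text(regression_table(fits, ladder))
    groups = sorted(k for k in fits if k.startswith("group_"))
    if groups:
        (out / "table_regression_by_group.txt").write_text(regression_table(fits, groups))

    prb_path = out / "prb_table.csv"
    if prb_path.exists():
        prb = _read_artifact_csv(prb_path, index_col="group")
        display = format_display_table(
            prb, ("lower_ur", "median", "mean", "upper_ur", "prb_at_mean_beta")
        )
        display.to_csv(out / "table_prb_display.csv")

    spl_pc_path = out / "spl_per_country.csv"
    if spl_pc_path.exists():
        per_country = _read_artifact_csv(spl_pc_path)
        spl_cost_histogram(per_country, out)
        spl_cost_bars(per_country, out)
    spl_sum_path = out / "spl_summary.csv"
    if spl_sum_path.exists():
        spl_sum = _read_artifact_csv(spl_sum_path, index_col="group")
        format_display_table(spl_sum, ("p10", "median", "mean", "p90")).to_csv(
            out / "table_spl_display.csv"
        )
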