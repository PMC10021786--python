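"""Country-year panel ingestion, validation and transformation.

This module turns a long-format country-year table (the shape of a World
Bank WDI extract) into the estimation-ready rows consumed by the
fixed-effects elasticity model: it validates ranges, rejects rows that
would break the log-log specification, constructs the lagged-spending
regressor, applies the complete-case sample rule (at least ``min_years``
complete years per country since the year window start), and produces
first-/last-year summary tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INCOME_GROUPS = ("low", "lower_middle", "upper_middle")

#: Logical column name -> header used by WDI-style CSV exports.
WDI_SCHEMA: dict[str, str] = {
    "country": "country",
    "year": "year",
    "income_group": "income_group",
    "pov": "pov_headcount_190",
    "phe_pc": "gov_health_exp_pc_ppp2017",
    "gdp_pc": "gdp_pc_ppp2017",
    "gini": "gini",
    "population": "population",
    "ext_pc": "ext_health_exp_pc_ppp2017",
}

REQUIRED_FIELDS = (
    "country",
    "year",
    "income_group",
    "pov",
    "phe_pc",
    "gdp_pc",
    "gini",
    "population",
)

#: Columns an estimation row must have for the regression (population is
#: only needed later, when benchmarks are computed).
MODEL_COLUMNS = ("log_pov", "log_phe_lag", "log_gdp", "gini")


@dataclass
class Panel:
    """A validated country-year panel.

    ``records`` holds one row per (country, year) with canonical column
    names (``country, year, income_group, pov, phe_pc, gdp_pc, gini,
    population`` and optionally ``ext_pc``).  ``rejections`` records every
    dropped input row together with a reason code.
    """

    records: pd.DataFrame
    year_min: int = 2000
    metadata: dict = field(default_factory=dict)
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "country", "year", "reason"])
    )

    @property
    def countries(self) -> list[str]:
        return sorted(self.records["country"].unique())

    def __len__(self) -> int:  # number of retained records
        return len(self.records)


def _check_row(row: pd.Series, have_ext: bool) -> str | None:
    """Return a rejection reason for one raw row, or None if valid."""
    for name in REQUIRED_FIELDS:
        if pd.isna(row[name]):
            return f"missing {name}"
    if row["income_group"] not in INCOME_GROUPS:
        return f"unknown income group {row['income_group']!r}"
    if row["pov"] <= 0:
        return "nonpositive poverty (log undefined)"
    if row["pov"] > 1:
        return "poverty headcount ratio > 1"
    if row["phe_pc"] <= 0:
        return "nonpositive health spending (log undefined)"
    if row["gdp_pc"] <= 0:
        return "nonpositive GDP per capita"
    if not 0 <= row["gini"] <= 100:
        return "Gini index outside [0, 100]"
    if row["population"] <= 0:
        return "nonpositive population"
    if have_ext and not pd.isna(row.get("ext_pc")) and row["ext_pc"] < 0:
        return "negative external health spending"
    return None


def validate_panel(
    raw: pd.DataFrame,
    year_min: int = 2000,
    year_max: int | None = None,
    source: str = "<memory>",
) -> Panel:
    """Validate a canonical-column DataFrame into a :class:`Panel`.

    Rows violating range invariants are excluded and logged with a reason
    code, never coerced.  Duplicate (country, year) keys among valid rows
    are a hard error: they indicate a malformed extract rather than a data
    gap.
    """
    df = raw.copy().reset_index(drop=True)
    have_ext = "ext_pc" in df.columns

    numeric = ["year", "pov", "phe_pc", "gdp_pc", "gini", "population"]
    if have_ext:
        numeric.append("ext_pc")
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reasons: list[tuple[int, object, object, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        reason = _check_row(row, have_ext)
        if reason is None and not pd.isna(row["year"]):
            if row["year"] < year_min:
                reason = f"year before window start {year_min}"
            elif year_max is not None and row["year"] > year_max:
                reason = f"year after window end {year_max}"
        if reason is not None:
            keep[i] = False
            reasons.append((i, row.get("country"), row.get("year"), reason))
            logger.info("panel row %d rejected: %s", i, reason)

    records = df.loc[keep].copy()
    records["year"] = records["year"].astype(int)

    dup = records.duplicated(subset=["country", "year"], keep=False)
    if dup.any():
        keys = records.loc[dup, ["country", "year"]].drop_duplicates()
        pairs = ", ".join(f"({c}, {y})" for c, y in keys.itertuples(index=False))
        raise ValueError(f"duplicate (country, year) keys in panel: {pairs}")

    multi = records.groupby("country")["income_group"].nunique()
    varying = multi[multi > 1]
    if len(varying):
        raise ValueError(
            "income_group must be time-invariant within a country; varies for: "
            + ", ".join(varying.index)
        )

    records = records.sort_values(["country", "year"]).reset_index(drop=True)
    rejections = pd.DataFrame(reasons, columns=["row", "country", "year", "reason"])
    meta = {"source": source, "year_min": year_min, "year_max": year_max,
            "n_input_rows": len(df), "n_rejected": len(rejections)}
    return Panel(records=records, year_min=year_min, metadata=meta, rejections=rejections)


def load_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    year_min: int = 2000,
    year_max: int | None = None,
) -> Panel:
    """Read a long-format country-year CSV and validate it.

    Parameters
    ----------
    path:
        CSV file (UTF-8, header row), one row per country-year.
    schema:
        Mapping from logical names (``country, year, income_group, pov,
        phe_pc, gdp_pc, gini, population`` and optional ``ext_pc``) to the
        column headers actually present in the file.  Defaults to the
        WDI-style headers in :data:`WDI_SCHEMA`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or WDI_SCHEMA)
    raw = pd.read_csv(path, comment="#")

    missing = [v for k, v in schema.items() if k in REQUIRED_FIELDS and v not in raw.columns]
    if missing:
        raise ValueError(f"mapped columns missing from {path.name}: {missing}")

    rename = {v: k for k, v in schema.items() if v in raw.columns}
    df = raw[list(rename)].rename(columns=rename)
    return validate_panel(df, year_min=year_min, year_max=year_max, source=str(path))


def build_estimation_rows(
    panel: Panel,
    lag: int = 1,
    spending: str = "government",
) -> pd.DataFrame:
    """Construct log-transformed estimation rows with lagged spending.

    One row is produced per (country, year) whose lag-source record —
    the same country exactly ``lag`` years earlier — exists in the
    validated panel.  ``log_phe_lag`` is ln of government spending per
    capita at t-lag, optionally with external health spending added
    (``spending="government_plus_external"``).
    """
    if lag <= 0:
        raise ValueError(f"lag must be a positive integer, got {lag}")
    if spending not in ("government", "government_plus_external"):
        raise ValueError(f"unknown spending variant {spending!r}")

    records = panel.records
    src_cols = ["country", "year", "phe_pc"]
    if spending == "government_plus_external":
        if "ext_pc" not in records.columns or records["ext_pc"].isna().all():
            raise ValueError(
                "spending='government_plus_external' requires ext_pc data on the panel"
            )
        src_cols.append("ext_pc")

    src = records[src_cols].copy()
    src["year"] = src["year"] + lag
    if spending == "government_plus_external":
        src["spend_lag"] = src["phe_pc"] + src["ext_pc"]
        src = src.dropna(subset=["spend_lag"])
    else:
        src["spend_lag"] = src["phe_pc"]
    src = src[["country", "year", "spend_lag"]]

    rows = records.merge(src, on=["country", "year"], how="inner")
    rows["log_pov"] = np.log(rows["pov"])
    rows["log_phe_lag"] = np.log(rows["spend_lag"])
    rows["log_gdp"] = np.log(rows["gdp_pc"])

    out_cols = [
        "country", "year", "income_group", "log_pov", "log_phe_lag", "log_gdp",
        "gini", "population", "pov", "phe_pc", "gdp_pc", "spend_lag",
    ]
    rows = rows[out_cols].sort_values(["country", "year"]).reset_index(drop=True)
    return rows


def filter_complete(
    rows: pd.DataFrame,
    min_years: int = 2,
    income_groups: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Apply the sample rule: keep countries with >= ``min_years`` complete rows.

    A row is complete when every model variable (log poverty, lagged log
    spending, log GDP, Gini) is present.  Optionally restricts to a set of
    income groups first.  The per-country year counts of the retained
    sample are attached as ``result.attrs["country_year_counts"]``.
    """
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    out = rows.dropna(subset=list(MODEL_COLUMNS))
    if income_groups is not None:
        out = out[out["income_group"].isin(set(income_groups))]
    counts = out.groupby("country")["year"].size()
    keep = counts[counts >= min_years].index
    out = out[out["country"].isin(keep)]
    if out.empty:
        raise ValueError(
            "no countries satisfy the completeness rule "
            f"(min_years={min_years}, income_groups={income_groups}); "
            f"candidate counts: {counts.to_dict()}"
        )
    out = out.sort_values(["country", "year"]).reset_index(drop=True)
    out.attrs["country_year_counts"] = counts[counts >= min_years].to_dict()
    return out


def year_counts(rows: pd.DataFrame) -> pd.Series:
    """Number of complete estimation rows per country."""
    return rows.groupby("country")["year"].size()


def summarize_panel(rows: pd.DataFrame, at: str = "last_year") -> pd.DataFrame:
    """Summary statistics on each country's first or last available row.

    Returns one row per income group plus an ``all`` row with the country
    count and the group means of poverty headcount, lagged spending (in
    dollar levels), GDP per capita and Gini index.
    """
    if at not in ("first_year", "last_year"):
        raise ValueError(f"at must be 'first_year' or 'last_year', got {at!r}")
    if rows.empty:
        raise ValueError("cannot summarize an empty row collection")

    picker = "idxmax" if at == "last_year" else "idxmin"
    idx = rows.groupby("country")["year"].agg(picker)
    snap = rows.loc[idx].copy()

    def _stats(df: pd.DataFrame) -> dict:
        return {
            "n_countries": len(df),
            "mean_pov": df["pov"].mean(),
            "mean_phe_lag": df["spend_lag"].mean(),
            "mean_gdp_pc": df["gdp_pc"].mean(),
            "mean_gini": df["gini"].mean(),
        }

    table = {"all": _stats(snap)}
    for group, df in snap.groupby("income_group"):
        table[str(group)] = _stats(df)
    out = pd.DataFrame(table).T
    out.index.name = "group"
    out["n_countries"] = out["n_countries"].astype(int)
    return out


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write the validated records (and a sibling rejection log) to CSV."""
    path = Path(path)
    panel.records.to_csv(path, index=False)
    rej = path.with_name(path.stem + "_rejections.csv")
    panel.rejections.to_csv(rej, index=False)
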