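"""Cost per poverty case averted for social protection and labor (SPL) programs.

From ASPIRE-style country indicators — program coverage, average transfer
per beneficiary, and the poverty-headcount reduction attributed to SPL
programs — the annual program outlay is coverage * population * annualized
transfer, and the cases averted are the headcount reduction times
population (applied to the pre-transfer headcount when the reduction is
expressed in relative terms).  Their ratio is the SPL analogue of the
health-sector poverty reduction benchmark, and population cancels out of
it exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Factor converting a per-period transfer into a yearly amount.
ANNUALIZATION = {"daily": 365.0, "monthly": 12.0, "yearly": 1.0}

SPL_SCHEMA = {
    "country": "country",
    "income_group": "income_group",
    "coverage": "spl_coverage",
    "transfer_pc": "spl_transfer_pc",
    "pov_reduction": "spl_pov_reduction",
    "pre_transfer_pov": "pre_transfer_pov",
    "population": "population",
    "year": "year",
}


@dataclass(frozen=True)
class SPLRecord:
    """One country's SPL indicators at its last available year.

    ``transfer_pc`` is the average transfer per beneficiary per
    ``transfer_period``; ``pov_reduction`` is either a relative fraction of
    the pre-transfer headcount (``reduction_kind="relative_percent"``, e.g.
    0.10 for a 10% reduction) or an absolute headcount-ratio change
    (``"percentage_points"``, as a fraction of the population).
    """

    country_id: str
    income_group: str
    coverage: float
    transfer_pc: float
    pov_reduction: float
    population: float
    transfer_period: str = "yearly"
    reduction_kind: str = "relative_percent"
    pre_transfer_pov: float | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ValueError(f"{self.country_id}: coverage must be in [0, 1]")
        if self.transfer_pc < 0:
            raise ValueError(f"{self.country_id}: transfer amount must be non-negative")
        if self.pov_reduction < 0:
            raise ValueError(f"{self.country_id}: poverty reduction must be non-negative")
        if self.population <= 0:
            raise ValueError(f"{self.country_id}: population must be positive")
        if self.transfer_period not in ANNUALIZATION:
            raise ValueError(f"{self.country_id}: unknown transfer period {self.transfer_period!r}")
        if self.reduction_kind not in ("relative_percent", "percentage_points"):
            raise ValueError(f"{self.country_id}: unknown reduction kind {self.reduction_kind!r}")
        if self.reduction_kind == "relative_percent":
            if self.pre_transfer_pov is None:
                raise ValueError(
                    f"{self.country_id}: relative_percent reduction requires pre_transfer_pov"
                )
            if not 0 < self.pre_transfer_pov <= 1:
                raise ValueError(f"{self.country_id}: pre_transfer_pov must be in (0, 1]")


@dataclass
class SPLCostResult:
    """Per-country costs and their cross-country distribution by group."""

    per_country: pd.Series
    summaries: pd.DataFrame
    n_undefined: int


def spl_cost_per_case(record: SPLRecord) -> float:
    """Dollars of annual SPL transfers per poverty case averted.

    Annual cost = coverage * population * annualized transfer; cases
    averted = reduction * pre-transfer headcount * population (relative
    form) or reduction * population (percentage-point form).  Returns NaN
    (flagged undefined) when no cases are averted.
    """
    annual_transfer = record.transfer_pc * ANNUALIZATION[record.transfer_period]
    cost = record.coverage * record.population * annual_transfer
    if record.reduction_kind == "relative_percent":
        cases = record.pov_reduction * record.pre_transfer_pov * record.population
    else:
        cases = record.pov_reduction * record.population
    if cases == 0:
        logger.info("undefined SPL cost for %s: zero cases averted", record.country_id)
        return math.nan
    return cost / cases


def load_spl_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    transfer_period: str = "yearly",
    reduction_kind: str = "relative_percent",
) -> list[SPLRecord]:
    """Read an ASPIRE-style CSV into SPL records.

    The transfer periodicity and the meaning of the reduction indicator
    vary between extracts and are not inferable from the numbers, so they
    must be declared (per file, or per row via ``transfer_period`` /
    ``reduction_kind`` columns).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or SPL_SCHEMA)
    raw = pd.read_csv(path, comment="#")
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    df = raw.rename(columns=rename)

    records = []
    for _, r in df.iterrows():
        records.append(
            SPLRecord(
                country_id=str(r["country"]),
                income_group=str(r["income_group"]),
                coverage=float(r["coverage"]),
                transfer_pc=float(r["transfer_pc"]),
                pov_reduction=float(r["pov_reduction"]),
                population=float(r["population"]),
                transfer_period=str(r.get("transfer_period", transfer_period)),
                reduction_kind=str(r.get("reduction_kind", reduction_kind)),
                pre_transfer_pov=(
                    float(r["pre_transfer_pov"])
                    if "pre_transfer_pov" in df.columns and pd.notna(r["pre_transfer_pov"])
                    else None
                ),
                year=int(r["year"]) if "year" in df.columns and pd.notna(r["year"]) else None,
            )
        )
    return records


def cost_table(records: Sequence[SPLRecord]) -> pd.DataFrame:
    """Per-country cost table (country, income group, cost per case)."""
    return pd.DataFrame(
        {
            "country": [r.country_id for r in records],
            "income_group": [r.income_group for r in records],
            "cost_per_case": [spl_cost_per_case(r) for r in records],
        }
    ).set_index("country")


def summarize_spl(
    costs: Mapping[str, float],
    groups: Mapping[str, str],
) -> SPLCostResult:
    """Distribution summaries (10th/50th percentile, mean, 90th percentile).

    Countries with an undefined (NaN) cost are excluded with a reported
    count; empty groups are omitted with a warning.  Percentiles use the
    same inclusive linear-interpolation definition as the health-sector
    benchmark module.
    """
    per_country = pd.Series(dict(costs), name="cost_per_case", dtype=float)
    grp = pd.Series(dict(groups)).reindex(per_country.index)
    defined = per_country.dropna()
    n_undefined = int(per_country.isna().sum())
    if n_undefined:
        logger.warning("excluding %d countries with undefined SPL cost", n_undefined)

    def _stats(vals: np.ndarray) -> dict:
        return {
            "p10": float(np.percentile(vals, 10)),
            "median": float(np.percentile(vals, 50)),
            "mean": float(vals.mean()),
            "p90": float(np.percentile(vals, 90)),
            "n_countries": int(len(vals)),
        }

    rows = {}
    if len(defined):
        rows["all"] = _stats(defined.to_numpy())
    for g in sorted(grp.dropna().unique()):
        vals = defined[grp.reindex(defined.index) == g]
        if len(vals) == 0:
            logger.warning("SPL group %r has no defined costs; omitted", g)
            continue
        rows[g] = _stats(vals.to_numpy())
    if not rows:
        raise ValueError("no defined SPL costs in any group")

    summaries = pd.DataFrame(rows).T
    summaries.index.name = "group"
    summaries["n_countries"] = summaries["n_countries"].astype(int)
    return SPLCostResult(per_country=per_country, summaries=summaries, n_undefined=n_undefined)
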