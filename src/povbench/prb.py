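"""Poverty reduction benchmarks: dollars of health spending per poverty case averted.

Given an elasticity beta of the poverty headcount with respect to lagged
government health spending, a one-percent spending increase in a country
with headcount ratio p and population N changes the number of poor by
(beta/100) * p * N, at a budget cost of (1/100) * phe_pc * N.  The ratio —
budget increment over cases averted — is the country's poverty reduction
benchmark (PRB), and collapses algebraically to phe_pc / (-beta * p):
independent of population and of the size of the hypothetical increase.

Uncertainty ranges come from Monte-Carlo draws of the coefficient vector:
for each draw the cross-country average PRB is formed, and the median and
2.5/97.5 percentiles are taken across draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountrySnapshot:
    """A country's last complete year: headcount ratio, spending, population."""

    country_id: str
    income_group: str
    p: float
    phe_pc: float
    N: float
    year: int

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"{self.country_id}: poverty headcount ratio must be in (0, 1]")
        if self.phe_pc <= 0:
            raise ValueError(f"{self.country_id}: spending per capita must be positive")
        if self.N <= 0:
            raise ValueError(f"{self.country_id}: population must be positive")


@dataclass
class PRBSummary:
    """Group-level PRB distribution over Monte-Carlo iterations."""

    group: str
    median: float
    mean: float
    lower_ur: float
    upper_ur: float
    n_iterations: int
    n_countries: int
    n_dropped_draws: int
    prb_at_mean_beta: float
    per_country_point: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "lower_ur": self.lower_ur,
            "median": self.median,
            "mean": self.mean,
            "upper_ur": self.upper_ur,
            "n_iterations": self.n_iterations,
            "n_countries": self.n_countries,
            "n_dropped_draws": self.n_dropped_draws,
            "prb_at_mean_beta": self.prb_at_mean_beta,
        }


def country_snapshots(records: pd.DataFrame) -> list[CountrySnapshot]:
    """Take each country's last year with poverty, spending and population."""
    ok = records.dropna(subset=["pov", "phe_pc", "population"])
    idx = ok.groupby("country")["year"].idxmax()
    snaps = []
    for _, r in ok.loc[idx].iterrows():
        snaps.append(
            CountrySnapshot(
                country_id=str(r["country"]),
                income_group=str(r["income_group"]),
                p=float(r["pov"]),
                phe_pc=float(r["phe_pc"]),
                N=float(r["population"]),
                year=int(r["year"]),
            )
        )
    return snaps


def poverty_cases_averted(beta: float, p: float, N: float, pct: float = 1.0) -> float:
    """People moved out of poverty by a pct-percent spending increase.

    Positive when beta < 0 (spending reduces poverty); negative when the
    elasticity is positive — the sign is handled by the caller.
    """
    if not 0 < p <= 1:
        raise ValueError("poverty headcount ratio must be in (0, 1]")
    if N <= 0:
        raise ValueError("population must be positive")
    return -(beta * pct / 100.0) * p * N


def budget_increment(phe_pc: float, N: float, pct: float = 1.0) -> float:
    """Dollar cost of raising per-capita spending phe_pc by pct percent."""
    if phe_pc <= 0:
        raise ValueError("spending per capita must be positive")
    if N <= 0:
        raise ValueError("population must be positive")
    return (pct / 100.0) * phe_pc * N


def country_prb(beta: float, snapshot: CountrySnapshot, pct: float = 1.0) -> float:
    """Dollar cost per poverty case averted for one country.

    Returns NaN (flagged undefined) when beta >= 0: a non-negative
    elasticity averts no poverty, so no finite price exists — never a
    negative one.
    """
    if beta >= 0:
        logger.info(
            "undefined PRB for %s: elasticity %.4g >= 0", snapshot.country_id, beta
        )
        return math.nan
    cases = poverty_cases_averted(beta, snapshot.p, snapshot.N, pct)
    cost = budget_increment(snapshot.phe_pc, snapshot.N, pct)
    return cost / cases


def aggregate_prb(
    beta_draws: Sequence[float] | np.ndarray,
    snapshots: Sequence[CountrySnapshot],
    group: str = "all",
    point_beta: float | None = None,
    population_weighted: bool = False,
) -> PRBSummary:
    """Summarize the PRB distribution across Monte-Carlo elasticity draws.

    For each draw the (by default unweighted) mean PRB across countries is
    computed; the median, mean and 2.5/97.5 percentiles of those
    iteration-means form the summary.  Draws with beta >= 0 are dropped
    and counted — an undefined price cannot enter an average.  Percentiles
    use inclusive linear interpolation (numpy's default), making the
    uncertainty ranges bit-reproducible.
    """
    betas = np.asarray(beta_draws, dtype=float)
    if betas.ndim != 1 or betas.size < 1:
        raise ValueError("beta_draws must be a non-empty 1-D array")
    if not snapshots:
        raise ValueError(f"no country snapshots in group {group!r}")

    phe = np.array([s.phe_pc for s in snapshots])
    p = np.array([s.p for s in snapshots])
    if population_weighted:
        w = np.array([s.N for s in snapshots])
        w = w / w.sum()
    else:
        w = np.full(len(snapshots), 1.0 / len(snapshots))

    valid = betas < 0
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("dropping %d draws with beta >= 0", n_dropped)
    if not valid.any():
        raise ValueError("all coefficient draws are >= 0; PRB undefined everywhere")
    neg = betas[valid]

    # per-iteration cross-country average of phe_c / (-beta_i * p_c)
    per_country_k = phe / p  # shape (n_countries,)
    iteration_means = (per_country_k * w).sum() / (-neg)

    if point_beta is None:
        point_beta = float(np.median(neg))
    per_country_point = {
        s.country_id: country_prb(point_beta, s) for s in snapshots
    }
    prb_at_mean_beta = float((per_country_k * w).sum() / (-neg.mean()))

    return PRBSummary(
        group=group,
        median=float(np.percentile(iteration_means, 50)),
        mean=float(iteration_means.mean()),
        lower_ur=float(np.percentile(iteration_means, 2.5)),
        upper_ur=float(np.percentile(iteration_means, 97.5)),
        n_iterations=int(valid.sum()),
        n_countries=len(snapshots),
        n_dropped_draws=n_dropped,
        prb_at_mean_beta=prb_at_mean_beta,
        per_country_point=per_country_point,
    )


def prb_table(summaries: Sequence[PRBSummary]) -> pd.DataFrame:
    """Stack group summaries into a benchmark table."""
    return pd.DataFrame([s.to_dict() for s in summaries]).set_index("group")
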