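"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from povbench.panel import validate_panel


def make_records(entries: list[dict]) -> pd.DataFrame:
    """Build a canonical raw panel frame, filling sensible defaults."""
    defaults = dict(
        income_group="low", pov=0.3, phe_pc=25.0, gdp_pc=1500.0,
        gini=40.0, population=1e7,
    )
    return pd.DataFrame([{**defaults, **e} for e in entries])


def random_estimation_rows(
    rng: np.random.Generator, n_countries: int = 6, n_years: int = 4
) -> pd.DataFrame:
    """Random prepared estimation rows (no structure between y and X)."""
    recs = []
    for c in range(n_countries):
        group = "low" if c % 2 else "lower_middle"
        for t in range(n_years):
            recs.append(
                dict(
                    country=f"C{c:02d}", year=2000 + t, income_group=group,
                    log_pov=rng.normal(-1.5, 0.5),
                    log_phe_lag=rng.normal(3.0, 1.0),
                    log_gdp=rng.normal(8.0, 0.5),
                    gini=rng.uniform(30, 50),
                    population=float(rng.integers(1, 100)) * 1e6,
                )
            )
    df = pd.DataFrame(recs)
    df["pov"] = np.exp(df["log_pov"])
    df["phe_pc"] = np.exp(df["log_phe_lag"])
    return df


def lsdv_oracle(rows: pd.DataFrame, controls: tuple[str, ...] = ("log_gdp", "gini")):
    """Brute-force dummy-variable OLS (the fixed-effects oracle).

    Fits log_pov on the slope regressors plus one explicit dummy per
    country with statsmodels and returns (params, se, r_squared) for the
    slope coefficients only.
    """
    import statsmodels.formula.api as smf

    terms = ["log_phe_lag", *controls, "C(country)"]
    res = smf.ols("log_pov ~ " + " + ".join(terms), data=rows).fit()
    names = ["log_phe_lag", *controls]
    return (
        pd.Series({k: res.params[k] for k in names}),
        pd.Series({k: res.bse[k] for k in names}),
        float(res.rsquared),
    )


def interpolated_percentile(values, q: float) -> float:
    """Sort-based percentile with inclusive linear interpolation, by hand."""
    s = np.sort(np.asarray(values, dtype=float))
    idx = q / 100.0 * (len(s) - 1)
    lo = int(np.floor(idx))
    hi = min(lo + 1, len(s) - 1)
    frac = idx - lo
    return float(s[lo] * (1 - frac) + s[hi] * frac)


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """Two countries x three years, all rows valid."""
    return make_records(
        [
            dict(country="AAA", year=y, pov=0.4 - 0.02 * i, phe_pc=20 + 2 * i)
            for i, y in enumerate((2005, 2006, 2007))
        ]
        + [
            dict(country="BBB", year=y, income_group="lower_middle",
                 pov=0.2 - 0.01 * i, phe_pc=100 + 5 * i, gdp_pc=5000.0)
            for i, y in enumerate((2005, 2006, 2007))
        ]
    )


@pytest.fixture
def toy_panel(toy_records):
    return validate_panel(toy_records)
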