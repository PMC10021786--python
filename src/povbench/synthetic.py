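"""Synthetic country-year panels and SPL tables with known ground truth.

The panel generator draws data from the same log-log fixed-effects model
the estimator fits,

    ln pov_{c,t} = alpha_c + beta * ln phe_{c,t-1}
                   + gamma_gdp * ln gdp_{c,t} + gamma_gini * gini_{c,t}
                   + eps_{c,t},       eps ~ iid Normal(0, noise_sd^2),

with geometric (log-space) spending and GDP paths that drift upward and
carry mildly autocorrelated innovations, so the within-country variation
the estimator relies on is realistic.  Because the model is linear in
logs, nothing bounds pov above by 1: a configuration whose draws produce
pov > 1 is rejected with a hard error rather than silently truncated,
which forces configurations into the regime where the log-linear model is
a sensible description.

Default magnitudes follow the sample frame of low/lower-middle-income
country panels: 20 + 43 countries, years 2001-2019 (estimation rows
2002-2019), spending around $26 vs $134 per capita, GDP around $1.8k vs
$5.9k.  Poverty levels are centred below observed country means (about
0.22 and 0.07) so that country effects and noise of realistic size keep
every draw strictly below a headcount ratio of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import Panel
from .spl import SPLRecord


@dataclass(frozen=True)
class PathProcess:
    """Geometric path: level log-mean/log-sd across countries, annual log
    drift, and AR(1) log innovations (autocorrelation ``ar``, step sd
    ``step_sd``)."""

    log_mean: float
    log_sd: float = 0.3
    drift: float = 0.0
    step_sd: float = 0.08
    ar: float = 0.6


@dataclass(frozen=True)
class LevelProcess:
    """Stationary level path (used for the Gini index): cross-country
    mean/sd plus an AR(1) wiggle in levels."""

    mean: float
    sd: float = 5.0
    step_sd: float = 0.5
    ar: float = 0.9


def _default_phe() -> dict:
    return {
        "low": PathProcess(log_mean=math.log(26.0), drift=0.03, step_sd=0.12),
        "lower_middle": PathProcess(log_mean=math.log(134.0), drift=0.03, step_sd=0.12),
    }


def _default_gdp() -> dict:
    return {
        "low": PathProcess(log_mean=math.log(1775.0), drift=0.02),
        "lower_middle": PathProcess(log_mean=math.log(5910.0), drift=0.02),
    }


def _default_gini() -> dict:
    return {"low": LevelProcess(mean=40.0), "lower_middle": LevelProcess(mean=40.0)}


def _default_population() -> dict:
    # log persons: medians around 20M (low) and 30M (lower-middle)
    return {"low": (16.8, 1.0), "lower_middle": (17.2, 1.0)}


@dataclass
class SyntheticPanelConfig:
    """Generative parameters of the panel data-generating process."""

    n_countries_by_group: dict = field(
        default_factory=lambda: {"low": 20, "lower_middle": 43}
    )
    year_start: int = 2001
    year_end: int = 2019
    beta_true: float = -0.5
    gamma_gdp: float = -0.3
    gamma_gini: float = 0.02
    alpha_mean: float = 1.56
    alpha_sd: float = 0.2
    phe_process: dict = field(default_factory=_default_phe)
    gdp_process: dict = field(default_factory=_default_gdp)
    gini_process: dict = field(default_factory=_default_gini)
    population_dist: dict = field(default_factory=_default_population)
    noise_sd: float = 0.2
    missing_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.year_end <= self.year_start:
            raise ValueError("year_end must exceed year_start")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.alpha_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for g, n in self.n_countries_by_group.items():
            if n < 1:
                raise ValueError(f"need at least one country in group {g!r}")
            for proc in (self.phe_process, self.gdp_process, self.gini_process,
                         self.population_dist):
                if g not in proc:
                    raise ValueError(f"no process parameters for group {g!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phe_process"] = {g: asdict(p) for g, p in self.phe_process.items()}
        d["gdp_process"] = {g: asdict(p) for g, p in self.gdp_process.items()}
        d["gini_process"] = {g: asdict(p) for g, p in self.gini_process.items()}
        return d


def _ar1_paths(rng: np.random.Generator, n: int, t: int, ar: float, step_sd: float) -> np.ndarray:
    """Stationary AR(1) paths, shape (n, t)."""
    out = np.empty((n, t))
    stat_sd = step_sd / math.sqrt(1 - ar**2) if ar < 1 else step_sd
    out[:, 0] = rng.normal(0.0, stat_sd, size=n)
    for j in range(1, t):
        out[:, j] = ar * out[:, j - 1] + rng.normal(0.0, step_sd, size=n)
    return out


def generate_panel(config: SyntheticPanelConfig) -> tuple[Panel, dict]:
    """Simulate a panel from the generative model; return it with its truth record.

    The truth record stores every parameter, the per-country fixed effects,
    and the realized last-year snapshots (after missingness).  The returned
    records are already in the canonical validated-panel form and
    round-trip unchanged through the panel I/O layer.

    One seed drives three independent substreams (country structure,
    covariate paths + missingness, regression noise), so enlarging one
    stream never perturbs the others.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_path, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    # paths start one year early so the lagged regressor is defined for the
    # first emitted year
    years = np.arange(config.year_start - 1, config.year_end + 1)
    t = len(years)

    frames = []
    alphas: dict[str, float] = {}
    prefix = {"low": "LIC", "lower_middle": "LMC", "upper_middle": "UMC"}
    for group in sorted(config.n_countries_by_group):
        n = config.n_countries_by_group[group]
        names = [f"{prefix.get(group, group.upper())}{i + 1:03d}" for i in range(n)]
        phe_p: PathProcess = config.phe_process[group]
        gdp_p: PathProcess = config.gdp_process[group]
        gini_p: LevelProcess = config.gini_process[group]
        pop_mu, pop_sd = config.population_dist[group]

        alpha = rng_struct.normal(config.alpha_mean, config.alpha_sd, size=n)
        phe_off = rng_struct.normal(0.0, phe_p.log_sd, size=n)
        gdp_off = rng_struct.normal(0.0, gdp_p.log_sd, size=n)
        gini_off = rng_struct.normal(0.0, gini_p.sd, size=n)
        pop = np.exp(rng_struct.normal(pop_mu, pop_sd, size=n))

        trend = years - config.year_start
        log_phe = (
            phe_p.log_mean + phe_off[:, None] + phe_p.drift * trend[None, :]
            + _ar1_paths(rng_path, n, t, phe_p.ar, phe_p.step_sd)
        )
        log_gdp = (
            gdp_p.log_mean + gdp_off[:, None] + gdp_p.drift * trend[None, :]
            + _ar1_paths(rng_path, n, t, gdp_p.ar, gdp_p.step_sd)
        )
        gini = (
            gini_p.mean + gini_off[:, None]
            + _ar1_paths(rng_path, n, t, gini_p.ar, gini_p.step_sd)
        )

        eps = rng_noise.normal(0.0, config.noise_sd, size=(n, t)) if config.noise_sd > 0 \
            else np.zeros((n, t))
        log_pov = np.full((n, t), np.nan)
        log_pov[:, 1:] = (
            alpha[:, None]
            + config.beta_true * log_phe[:, :-1]
            + config.gamma_gdp * log_gdp[:, 1:]
            + config.gamma_gini * gini[:, 1:]
            + eps[:, 1:]
        )
        pov = np.exp(log_pov)

        bad = np.argwhere(pov > 1.0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"configuration produced poverty headcount > 1: country "
                f"{names[i]} year {years[j]} pov={pov[i, j]:.3f}; the log-linear "
                "model does not bound poverty above — use a lower poverty level "
                "or less dispersion"
            )

        for i, name in enumerate(names):
            alphas[name] = float(alpha[i])
            frames.append(
                pd.DataFrame(
                    {
                        "country": name,
                        "year": years[1:],
                        "income_group": group,
                        "pov": pov[i, 1:],
                        "phe_pc": np.exp(log_phe[i, 1:]),
                        "gdp_pc": np.exp(log_gdp[i, 1:]),
                        "gini": gini[i, 1:],
                        "population": pop[i],
                    }
                )
            )

    records = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        keep = rng_path.random(len(records)) >= config.missing_rate
        records = records[keep]
    records = records.sort_values(["country", "year"]).reset_index(drop=True)

    snapshots = records.loc[records.groupby("country")["year"].idxmax()]
    truth = {
        "config": config.to_dict(),
        "beta_true": config.beta_true,
        "gamma_gdp": config.gamma_gdp,
        "gamma_gini": config.gamma_gini,
        "alpha": alphas,
        "last_year_snapshots": snapshots[
            ["country", "year", "income_group", "pov", "phe_pc", "population"]
        ].to_dict(orient="records"),
    }
    panel = Panel(
        records=records,
        year_min=config.year_start,
        metadata={"source": "synthetic", "seed": config.seed,
                  "n_rejected": 0, "n_input_rows": len(records)},
    )
    return panel, truth


def generate_spl_table(
    n_countries_by_group: dict | None = None,
    seed: int = 0,
    ranges: dict | None = None,
) -> tuple[list[SPLRecord], pd.Series]:
    """Simulate an ASPIRE-style SPL indicator table with known true costs.

    Coverage, yearly transfer, relative poverty reduction and pre-transfer
    headcount are drawn uniformly from the configured ranges; the true
    cost per case averted (coverage * transfer / (reduction * pre-transfer
    headcount), population-free) is returned alongside for round-trip
    tests.  The 33-country default mirrors the scale of ASPIRE coverage of
    low- and lower-middle-income countries.
    """
    n_by_group = dict(n_countries_by_group or {"low": 10, "lower_middle": 23})
    r = {
        "coverage": (0.05, 0.6),
        "transfer_pc": (20.0, 400.0),
        "pov_reduction": (0.02, 0.3),
        "pre_transfer_pov": (0.08, 0.6),
        "population_log": (16.5, 1.0),
        **(ranges or {}),
    }
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    records: list[SPLRecord] = []
    truth = {}
    prefix = {"low": "LIC", "lower_middle": "LMC"}
    for group in sorted(n_by_group):
        for i in range(n_by_group[group]):
            name = f"SPL-{prefix.get(group, group.upper())}{i + 1:03d}"
            coverage = rng.uniform(*r["coverage"])
            transfer = rng.uniform(*r["transfer_pc"])
            reduction = rng.uniform(*r["pov_reduction"])
            pre_pov = rng.uniform(*r["pre_transfer_pov"])
            pop = float(np.exp(rng.normal(*r["population_log"])))
            records.append(
                SPLRecord(
                    country_id=name,
                    income_group=group,
                    coverage=coverage,
                    transfer_pc=transfer,
                    pov_reduction=reduction,
                    reduction_kind="relative_percent",
                    pre_transfer_pov=pre_pov,
                    transfer_period="yearly",
                    population=pop,
                    year=2019,
                )
            )
            truth[name] = coverage * transfer / (reduction * pre_pov)
    return records, pd.Series(truth, name="true_cost_per_case")


def spl_records_to_frame(records: list[SPLRecord]) -> pd.DataFrame:
    """Flatten SPL records to the CSV schema used by the I/O layer."""
    return pd.DataFrame(
        {
            "country": [x.country_id for x in records],
            "income_group": [x.income_group for x in records],
            "spl_coverage": [x.coverage for x in records],
            "spl_transfer_pc": [x.transfer_pc for x in records],
            "transfer_period": [x.transfer_period for x in records],
            "spl_pov_reduction": [x.pov_reduction for x in records],
            "reduction_kind": [x.reduction_kind for x in records],
            "pre_transfer_pov": [x.pre_transfer_pov for x in records],
            "population": [x.population for x in records],
            "year": [x.year for x in records],
        }
    )
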