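"""Log-log country-fixed-effects regression of poverty on lagged health spending.

The model is

    ln(Pov_{c,t}) = alpha_c + beta * ln(PHE_{c,t-k}) + gamma' X_{c,t} + eps_{c,t}

where alpha_c are country fixed effects, PHE is per-capita government
health expenditure and X holds the controls (log GDP per capita, Gini
index).  beta is the elasticity of the poverty headcount with respect to
lagged spending.  The within (demeaning) transformation is used to absorb
the fixed effects; the explicit-dummy (LSDV) formulation is numerically
identical and serves as the correctness oracle in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SLOPE_OF_INTEREST = "log_phe_lag"


@dataclass(frozen=True)
class RegressionSpec:
    """One regression specification of the ladder.

    The three canonical columns of the specification ladder are
    (FE=False, controls=()), (FE=True, controls=()) and
    (FE=True, controls=("log_gdp", "gini")).
    """

    include_fixed_effects: bool = True
    controls: tuple[str, ...] = ("log_gdp", "gini")
    lag: int = 1
    spending: str = "government"
    income_groups: tuple[str, ...] | None = None
    vcov_kind: str = "classical"  # or "cluster_by_country"

    def __post_init__(self) -> None:
        if self.vcov_kind not in ("classical", "cluster_by_country"):
            raise ValueError(f"unknown vcov_kind {self.vcov_kind!r}")
        object.__setattr__(self, "controls", tuple(self.controls))
        if self.income_groups is not None:
            object.__setattr__(self, "income_groups", tuple(self.income_groups))


@dataclass
class FitResult:
    """Slope coefficients, their covariance, and fit diagnostics.

    ``params``/``se``/``vcov`` cover the slope coefficients only (the
    elasticity on lagged log spending plus any controls); fixed effects or
    the pooled intercept are reported separately.
    """

    params: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    r_squared: float
    n_obs: int
    n_countries: int
    df_resid: int
    spec: RegressionSpec
    fixed_effects: pd.Series | None = None
    intercept: float | None = None
    dropped_singletons: list[str] = field(default_factory=list)

    @property
    def beta(self) -> float:
        """The elasticity of poverty with respect to lagged spending."""
        return float(self.params[SLOPE_OF_INTEREST])

    def t_stats(self) -> pd.Series:
        return self.params / self.se

    def p_values(self) -> pd.Series:
        from scipy import stats

        t = self.t_stats()
        return pd.Series(
            2 * stats.t.sf(np.abs(t.to_numpy()), df=self.df_resid), index=t.index
        )

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "se": self.se.to_dict(),
            "vcov": {"index": list(self.vcov.index),
                     "values": self.vcov.to_numpy().tolist()},
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "n_countries": self.n_countries,
            "df_resid": self.df_resid,
            "intercept": self.intercept,
            "dropped_singletons": self.dropped_singletons,
            "spec": asdict(self.spec),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        names = d["vcov"]["index"]
        spec_d = dict(d["spec"])
        spec_d["controls"] = tuple(spec_d["controls"])
        if spec_d.get("income_groups") is not None:
            spec_d["income_groups"] = tuple(spec_d["income_groups"])
        return cls(
            params=pd.Series(d["params"]).reindex(names).rename("coef"),
            se=pd.Series(d["se"]).reindex(names).rename("se"),
            vcov=pd.DataFrame(np.asarray(d["vcov"]["values"]), index=names, columns=names),
            r_squared=d["r_squared"],
            n_obs=d["n_obs"],
            n_countries=d["n_countries"],
            df_resid=d["df_resid"],
            spec=RegressionSpec(**spec_d),
            intercept=d.get("intercept"),
            dropped_singletons=list(d.get("dropped_singletons", [])),
        )


def fit_fixed_effects(rows: pd.DataFrame, spec: RegressionSpec) -> FitResult:
    """Estimate the elasticity model on prepared estimation rows.

    With fixed effects the slopes come from OLS on country-demeaned
    variables; degrees of freedom subtract one per country so classical
    standard errors match the dummy-variable formulation exactly.  R^2 is
    the full-model (LSDV) statistic, i.e. fixed effects count as
    regressors.  Countries reduced to a single row are dropped with a
    warning when fixed effects are requested: a single observation
    identifies only its own intercept.
    """
    x_cols = [SLOPE_OF_INTEREST, *spec.controls]
    df = rows
    if spec.income_groups is not None:
        df = df[df["income_group"].isin(set(spec.income_groups))]
    df = df.dropna(subset=["log_pov", *x_cols]).copy()

    dropped: list[str] = []
    if spec.include_fixed_effects:
        sizes = df.groupby("country")["year"].size()
        dropped = sorted(sizes[sizes < 2].index)
        if dropped:
            logger.warning(
                "dropping %d singleton countries under fixed effects: %s",
                len(dropped), dropped,
            )
            df = df[~df["country"].isin(dropped)]
    if df.empty:
        raise ValueError("no estimation rows left after filtering")

    y = df["log_pov"].to_numpy(float)
    X = df[x_cols].to_numpy(float)
    n = len(df)
    groups = df["country"].to_numpy()
    n_countries = df["country"].nunique()

    if spec.include_fixed_effects:
        gmean_x = df.groupby("country")[x_cols].transform("mean").to_numpy(float)
        gmean_y = df.groupby("country")["log_pov"].transform("mean").to_numpy(float)
        Xd = X - gmean_x
        yd = y - gmean_y
        # a regressor with no within-country variation is absorbed by the
        # fixed effects and cannot be identified
        within_var = Xd.var(axis=0)
        degenerate = [c for c, v in zip(x_cols, within_var) if v < 1e-12]
        if degenerate:
            raise ValueError(
                f"rank deficiency under fixed effects: no within-country "
                f"variation in {degenerate}"
            )
        k_model = len(x_cols) + n_countries
        design, target = Xd, yd
    else:
        design = np.column_stack([np.ones(n), X])
        target = y
        k_model = len(x_cols) + 1

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear regressors)")

    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    rss = float(resid @ resid)
    df_resid = n - k_model
    if df_resid <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({df_resid})")
    sigma2 = rss / df_resid

    xtx_inv = np.linalg.inv(design.T @ design)
    if spec.vcov_kind == "classical":
        vcov_full = sigma2 * xtx_inv
    else:
        # CR1 cluster-robust by country with the standard small-sample factor
        meat = np.zeros((design.shape[1],) * 2)
        for g in np.unique(groups):
            sel = groups == g
            xu = design[sel].T @ resid[sel]
            meat += np.outer(xu, xu)
        g_count = n_countries
        c = g_count / (g_count - 1) * (n - 1) / df_resid
        vcov_full = c * xtx_inv @ meat @ xtx_inv

    if spec.include_fixed_effects:
        slope_idx = np.arange(len(x_cols))
        intercept = None
        slopes = coef
        alpha = (
            df.groupby("country")["log_pov"].mean()
            - df.groupby("country")[x_cols].mean() @ slopes
        )
        fixed_effects = alpha.rename("alpha")
    else:
        slope_idx = np.arange(1, len(x_cols) + 1)
        intercept = float(coef[0])
        slopes = coef[1:]
        fixed_effects = None

    vcov = vcov_full[np.ix_(slope_idx, slope_idx)]
    vcov = (vcov + vcov.T) / 2  # enforce exact symmetry
    tss = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - rss / tss if tss > 0 else float("nan")

    params = pd.Series(slopes, index=x_cols, name="coef")
    return FitResult(
        params=params,
        se=pd.Series(np.sqrt(np.diag(vcov)), index=x_cols, name="se"),
        vcov=pd.DataFrame(vcov, index=x_cols, columns=x_cols),
        r_squared=r_squared,
        n_obs=n,
        n_countries=n_countries,
        df_resid=df_resid,
        spec=spec,
        fixed_effects=fixed_effects,
        intercept=intercept,
        dropped_singletons=dropped,
    )


def sample_coefficients(fit: FitResult, n: int, seed: int) -> pd.DataFrame:
    """Draw n i.i.d. multivariate-normal slope vectors from the fit.

    The mean is the fitted slope vector and the covariance the fitted
    variance-covariance matrix; downstream consumers extract the
    ``log_phe_lag`` column as the elasticity draws.  Reproducible for a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cov = fit.vcov.to_numpy(float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("vcov must be symmetric")
    eigmin = float(np.linalg.eigvalsh(cov).min())
    scale = max(1.0, float(np.abs(cov).max()))
    if eigmin < -1e-10 * scale:
        raise ValueError(f"vcov is not positive semi-definite (min eigenvalue {eigmin:g})")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        fit.params.to_numpy(float), cov, size=n, check_valid="ignore", method="svd"
    )
    return pd.DataFrame(draws, columns=list(fit.params.index))
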