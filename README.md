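# povbench

Poverty reduction benchmarks (PRBs) for health-sector spending: how many
dollars of government health expenditure does it take to move one person
out of poverty?

`povbench` is aimed at health-economics and global-health analysts working
with country-year panels of the World Bank WDI shape (poverty headcount at
the $1.90/day 2011-PPP line, per-capita government health expenditure in
constant 2017 international $, GDP per capita, Gini index, population) and
ASPIRE-shaped social-protection indicator tables. It estimates the
elasticity of the national poverty headcount with respect to lagged health
spending, converts it into a per-country dollar cost per poverty case
averted with Monte-Carlo uncertainty ranges, and computes the analogous
cost for social protection and labor (SPL) programs for comparison.

## The model

The elasticity comes from a log-log country-fixed-effects panel regression

```
ln(Pov_ct) = alpha_c + beta * ln(PHE_c,t-1) + gamma' X_ct + eps_ct
```

where `Pov_ct` is the poverty headcount ratio, `alpha_c` a country fixed
effect, `PHE_c,t-1` per-capita government health spending lagged one year
(five years as a sensitivity), and `X_ct` holds log GDP per capita and the
Gini index. `beta` is the percent change in the headcount per one-percent
spending increase.

For a country with headcount ratio `p`, population `N` and spending
`phe_pc`, a one-percent spending increase changes the number of poor by
`(beta/100) p N` at a budget cost of `phe_pc N / 100`; the ratio — the
country PRB — collapses to

```
PRB = phe_pc / (-beta * p)      [$ per poverty case averted]
```

independent of population and of the size of the hypothetical increase.
Uncertainty ranges propagate estimation error by drawing 1000 coefficient
vectors from a multivariate normal with the fitted mean and
variance-covariance matrix, averaging per-country PRBs across countries
within each draw, and taking the median and 2.5/97.5 percentiles across
draws. SPL costs per case averted are the annualized transfer outlay
(coverage x population x transfer) divided by the cases averted implied by
the program-attributable headcount reduction.

Because real WDI/ASPIRE extracts are revised over time and are not
redistributed here, the package ships a synthetic-data module that draws
panels from the generative form of the model above with known parameters,
so every stage is testable end to end without downloads. Users supply
their own extracts for real analyses (`panel_path` / `spl_path` in the run
configuration, with a column-name mapping).

## Worked example

```python
from povbench import (SyntheticPanelConfig, generate_panel, build_estimation_rows,
                      filter_complete, RegressionSpec, fit_fixed_effects,
                      sample_coefficients, country_snapshots, aggregate_prb)

config = SyntheticPanelConfig(seed=42)          # 63 countries, true elasticity -0.5
panel, truth = generate_panel(config)
rows = filter_complete(build_estimation_rows(panel, lag=1))

fit = fit_fixed_effects(rows, RegressionSpec())  # FE + log GDP + Gini controls
print(f"elasticity = {fit.beta:.3f} (SE {fit.se['log_phe_lag']:.3f}), "
      f"R2 = {fit.r_squared:.2f}, n = {fit.n_obs} rows, {fit.n_countries} countries")

draws = sample_coefficients(fit, n=1000, seed=42)
snaps = country_snapshots(rows)
summary = aggregate_prb(draws["log_phe_lag"].to_numpy(), snaps,
                        group="all", point_beta=fit.beta)
print(f"PRB (all countries): median ${summary.median:,.0f} per case averted "
      f"(95% UR ${summary.lower_ur:,.0f}-{summary.upper_ur:,.0f})")
```

prints

```
elasticity = -0.512 (SE 0.043), R2 = 0.91, n = 747 rows, 63 countries
PRB (all countries): median $7,604 per case averted (95% UR $6,498-9,149)
```

The fitted elasticity recovers the generator's true value (-0.5) within
one standard error: a 1% spending increase is associated with a ~0.5%
lower headcount. At the simulated spending and poverty levels, averting
one poverty case through the health sector costs a median $7,604, with the
95% uncertainty range reflecting only coefficient estimation error.

The same pipeline is available from the shell:

```
povbench run --seed 42 --out results/demo            # simulate -> ... -> report
povbench fit --config myrun.yaml --out results/real  # stages individually
```

which writes regression tables (with significance markers), the PRB table
per income group, the SPL cost distribution table, per-country CSVs, SVG/PNG
figures, and a `manifest.json` with the full configuration, its hash and
the seed; rerunning a configuration reproduces every numeric artifact
byte for byte.

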