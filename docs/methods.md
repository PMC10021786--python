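# Methods

## Model and estimand

The package estimates the association between national poverty and lagged
public health spending with a log-log country-fixed-effects panel model,

    ln Pov_ct = alpha_c + beta ln PHE_c,t-k + g1 ln GDP_ct + g2 Gini_ct + eps_ct,

where `Pov_ct` is the poverty headcount ratio (proportion below the
$1.90/day 2011-PPP line), `PHE` per-capita domestic government health
expenditure (constant 2017 international $), and `alpha_c` absorbs all
time-invariant country characteristics. `beta` is an elasticity: the
percent change in the headcount per one-percent change in lagged
spending. The default lag is k = 1 year (k = 5 supported as a
sensitivity, as is adding external health expenditure to the spending
variable). The estimate is an association, not a causal effect: nothing
here addresses time-varying confounding or reverse causation.

Estimation uses the within transformation (country demeaning). The
explicit-dummy LSDV regression is numerically identical; the test suite
keeps an LSDV fit (via statsmodels) as an independent oracle and checks
coefficient-by-coefficient agreement to 1e-8 on random panels. Degrees of
freedom subtract one per country, so classical standard errors equal the
LSDV ones exactly; R² is reported on the full model, fixed effects
counted as regressors. Cluster-robust (by country) covariance is
available via `vcov_kind="cluster_by_country"` using the standard CR1
small-sample factor G/(G-1)·(n-1)/(n-k); classical is the default, and
whichever covariance the fit carries is what the uncertainty propagation
uses. There are no time fixed effects: the specification is deliberately
the sparse country-effects model.

### Sample rules

Input rows are validated, never coerced: a row with a non-positive
headcount or spending value (log undefined), a Gini outside [0, 100], or
a missing model variable is excluded with a logged reason code. Duplicate
(country, year) keys and income-group labels that vary within a country
are hard errors. The estimation sample keeps countries with at least two
complete estimation rows (`min_years=2`) inside the year window (default
2000 onward, both bounds configurable). The lag source must be exactly
t − k; nearest-available-year matching is deliberately not implemented.
Countries reduced to a single row under fixed effects are dropped with a
warning rather than erroring, since lag construction routinely creates
them. Summary tables report group means at each country's first and last
available year.

## From elasticity to a poverty reduction benchmark (PRB)

At each country's last complete year (headcount p, population N,
spending phe_pc), a one-percent spending increase changes the poor
population by (beta/100)·p·N and costs phe_pc·N/100. The PRB is their
ratio,

    PRB = phe_pc / (-beta · p)   [$ per poverty case averted],

exactly independent of N and of the percent increase (both cancel; the
tests assert this numerically to 1e-12). A beta ≥ 0 yields no averted
cases: the PRB is flagged undefined (NaN), never returned as a negative
price.

Uncertainty propagation samples n = 1000 coefficient vectors from a
multivariate normal with the fitted mean and covariance (the full slope
vector is sampled and the beta component extracted; for beta itself this
is distributionally identical to sampling its marginal). Per draw, the
unweighted mean PRB across countries is formed (population weighting is
available but off by default); the median, mean and 2.5/97.5 percentiles
across draws give the point summary and 95% uncertainty range. Draws with
beta ≥ 0 are dropped and counted in the output — an undefined price
cannot enter an average; with the default frame's standard errors such
draws are rare but the count makes the policy auditable. Because the map
beta → K/(−beta) is strictly increasing on beta < 0, quantiles of the
iteration means coincide with the map evaluated at the matching beta
quantiles whenever the percentile index lands on an order statistic; with
interpolated indices the two differ by the interpolation of a nonlinear
map, which is why percentiles are pinned to a single definition
(inclusive linear interpolation, numpy's default) and reproduced
bit-for-bit.

Which fit feeds which benchmark row is configurable: by default the
pooled fit feeds the "all" row and the income-group fits feed the group
rows (`beta_source="group"`); `"pooled"` reuses the pooled elasticity
everywhere. Both the mean of the iteration-means and the PRB evaluated at
the mean beta draw are reported, since the two "mean" conventions differ.

## SPL program costs

For social protection and labor programs, the cost per poverty case
averted is the annualized transfer outlay divided by the cases averted:

    cost = coverage · N · transfer_per_beneficiary · annualization
    cases = reduction · pre_transfer_headcount · N        (relative form)
          = reduction · N                                 (percentage-point form)

with annualization 365 (daily), 12 (monthly) or 1 (yearly). Population
cancels. Indicator conventions genuinely vary between extracts — transfer
periodicity, per-beneficiary vs per-capita denominators, relative vs
absolute reductions — so the schema requires an explicit declaration
rather than guessing; defaults are yearly, per-beneficiary, relative.
Group distributions report the 10th percentile, median, mean and 90th
percentile, with the same percentile definition as the PRB module;
undefined countries are excluded with a reported count.

## Synthetic data generator

The generator draws panels from the generative form of the model itself:
country effects alpha_c ~ N(alpha_mean, alpha_sd²); geometric spending
and GDP paths (per-group log-level, cross-country log-sd, annual log
drift, AR(1) innovations) so logs are always defined and the
within-estimator sees realistic, mildly autocorrelated variation; a
stationary AR(1) Gini path in levels; iid Gaussian noise on log poverty.
One seed feeds three independent substreams (country structure, covariate
paths and missingness, regression noise), so enlarging one stream never
perturbs another; identical seeds give byte-identical panels.

The default frame mirrors the study sample the package targets: 20
low-income + 43 lower-middle-income countries, years 2001–2019
(estimation rows 2002–2019), spending centred near $26 vs $134 per
capita, GDP near $1.8k vs $5.9k, Gini near 40, true elasticity −0.5, and
a 20% missingness rate that yields 2–18 complete years per country.
Because the model is linear in logs, nothing bounds the generated
headcount above by 1; the generator treats any draw with pov > 1 as a
hard configuration error rather than truncating, since truncation would
silently break the generative/estimated-model correspondence. That
constraint is why the default poverty levels are centred below the
means observed in real low-income samples (about 0.22 low / 0.07
lower-middle rather than ~0.47 / ~0.19): with realistic country-effect
and noise dispersion, higher centres would cross 1. The group contrast
and all spending/GDP magnitudes are preserved; PRB magnitudes scale
accordingly and are validated structurally, not against any published
dollar figure. The parameter-recovery experiments (63 countries × 10
years, noise sd 0.3, 200 replicates) use a lower poverty centre
(alpha_mean = 1.0, headcounts ~0.13) for the same reason: at that noise
level every replicate must satisfy the bound. What the generator does not
emulate: measurement error and survey revisions in the headcount,
spending data gaps correlated with crises, population growth, income-group
reclassification over time, and any bounded-outcome censoring near 1 —
so passing tests demonstrate estimator and pipeline correctness under the
model's own assumptions, not robustness to real-data pathologies.

The SPL generator draws coverage, yearly transfer, relative reduction and
pre-transfer headcount uniformly from plausible ASPIRE-like ranges for 10
low + 23 lower-middle countries and records the true cost per case from
the closed form, enabling exact round-trips.

## Numerical and design choices

- Percentiles: inclusive linear interpolation everywhere (documented
  above); uncertainty ranges are bit-reproducible given the seed.
- Coefficient sampling checks symmetry and positive semi-definiteness
  (eigenvalue tolerance −1e-10 relative) and uses an SVD factorization,
  so a degenerate (zero) covariance reproduces the point estimate
  exactly.
- Rank checks name the offending column when a control has no
  within-country variation.
- The pipeline stamps every CSV artifact with the configuration hash and
  seed; the output directory is excluded from the hash so runs in
  different locations compare byte-identical. Figures are written with
  metadata stripped for the same reason.
- Problem sizes in the test suite (small random panels for oracle
  equivalence, 200 replicates for recovery, n = 1000–1001 draws for the
  uncertainty structure) are chosen so the full suite runs in well under
  a minute while keeping Monte-Carlo error far from the asserted bounds.

## Limitations

Elasticities are associations conditioned on a sparse specification; PRBs
inherit that caveat and are benchmarks, not causal prices. The constant
elasticity extrapolates a one-percent marginal change; large spending
changes would leave its support. Cross-country averaging of PRBs mixes
very different spending levels, which is why group-specific rows are the
default. SPL comparisons depend on indicator conventions the user must
declare, and administrative costs beyond transfers are not counted.
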