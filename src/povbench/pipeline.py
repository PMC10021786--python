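"""Run orchestration: configuration, stage execution, artifact manifest.

Stages (``simulate → fit → prb → spl → report``) communicate through
files in the output directory, so they can run in one call or as separate
CLI invocations.  Every run writes a manifest recording the full
configuration, its hash and the seed; rerunning with the same
configuration and inputs reproduces every numeric artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fe, panel as panel_io, prb as prb_mod, spl as spl_mod, synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "prb", "spl", "report")

#: The specification ladder: bivariate, + fixed effects, + controls.
LADDER = (
    ("bivariate", fe.RegressionSpec(include_fixed_effects=False, controls=())),
    ("fixed_effects", fe.RegressionSpec(include_fixed_effects=True, controls=())),
    ("fe_controls", fe.RegressionSpec(include_fixed_effects=True, controls=("log_gdp", "gini"))),
)


@dataclass
class RunConfig:
    """Everything a run needs; serialized into the manifest."""

    out_dir: str = "povbench_out"
    seed: int = 0
    # inputs: paths to user-supplied extracts, or None to simulate
    panel_path: str | None = None
    spl_path: str | None = None
    panel_schema: dict | None = None
    spl_schema: dict | None = None
    year_min: int = 2000
    year_max: int | None = None
    # estimation
    lag: int = 1
    spending: str = "government"
    min_years: int = 2
    vcov_kind: str = "classical"
    # PRB settings
    n_draws: int = 1000
    beta_source: str = "group"  # "group": per-group fits feed group rows; "pooled": pooled beta everywhere
    population_weighted: bool = False
    # SPL unit declarations
    transfer_period: str = "yearly"
    reduction_kind: str = "relative_percent"
    # synthetic generator overrides (flat fields of SyntheticPanelConfig)
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        # out_dir is a location, not part of the scientific configuration:
        # excluding it keeps the hash and manifest identical across
        # otherwise-equal runs in different directories
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(config: RunConfig) -> str:
    return f"# config_hash={config.config_hash()} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=index, lineterminator="\n")


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{produced_by}' stage first"
        )
    return path


def _synthetic_config(config: RunConfig) -> synthetic.SyntheticPanelConfig:
    overrides = dict(config.synthetic)
    overrides.setdefault("seed", config.seed)
    return synthetic.SyntheticPanelConfig(**overrides)


def stage_simulate(config: RunConfig, out: Path) -> None:
    """Generate a synthetic panel and SPL table with their truth record."""
    cfg = _synthetic_config(config)
    pan, truth = synthetic.generate_panel(cfg)
    panel_io.write_panel(pan, out / "panel.csv")
    spl_records, true_costs = synthetic.generate_spl_table(seed=config.seed)
    synthetic.spl_records_to_frame(spl_records).to_csv(out / "spl_input.csv", index=False)
    truth["spl_true_costs"] = true_costs.to_dict()
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    logger.info("simulate: %d panel records, %d SPL countries", len(pan), len(spl_records))


def _load_rows(config: RunConfig, out: Path) -> pd.DataFrame:
    if config.panel_path is not None:
        path = Path(config.panel_path)
    else:
        path = _require(out / "panel.csv", "simulate")
    pan = panel_io.load_panel(
        path,
        schema=config.panel_schema
        or ({k: k for k in panel_io.WDI_SCHEMA} if config.panel_path is None else None),
        year_min=config.year_min,
        year_max=config.year_max,
    )
    rows = panel_io.build_estimation_rows(pan, lag=config.lag, spending=config.spending)
    return panel_io.filter_complete(rows, min_years=config.min_years)


def stage_fit(config: RunConfig, out: Path) -> None:
    """Estimate the specification ladder and the income-group fits."""
    rows = _load_rows(config, out)
    fits: dict[str, dict] = {}
    for name, spec in LADDER:
        spec = dataclasses.replace(spec, lag=config.lag, spending=config.spending,
                                   vcov_kind=config.vcov_kind)
        fits[name] = fe.fit_fixed_effects(rows, spec).to_dict()
    for group in sorted(rows["income_group"].unique()):
        spec = fe.RegressionSpec(
            include_fixed_effects=True, controls=("log_gdp", "gini"),
            lag=config.lag, spending=config.spending,
            income_groups=(group,), vcov_kind=config.vcov_kind,
        )
        try:
            fits[f"group_{group}"] = fe.fit_fixed_effects(rows, spec).to_dict()
        except ValueError as err:
            logger.warning("skipping group fit for %s: %s", group, err)
    (out / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
    _write_csv(panel_io.summarize_panel(rows, at="first_year"), out / "summary_first_year.csv", config)
    _write_csv(panel_io.summarize_panel(rows, at="last_year"), out / "summary_last_year.csv", config)


def _load_fits(out: Path) -> dict[str, fe.FitResult]:
    path = _require(out / "fits.json", "fit")
    raw = json.loads(path.read_text())
    return {k: fe.FitResult.from_dict(v) for k, v in raw.items()}


def stage_prb(config: RunConfig, out: Path) -> None:
    """Monte-Carlo poverty reduction benchmarks per group and pooled."""
    fits = _load_fits(out)
    rows = _load_rows(config, out)
    snaps = prb_mod.country_snapshots(rows)

    summaries = []
    groups = ["all"] + sorted({s.income_group for s in snaps})
    for i, group in enumerate(groups):
        if group == "all" or config.beta_source == "pooled":
            fit_key = "fe_controls"
        else:
            fit_key = f"group_{group}"
        if fit_key not in fits:
            logger.warning("no fit available for group %s; skipped", group)
            continue
        fit = fits[fit_key]
        draws = fe.sample_coefficients(fit, config.n_draws, seed=config.seed + i)
        subset = snaps if group == "all" else [s for s in snaps if s.income_group == group]
        summaries.append(
            prb_mod.aggregate_prb(
                draws[fe.SLOPE_OF_INTEREST].to_numpy(),
                subset,
                group=group,
                point_beta=fit.beta,
                population_weighted=config.population_weighted,
            )
        )
    table = prb_mod.prb_table(summaries)
    _write_csv(table, out / "prb_table.csv", config)
    per_country = pd.DataFrame(
        [
            {"group": s.group, "country": c, "prb": v}
            for s in summaries
            if s.group != "all"
            for c, v in s.per_country_point.items()
        ]
    )
    _write_csv(per_country, out / "prb_per_country.csv", config, index=False)


def stage_spl(config: RunConfig, out: Path) -> None:
    """SPL program costs per poverty case averted."""
    if config.spl_path is not None:
        path = Path(config.spl_path)
    else:
        path = _require(out / "spl_input.csv", "simulate")
    records = spl_mod.load_spl_table(
        path, schema=config.spl_schema,
        transfer_period=config.transfer_period, reduction_kind=config.reduction_kind,
    )
    costs = {r.country_id: spl_mod.spl_cost_per_case(r) for r in records}
    groups = {r.country_id: r.income_group for r in records}
    result = spl_mod.summarize_spl(costs, groups)
    _write_csv(result.summaries, out / "spl_summary.csv", config)
    per_country = spl_mod.cost_table(records).sort_values("cost_per_case", ascending=False)
    _write_csv(per_country, out / "spl_per_country.csv", config)


def stage_report(config: RunConfig, out: Path) -> None:
    from . import report

    _require(out / "fits.json", "fit")
    report.render_all(out, config)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "prb": stage_prb,
    "spl": stage_spl,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        logger.info("stage %s", stage)
        _STAGE_FUNCS[stage](config, out)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ordered,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
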