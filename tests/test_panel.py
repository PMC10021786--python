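"""Panel ingestion, validation, lag construction and sample filtering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_records
from povbench.panel import (
    WDI_SCHEMA,
    build_estimation_rows,
    filter_complete,
    load_panel,
    summarize_panel,
    validate_panel,
    write_panel,
)


class TestLoadAndValidate:
    def test_all_valid_rows_are_retained(self, tmp_path, toy_records):
        path = tmp_path / "panel.csv"
        toy_records.rename(columns=WDI_SCHEMA).to_csv(path, index=False)
        panel = load_panel(path)
        assert len(panel) == 6
        assert panel.rejections.empty
        assert panel.countries == ["AAA", "BBB"]

    def test_schema_mapping_renames_columns(self, tmp_path, toy_records):
        headers = {k: k.upper() for k in WDI_SCHEMA}
        path = tmp_path / "panel.csv"
        toy_records.rename(columns=headers).to_csv(path, index=False)
        panel = load_panel(path, schema=headers)
        assert len(panel) == 6

    def test_missing_mapped_column_is_hard_error(self, tmp_path, toy_records):
        path = tmp_path / "panel.csv"
        toy_records.drop(columns=["gini"]).rename(columns=WDI_SCHEMA).to_csv(path, index=False)
        with pytest.raises(ValueError, match="gini"):
            load_panel(path)

    @pytest.mark.parametrize(
        "field,value,reason",
        [
            ("pov", 0.0, "nonpositive poverty"),
            ("pov", 1.7, "> 1"),
            ("phe_pc", -3.0, "nonpositive health spending"),
            ("gdp_pc", 0.0, "nonpositive GDP"),
            ("gini", 140.0, "Gini"),
            ("population", 0.0, "nonpositive population"),
            ("pov", np.nan, "missing pov"),
            ("income_group", "middle-earth", "unknown income group"),
        ],
    )
    def test_invalid_rows_rejected_with_reason(self, toy_records, field, value, reason):
        bad = toy_records.copy()
        bad.loc[0, field] = value
        panel = validate_panel(bad)
        assert len(panel) == 5
        assert len(panel.rejections) == 1
        assert reason in panel.rejections["reason"].iloc[0]

    def test_duplicate_country_year_is_hard_error(self, toy_records):
        dup = pd.concat([toy_records, toy_records.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match=r"AAA, 2005"):
            validate_panel(dup)

    def test_year_window_filters_rows(self, toy_records):
        old = toy_records.copy()
        old.loc[0, "year"] = 1998
        panel = validate_panel(old, year_min=2000)
        assert len(panel) == 5
        assert "window start" in panel.rejections["reason"].iloc[0]

    def test_income_group_must_be_time_invariant(self, toy_records):
        drift = toy_records.copy()
        drift.loc[1, "income_group"] = "lower_middle"
        with pytest.raises(ValueError, match="AAA"):
            validate_panel(drift)

    def test_write_then_reload_round_trips(self, tmp_path, toy_panel):
        path = tmp_path / "out.csv"
        write_panel(toy_panel, path)
        back = load_panel(path, schema={k: k for k in WDI_SCHEMA})
        pd.testing.assert_frame_equal(
            back.records[toy_panel.records.columns], toy_panel.records
        )


class TestLagConstruction:
    def test_lag_one_aligns_to_previous_year(self):
        panel = validate_panel(make_records(
            [dict(country="AAA", year=2005, phe_pc=20.0),
             dict(country="AAA", year=2006, phe_pc=30.0)]
        ))
        rows = build_estimation_rows(panel, lag=1)
        assert len(rows) == 1
        assert rows.loc[0, "year"] == 2006
        assert rows.loc[0, "log_phe_lag"] == pytest.approx(np.log(20.0), abs=1e-15)

    def test_missing_lag_source_yields_no_row(self):
        panel = validate_panel(make_records(
            [dict(country="AAA", year=2005), dict(country="AAA", year=2006)]
        ))
        assert len(build_estimation_rows(panel, lag=5)) == 0

    def test_external_spending_added_to_lag_source(self):
        recs = make_records(
            [dict(country="AAA", year=2005, phe_pc=20.0),
             dict(country="AAA", year=2006, phe_pc=30.0)]
        )
        recs["ext_pc"] = [5.0, 2.0]
        rows = build_estimation_rows(validate_panel(recs),
                                     spending="government_plus_external")
        assert rows.loc[0, "log_phe_lag"] == pytest.approx(np.log(25.0), abs=1e-15)

    def test_external_variant_requires_ext_data(self, toy_panel):
        with pytest.raises(ValueError, match="ext_pc"):
            build_estimation_rows(toy_panel, spending="government_plus_external")

    def test_nonpositive_lag_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="lag"):
            build_estimation_rows(toy_panel, lag=0)

    def test_row_order_does_not_matter(self, toy_records):
        panel_a = validate_panel(toy_records)
        panel_b = validate_panel(toy_records.sample(frac=1, random_state=4))
        pd.testing.assert_frame_equal(
            build_estimation_rows(panel_a), build_estimation_rows(panel_b)
        )

    def test_no_row_references_a_missing_lag_source(self, toy_records):
        gappy = toy_records[~((toy_records.country == "AAA") & (toy_records.year == 2006))]
        panel = validate_panel(gappy)
        rows = build_estimation_rows(panel, lag=1)
        keys = set(zip(panel.records.country, panel.records.year))
        assert all((c, y - 1) in keys for c, y in zip(rows.country, rows.year))


class TestSampleRule:
    def _rows(self):
        entries = [dict(country="AAA", year=y) for y in (2005, 2006, 2007)]
        entries += [dict(country="BBB", year=y, income_group="lower_middle")
                    for y in (2010, 2011)]
        entries += [dict(country="CCC", year=y) for y in (2012, 2013)]
        return build_estimation_rows(validate_panel(make_records(entries)))

    def test_country_below_min_years_is_dropped(self):
        rows = self._rows()  # CCC has exactly one estimation row (2013)
        kept = filter_complete(rows, min_years=2)
        assert set(kept.country) == {"AAA"}  # BBB has 1 row too
        assert kept.attrs["country_year_counts"] == {"AAA": 2}

    def test_boundary_country_with_two_rows_is_retained(self):
        entries = [dict(country="AAA", year=y) for y in (2005, 2006, 2007)]
        rows = build_estimation_rows(validate_panel(make_records(entries)))
        kept = filter_complete(rows, min_years=2)
        assert kept.attrs["country_year_counts"] == {"AAA": 2}

    def test_income_group_subset(self, toy_panel):
        rows = build_estimation_rows(toy_panel)
        kept = filter_complete(rows, income_groups={"low"})
        assert set(kept.income_group) == {"low"}

    def test_filtering_is_idempotent(self, toy_panel):
        rows = build_estimation_rows(toy_panel)
        once = filter_complete(rows)
        twice = filter_complete(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_is_hard_error_with_diagnostics(self, toy_panel):
        rows = build_estimation_rows(toy_panel)
        with pytest.raises(ValueError, match="min_years=99"):
            filter_complete(rows, min_years=99)


class TestSummaries:
    def test_single_country_mean_is_its_own_value(self, toy_panel):
        rows = build_estimation_rows(toy_panel)
        rows = rows[rows.country == "AAA"]
        table = summarize_panel(rows, at="last_year")
        last = rows.loc[rows.year.idxmax()]
        assert table.loc["all", "mean_pov"] == pytest.approx(last.pov)
        assert table.loc["all", "n_countries"] == 1

    def test_two_country_mean_is_midpoint(self):
        entries = []
        for c, pov in (("AAA", 0.2), ("BBB", 0.4)):
            entries += [dict(country=c, year=y, pov=pov) for y in (2005, 2006)]
        rows = build_estimation_rows(validate_panel(make_records(entries)))
        table = summarize_panel(rows, at="last_year")
        assert table.loc["all", "mean_pov"] == pytest.approx(0.3)

    def test_first_vs_last_year_pick_different_snapshots(self):
        entries = [dict(country="AAA", year=2005 + i, pov=0.4 - 0.1 * i)
                   for i in range(3)]
        rows = build_estimation_rows(validate_panel(make_records(entries)))
        first = summarize_panel(rows, at="first_year")
        last = summarize_panel(rows, at="last_year")
        assert first.loc["all", "mean_pov"] > last.loc["all", "mean_pov"]
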