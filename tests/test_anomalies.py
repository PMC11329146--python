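"""Anomaly flagging and regional aggregation against the published
reference values (29 province-seasons) and edge-case conventions."""

import numpy as np
import pandas as pd
import pytest

import huntwatch as hw
from huntwatch.anomalies import aggregate_region, flag_anomalies
from huntwatch.datasets import reference_panel, reference_predictive_summary

from conftest import make_panel


def _one_row_summary(province="A", region="R", year=2020, med=100.0, lo=90.0, hi=110.0):
    return pd.DataFrame(
        [{"province": province, "region": region, "year": year,
          "median": med, "lo95": lo, "hi95": hi}]
    )


def test_all_reference_rows_flagged_as_decreases(reference_records):
    assert (reference_records["flag"] == "decrease").all()
    counts = reference_records.groupby("year").size()
    assert counts[2020] == 14 and counts[2021] == 15


def test_reference_delta_columns_reproduced(reference_table, reference_records):
    """delta_median is exact; the published min-max columns derive from
    rounded interval bounds, so they may be off by one count."""
    merged = reference_records.merge(
        reference_table, on=["province", "year"], suffixes=("", "_ref")
    )
    assert len(merged) == 29
    diff_med = merged["delta_median"] - merged["printed_delta_median"]
    assert diff_med.abs().max() <= 1
    assert (diff_med == 0).sum() >= 28  # one row off by one via a rounded median
    assert (merged["delta_lo"] - merged["printed_delta_lo"]).abs().max() <= 1
    assert (merged["delta_hi"] - merged["printed_delta_hi"]).abs().max() <= 1
    # flagged decreases satisfy the ordering invariant 0 < lo <= median <= hi
    assert (merged["delta_lo"] > 0).all()
    assert (merged["delta_lo"] <= merged["delta_median"]).all()
    assert (merged["delta_median"] <= merged["delta_hi"]).all()


def test_milan_2020_worked_example(reference_records):
    r = reference_records.query("province == 'Milan' and year == 2020").iloc[0]
    assert r["flag"] == "decrease"
    assert r["delta_median"] == 573
    assert (r["delta_lo"], r["delta_hi"]) == (396, 756)
    assert round(r["pct_median"], 1) == 10.2  # a 10.2% shortfall vs the median


def test_percentage_identities_hold_for_every_record(reference_records):
    rec = reference_records
    np.testing.assert_allclose(
        rec["pct_median"], 100 * rec["delta_median"] / rec["pred_median"], atol=1e-12
    )
    np.testing.assert_allclose(
        rec["pct_lo"], 100 * rec["delta_lo"] / rec["pred_lo"], atol=1e-12
    )
    np.testing.assert_allclose(
        rec["pct_hi"], 100 * rec["delta_hi"] / rec["pred_hi"], atol=1e-12
    )


def test_observed_at_median_is_not_flagged():
    panel = make_panel({"A": [100]}, first_year=2020)
    rec = flag_anomalies(_one_row_summary(med=100, lo=90, hi=110), panel, 2020)
    assert rec["flag"].iloc[0] == "none"
    assert rec["delta_median"].iloc[0] == 0


def test_boundary_convention_strict_exceedance():
    panel = make_panel({"A": [90]}, first_year=2020)
    summary = _one_row_summary(med=100, lo=90, hi=110)
    assert flag_anomalies(summary, panel, 2020)["flag"].iloc[0] == "none"
    assert (
        flag_anomalies(summary, panel, 2020, strict=False)["flag"].iloc[0] == "decrease"
    )


def test_increase_flagging():
    panel = make_panel({"A": [111]}, first_year=2020)
    rec = flag_anomalies(_one_row_summary(), panel, 2020)
    assert rec["flag"].iloc[0] == "increase"
    assert rec["delta_median"].iloc[0] == -11


def test_missing_observation_skipped_with_warning():
    panel = make_panel({"A": [100], "B": [None]}, first_year=2020)
    summary = pd.concat(
        [_one_row_summary("A"), _one_row_summary("B")], ignore_index=True
    )
    with pytest.warns(UserWarning, match="B"):
        rec = flag_anomalies(summary, panel, 2020)
    assert list(rec["province"]) == ["A"]


def test_regional_sums_match_published_totals(reference_records):
    lom20 = aggregate_region(reference_records, "Lombardy", 2020)
    assert lom20.n_flagged == 7
    assert lom20.sum_delta_median == 2720
    assert abs(lom20.sum_delta_lo - 1790) <= 3  # published bounds are rounded
    assert lom20.sum_delta_hi == 3688

    er20 = aggregate_region(reference_records, "Emilia-Romagna", 2020)
    assert er20.sum_delta_median == 808
    assert er20.sum_delta_lo == 255
    assert er20.sum_delta_hi == 1382

    tus20 = aggregate_region(reference_records, "Tuscany", 2020)
    assert tus20.sum_delta_median == 538
    assert (tus20.sum_delta_lo, tus20.sum_delta_hi) == (259, 828)

    assert aggregate_region(reference_records, "Emilia-Romagna", 2021).sum_delta_median == 682
    tus21 = aggregate_region(reference_records, "Tuscany", 2021)
    assert tus21.sum_delta_median == 741
    assert (tus21.sum_delta_lo, tus21.sum_delta_hi) == (213, 1291)


def test_absent_region_gives_empty_aggregate(reference_records):
    agg = aggregate_region(reference_records, "Veneto", 2020)
    assert agg.n_flagged == 0
    assert agg.sum_delta_median == 0.0


def test_aggregate_only_sums_flagged_decreases():
    panel = make_panel(
        {"A": [80], "B": [99]}, region_of={"A": "R", "B": "R"}, first_year=2020
    )
    summary = pd.concat(
        [_one_row_summary("A"), _one_row_summary("B")], ignore_index=True
    )
    rec = flag_anomalies(summary, panel, 2020)
    agg = aggregate_region(rec, "R", 2020)
    assert agg.n_flagged == 1
    assert agg.sum_delta_median == 20  # only the flagged province contributes


def test_invalid_interval_rejected():
    panel = make_panel({"A": [100]}, first_year=2020)
    with pytest.raises(ValueError, match="invalid predictive interval"):
        flag_anomalies(_one_row_summary(med=100, lo=105, hi=110), panel, 2020)
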