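"""Panel data model, validation and round-trip I/O."""

import io

import hypothesis.strategies as st
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings

import huntwatch as hw
from huntwatch.panel import (
    PanelSchemaError,
    PanelValidationError,
    compute_excess_mortality,
    read_panel,
    write_panel,
)

from conftest import make_panel


def test_read_minimal_panel(tmp_path):
    p = tmp_path / "panel.csv"
    p.write_text("province,region,year,count\nA,R,2011,10\nA,R,2012,9\nA,R,2013,8\n")
    panel = read_panel(p)
    assert panel.provinces == ("A",)
    assert panel.years == (2011, 2012, 2013)
    assert panel.get("A", 2012) == 9


def test_duplicate_province_year_is_error(tmp_path):
    p = tmp_path / "panel.csv"
    p.write_text(
        "province,region,year,count\nA,R,2011,10\nA,R,2011,11\nB,R,2011,5\n"
    )
    with pytest.raises(PanelValidationError, match=r"\('A', 2011\)"):
        read_panel(p)


def test_missing_column_is_schema_error(tmp_path):
    p = tmp_path / "panel.csv"
    p.write_text("province,year,count\nA,2011,10\n")
    with pytest.raises(PanelSchemaError, match="region"):
        read_panel(p)


@pytest.mark.parametrize("bad", ["-3", "2.5", "abc"])
def test_invalid_count_is_validation_error_with_row(tmp_path, bad):
    p = tmp_path / "panel.csv"
    p.write_text(f"province,region,year,count\nA,R,2011,10\nA,R,2012,{bad}\n")
    with pytest.raises(PanelValidationError, match=r"row index\(es\) \[\(1,"):
        read_panel(p)


def test_province_in_two_regions_rejected(tmp_path):
    p = tmp_path / "panel.csv"
    p.write_text("province,region,year,count\nA,R1,2011,10\nA,R2,2012,9\n")
    with pytest.raises(PanelValidationError, match="multiple regions"):
        read_panel(p)


def test_years_must_be_consecutive():
    with pytest.raises(PanelValidationError, match="consecutive"):
        hw.LicensePanel(
            provinces=("A",),
            region_of={"A": "R"},
            years=(2011, 2013),
            counts={("A", 2011): 1, ("A", 2013): 2},
        )


def test_empty_years_panel_writes_header_only(tmp_path):
    panel = hw.LicensePanel(provinces=(), region_of={}, years=(), counts={})
    path = write_panel(panel, tmp_path / "empty.csv")
    assert path.read_text() == "province,region,year,count\n"


def test_missing_cell_written_as_absent_row_not_zero(tmp_path):
    panel = make_panel({"A": [10, None, 8]})
    path = write_panel(panel, tmp_path / "p.csv")
    text = path.read_text()
    assert "2012" not in text  # missing season omitted entirely
    back = read_panel(path)
    assert back.get("A", 2012) is None
    assert back.years == (2011, 2013) or back.years == (2011, 2012, 2013)


panels = st.builds(
    lambda n_prov, n_years, missing, counts: _build(n_prov, n_years, missing, counts),
    st.integers(1, 5),
    st.integers(1, 4),
    st.sets(st.tuples(st.integers(0, 4), st.integers(0, 3))),
    st.lists(st.integers(0, 10**6), min_size=20, max_size=20),
)


def _build(n_prov, n_years, missing, counts):
    provinces = [f"P{i}" for i in range(n_prov)]
    region_of = {p: f"R{i % 2}" for i, p in enumerate(provinces)}
    years = tuple(range(2011, 2011 + n_years))
    cells = {}
    k = 0
    for i, p in enumerate(provinces):
        for j, y in enumerate(years):
            if (i, j) not in missing:
                cells[(p, y)] = counts[k % len(counts)]
                k += 1
    if not cells:  # keep at least one observation so years stay anchored
        cells[(provinces[0], years[0])] = counts[0]
    return hw.LicensePanel(
        provinces=tuple(provinces), region_of=region_of, years=years, counts=cells
    )


@settings(max_examples=60, deadline=None)
@given(panel=panels)
def test_write_read_round_trip_identity(panel):
    buf = io.StringIO()
    write_panel(panel, buf)
    buf.seek(0)
    back = read_panel(buf)
    assert back.counts == panel.counts
    assert {p: back.region_of[p] for p in back.provinces} == {
        p: panel.region_of[p] for p in panel.provinces if panel.observed_years(p)
    }


def test_round_trip_byte_identical(tmp_path):
    cfg = hw.SimulationConfig()
    panel, _, _ = hw.simulate_panel(cfg, seed=4)
    p1 = tmp_path / "a.csv"
    write_panel(panel, p1)
    p2 = tmp_path / "b.csv"
    write_panel(read_panel(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


# ----------------------------------------------------------------------


def test_excess_mortality_examples():
    deaths = {2015: 100, 2016: 100, 2017: 100, 2018: 100, 2019: 100, 2020: 132}
    assert compute_excess_mortality(deaths, 2020, range(2015, 2020)) == pytest.approx(32.0)
    deaths[2020] = 100
    assert compute_excess_mortality(deaths, 2020, range(2015, 2020)) == 0.0
    deaths2 = {2017: 90, 2018: 100, 2019: 110, 2020: 80}
    assert compute_excess_mortality(deaths2, 2020, [2017, 2018, 2019]) == pytest.approx(-20.0)


def test_excess_mortality_errors():
    with pytest.raises(ValueError):
        compute_excess_mortality({2020: 1}, 2020, [])
    with pytest.raises(KeyError):
        compute_excess_mortality({2020: 1}, 2020, [2019])
    with pytest.raises(ZeroDivisionError):
        compute_excess_mortality({2019: 0, 2020: 5}, 2020, [2019])


def test_split_spec_validation():
    with pytest.raises(PanelValidationError):
        hw.SplitSpec(frozenset({2019, 2020}), frozenset({2020}))
    with pytest.raises(PanelValidationError, match="strictly after"):
        hw.SplitSpec(frozenset({2018, 2020}), frozenset({2019}))
    s = hw.SplitSpec.from_cutoff(range(2011, 2022), 2019)
    assert s.sorted_training == tuple(range(2011, 2020))
    assert s.sorted_evaluation == (2020, 2021)


def test_covariate_table_rejects_duplicates():
    df = pd.DataFrame(
        {"province": ["A", "A"], "year": [2020, 2020], "excess_mortality_pct": [1.0, 2.0]}
    )
    with pytest.raises(PanelValidationError, match="duplicate"):
        hw.CovariateTable(df)


def test_covariate_negative_percent_allowed():
    df = pd.DataFrame(
        {"province": ["A"], "year": [2020], "excess_mortality_pct": [-12.5]}
    )
    assert hw.CovariateTable(df).lookup("A", 2020) == -12.5
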