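import numpy as np
import pandas as pd
import pytest

import huntwatch as hw
from huntwatch.datasets import (
    load_reference_anomalies,
    reference_panel,
    reference_predictive_summary,
)


@pytest.fixture(scope="session")
def reference_table() -> pd.DataFrame:
    return load_reference_anomalies()


@pytest.fixture(scope="session")
def reference_records(reference_table) -> pd.DataFrame:
    """Anomaly records recomputed from the published observed/predicted values."""
    panel = reference_panel(reference_table)
    summary = reference_predictive_summary(reference_table)
    return pd.concat(
        [hw.flag_anomalies(summary, panel, yr) for yr in (2020, 2021)],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def small_panel():
    """12-province, near-Poisson panel without anomalies."""
    cfg = hw.SimulationConfig(
        n_regions=3, provinces_per_region=4, theta=300.0, anomaly_fraction=0.0
    )
    panel, cov, truth = hw.simulate_panel(cfg, seed=20)
    return panel, cov, truth


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """One shared fit of the default model on the small panel."""
    panel, _, _ = small_panel
    est = hw.NegativeBinomialTrendModel(
        training_cutoff=2019, chains=2, draws=800, warmup=800, seed=11
    )
    est.fit(panel)
    return est


def make_panel(counts_by_province, region_of=None, first_year=2011):
    """Small literal panel helper: {'A': [10, 9, 8], ...}."""
    provinces = tuple(counts_by_province)
    region_of = region_of or {p: "R" for p in provinces}
    n_years = max(len(v) for v in counts_by_province.values())
    years = tuple(range(first_year, first_year + n_years))
    counts = {
        (p, first_year + i): int(c)
        for p, vals in counts_by_province.items()
        for i, c in enumerate(vals)
        if c is not None
    }
    return hw.LicensePanel(
        provinces=provinces, region_of=region_of, years=years, counts=counts
    )
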