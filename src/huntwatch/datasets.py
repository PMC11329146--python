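"""Bundled reference data.

``load_reference_anomalies`` returns published per-province reference values
for 29 Northern-Italian province-seasons (2020/2021 and 2021/2022 hunting
seasons, labelled by opening year): the observed license count, the
counterfactual prediction (posterior-predictive median and central 95%
interval from a model trained on 2011-2019 registrations), the published
anomalous-decrease columns, and the province's excess mortality (percentage
increase of the season-year's deaths over the 2015-2019 mean).  Only
provinces with an anomalous decrease are included.

These rows are worked-example inputs: feeding the observed/predicted columns
through :func:`huntwatch.anomalies.flag_anomalies` must reproduce the
published decrease columns, and the 2020 mortality/decrease pairing gives
Spearman's rho = 0.52.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .panel import CovariateTable, LicensePanel

__all__ = [
    "load_reference_anomalies",
    "reference_panel",
    "reference_predictive_summary",
    "reference_covariates",
]


def load_reference_anomalies() -> pd.DataFrame:
    """The raw reference table (29 rows, two seasons)."""
    with resources.files("huntwatch.data").joinpath("reference_anomalies.csv").open() as f:
        return pd.read_csv(f)


def reference_predictive_summary(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reference rows shaped as a predictive summary (median, lo95, hi95)."""
    df = load_reference_anomalies() if df is None else df
    out = df.rename(columns={"pred_median": "median", "pred_lo": "lo95", "pred_hi": "hi95"})
    return out[["province", "region", "year", "median", "lo95", "hi95"]].copy()


def reference_panel(df: pd.DataFrame | None = None) -> LicensePanel:
    """Observed counts of the reference rows as a (sparse) LicensePanel."""
    df = load_reference_anomalies() if df is None else df
    counts = {
        (str(r.province), int(r.year)): int(r.observed)
        for r in df.itertuples(index=False)
    }
    provinces = tuple(dict.fromkeys(df["province"].astype(str)))
    region_of = {
        str(r.province): str(r.region) for r in df.itertuples(index=False)
    }
    years = tuple(range(int(df["year"].min()), int(df["year"].max()) + 1))
    return LicensePanel(
        provinces=provinces, region_of=region_of, years=years, counts=counts
    )


def reference_covariates(df: pd.DataFrame | None = None) -> CovariateTable:
    """Excess-mortality covariate rows of the reference table."""
    df = load_reference_anomalies() if df is None else df
    return CovariateTable(
        df[["province", "year", "excess_mortality_pct"]].copy()
    )
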