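"""Counterfactual anomaly flagging and quantification.

An observation is anomalous when it falls strictly outside the central 95%
posterior-predictive interval of its counterfactual: ``decrease`` when the
observed count is below the 2.5% bound, ``increase`` when above the 97.5%
bound ("strictly outside" is the boundary convention; a value exactly on a
bound is not flagged, switchable via ``strict=False``).

Anomalies are quantified against the predictive median (the most likely
counterfactual) and against both interval bounds, which brackets the
plausible loss:

    delta_median = predicted median - observed
    delta_lo     = predicted 2.5% bound - observed
    delta_hi     = predicted 97.5% bound - observed
    pct_*        = 100 * delta_* / predicted_*

Positive deltas mean fewer licenses than predicted.  Regional aggregates sum
the deltas over the provinces flagged ``decrease`` only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import LicensePanel

__all__ = ["RegionalAnomaly", "flag_anomalies", "aggregate_region", "aggregate_all"]

RECORD_COLUMNS = [
    "province",
    "region",
    "year",
    "observed",
    "pred_median",
    "pred_lo",
    "pred_hi",
    "flag",
    "delta_median",
    "delta_lo",
    "delta_hi",
    "pct_median",
    "pct_lo",
    "pct_hi",
]


@dataclass(frozen=True)
class RegionalAnomaly:
    """Sum of flagged decreases in one region and season."""

    region: str
    year: int
    n_flagged: int
    sum_delta_median: float
    sum_delta_lo: float
    sum_delta_hi: float


def flag_anomalies(
    predictive_summary: pd.DataFrame,
    panel: LicensePanel,
    season_year: int,
    strict: bool = True,
) -> pd.DataFrame:
    """One anomaly record per province with observed data in ``season_year``.

    Parameters
    ----------
    predictive_summary
        Frame with columns province, region, year, median, lo95, hi95
        covering ``season_year``.
    panel
        Panel holding the observed counts.  Provinces with a missing
        observation are skipped with a warning (a missing year is data
        absence, not a zero).
    strict
        Flag only strictly outside the interval (default); ``False`` flags
        values on the bounds too.

    Unflagged provinces are kept with ``flag == "none"``; their deltas are
    still reported.
    """
    season_year = int(season_year)
    ps = predictive_summary[predictive_summary["year"] == season_year]
    if ps.empty:
        raise ValueError(f"predictive summary has no rows for year {season_year}")
    rows = []
    skipped = []
    for rec in ps.itertuples(index=False):
        obs = panel.get(str(rec.province), season_year)
        if obs is None:
            skipped.append(str(rec.province))
            continue
        med, lo, hi = float(rec.median), float(rec.lo95), float(rec.hi95)
        if not (lo <= med <= hi):
            raise ValueError(
                f"invalid predictive interval for {rec.province}: "
                f"lo {lo} median {med} hi {hi}"
            )
        if (obs < lo) if strict else (obs <= lo):
            flag = "decrease"
        elif (obs > hi) if strict else (obs >= hi):
            flag = "increase"
        else:
            flag = "none"
        rows.append(
            {
                "province": str(rec.province),
                "region": str(rec.region),
                "year": season_year,
                "observed": int(obs),
                "pred_median": med,
                "pred_lo": lo,
                "pred_hi": hi,
                "flag": flag,
                "delta_median": med - obs,
                "delta_lo": lo - obs,
                "delta_hi": hi - obs,
                "pct_median": 100.0 * (med - obs) / med,
                "pct_lo": 100.0 * (lo - obs) / lo,
                "pct_hi": 100.0 * (hi - obs) / hi,
            }
        )
    if skipped:
        warnings.warn(
            f"no observed count for year {season_year} in provinces {skipped}; "
            "records skipped",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def aggregate_region(
    records: pd.DataFrame, region: str, season_year: int
) -> RegionalAnomaly:
    """Sum flagged decreases of one region in one season."""
    season_year = int(season_year)
    sub = records[
        (records["region"] == str(region))
        & (records["year"] == season_year)
        & (records["flag"] == "decrease")
    ]
    return RegionalAnomaly(
        region=str(region),
        year=season_year,
        n_flagged=int(len(sub)),
        sum_delta_median=float(sub["delta_median"].sum()),
        sum_delta_lo=float(sub["delta_lo"].sum()),
        sum_delta_hi=float(sub["delta_hi"].sum()),
    )


def aggregate_all(records: pd.DataFrame) -> pd.DataFrame:
    """Regional aggregates for every (region, year) present in the records."""
    out = []
    for (region, year), _ in records.groupby(["region", "year"]):
        agg = aggregate_region(records, region, year)
        out.append(
            {
                "region": agg.region,
                "year": agg.year,
                "n_flagged": agg.n_flagged,
                "sum_delta_median": agg.sum_delta_median,
                "sum_delta_lo": agg.sum_delta_lo,
                "sum_delta_hi": agg.sum_delta_hi,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "region",
            "year",
            "n_flagged",
            "sum_delta_median",
            "sum_delta_lo",
            "sum_delta_hi",
        ],
    )
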