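"""Tie-aware rank correlation between anomalies and excess mortality.

Spearman's rho with midranks: tied values share the average of the ranks
they occupy, and rho is the Pearson product-moment correlation of the two
rank vectors (not the 6*sum(d^2) shortcut, which is biased under ties; the
mortality covariate is reported in whole percentage points and ties are
common).

``associate`` pairs each province's anomaly magnitude (absolute decrease
against the predictive median) with its excess-mortality percentage, with
optional lagging — e.g. second-season anomalies against first-season
mortality, the pairing used to probe a harvesting-effect interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .panel import CovariateTable

__all__ = ["AssociationResult", "spearman_rho", "associate"]


@dataclass(frozen=True)
class AssociationResult:
    anomaly_year: int
    covariate_year: int
    n: int
    rho: float
    policy: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rank correlation (midranks + Pearson on ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx * sx).sum() * (sy * sy).sum())
    if denom == 0.0:
        raise ValueError("rank correlation undefined: a vector is constant")
    return float((sx * sy).sum() / denom)


def associate(
    records: pd.DataFrame,
    covariates: CovariateTable,
    anomaly_season: int,
    covariate_season: int | None = None,
    policy: str = "flagged",
) -> AssociationResult:
    """Correlate per-province anomaly magnitudes with excess mortality.

    Parameters
    ----------
    records
        Anomaly records (output of :func:`huntwatch.anomalies.flag_anomalies`).
    covariates
        Excess-mortality table; must cover every paired province in
        ``covariate_season``.
    anomaly_season
        Season-year whose anomalies are used.
    covariate_season
        Season-year of the mortality covariate; defaults to
        ``anomaly_season`` (set earlier for lagged pairings).
    policy
        ``"flagged"`` (default) pairs only provinces flagged ``decrease``;
        ``"all"`` pairs every province with a record.
    """
    if policy not in ("flagged", "all"):
        raise ValueError("policy must be 'flagged' or 'all'")
    anomaly_season = int(anomaly_season)
    covariate_season = (
        anomaly_season if covariate_season is None else int(covariate_season)
    )
    sub = records[records["year"] == anomaly_season]
    if policy == "flagged":
        sub = sub[sub["flag"] == "decrease"]
    if sub.empty:
        raise ValueError(
            f"no {'flagged ' if policy == 'flagged' else ''}records for season "
            f"{anomaly_season}"
        )
    deltas, morts = [], []
    missing = []
    for rec in sub.itertuples(index=False):
        e = covariates.lookup(rec.province, covariate_season)
        if e is None:
            missing.append(rec.province)
            continue
        deltas.append(abs(float(rec.delta_median)))
        morts.append(e)
    if missing:
        raise ValueError(
            f"covariate missing for provinces {missing} in season {covariate_season}"
        )
    if len(deltas) < 3:
        raise ValueError(f"only {len(deltas)} pairs available; need at least 3")
    rho = spearman_rho(morts, deltas)
    return AssociationResult(
        anomaly_year=anomaly_season,
        covariate_year=covariate_season,
        n=len(deltas),
        rho=rho,
        policy=policy,
    )
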