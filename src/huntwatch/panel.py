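"""Count-panel data model and I/O.

The package's canonical container is the :class:`LicensePanel`: an annual
count panel of hunting licenses (one non-negative integer per province and
calendar year) with each province nested in exactly one region.  Years label
the season's opening (season 2020/2021 -> year 2020).  Missing cells are
represented as absent rows, never as zeros: a province that reported no data
for a year is distinct from a province that issued zero licenses.

The interchange format is long-format CSV with header
``province,region,year,count`` (RFC-4180, UTF-8), rows sorted by
(region, province, year).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PanelSchemaError",
    "PanelValidationError",
    "LicensePanel",
    "CovariateTable",
    "SplitSpec",
    "read_panel",
    "write_panel",
    "read_covariates",
    "write_covariates",
    "compute_excess_mortality",
]

PANEL_COLUMNS = ("province", "region", "year", "count")
COVARIATE_COLUMNS = ("province", "year", "excess_mortality_pct")


class PanelSchemaError(ValueError):
    """A file or frame does not have the expected columns."""


class PanelValidationError(ValueError):
    """Panel content violates an invariant (duplicates, negatives, ...)."""


@dataclass(frozen=True)
class LicensePanel:
    """Province x year license counts with region nesting.

    Parameters
    ----------
    provinces
        Unit identifiers, unique strings.
    region_of
        Mapping province -> region identifier; every province maps to
        exactly one region.
    years
        Sorted consecutive calendar years spanned by the panel.  Gaps in
        observation appear as missing cells, not missing years.
    counts
        Mapping ``(province, year) -> int`` for the observed cells only.
    """

    provinces: tuple[str, ...]
    region_of: Mapping[str, str]
    years: tuple[int, ...]
    counts: Mapping[tuple[str, int], int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "provinces", tuple(str(p) for p in self.provinces))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(
            self, "region_of", {str(p): str(r) for p, r in dict(self.region_of).items()}
        )
        object.__setattr__(
            self,
            "counts",
            {(str(p), int(y)): c for (p, y), c in dict(self.counts).items()},
        )
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if len(set(self.provinces)) != len(self.provinces):
            dupes = [p for p in set(self.provinces) if self.provinces.count(p) > 1]
            raise PanelValidationError(f"duplicate province ids: {sorted(dupes)}")
        missing_region = [p for p in self.provinces if p not in self.region_of]
        if missing_region:
            raise PanelValidationError(
                f"provinces without a region: {sorted(missing_region)}"
            )
        if list(self.years) != sorted(self.years):
            raise PanelValidationError("years must be sorted ascending")
        if self.years:
            lo, hi = self.years[0], self.years[-1]
            if list(self.years) != list(range(lo, hi + 1)):
                raise PanelValidationError(
                    "years must be consecutive integers; represent gaps as "
                    "missing cells, not missing years"
                )
        known = set(self.provinces)
        yearset = set(self.years)
        for (p, y), c in self.counts.items():
            if p not in known:
                raise PanelValidationError(f"count for unknown province {p!r}")
            if y not in yearset:
                raise PanelValidationError(f"count for year {y} outside panel years")
            if not float(c).is_integer() or int(c) < 0:
                raise PanelValidationError(
                    f"count for ({p!r}, {y}) must be a non-negative integer, got {c!r}"
                )

    # ------------------------------------------------------------------
    @property
    def regions(self) -> tuple[str, ...]:
        """Region ids in order of first appearance among provinces."""
        seen: dict[str, None] = {}
        for p in self.provinces:
            seen.setdefault(self.region_of[p], None)
        return tuple(seen)

    def get(self, province: str, year: int) -> int | None:
        return self.counts.get((province, int(year)))

    def observed_years(self, province: str) -> tuple[int, ...]:
        return tuple(y for y in self.years if (province, y) in self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame sorted by (region, province, year); observed cells only."""
        rows = [
            (p, self.region_of[p], y, int(self.counts[(p, y)]))
            for p in self.provinces
            for y in self.years
            if (p, y) in self.counts
        ]
        df = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
        return df.sort_values(["region", "province", "year"], kind="mergesort").reset_index(
            drop=True
        )

    def counts_matrix(self, years: Iterable[int] | None = None) -> np.ndarray:
        """(n_provinces, n_years) float array with NaN at missing cells."""
        yrs = tuple(years) if years is not None else self.years
        out = np.full((len(self.provinces), len(yrs)), np.nan)
        for i, p in enumerate(self.provinces):
            for j, y in enumerate(yrs):
                c = self.counts.get((p, int(y)))
                if c is not None:
                    out[i, j] = c
        return out

    def subset_years(self, years: Iterable[int]) -> "LicensePanel":
        keep = sorted(set(int(y) for y in years))
        return LicensePanel(
            provinces=self.provinces,
            region_of=self.region_of,
            years=tuple(range(keep[0], keep[-1] + 1)) if keep else (),
            counts={k: v for k, v in self.counts.items() if k[1] in set(keep)},
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LicensePanel":
        """Build and validate a panel from a long-format frame."""
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelSchemaError(f"missing required column(s): {missing}")
        df = df.loc[:, list(PANEL_COLUMNS)].copy()
        dup = df.duplicated(subset=["province", "year"], keep=False)
        if dup.any():
            pairs = sorted(
                set(map(tuple, df.loc[dup, ["province", "year"]].itertuples(index=False)))
            )
            raise PanelValidationError(f"duplicate (province, year) rows: {pairs}")
        bad = []
        counts: dict[tuple[str, int], int] = {}
        for idx, (p, y, c_raw) in enumerate(
            zip(df["province"], df["year"], df["count"])
        ):
            try:
                c = float(c_raw)
                ok = np.isfinite(c) and c.is_integer() and c >= 0
            except (TypeError, ValueError):
                ok = False
            if not ok:
                bad.append((idx, c_raw))
                continue
            counts[(str(p), int(y))] = int(c)
        if bad:
            raise PanelValidationError(
                f"non-integer or negative counts at row index(es) {bad}"
            )
        region_of: dict[str, str] = {}
        for p, r in zip(df["province"], df["region"]):
            p, r = str(p), str(r)
            if p in region_of and region_of[p] != r:
                raise PanelValidationError(
                    f"province {p!r} assigned to multiple regions: "
                    f"{region_of[p]!r} and {r!r}"
                )
            region_of[p] = r
        provinces = tuple(dict.fromkeys(str(p) for p in df["province"]))
        if len(df):
            ylo, yhi = int(df["year"].min()), int(df["year"].max())
            years = tuple(range(ylo, yhi + 1))
        else:
            years = ()
        return cls(provinces=provinces, region_of=region_of, years=years, counts=counts)

    def validation_report(self) -> dict:
        """JSON-ready summary used by the CLI's validate output."""
        n_missing = sum(
            1
            for p in self.provinces
            for y in self.years
            if (p, y) not in self.counts
        )
        return {
            "n_provinces": len(self.provinces),
            "n_regions": len(self.regions),
            "years": [self.years[0], self.years[-1]] if self.years else [],
            "n_cells_observed": len(self.counts),
            "n_cells_missing": n_missing,
            "count_min": int(min(self.counts.values())) if self.counts else None,
            "count_max": int(max(self.counts.values())) if self.counts else None,
        }


@dataclass(frozen=True)
class CovariateTable:
    """Per-province, per-season excess-mortality covariate (percent).

    ``excess_mortality_pct`` is the percentage increase of the season-year's
    deaths over a multi-year baseline mean (may be negative).  One row per
    (province, year).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise PanelSchemaError(f"covariate table missing column(s): {missing}")
        df = df.loc[:, list(COVARIATE_COLUMNS)].copy()
        df["province"] = df["province"].astype(str)
        df["year"] = df["year"].astype(int)
        df["excess_mortality_pct"] = df["excess_mortality_pct"].astype(float)
        dup = df.duplicated(subset=["province", "year"], keep=False)
        if dup.any():
            pairs = sorted(
                set(map(tuple, df.loc[dup, ["province", "year"]].itertuples(index=False)))
            )
            raise PanelValidationError(f"duplicate covariate rows for: {pairs}")
        df = df.sort_values(["year", "province"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    def lookup(self, province: str, year: int) -> float | None:
        m = self.frame[
            (self.frame["province"] == str(province)) & (self.frame["year"] == int(year))
        ]
        return float(m["excess_mortality_pct"].iloc[0]) if len(m) else None

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["year"].unique()))


@dataclass(frozen=True)
class SplitSpec:
    """Training / evaluation year split for counterfactual prediction."""

    training_years: frozenset[int]
    evaluation_years: frozenset[int]

    def __post_init__(self) -> None:
        tr = frozenset(int(y) for y in self.training_years)
        ev = frozenset(int(y) for y in self.evaluation_years)
        if tr & ev:
            raise PanelValidationError("training and evaluation years overlap")
        if not tr:
            raise PanelValidationError("training years empty")
        if ev and min(ev) <= max(tr):
            raise PanelValidationError(
                "evaluation years must all lie strictly after the last training year"
            )
        object.__setattr__(self, "training_years", tr)
        object.__setattr__(self, "evaluation_years", ev)

    @classmethod
    def from_cutoff(cls, years: Iterable[int], cutoff: int) -> "SplitSpec":
        ys = sorted(int(y) for y in years)
        return cls(
            training_years=frozenset(y for y in ys if y <= cutoff),
            evaluation_years=frozenset(y for y in ys if y > cutoff),
        )

    @property
    def sorted_training(self) -> tuple[int, ...]:
        return tuple(sorted(self.training_years))

    @property
    def sorted_evaluation(self) -> tuple[int, ...]:
        return tuple(sorted(self.evaluation_years))


# ----------------------------------------------------------------------
# I/O


def read_panel(path: str | Path | io.IOBase, dialect: str = "csv") -> LicensePanel:
    """Read a long-format count panel.

    Parameters
    ----------
    path
        CSV file with columns ``province,region,year,count``.
    dialect
        ``"csv"`` (comma) or ``"tsv"`` (tab).
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise PanelSchemaError("empty file: expected a header row") from None
    return LicensePanel.from_frame(df)


def write_panel(panel: LicensePanel, path: str | Path | io.IOBase):
    """Write the canonical long-format CSV (stable column order and row sort)."""
    if isinstance(path, (str, Path)):
        path = Path(path)
    panel.to_frame().to_csv(path, index=False, lineterminator="\n")
    return path


def read_covariates(path: str | Path, dialect: str = "csv") -> CovariateTable:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise PanelSchemaError("empty file: expected a header row") from None
    return CovariateTable(df)


def write_covariates(table: CovariateTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, index=False, lineterminator="\n")
    return path


# ----------------------------------------------------------------------


def compute_excess_mortality(
    deaths_by_year: Mapping[int, float],
    target_year: int,
    baseline_years: Iterable[int],
) -> float:
    """Percentage increase of a year's deaths over a baseline mean.

    ``100 * (deaths[target] - mean(baseline deaths)) / mean(baseline deaths)``;
    the convention used for excess mortality relative to a 2015-2019 baseline.
    """
    baseline_years = list(baseline_years)
    if not baseline_years:
        raise ValueError("baseline_years must be non-empty")
    missing = [y for y in [target_year, *baseline_years] if y not in deaths_by_year]
    if missing:
        raise KeyError(f"years absent from deaths_by_year: {missing}")
    base = float(np.mean([deaths_by_year[y] for y in baseline_years]))
    if base == 0.0:
        raise ZeroDivisionError("baseline mean mortality is zero; excess undefined")
    return 100.0 * (float(deaths_by_year[target_year]) - base) / base
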