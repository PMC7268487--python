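"""Country-year panel container and CSV input/output.

The analysis operates on a single-year cross-section of countries with three
development covariates (GDP per capita, urbanization rate, neonatal mortality
rate) and two optional non-communicable-disease outcomes (the age-standardized
NCD mortality rate per 100,000 and NCD deaths as a percentage of all deaths).
Percentages are stored on the 0-100 scale throughout, matching how they are
printed in the sources. Missing outcomes are permitted and propagate as NaN;
they are excluded from fits, never imputed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: Canonical column order of a panel file.
PANEL_COLUMNS = [
    "country_id",
    "year",
    "gdp_per_capita",
    "urbanization_rate",
    "neonatal_mortality",
    "ncd_mortality_rate",
    "ncd_death_share",
]

#: Columns that must be present and non-missing in every row.
MANDATORY_COLUMNS = PANEL_COLUMNS[:5]

#: Outcome columns that may be missing (NaN) row-wise.
OPTIONAL_COLUMNS = PANEL_COLUMNS[5:]


class PanelValidationError(ValueError):
    """Raised when a panel violates the schema or a row-level invariant.

    ``problems`` holds one human-readable message per offending row/column.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid country panel:\n  " + "\n  ".join(self.problems)
        )


@dataclasses.dataclass(frozen=True)
class CountryRecord:
    """One country-year row of covariates and NCD outcomes."""

    country_id: str
    year: int
    gdp_per_capita: float
    urbanization_rate: float
    neonatal_mortality: float
    ncd_mortality_rate: float | None = None
    ncd_death_share: float | None = None

    def __post_init__(self) -> None:
        problems = _row_problems(
            self.country_id,
            self.gdp_per_capita,
            self.urbanization_rate,
            self.neonatal_mortality,
            self.ncd_mortality_rate,
            self.ncd_death_share,
        )
        if problems:
            raise PanelValidationError(
                [f"record {self.country_id!r}/{self.year}: {p}" for p in problems]
            )


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _row_problems(country_id, gdp, urban, neonatal, rate, share) -> list[str]:
    problems = []
    if not str(country_id).strip():
        problems.append("empty country_id")
    if _is_missing(gdp) or gdp <= 0:
        problems.append(f"gdp_per_capita must be > 0, got {gdp!r}")
    if _is_missing(urban) or not (0.0 <= urban <= 100.0):
        problems.append(f"urbanization_rate must be in [0, 100], got {urban!r}")
    if _is_missing(neonatal) or neonatal < 0:
        problems.append(f"neonatal_mortality must be >= 0, got {neonatal!r}")
    if not _is_missing(rate) and rate < 0:
        problems.append(f"ncd_mortality_rate must be >= 0, got {rate!r}")
    if not _is_missing(share) and not (0.0 <= share <= 100.0):
        problems.append(f"ncd_death_share must be in [0, 100], got {share!r}")
    return problems


class CountryPanel:
    """Validated collection of :class:`CountryRecord` rows keyed by (country, year).

    Thin wrapper over a :class:`pandas.DataFrame` with the canonical schema;
    ``panel.data`` exposes the frame (a copy-on-construction, canonical column
    order, default integer index).
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        problems: list[str] = []
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError([f"missing mandatory column(s): {missing}"])
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[PANEL_COLUMNS].reset_index(drop=True)
        df["country_id"] = df["country_id"].astype(str)
        for col in PANEL_COLUMNS[2:]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        try:
            df["year"] = df["year"].astype(int)
        except (ValueError, TypeError):
            raise PanelValidationError(["year column is not integer-valued"]) from None

        dup = df.duplicated(subset=["country_id", "year"], keep=False)
        if dup.any():
            keys = df.loc[dup, ["country_id", "year"]].drop_duplicates()
            problems.extend(
                f"duplicate key ({r.country_id!r}, {r.year})" for r in keys.itertuples()
            )
        for i, row in df.iterrows():
            for p in _row_problems(
                row["country_id"],
                row["gdp_per_capita"],
                row["urbanization_rate"],
                row["neonatal_mortality"],
                row["ncd_mortality_rate"],
                row["ncd_death_share"],
            ):
                problems.append(f"row {i}: {p}")
        if problems:
            raise PanelValidationError(problems)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountryPanel) and self.data.equals(other.data)

    def records(self) -> Iterator[CountryRecord]:
        for row in self.data.itertuples(index=False):
            yield CountryRecord(
                country_id=row.country_id,
                year=int(row.year),
                gdp_per_capita=float(row.gdp_per_capita),
                urbanization_rate=float(row.urbanization_rate),
                neonatal_mortality=float(row.neonatal_mortality),
                ncd_mortality_rate=(
                    None if pd.isna(row.ncd_mortality_rate) else float(row.ncd_mortality_rate)
                ),
                ncd_death_share=(
                    None if pd.isna(row.ncd_death_share) else float(row.ncd_death_share)
                ),
            )

    @classmethod
    def from_records(cls, records) -> "CountryPanel":
        return cls(pd.DataFrame([dataclasses.asdict(r) for r in records]))


def read_panel(path: str | Path, schema: Mapping[str, str] | None = None) -> CountryPanel:
    """Read a delimited country panel into a validated :class:`CountryPanel`.

    Parameters
    ----------
    path
        CSV file (RFC 4180, UTF-8, header row).
    schema
        Optional mapping from file column names to canonical names
        (e.g. ``{"Country Name": "country_id"}``). Unmapped canonical names
        must already be present in the file.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    return CountryPanel(df)


def write_panel(panel: CountryPanel, path: str | Path) -> None:
    """Write a panel as canonical CSV; ``read_panel`` round-trips it exactly."""
    panel.data.to_csv(path, index=False)
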