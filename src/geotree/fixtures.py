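"""Packaged reference data: country income-type listing and published q-values.

The income-type listing covers the 176 WHO member states used in the 2015
cross-sectional analysis, grouped into the four World Bank income bands
(type I low, II lower-middle, III upper-middle, IV high). The printed source
listing enumerates only 49 of the stated 50 lower-middle-income countries;
the missing entry is reconstructed as Eswatini (lower-middle income in the
World Bank 2018 classification and the only WHO member state of that band
absent from the listing) — a synthetic completion, flagged here.

``REFERENCE_Q`` carries the published Geodetector q-values for the two NCD
death indexes; they derive from the original WHO/World Bank extract, which is
not redistributable, so they are reference constants, not reproducible
quantities.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

#: Ordered income-type labels, least to most developed.
INCOME_TYPES = ("I", "II", "III", "IV")

#: Entries of the packaged listing that are synthetic completions rather than
#: transcriptions (see module docstring).
SYNTHETIC_TABLE1_ENTRIES = frozenset({"Eswatini"})


@dataclasses.dataclass(frozen=True)
class IncomeThresholds:
    """Upper GNI/GDP-per-capita bounds (current USD) of income bands I-III.

    Defaults are the World Bank 2018 operational thresholds: low income
    <= $1,025; lower-middle $1,026-$3,995; upper-middle $3,996-$12,375;
    high income >= $12,376.
    """

    low_max: float = 1025.0
    lower_mid_max: float = 3995.0
    upper_mid_max: float = 12375.0

    def __post_init__(self) -> None:
        if not (0 < self.low_max < self.lower_mid_max < self.upper_mid_max):
            raise ValueError(
                "income thresholds must satisfy 0 < low_max < lower_mid_max < upper_mid_max"
            )


DEFAULT_THRESHOLDS = IncomeThresholds()

#: Published factor-detector q-values of the two stage indicators against each
#: NCD death index (used for weight allocation), and of the resulting
#: classifications. Keys: response -> factor -> q.
REFERENCE_Q = {
    "ncd_mortality_rate": {
        "neonatal_mortality": 0.46647,
        "urbanization_rate": 0.389107,
        "income_type": 0.452723,
        "stage": 0.492107,
    },
    "ncd_death_share": {
        "neonatal_mortality": 0.780991,
        "urbanization_rate": 0.258799,
        "income_type": 0.612019,
        "stage": 0.735285,
    },
}

#: Published composite-stage weights (neonatal, urbanization) per response,
#: i.e. REFERENCE_Q ratios rounded to two decimals.
REFERENCE_WEIGHTS = {
    "ncd_mortality_rate": {"neonatal_mortality": 0.55, "urbanization_rate": 0.45},
    "ncd_death_share": {"neonatal_mortality": 0.75, "urbanization_rate": 0.25},
}


def load_table1_fixture(aliases: dict[str, str] | None = None) -> dict[str, str]:
    """Return the packaged mapping country name -> income type ("I".."IV").

    Matching is on the exact printed name; ``aliases`` optionally maps variant
    spellings onto the canonical names (e.g. ``{"Vietnam": "Viet Nam"}``).
    """
    path = resources.files("geotree.data") / "table1_income_types.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    mapping = dict(zip(df["country"], df["income_type"]))
    if len(mapping) != len(df):
        raise ValueError("duplicate country names in packaged listing")
    if aliases:
        for variant, canonical in aliases.items():
            if canonical not in mapping:
                raise KeyError(f"alias target {canonical!r} not in listing")
            mapping[variant] = mapping[canonical]
    return mapping


def table1_group_sizes() -> dict[str, int]:
    """Number of countries per income type in the packaged listing."""
    mapping = load_table1_fixture()
    return {t: sum(1 for v in mapping.values() if v == t) for t in INCOME_TYPES}
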