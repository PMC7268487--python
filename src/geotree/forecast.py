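"""Scenario construction and NCD-index forecasting for a target year.

The 2030 scenario combines projected GDP per capita and urbanization (e.g.
from Shared Socioeconomic Pathways tables supplied by the user) with neonatal
mortality linearly extrapolated per country from its 1960-2016 history.
Countries are then re-classified — income type, indicator strata and
composite stage — using the break points, weights and thresholds learned on
the base year (so stage semantics stay comparable across years), and the
fitted cross-classified model predicts each country's NCD index. The global
summary is the unweighted mean over countries by default; a population-
weighted mean is reported when a population column is supplied.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .mlm import CrossClassifiedMLMResults, MLMPredictor
from .panel import CountryPanel
from .tree import Geotree, assign_with_tree

logger = logging.getLogger(__name__)


def linear_extrapolate(series, target_year: int, clamp_zero: bool = True) -> float:
    """Evaluate the OLS line through (year, value) points at ``target_year``.

    ``series`` is a mapping year -> value or a pandas Series indexed by year;
    at least two distinct years are required. Mortality-type quantities are
    clamped at 0 from below (default).
    """
    if isinstance(series, pd.Series):
        years = series.index.to_numpy(dtype=float)
        values = series.to_numpy(dtype=float)
    else:
        years = np.array(sorted(series), dtype=float)
        values = np.array([series[int(y)] if int(y) in series else series[y] for y in years],
                          dtype=float)
    ok = ~np.isnan(values)
    years, values = years[ok], values[ok]
    if np.unique(years).size < 2:
        raise ValueError("linear extrapolation needs >= 2 distinct years")
    slope, intercept = np.polyfit(years, values, 1)
    value = intercept + slope * float(target_year)
    return max(value, 0.0) if clamp_zero else float(value)


@dataclasses.dataclass
class ScenarioPanel:
    """Target-year covariate panel with per-field provenance.

    ``provenance`` maps column -> {"projected", "extrapolated", "carried"};
    ``excluded`` lists countries dropped for missing projections.
    """

    panel: CountryPanel
    target_year: int
    provenance: dict
    excluded: list


@dataclasses.dataclass(frozen=True)
class GlobalSummary:
    """Global mean NCD indexes for the target year."""

    target_year: int
    mean_ncd_mortality_rate: float | None
    mean_ncd_death_share: float | None
    weighting: str = "unweighted"

    def __post_init__(self) -> None:
        if self.mean_ncd_mortality_rate is not None and self.mean_ncd_mortality_rate < 0:
            raise ValueError("mean NCD mortality rate must be >= 0")
        if self.mean_ncd_death_share is not None and not (
            0 <= self.mean_ncd_death_share <= 100
        ):
            raise ValueError("mean NCD death share must lie in [0, 100]")


def build_scenario(
    base_panel: CountryPanel,
    projections: pd.DataFrame,
    histories: pd.DataFrame,
    target_year: int = 2030,
) -> ScenarioPanel:
    """Assemble the target-year covariate panel.

    ``projections`` needs columns country_id, gdp_per_capita,
    urbanization_rate (optionally population); ``histories`` is long-format
    (country_id, year, neonatal_mortality). Countries of the base panel
    missing from the projections are excluded with a logged notice.
    """
    base = base_panel.data
    proj = projections.drop_duplicates(subset="country_id").set_index("country_id")
    needed = {"gdp_per_capita", "urbanization_rate"}
    if not needed.issubset(proj.columns):
        raise ValueError(f"projections must carry columns {sorted(needed)}")

    rows, excluded = [], []
    hist_groups = dict(tuple(histories.groupby("country_id")))
    for row in base.itertuples(index=False):
        cid = row.country_id
        if cid not in proj.index or pd.isna(proj.loc[cid, "gdp_per_capita"]) or pd.isna(
            proj.loc[cid, "urbanization_rate"]
        ):
            excluded.append(cid)
            continue
        h = hist_groups.get(cid)
        if h is None or len(h) < 2:
            excluded.append(cid)
            continue
        neonatal = linear_extrapolate(
            pd.Series(h["neonatal_mortality"].to_numpy(), index=h["year"].to_numpy()),
            target_year,
        )
        rec = {
            "country_id": cid,
            "year": target_year,
            "gdp_per_capita": float(proj.loc[cid, "gdp_per_capita"]),
            "urbanization_rate": float(proj.loc[cid, "urbanization_rate"]),
            "neonatal_mortality": neonatal,
        }
        if "population" in proj.columns:
            rec["population"] = float(proj.loc[cid, "population"])
        rows.append(rec)
    if excluded:
        logger.info(
            "build_scenario: excluded %d countries without projections/histories: %s",
            len(excluded), excluded,
        )
    if not rows:
        raise ValueError("no countries left after matching projections and histories")
    frame = pd.DataFrame(rows)
    population = frame.pop("population") if "population" in frame.columns else None
    scenario = ScenarioPanel(
        panel=CountryPanel(frame),
        target_year=target_year,
        provenance={
            "gdp_per_capita": "projected",
            "urbanization_rate": "projected",
            "neonatal_mortality": "extrapolated",
        },
        excluded=excluded,
    )
    if population is not None:
        scenario.panel.data["population"] = population.to_numpy()
    return scenario


def forecast_ncd(
    fit: CrossClassifiedMLMResults | MLMPredictor,
    scenario: ScenarioPanel,
    tree: Geotree,
    weighting: str = "unweighted",
) -> tuple[pd.DataFrame, GlobalSummary]:
    """Per-country predictions of the tree's response plus the global summary.

    Countries are re-classified from scenario covariates with the training-
    time tree (break points, weights, thresholds); predictions come from the
    fitted model's fixed part plus the BLUPs of the assigned groups.
    Death-share predictions are clipped into [0, 100] (the Gaussian model is
    unbounded) with a logged warning when clipping occurs.
    """
    if not getattr(fit, "converged", True):
        raise ValueError("refusing to forecast from a non-converged fit")
    assignments = assign_with_tree(tree, scenario.panel)
    frame = scenario.panel.data.merge(assignments, on="country_id", validate="1:1")
    frame["log_gdp_per_capita"] = np.log(frame["gdp_per_capita"])
    pred = fit.predict(frame)

    if tree.response == "ncd_death_share":
        out_of_range = (pred < 0) | (pred > 100)
        if out_of_range.any():
            logger.warning(
                "forecast_ncd: clipped %d death-share predictions into [0, 100]",
                int(out_of_range.sum()),
            )
        pred = np.clip(pred, 0.0, 100.0)
    else:
        pred = np.clip(pred, 0.0, None)

    predictions = assignments.assign(**{f"predicted_{tree.response}": pred})

    if weighting == "unweighted":
        mean_value = float(np.mean(pred))
    elif weighting == "population":
        if "population" not in frame.columns or frame["population"].isna().any():
            raise ValueError("population weighting requested but no population column")
        mean_value = float(np.average(pred, weights=frame["population"].to_numpy(float)))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    summary = GlobalSummary(
        target_year=scenario.target_year,
        mean_ncd_mortality_rate=mean_value if tree.response == "ncd_mortality_rate" else None,
        mean_ncd_death_share=mean_value if tree.response == "ncd_death_share" else None,
        weighting=weighting,
    )
    return predictions, summary
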