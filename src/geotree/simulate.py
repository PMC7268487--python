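"""Synthetic country panels with the generative structure the analysis assumes.

The generator emulates the statistical features of the real 2015 cross-section
that the downstream pipeline relies on, without attempting geographic realism:

* right-skewed GDP per capita (log-normal), spanning all four income bands;
* urbanization rising logistically with log GDP (noisy, clipped to [0, 100]);
* neonatal mortality falling linearly with log GDP (noisy, clipped at 0);
* outcomes built as beta0 + beta.x + u_t + u_s + e with Gaussian crossed
  group effects and residual — the cross-classified model's own data law;
* per-country 1960-2016 neonatal-mortality histories that are straight lines
  plus noise, for extrapolation tests.

Group memberships for u_t and u_s are assigned by the pipeline's own
classifiers applied to the simulated covariates (income thresholds, natural
breaks, weighted composite stage), so synthetic data exercises the
classification -> model chain end-to-end. Because pipeline stage weights are
derived from the outcome, which does not exist yet at assignment time, the
generator uses fixed stage weights (defaults = the published 0.55/0.45 and
0.75/0.25); the analysis still re-derives weights from q downstream.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd

from .breaks import natural_breaks
from .fixtures import DEFAULT_THRESHOLDS, IncomeThresholds
from .geodetector import WeightAllocation
from .panel import CountryPanel
from .tree import N_STAGES, STAGE_INDICATORS, classify_income_array, composite_stage

REFERENCE_YEAR = 2015
HISTORY_YEARS = (1960, 2016)


@dataclasses.dataclass(frozen=True)
class OutcomeEffects:
    """Effect structure of one NCD outcome index.

    ``beta`` are the coefficients on (log GDP per capita, urbanization rate,
    neonatal mortality); ``stage_weights`` = (neonatal, urbanization) weights
    used to assign the composite stage that carries u_s.
    """

    beta0: float
    beta: tuple[float, float, float]
    sigma_type: float
    sigma_stage: float
    sigma_resid: float
    stage_weights: tuple[float, float] = (0.55, 0.45)

    def __post_init__(self) -> None:
        if self.sigma_type < 0 or self.sigma_stage < 0:
            raise ValueError("group-effect SDs must be >= 0")
        if self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be > 0")


#: Death-share (% of all deaths) effects: rises with development, modest
#: group effects on the percentage scale, published 0.75/0.25 stage weights.
DEFAULT_SHARE_EFFECTS = OutcomeEffects(
    beta0=-21.0,
    beta=(8.0, 0.25, -0.3),
    sigma_type=3.0,
    sigma_stage=2.0,
    sigma_resid=1.5,
    stage_weights=(0.75, 0.25),
)


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults emulate the 176-country 2015 study scale.

    The primary outcome (written to ``ncd_mortality_rate``, per 100,000)
    defaults to a mean near 550 falling with development, with crossed group
    SDs 30 (income type) and 20 (stage) over a residual SD of 10.
    """

    n_countries: int = 176
    seed: int = 0
    # primary outcome (age-standardized NCD mortality rate)
    beta0: float = 840.0
    beta: tuple[float, float, float] = (-35.0, -1.2, 3.0)
    sigma_type: float = 30.0
    sigma_stage: float = 20.0
    sigma_resid: float = 10.0
    stage_weights: tuple[float, float] = (0.55, 0.45)
    # covariate generation
    gdp_log_mean: float = 8.3
    gdp_log_sd: float = 1.4
    urban_gdp_slope: float = 0.9
    urban_center: float = 8.3
    urban_noise_sd: float = 6.0
    neonatal_intercept: float = 95.0
    neonatal_gdp_slope: float = -9.0
    neonatal_noise_sd: float = 2.0
    # historical series
    series_years: tuple[int, int] = HISTORY_YEARS
    series_noise_sd: float = 0.5
    # secondary outcome (NCD death share); None disables it
    share_effects: OutcomeEffects | None = DEFAULT_SHARE_EFFECTS
    thresholds: IncomeThresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.n_countries < 8:
            raise ValueError("n_countries must be >= 8")
        for s in (self.sigma_type, self.sigma_stage, self.urban_noise_sd,
                  self.neonatal_noise_sd, self.series_noise_sd):
            if s < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be > 0")
        if self.series_years[0] >= self.series_years[1]:
            raise ValueError("series_years must be an increasing range")

    @property
    def primary_effects(self) -> OutcomeEffects:
        return OutcomeEffects(
            beta0=self.beta0,
            beta=self.beta,
            sigma_type=self.sigma_type,
            sigma_stage=self.sigma_stage,
            sigma_resid=self.sigma_resid,
            stage_weights=self.stage_weights,
        )


@dataclasses.dataclass
class TruthRecord:
    """Everything the generator drew, for oracle checks downstream."""

    params: SimulationParams
    assignments: pd.DataFrame  # per-outcome group memberships
    u_type: dict
    u_stage: dict
    share_u_type: dict | None
    share_u_stage: dict | None
    linear_predictor: np.ndarray
    share_linear_predictor: np.ndarray | None
    history_lines: dict = dataclasses.field(default_factory=dict)

    def true_mean_response(self) -> np.ndarray:
        """E[y | covariates, realized group effects] for the primary outcome."""
        return self.linear_predictor


def _stage_assign(
    neonatal, urban, weights: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = WeightAllocation(
        {
            STAGE_INDICATORS[0]: weights[0] / sum(weights),
            STAGE_INDICATORS[1]: weights[1] / sum(weights),
        }
    )
    neo_strata = natural_breaks(neonatal, N_STAGES).class_of
    urb_strata = natural_breaks(urban, N_STAGES).class_of
    return neo_strata, urb_strata, composite_stage(neo_strata, urb_strata, w)


def generate_panel(params: SimulationParams) -> tuple[CountryPanel, TruthRecord]:
    """Draw one synthetic reference-year cross-section plus its truth record."""
    rng = np.random.default_rng(params.seed)
    n = params.n_countries

    log_gdp = rng.normal(params.gdp_log_mean, params.gdp_log_sd, n)
    gdp = np.exp(log_gdp)
    urban = 100.0 / (1.0 + np.exp(-params.urban_gdp_slope * (log_gdp - params.urban_center)))
    urban = np.clip(urban + rng.normal(0.0, params.urban_noise_sd, n), 0.0, 100.0)
    neonatal = params.neonatal_intercept + params.neonatal_gdp_slope * log_gdp
    neonatal = np.clip(neonatal + rng.normal(0.0, params.neonatal_noise_sd, n), 0.0, None)

    income = classify_income_array(gdp, params.thresholds)
    X = np.column_stack([log_gdp, urban, neonatal])

    def build_outcome(eff: OutcomeEffects, tag: str):
        neo_s, urb_s, stage = _stage_assign(neonatal, urban, eff.stage_weights)
        u_t = {t: rng.normal(0.0, eff.sigma_type) for t in ("I", "II", "III", "IV")}
        u_s = {s: rng.normal(0.0, eff.sigma_stage) for s in range(1, N_STAGES + 1)}
        lin = (
            eff.beta0
            + X @ np.asarray(eff.beta)
            + np.array([u_t[t] for t in income])
            + np.array([u_s[int(s)] for s in stage])
        )
        y = lin + rng.normal(0.0, eff.sigma_resid, n)
        cols = {
            f"{tag}income_type": income,
            f"{tag}neonatal_stratum": neo_s,
            f"{tag}urban_stratum": urb_s,
            f"{tag}stage": stage,
        }
        return y, lin, u_t, u_s, cols

    y1, lin1, u_t, u_s, cols1 = build_outcome(params.primary_effects, "")
    y1 = np.clip(y1, 0.0, None)

    if params.share_effects is not None:
        y2, lin2, su_t, su_s, cols2 = build_outcome(params.share_effects, "share_")
        y2 = np.clip(y2, 0.0, 100.0)
    else:
        y2 = np.full(n, np.nan)
        lin2, su_t, su_s, cols2 = None, None, None, {}

    country_ids = np.array([f"C{i:03d}" for i in range(1, n + 1)])
    panel = CountryPanel(
        pd.DataFrame(
            {
                "country_id": country_ids,
                "year": REFERENCE_YEAR,
                "gdp_per_capita": gdp,
                "urbanization_rate": urban,
                "neonatal_mortality": neonatal,
                "ncd_mortality_rate": y1,
                "ncd_death_share": y2,
            }
        )
    )
    assignments = pd.DataFrame({"country_id": country_ids, **cols1, **cols2})
    truth = TruthRecord(
        params=params,
        assignments=assignments,
        u_type=u_t,
        u_stage=u_s,
        share_u_type=su_t,
        share_u_stage=su_s,
        linear_predictor=lin1,
        share_linear_predictor=lin2,
    )
    return panel, truth


def generate_history(
    params: SimulationParams,
    country_id: str,
    anchor: float = 20.0,
    slope: float | None = None,
) -> tuple[pd.Series, float, float]:
    """One country's yearly neonatal-mortality series over ``series_years``.

    The series is intercept + slope*year + Gaussian noise, clipped at 0; the
    slope is non-positive (medical development only improves). The line is
    anchored so its value at the final year equals ``anchor``. Returns
    (series, intercept, slope) — the true line for oracle use. Deterministic
    per (params.seed, country_id).
    """
    sub = zlib.crc32(str(country_id).encode("utf-8"))
    rng = np.random.default_rng([params.seed, sub])
    if slope is None:
        slope = -rng.uniform(0.1, 0.8)
    if slope > 0:
        raise ValueError("neonatal-mortality trend slope must be <= 0")
    y0, y1 = params.series_years
    intercept = anchor - slope * y1
    years = np.arange(y0, y1 + 1)
    values = intercept + slope * years
    if params.series_noise_sd > 0:
        values = values + rng.normal(0.0, params.series_noise_sd, years.size)
    series = pd.Series(np.clip(values, 0.0, None), index=years, name=str(country_id))
    return series, float(intercept), float(slope)


def generate_histories(
    params: SimulationParams,
    country_ids,
    anchors=None,
    truth: TruthRecord | None = None,
) -> pd.DataFrame:
    """Long-format histories (country_id, year, neonatal_mortality) for many
    countries; true lines are stored into ``truth.history_lines`` if given."""
    frames = []
    for i, cid in enumerate(country_ids):
        anchor = 20.0 if anchors is None else float(np.asarray(anchors)[i])
        series, intercept, slope = generate_history(params, cid, anchor=anchor)
        if truth is not None:
            truth.history_lines[str(cid)] = (intercept, slope)
        frames.append(
            pd.DataFrame(
                {
                    "country_id": str(cid),
                    "year": series.index,
                    "neonatal_mortality": series.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
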