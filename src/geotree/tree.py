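"""Two-level development tree: income-type branches, q-weighted stage trunks.

The tree stratifies countries twice. First branches: four World Bank income
bands on GDP per capita (a stand-in for GNI per capita, to which it is roughly
equivalent). Second trunks: each of the two development-stage indicators
(neonatal mortality, urbanization rate) is cut into six strata by Fisher-Jenks
natural breaks; the factor-detector q of each indicator against the NCD
response sets proportional weights; the composite development stage is the
weighted stratum mean rounded half-up to an integer 1..6. Neonatal strata are
reverse-oriented before weighting so that a higher stratum always means more
developed (stage trends would otherwise be incoherent between the two
indicators). Countries are the leaves.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .breaks import BreaksResult, assign_classes, natural_breaks
from .fixtures import DEFAULT_THRESHOLDS, INCOME_TYPES, IncomeThresholds
from .geodetector import (
    QResult,
    WeightAllocation,
    allocate_weights,
    q_significance,
    q_statistic,
)
from .panel import CountryPanel

#: The two development-stage indicator columns, in weighting order.
STAGE_INDICATORS = ("neonatal_mortality", "urbanization_rate")

#: Number of strata per indicator and of composite stages.
N_STAGES = 6


def classify_income(
    per_capita_income: float, thresholds: IncomeThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Income type "I".."IV" of a per-capita income (USD).

    Band upper bounds are inclusive: exactly ``low_max`` is still type I.
    """
    if not per_capita_income > 0:
        raise ValueError(f"per-capita income must be positive, got {per_capita_income!r}")
    if per_capita_income <= thresholds.low_max:
        return "I"
    if per_capita_income <= thresholds.lower_mid_max:
        return "II"
    if per_capita_income <= thresholds.upper_mid_max:
        return "III"
    return "IV"


def classify_income_array(
    incomes, thresholds: IncomeThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Vectorized :func:`classify_income`."""
    x = np.asarray(incomes, dtype=float)
    if not (x > 0).all():
        raise ValueError("per-capita incomes must be positive")
    cuts = [thresholds.low_max, thresholds.lower_mid_max, thresholds.upper_mid_max]
    idx = np.searchsorted(cuts, x, side="left")
    return np.asarray(INCOME_TYPES, dtype=object)[idx]


def orient_neonatal(stratum) -> np.ndarray | int:
    """Reverse a 1..6 neonatal-mortality stratum so 6 = lowest mortality."""
    return (N_STAGES + 1) - np.asarray(stratum) if np.ndim(stratum) else (N_STAGES + 1) - stratum


def composite_stage(
    neonatal_stratum, urban_stratum, weights: WeightAllocation
) -> np.ndarray:
    """Composite development stage from the two oriented indicator strata.

    stage = round-half-up( w_n * (7 - neonatal_stratum) + w_u * urban_stratum ),
    clamped to 1..6. Monotone non-decreasing in each oriented stratum.
    """
    w_n = weights[STAGE_INDICATORS[0]]
    w_u = weights[STAGE_INDICATORS[1]]
    oriented = orient_neonatal(np.asarray(neonatal_stratum, dtype=float))
    score = w_n * oriented + w_u * np.asarray(urban_stratum, dtype=float)
    stage = np.floor(score + 0.5).astype(int)  # round half up
    return np.clip(stage, 1, N_STAGES)


@dataclasses.dataclass(frozen=True)
class GeotreeAssignment:
    """Per-country classification: income type, indicator strata, stage."""

    country_id: str
    income_type: str
    neonatal_stratum: int
    urban_stratum: int
    stage: int

    def __post_init__(self) -> None:
        if self.income_type not in INCOME_TYPES:
            raise ValueError(f"bad income type {self.income_type!r}")
        for v in (self.neonatal_stratum, self.urban_stratum, self.stage):
            if not 1 <= v <= N_STAGES:
                raise ValueError("strata and stage must lie in 1..6")


@dataclasses.dataclass
class Geotree:
    """Branch (income type) -> trunk (stage) -> leaf (country) hierarchy.

    ``branches`` maps income type -> stage -> sorted list of country ids;
    metadata records the response the tree was built against, the indicator
    weights, break points, q-results and thresholds, so the same
    classification can be re-applied to new covariate values.
    """

    response: str
    weights: dict
    breaks: dict
    thresholds: IncomeThresholds
    q: dict
    branches: dict

    def leaf_count(self) -> int:
        return sum(len(v) for t in self.branches.values() for v in t.values())

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "weights": dict(self.weights),
            "breaks": {k: list(v) for k, v in self.breaks.items()},
            "thresholds": dataclasses.asdict(self.thresholds),
            "q": {k: {"q": r.q, "p_value": r.p_value} for k, r in self.q.items()},
            "branches": [
                {
                    "type": t,
                    "trunks": [
                        {"stage": s, "leaves": list(self.branches[t][s])}
                        for s in sorted(self.branches[t])
                        if self.branches[t][s]
                    ],
                }
                for t in INCOME_TYPES
                if self.branches.get(t)
            ],
        }


def build_geotree(
    panel: CountryPanel,
    response: str,
    thresholds: IncomeThresholds = DEFAULT_THRESHOLDS,
    k: int = N_STAGES,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> tuple[Geotree, pd.DataFrame]:
    """Build the two-level tree for one NCD response column.

    Steps: income classification per country; natural breaks (k strata) on
    each stage indicator over the full cross-section; factor-detector q of
    each indicator's strata against the response (rows with missing response
    are dropped pairwise inside q); proportional weight allocation; composite
    stage per country; branch/trunk/leaf assembly.

    Returns the tree and an assignments frame with columns country_id,
    income_type, neonatal_stratum, urban_stratum, stage.
    """
    df = panel.data
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not in panel")

    income = classify_income_array(df["gdp_per_capita"].to_numpy(), thresholds)

    strata: dict[str, BreaksResult] = {}
    qres: dict[str, QResult] = {}
    for col in STAGE_INDICATORS:
        br = natural_breaks(df[col].to_numpy(), k)
        strata[col] = br
        if n_permutations:
            qres[col] = q_significance(
                df[response].to_numpy(), br.class_of, n_permutations, seed
            )
        else:
            qres[col] = q_statistic(df[response].to_numpy(), br.class_of)

    weights = allocate_weights({c: qres[c].q for c in STAGE_INDICATORS})
    stage = composite_stage(
        strata[STAGE_INDICATORS[0]].class_of,
        strata[STAGE_INDICATORS[1]].class_of,
        weights,
    )

    assignments = pd.DataFrame(
        {
            "country_id": df["country_id"].to_numpy(),
            "income_type": income,
            "neonatal_stratum": strata[STAGE_INDICATORS[0]].class_of,
            "urban_stratum": strata[STAGE_INDICATORS[1]].class_of,
            "stage": stage,
        }
    )

    branches: dict[str, dict[int, list[str]]] = {t: {} for t in INCOME_TYPES}
    for row in assignments.itertuples(index=False):
        branches[row.income_type].setdefault(int(row.stage), []).append(row.country_id)
    for t in branches:
        for s in branches[t]:
            branches[t][s].sort()

    tree = Geotree(
        response=response,
        weights=dict(weights.weights),
        breaks={c: strata[c].breaks for c in STAGE_INDICATORS},
        thresholds=thresholds,
        q=qres,
        branches=branches,
    )
    return tree, assignments


def assign_with_tree(tree: Geotree, panel: CountryPanel) -> pd.DataFrame:
    """Classify (possibly new) countries with a built tree's break points,
    weights and thresholds — no re-estimation."""
    df = panel.data
    income = classify_income_array(df["gdp_per_capita"].to_numpy(), tree.thresholds)
    neo = assign_classes(df["neonatal_mortality"].to_numpy(), tree.breaks[STAGE_INDICATORS[0]])
    urb = assign_classes(df["urbanization_rate"].to_numpy(), tree.breaks[STAGE_INDICATORS[1]])
    # break points cut the training range into 6 classes; new values beyond the
    # extremes still map into classes 1/6 by construction of assign_classes,
    # but guard the upper side explicitly
    neo = np.clip(neo, 1, N_STAGES)
    urb = np.clip(urb, 1, N_STAGES)
    weights = WeightAllocation(dict(tree.weights))
    stage = composite_stage(neo, urb, weights)
    return pd.DataFrame(
        {
            "country_id": df["country_id"].to_numpy(),
            "income_type": income,
            "neonatal_stratum": neo,
            "urban_stratum": urb,
            "stage": stage,
        }
    )


def export_tree(tree: Geotree, path: str | Path) -> None:
    """Serialize a tree to schema-stable JSON (empty trunks omitted)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree.to_dict(), fh, indent=2, ensure_ascii=False)


def load_tree(path: str | Path) -> Geotree:
    """Inverse of :func:`export_tree` (lossless for occupied trunks)."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    branches: dict[str, dict[int, list[str]]] = {}
    for b in d["branches"]:
        branches[b["type"]] = {int(t["stage"]): list(t["leaves"]) for t in b["trunks"]}
    qres = {k: _ref_q(v) for k, v in d["q"].items()}
    return Geotree(
        response=d["response"],
        weights=dict(d["weights"]),
        breaks={k: tuple(v) for k, v in d["breaks"].items()},
        thresholds=IncomeThresholds(**d["thresholds"]),
        q=qres,
        branches=branches,
    )


def _ref_q(v: dict) -> QResult:
    # reconstruct a QResult carrying only q (and p); decomposition chosen
    # consistently so the dataclass invariants hold
    q = float(v["q"])
    return QResult(
        q=q, n_total=0, ssw=1.0 - q, sst=1.0, stratum_sizes={}, p_value=v.get("p_value")
    )
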