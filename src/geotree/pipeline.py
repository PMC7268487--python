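"""End-to-end pipeline: simulate -> classify -> detect -> fit -> evaluate -> forecast.

A single declarative YAML config drives the run; every stochastic stage has a
named seed, and a manifest (config hash, seeds, package version, artifact
list) is written so a run can be reconstructed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fixtures import DEFAULT_THRESHOLDS, IncomeThresholds
from .forecast import build_scenario, forecast_ncd
from .mlm import CrossClassifiedSpec, DEFAULT_COVARIATES, design_frame, fit_crossed_mlm, holdout_evaluate
from .panel import read_panel, write_panel
from .simulate import SimulationParams, generate_histories, generate_panel
from .tree import build_geotree, export_tree


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (flags may override config values)."""

    out_dir: str
    panel_path: str | None = None          # None -> simulate a panel
    response: str = "ncd_mortality_rate"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    k_strata: int = 6
    thresholds: IncomeThresholds = DEFAULT_THRESHOLDS
    train_fraction: float = 0.7
    permutations: int = 999
    target_year: int = 2030
    n_countries: int = 176
    seeds: dict = dataclasses.field(
        default_factory=lambda: {"simulate": 1, "detect": 2, "holdout": 3}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.k_strata < 2:
            raise ValueError("k_strata must be >= 2")
        if self.permutations < 99:
            raise ValueError("permutations must be >= 99")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = IncomeThresholds(**raw["thresholds"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["covariates"] = list(self.covariates)
        return d


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Artifacts: panel.csv, assignments.csv, tree.json, q_table.csv, fit.json,
    evaluation.json, scenario.csv, forecasts.csv, summary.json, manifest.json.
    Any stage error aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stage = "setup"
    try:
        stage = "input"
        if config.panel_path:
            panel = read_panel(config.panel_path)
            truth = None
        else:
            params = SimulationParams(
                n_countries=config.n_countries, seed=config.seeds["simulate"]
            )
            panel, truth = generate_panel(params)
        write_panel(panel, out / "panel.csv")
        artifacts.append("panel.csv")

        stage = "classify"
        tree, assignments = build_geotree(
            panel,
            config.response,
            thresholds=config.thresholds,
            k=config.k_strata,
            n_permutations=config.permutations,
            seed=config.seeds["detect"],
        )
        assignments.to_csv(out / "assignments.csv", index=False)
        export_tree(tree, out / "tree.json")
        artifacts += ["assignments.csv", "tree.json"]

        stage = "detect"
        q_rows = [
            {
                "factor": name,
                "q": res.q,
                "p_value": res.p_value,
                "n": res.n_total,
                "n_permutations": res.n_permutations,
            }
            for name, res in tree.q.items()
        ]
        pd.DataFrame(q_rows).to_csv(out / "q_table.csv", index=False)
        artifacts.append("q_table.csv")

        stage = "fit"
        frame = design_frame(panel.data, assignments)
        spec = CrossClassifiedSpec(config.response, tuple(config.covariates))
        fit = fit_crossed_mlm(frame, spec)
        fit.save(out / "fit.json")
        artifacts.append("fit.json")

        stage = "evaluate"
        ev = holdout_evaluate(
            frame, spec, train_fraction=config.train_fraction,
            seed=config.seeds["holdout"],
        )
        with open(out / "evaluation.json", "w", encoding="utf-8") as fh:
            json.dump({k: v for k, v in ev.items() if isinstance(v, (int, float))},
                      fh, indent=2)
        artifacts.append("evaluation.json")

        stage = "forecast"
        # identity projections (base-year GDP/urbanization) unless the caller
        # supplies SSP-style tables through the CLI; histories from the
        # generator when the panel is synthetic
        proj = panel.data[["country_id", "gdp_per_capita", "urbanization_rate"]]
        if truth is not None:
            histories = generate_histories(
                truth.params, panel.data["country_id"],
                anchors=panel.data["neonatal_mortality"].to_numpy(), truth=truth,
            )
        else:
            histories = panel.data[["country_id", "year", "neonatal_mortality"]]
            # a single base year cannot be extrapolated; carry it flat
            histories = pd.concat(
                [histories, histories.assign(year=histories["year"] - 1)],
                ignore_index=True,
            )
        scenario = build_scenario(panel, proj, histories, config.target_year)
        write_panel(scenario.panel, out / "scenario.csv")
        predictions, summary = forecast_ncd(fit, scenario, tree)
        predictions.to_csv(out / "forecasts.csv", index=False)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(summary), fh, indent=2)
        artifacts += ["scenario.csv", "forecasts.csv", "summary.json"]

        stage = "manifest"
        cfg = config.to_jsonable()
        manifest = {
            "version": __version__,
            "config": cfg,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "seeds": config.seeds,
            "artifacts": artifacts,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
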