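"""End-to-end orchestration: simulate/load -> (select) -> fit -> predict ->
flag -> aggregate -> associate, with every output persisted and a manifest
that suffices to reproduce the run.

Configuration is a nested-section YAML file (see :class:`PipelineConfig`);
every run writes its fully resolved configuration next to its outputs.  All
randomness derives from the single master seed.  A stage failure raises
:class:`PipelineError` tagged with the stage name; the manifest is still
written, marked incomplete.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anomalies import aggregate_all, flag_anomalies
from .association import associate
from .model import NegativeBinomialTrendModel, PriorSpec, SamplerConfig
from .panel import (
    CovariateTable,
    SplitSpec,
    read_covariates,
    read_panel,
    write_covariates,
)
from .selection import default_candidates, select
from .simulate import SimulationConfig, config_metadata, simulate_panel, summarize_truth

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("huntwatch")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved pipeline configuration.

    ``panel``/``covariates`` are input paths; when ``panel`` is None the
    synthetic generator runs with the ``simulate`` overrides.  ``seed`` is
    the master seed for every stage.
    """

    seed: int = 0
    panel: str | None = None
    covariates: str | None = None
    simulate: dict = field(default_factory=dict)
    training_cutoff: int = 2019
    model: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    selection: dict = field(default_factory=lambda: {"enabled": False})
    anomaly: dict = field(default_factory=lambda: {"strict": True})
    association: dict = field(default_factory=lambda: {"policy": "flagged"})

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> PipelineConfig:
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as f:
            loaded = yaml.safe_load(f) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(int(seed)).generate_state(4, dtype=np.uint32) >> 1
    return {
        "simulate": int(state[0]),
        "sampler": int(state[1]),
        "predict": int(state[2]),
        "spare": int(state[3]),
    }


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, lineterminator="\n")
    return path.name


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "package": "huntwatch",
        "version": __version__,
        "seed": int(config.seed),
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "status": "incomplete",
        "outputs": [],
        "stages": {},
    }
    with open(out / "resolved_config.yaml", "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)
    manifest["outputs"].append("resolved_config.yaml")

    def finish(status: str) -> None:
        manifest["status"] = status
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True, default=str)

    current_stage = {"name": "input"}

    def stage(name: str):
        current_stage["name"] = name
        log.info("stage %s: start", name)
        t0 = time.monotonic()

        def done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.monotonic() - t0, 2),
                **info,
            }
            log.info("stage %s: done in %.1fs", name, time.monotonic() - t0)

        return done

    try:
        # -------------------------------------------------- input stage
        done = stage("input")
        covariates: CovariateTable | None = None
        if config.panel is not None:
            panel = read_panel(config.panel)
            if config.covariates is not None:
                covariates = read_covariates(config.covariates)
            done(source="files", panel=str(config.panel))
        else:
            sim_cfg = SimulationConfig(**config.simulate)
            panel, covariates, truth = simulate_panel(sim_cfg, seed=seeds["simulate"])
            _write_csv(panel.to_frame(), out / "panel.csv")
            write_covariates(covariates, out / "covariates.csv")
            _write_csv(summarize_truth(truth), out / "ground_truth.csv")
            manifest["outputs"] += ["panel.csv", "covariates.csv", "ground_truth.csv"]
            manifest["simulation"] = config_metadata(sim_cfg, seed=seeds["simulate"])
            done(source="synthetic", n_provinces=len(panel.provinces))
        split = SplitSpec.from_cutoff(panel.years, config.training_cutoff)
        if not split.evaluation_years:
            raise ValueError(
                f"no evaluation years after cutoff {config.training_cutoff}"
            )
        manifest["validation"] = panel.validation_report()

        # ---------------------------------------------- selection stage
        model_kwargs = dict(config.model)
        if config.selection.get("enabled", False):
            done = stage("select")
            best, table = select(
                panel,
                split,
                candidates=default_candidates(),
                priors=PriorSpec(**config.priors) if config.priors else None,
                sampler_config=SamplerConfig(
                    seed=seeds["sampler"], **config.sampler
                ),
                loo_method=config.selection.get("loo_method", "auto"),
            )
            _write_csv(table, out / "model_comparison.csv")
            manifest["outputs"].append("model_comparison.csv")
            model_kwargs = {
                "include_linear_trend": best.include_linear_trend,
                "rw_order": best.rw_order,
                "intercept_structure": best.intercept_structure,
            }
            done(selected=best.label)

        # ---------------------------------------------------- fit stage
        done = stage("fit")
        est = NegativeBinomialTrendModel(
            training_cutoff=config.training_cutoff,
            priors=PriorSpec(**config.priors) if config.priors else None,
            seed=seeds["sampler"],
            **{**config.sampler, **model_kwargs},
        )
        est.fit(panel, split=split)
        diags = est.diagnostics_
        draws_df = est.draws_.to_frame()
        _write_csv(draws_df, out / "posterior_draws.csv")
        meta = est.draws_.meta()
        meta["diagnostics"] = diags.summary()
        with open(out / "posterior_draws_meta.json", "w") as f:
            json.dump(meta, f, indent=2, sort_keys=True)
        manifest["outputs"] += ["posterior_draws.csv", "posterior_draws_meta.json"]
        manifest["diagnostics"] = {
            "max_rhat": diags.max_rhat,
            "min_ess_bulk": diags.min_ess_bulk,
            "usable": diags.usable,
        }
        if not diags.usable:
            raise RuntimeError(
                f"fit flagged unusable: max R-hat {diags.max_rhat:.3f} > 1.05"
            )
        done(max_rhat=round(diags.max_rhat, 4))

        # ------------------------------------------------ predict stage
        done = stage("predict")
        summary = est.predictive_summary(seed=seeds["predict"])
        _write_csv(summary, out / "predictive_summary.csv")
        manifest["outputs"].append("predictive_summary.csv")
        done(n_rows=len(summary))

        # ------------------------------------------------- detect stage
        done = stage("detect")
        strict = bool(config.anomaly.get("strict", True))
        records = pd.concat(
            [
                flag_anomalies(summary, panel, yr, strict=strict)
                for yr in split.sorted_evaluation
            ],
            ignore_index=True,
        )
        _write_csv(records, out / "anomalies.csv")
        regional = aggregate_all(records)
        _write_csv(regional, out / "regional_aggregates.csv")
        manifest["outputs"] += ["anomalies.csv", "regional_aggregates.csv"]
        done(n_flagged=int((records["flag"] == "decrease").sum()))

        # ---------------------------------------------- associate stage
        done = stage("associate")
        if covariates is None:
            manifest["association"] = "skipped: no covariate table provided"
            done(skipped=True)
        else:
            policy = config.association.get("policy", "flagged")
            pairings = config.association.get("pairings")
            eval_years = split.sorted_evaluation
            if pairings is None:
                pairings = [[y, y] for y in eval_years]
                pairings += [[y, eval_years[0]] for y in eval_years[1:]]
            rows = []
            for ay, cy in pairings:
                try:
                    res = associate(records, covariates, ay, cy, policy=policy)
                    rows.append(
                        {
                            "anomaly_year": res.anomaly_year,
                            "covariate_year": res.covariate_year,
                            "n": res.n,
                            "rho": res.rho,
                            "policy": res.policy,
                            "note": "",
                        }
                    )
                except ValueError as exc:
                    rows.append(
                        {
                            "anomaly_year": int(ay),
                            "covariate_year": int(cy),
                            "n": 0,
                            "rho": np.nan,
                            "policy": policy,
                            "note": f"skipped: {exc}",
                        }
                    )
            assoc = pd.DataFrame(rows)
            _write_csv(assoc, out / "association.csv")
            manifest["outputs"].append("association.csv")
            done(n_pairings=len(rows))
    except Exception as exc:  # tag with the failing stage and persist
        failing = current_stage["name"]
        finish(f"failed at stage {failing}")
        raise PipelineError(failing, str(exc)) from exc

    finish("complete")
    return manifest
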