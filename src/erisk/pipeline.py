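"""Configured end-to-end pipeline: simulate → impute → fit → project → validate → dca.

A pipeline run is described by a YAML/JSON mapping (see
:class:`PipelineConfig`); every stage is seeded from the single top-level
seed, all tabular outputs are CSV and models/reports JSON, and a manifest
records inputs, outputs, seeds, package versions and wall time per stage,
so that identical configurations reproduce identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .absolute_risk import project_risks
from .cohort import read_cohort, validate_cohort, write_cohort
from .coding import CAUSES
from .config import CovariateConfig, default_covariate_config
from .decision_curve import applicability_area, net_benefit_curve
from .hazards import fit_gompertz, fit_piecewise, split_person_time
from .imputation import impute_chained, pool_rubin
from .models import RiskModel, default_model_spec
from .synthetic import TrueModel, epic_like_true_model, generate_covariates, inject_missingness, simulate_outcomes
from .validation import crossvalidate_5fold

log = logging.getLogger("erisk.pipeline")

_ALL_STAGES = ("simulate", "impute", "fit", "project", "validate", "dca")


@dataclass
class PipelineConfig:
    seed: int = 0
    n: int = 20_000
    outdir: str = "erisk_out"
    stages: dict[str, bool] = field(default_factory=lambda: {s: s != "impute" for s in _ALL_STAGES})
    cohort_path: str | None = None  # skip simulation, load this cohort instead
    covariate_config: str | None = None
    true_model: str | None = None
    missingness: dict[str, float] = field(default_factory=dict)
    with_stratum: bool = False
    horizon: float = 5.0
    m_imputations: int = 5
    sweeps: int = 10
    dca_cause: str = "er_pos"
    dca_grid_step: float = 5e-4

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls(**{k: v for k, v in data.items() if k != "stages"})
        if "stages" in data:
            cfg.stages.update(data["stages"])
        unknown = set(cfg.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages {sorted(unknown)}")
        return cfg


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the enabled stages in order; returns the manifest."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.load(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "libraries": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "stages": [],
    }

    def record(stage: str, outputs: list[str], t0: float, **extra) -> None:
        manifest["stages"].append(
            {"stage": stage, "outputs": outputs, "seed": config.seed, "wall_time_s": round(time.time() - t0, 3), **extra}
        )

    cohort = None
    tables = None
    risk_model = None
    spec = default_model_spec(with_stratum=config.with_stratum)

    try:
        if config.stages.get("simulate", True) and config.cohort_path is None:
            t0 = time.time()
            log.info("[simulate] n=%d seed=%d", config.n, config.seed)
            cov_cfg = (
                CovariateConfig.load(config.covariate_config)
                if config.covariate_config
                else default_covariate_config()
            )
            truth = (
                TrueModel.load(config.true_model) if config.true_model else epic_like_true_model()
            )
            cohort = generate_covariates(config.n, cov_cfg, seed=config.seed)
            cohort = simulate_outcomes(cohort, truth, seed=config.seed + 1)
            if config.missingness:
                cohort = inject_missingness(cohort, config.missingness, seed=config.seed + 2)
            path = outdir / "cohort.csv"
            write_cohort(cohort, path)
            record("simulate", [str(path)], t0, n=config.n)
        elif config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
            validate_cohort(cohort)

        if cohort is None:
            raise RuntimeError("no cohort available: enable the simulate stage or set cohort_path")

        if config.stages.get("impute", False):
            t0 = time.time()
            log.info("[impute] m=%d sweeps=%d", config.m_imputations, config.sweeps)
            imp = impute_chained(cohort, m=config.m_imputations, sweeps=config.sweeps, seed=config.seed + 10)
            tables = imp.tables
            paths = []
            for j, tab in enumerate(tables, start=1):
                p = outdir / f"imputed_{j}.csv"
                write_cohort(tab, p)
                paths.append(str(p))
            record("impute", paths, t0, m=imp.m)
        else:
            tables = [cohort]

        if config.stages.get("fit", True):
            t0 = time.time()
            log.info("[fit] %d table(s)", len(tables))
            fits = [fit_piecewise(split_person_time(t, spec.cutoffs), spec) for t in tables]
            gomps = [fit_gompertz(t) for t in tables]
            names = spec.param_names()
            vectors = [np.array([f.params.get(nm, 0.0) for nm in names]) for f in fits]
            covs = [f.cov.reindex(index=names, columns=names).fillna(0.0).to_numpy() for f in fits]
            pooled = pool_rubin(vectors, covs)
            model = fits[0]
            model.params = {nm: float(v) for nm, v in zip(names, pooled.mean)}
            model.cov = pd.DataFrame(pooled.total, index=names, columns=names)
            gomp = gomps[0]
            gomp.alpha = float(np.mean([g.alpha for g in gomps]))
            gomp.gamma = float(np.mean([g.gamma for g in gomps]))
            risk_model = RiskModel(piecewise=model, gompertz=gomp)
            path = outdir / "model.json"
            risk_model.save(path)
            record("fit", [str(path)], t0, loglik=model.loglik)

        risks = None
        if config.stages.get("project", True):
            if risk_model is None:
                raise RuntimeError("project stage requires the fit stage")
            t0 = time.time()
            log.info("[project] horizon=%.1f", config.horizon)
            risks = project_risks(
                risk_model.piecewise, risk_model.gompertz, tables[0], horizon=config.horizon
            )
            path = outdir / "risks.csv"
            risks.to_csv(path, index=False)
            record("project", [str(path)], t0)

        if config.stages.get("validate", True):
            t0 = time.time()
            log.info("[validate] fivefold cross-validation")
            report = crossvalidate_5fold(
                tables[0], spec, seed=config.seed + 20, horizon=config.horizon, n_bootstrap=50
            )
            path = outdir / "validation.json"
            path.write_text(json.dumps(report.to_dict(), indent=2))
            record("validate", [str(path)], t0)

        if config.stages.get("dca", True):
            if risks is None:
                raise RuntimeError("dca stage requires the project stage")
            t0 = time.time()
            cause = config.dca_cause
            log.info("[dca] cause=%s", cause)
            time_in = tables[0]["exit_age"].to_numpy() - tables[0]["entry_age"].to_numpy()
            outcome = (tables[0]["event"].to_numpy() == cause) & (time_in <= config.horizon)
            col = f"risk_{cause}" if cause in CAUSES else cause
            curve = net_benefit_curve(
                risks[col].to_numpy(), outcome, grid_step=config.dca_grid_step
            )
            below, above, total = applicability_area(curve)
            curve_path = outdir / "dca_curve.csv"
            curve.to_frame().to_csv(curve_path, index=False)
            areas_path = outdir / "dca_areas.json"
            areas_path.write_text(
                json.dumps(
                    {"area_below": below, "area_above": above, "total": total,
                     "event_proportion": curve.event_proportion},
                    indent=2,
                )
            )
            record("dca", [str(curve_path), str(areas_path)], t0)
    except Exception as err:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "startup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {err}") from err

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
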