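"""CSV/JSON readers and writers and the end-to-end analysis pipeline.

Design CSVs carry one row per run (``run,x1,...,xq``) with fractions or
percentages (auto-detected); responses align to designs by run id.  Model
and goal configurations are JSON.  :func:`run_pipeline` chains
fit -> ANOVA -> optional model reduction -> desirability optimization and
writes coefficient tables, ANOVA reports and the optimum blend.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import SUM_TOL, Blend, MixtureDesign
from .desirability import DesirabilityGoal, OptimizationResult, optimize
from .fit import FitResult, anova, fit, reduce_model
from .models import ModelSpec, get_transform, parse_term

__all__ = [
    "read_design",
    "read_design_responses",
    "write_design",
    "model_from_json",
    "goals_from_json",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("mixsurf")


def write_design(design: MixtureDesign, path) -> None:
    """Write ``run,x1,...,xq`` CSV with fractions as decimals."""
    df = pd.DataFrame(design.as_array(), columns=design.component_names)
    df.insert(0, "run", design.run_ids)
    df.to_csv(path, index=False)


def _composition_frame(df: pd.DataFrame, path) -> MixtureDesign:
    cols = [c for c in df.columns if c != "run"]
    comp = df[cols].to_numpy(dtype=float)
    # percent notation auto-detect: fractions never exceed 1 by more than rounding
    if np.nanmax(comp) > 1.5:
        comp = comp / 100.0
    runs = []
    for i, row in enumerate(comp):
        if abs(row.sum() - 1.0) > SUM_TOL:
            raise ValueError(
                f"{path}: row {i + 1} (run {df['run'].iloc[i]}) sums to "
                f"{row.sum():.6g}, not 1"
            )
        runs.append(Blend(row))
    return MixtureDesign(runs=runs, run_ids=df["run"].astype(str).tolist(),
                         component_names=cols)


def read_design(path) -> MixtureDesign:
    """Read a design CSV (name-keyed columns; ``run`` column required)."""
    df = pd.read_csv(path)
    if "run" not in df.columns:
        raise ValueError(f"{path}: missing 'run' column")
    return _composition_frame(df, path)


def read_design_responses(design_path, responses_path) -> tuple[MixtureDesign, pd.DataFrame]:
    """Read and align a design CSV and a response CSV by run id."""
    design = read_design(design_path)
    resp = pd.read_csv(responses_path)
    if "run" not in resp.columns:
        raise ValueError(f"{responses_path}: missing 'run' column")
    resp["run"] = resp["run"].astype(str)
    resp = resp.set_index("run")
    missing = [r for r in design.run_ids if r not in resp.index]
    if missing:
        raise ValueError(f"{responses_path}: missing responses for runs {missing}")
    resp = resp.loc[design.run_ids]
    if resp.isna().any().any():
        bad = resp.columns[resp.isna().any()].tolist()
        raise ValueError(f"{responses_path}: missing values in columns {bad}")
    return design, resp


def model_from_json(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from ``{"response", "transform", "terms", "units"?}``.

    Terms use component aliases A, B, C, ... in design column order.
    """
    return ModelSpec(
        response=cfg["response"],
        terms=[parse_term(t) for t in cfg["terms"]],
        transform=get_transform(cfg.get("transform", "identity")),
        units=cfg.get("units", ""),
    )


def goals_from_json(cfg: dict, responses: pd.DataFrame) -> dict[str, DesirabilityGoal]:
    """Build goals from ``{response: {"direction", "low"?, "high"?, ...}}``.

    Bounds default to each response's observed min/max in ``responses``.
    """
    goals = {}
    for name, g in cfg.items():
        obs = responses[name].to_numpy(dtype=float)
        goals[name] = DesirabilityGoal(
            direction=g.get("direction", "minimize"),
            low=float(g.get("low", obs.min())),
            high=float(g.get("high", obs.max())),
            target=g.get("target"),
            weight=float(g.get("weight", 1.0)),
            importance=float(g.get("importance", 1.0)),
        )
    return goals


@dataclass
class RunConfig:
    """Paths and options for the end-to-end pipeline."""

    design_csv: str
    responses_csv: str
    models_json: str
    goals_json: str | None = None
    out_dir: str = "mixsurf_out"
    reduce_alpha: float | None = None
    grid_step: float = 0.005
    seed: int = 0


def run_pipeline(cfg: RunConfig) -> dict:
    """fit -> ANOVA -> optional reduction -> desirability optimization.

    Writes per-response coefficient and ANOVA CSVs, a desirability-optimum
    JSON, and a replay log; returns the in-memory bundle
    ``{"fits", "anovas", "optimum"}``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design, responses = read_design_responses(cfg.design_csv, cfg.responses_csv)
    with open(cfg.models_json) as fh:
        model_cfgs = json.load(fh)
    if isinstance(model_cfgs, dict):
        model_cfgs = [model_cfgs]

    fits: dict[str, FitResult] = {}
    anovas = {}
    for mc in model_cfgs:
        spec = model_from_json(mc)
        name = spec.response
        log.info("fitting %s (%d terms, %s scale)", name, len(spec.terms),
                 spec.transform.name)
        if cfg.reduce_alpha is not None:
            spec = reduce_model(design, responses[name], spec, alpha=cfg.reduce_alpha)
        res = fit(design, responses[name], spec)
        fits[name] = res
        tab = anova(res)
        anovas[name] = tab
        res.coefficient_table().to_csv(out / f"coefficients_{name}.csv", index=False)
        tab.to_frame().to_csv(out / f"anova_{name}.csv", index=False)
        (out / f"anova_{name}.txt").write_text(tab.to_text() + "\n")

    optimum: OptimizationResult | None = None
    if cfg.goals_json is not None:
        with open(cfg.goals_json) as fh:
            goal_cfg = json.load(fh)
        goals = goals_from_json(goal_cfg, responses)
        opt_fits = {n: fits[n] for n in goals}
        optimum = optimize(opt_fits, goals, grid_step=cfg.grid_step, seed=cfg.seed)
        payload = {
            "blend_fractions": dict(zip(design.component_names, optimum.blend.fractions)),
            "blend_percent": dict(zip(design.component_names, optimum.percentages)),
            "overall_desirability": optimum.overall,
            "predictions": optimum.predictions,
            "individual_desirabilities": optimum.individual,
            "grid_step": optimum.grid_step,
            "feasible": optimum.feasible,
        }
        (out / "optimum.json").write_text(json.dumps(payload, indent=2) + "\n")

    (out / "pipeline_log.json").write_text(
        json.dumps(
            {
                "mixsurf_version": __version__,
                "seed": cfg.seed,
                "grid_step": cfg.grid_step,
                "reduce_alpha": cfg.reduce_alpha,
                "responses": list(fits),
                "n_runs": design.n_runs,
            },
            indent=2,
        )
        + "\n"
    )
    return {"fits": fits, "anovas": anovas, "optimum": optimum}
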