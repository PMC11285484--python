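"""End-to-end driver: simulate (or ingest) -> model-free AUC ->
hyperbolic and MLE discounting fits -> optional hierarchical DDM ->
between-subject ANOVA -> JSON report.

The report carries, per analysis stage, the inputs digest, the
parameters used and warning counts, plus a cell-by-cell summary table
(mean and SD of AUC, hyperbolic k and V, and MLE k and V for each
sex x condition cell).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discount_models, modelfree
from .ddm import MCMCConfig, credible_group_difference, fit_hierarchical_ddm
from .design_stats import two_way_anova
from .io import read_trials, write_trials
from .simulate import (AgentParams, CohortTruth, DDMParams, CELLS,
                       DEFAULT_DISPERSION, default_truth, simulate_cohort)
from .task import TaskDesign

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "truth_from_dict",
           "truth_to_dict"]


def truth_to_dict(truth: CohortTruth) -> dict:
    """Serializable form of a cohort truth (sidecar for recovery tests)."""
    cells = {}
    for (sex, cond) in CELLS:
        a = truth.cell_agent[(sex, cond)]
        rec = {"k": a.k, "V": a.V, "sigma": a.sigma}
        if truth.cell_ddm is not None:
            d = truth.cell_ddm[(sex, cond)]
            rec.update(alpha=d.alpha, beta=d.beta, delta=d.delta, tau=d.tau)
        cells[f"{sex},{cond}"] = rec
    return {"n_per_cell": truth.n_per_cell, "cells": cells,
            "dispersion": dict(truth.dispersion),
            "fast_guess_rate": truth.fast_guess_rate,
            "skip_rate": truth.skip_rate, "seed": truth.seed}


def truth_from_dict(spec: dict, seed: int | None = None) -> CohortTruth:
    """Build a :class:`CohortTruth` from a config mapping.

    Missing cells fall back to the default null-effect parameters; a
    cell record without diffusion keys yields a softmax-only truth.
    """
    base = default_truth()
    cells = spec.get("cells", {})
    agent, ddm = {}, {}
    has_ddm = spec.get("mode", "auto") != "softmax"
    for cell in CELLS:
        key = f"{cell[0]},{cell[1]}"
        rec = cells.get(key, {})
        ref_a = base.cell_agent[cell]
        agent[cell] = AgentParams(k=rec.get("k", ref_a.k),
                                  V=rec.get("V", ref_a.V),
                                  sigma=rec.get("sigma", ref_a.sigma))
        ref_d = base.cell_ddm[cell]
        ddm[cell] = DDMParams(alpha=rec.get("alpha", ref_d.alpha),
                              beta=rec.get("beta", ref_d.beta),
                              delta=rec.get("delta", ref_d.delta),
                              tau=rec.get("tau", ref_d.tau))
    return CohortTruth(
        n_per_cell=int(spec.get("n_per_cell", 10)),
        cell_agent=agent,
        cell_ddm=ddm if has_ddm else None,
        dispersion=dict(spec.get("dispersion", DEFAULT_DISPERSION)),
        fast_guess_rate=float(spec.get("fast_guess_rate", 0.0)),
        skip_rate=float(spec.get("skip_rate", 0.0)),
        seed=spec.get("seed", seed))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run. ``seed`` is mandatory: every
    stochastic stage derives its randomness from it."""

    seed: int | None = None
    out_dir: str = "socdisc_run"
    trials_path: str | None = None      # ingest instead of simulating
    truth: dict = field(default_factory=dict)
    mode: str = "auto"                  # softmax | ddm | auto
    rt_floor: float = 0.3
    run_ddm: bool = False
    mcmc: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def task_design(self) -> TaskDesign:
        return TaskDesign(**self.design)


@dataclass
class RunReport:
    """Record of a pipeline run: per-stage entries and the cell summary."""

    seed: int
    timestamp: str
    stages: list
    summary: dict
    anova: dict
    ddm: dict | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _cell_summary(frames: dict) -> dict:
    """Means (SD) of AUC, hyperbolic k and V, and MLE k and V per
    sex x condition cell -- the layout of a standard task summary table."""
    out: dict = {}
    merged = frames["auc"][["participant_id", "sex", "condition", "auc"]]
    hyp = frames["hyperbolic"][["participant_id", "k", "V"]].rename(
        columns={"k": "k_hyp", "V": "V_hyp"})
    mle = frames["mle"][["participant_id", "k", "V"]].rename(
        columns={"k": "k_mle", "V": "V_mle"})
    merged = merged.merge(hyp, on="participant_id").merge(
        mle, on="participant_id")
    for (sex, cond), grp in merged.groupby(["sex", "condition"]):
        out[f"{sex},{cond}"] = {
            col: {"mean": float(np.nanmean(grp[col])),
                  "sd": float(np.nanstd(grp[col], ddof=1)),
                  "n": int(grp[col].notna().sum())}
            for col in ("auc", "k_hyp", "V_hyp", "k_mle", "V_mle")}
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis pipeline; see module docstring.

    Raises immediately (before any computation) if no seed is set, and
    aborts naming the stage if any stage fails.
    """
    if config.seed is None:
        raise ValueError("PipelineConfig.seed is required before any "
                         "stochastic stage can run")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.task_design()
    stages: list = []

    def stage(name: str, **info) -> None:
        stages.append({"stage": name, **info})

    try:
        if config.trials_path:
            dataset = read_trials(config.trials_path, design)
            stage("ingest", path=str(config.trials_path),
                  digest=_digest(Path(config.trials_path)),
                  n_trials=len(dataset.trials))
        else:
            truth = truth_from_dict({**config.truth, "mode": config.mode},
                                    seed=config.seed)
            dataset = simulate_cohort(truth, design, mode=config.mode)
            trials_csv = out / "trials.csv"
            write_trials(dataset, trials_csv)
            (out / "truth.yaml").write_text(
                yaml.safe_dump(truth_to_dict(truth)))
            stage("simulate", n_participants=len(dataset.participants),
                  n_trials=len(dataset.trials),
                  digest=_digest(trials_csv), truth="truth.yaml")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate/ingest' failed: {exc}"
                           ) from exc

    frames: dict = {}
    try:
        profiles, auc = modelfree.profile_cohort(dataset)
        frames["auc"] = auc
        auc.to_csv(out / "auc.csv", index=False)
        stage("modelfree", n_participants=len(auc), output="auc.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'modelfree' failed: {exc}"
                           ) from exc

    try:
        rows = []
        for prof in profiles:
            fit = discount_models.fit_hyperbolic(prof)
            rows.append({"participant_id": fit.participant_id, "k": fit.k,
                         "log_k": fit.log_k, "V": fit.V,
                         "converged": fit.converged, "notes": fit.notes})
        frames["hyperbolic"] = pd.DataFrame(rows)
        frames["hyperbolic"].to_csv(out / "hyperbolic.csv", index=False)
        stage("hyperbolic", n_participants=len(rows),
              output="hyperbolic.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'hyperbolic' failed: {exc}"
                           ) from exc

    try:
        n_before = int((dataset.trials["choice"] != "skipped").sum())
        n_after = len(dataset.scored(config.rt_floor))
        mle = discount_models.fit_mle_cohort(dataset,
                                             rt_floor=config.rt_floor)
        frames["mle"] = mle
        mle.to_csv(out / "mle.csv", index=False)
        stage("mle", rt_floor=config.rt_floor,
              n_scored=n_before, n_after_rt_filter=n_after,
              n_filtered=n_before - n_after, output="mle.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'mle' failed: {exc}") from exc

    anova_results: dict = {}
    try:
        merged = frames["auc"]
        res = two_way_anova(merged["auc"], merged["sex"], merged["condition"],
                            factor_a="sex", factor_b="condition")
        anova_results["auc"] = json.loads(
            res.table.to_json(orient="index"))
        mle_ok = frames["mle"].dropna(subset=["log_k"])
        res_k = two_way_anova(mle_ok["log_k"], mle_ok["sex"],
                              mle_ok["condition"],
                              factor_a="sex", factor_b="condition")
        anova_results["log_k_mle"] = json.loads(
            res_k.table.to_json(orient="index"))
        stage("anova", responses=["auc", "log_k_mle"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'anova' failed: {exc}") from exc

    ddm_report = None
    if config.run_ddm:
        try:
            mcfg = MCMCConfig(seed=config.seed, rt_floor=config.rt_floor,
                              **config.mcmc)
            post = fit_hierarchical_ddm(dataset, mcfg)
            ddm_report = {
                "rhat": post.rhat,
                "hdi_95": {k: list(v) for k, v in post.hdi_95.items()},
                "verdicts": {name: credible_group_difference(post, name)
                             for name in post.effect_names},
                "converged": post.converged,
            }
            (out / "ddm.json").write_text(json.dumps(ddm_report, indent=2))
            stage("ddm", chains=mcfg.chains, iterations=mcfg.iterations,
                  converged=post.converged, output="ddm.json")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'ddm' failed: {exc}"
                               ) from exc

    report = RunReport(
        seed=config.seed,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        stages=stages,
        summary=_cell_summary(frames),
        anova=anova_results,
        ddm=ddm_report)
    report.to_json(out / "report.json")
    return report
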