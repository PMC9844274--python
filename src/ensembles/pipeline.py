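"""End-to-end orchestration: design -> simulate -> score -> screen -> infer.

Every stage is a pure function of its declared inputs plus a child seed
spawned deterministically from the run seed, so a fixed (seed, config) pair
reproduces byte-identical CSV/JSON outputs. External trial tables (e.g. a
real data deposit) enter through :func:`ingest_external` and flow through
the identical scoring/screening/inference path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .bayes import SequentialResult, correlate, sequential_run
from .config import RunConfig
from .design import (LENGTH, ORIENTATION, PROBES, TASKS, build_layouts,
                     realize_design)
from .observers import simulate_study
from .scoring import error_score_pairs, score_table
from .screening import apply_exclusion, included_ids, task_reliability
from .pipeline_io import design_to_json, reports_to_json, result_to_json

log = logging.getLogger("ensembles")

TRIAL_COLUMNS = ("observer_id", "task", "trial_index", "true_mean",
                 "response", "error", "correct")


class StageError(RuntimeError):
    """Failure annotated with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _safe_alpha(trials: pd.DataFrame, task: str, kept: list[int]) -> float:
    """Cronbach alpha, nan when undefined (e.g. zero error variance)."""
    try:
        return task_reliability(trials, task, kept).alpha
    except ValueError:
        return float("nan")


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def run_full(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the whole pipeline, writing one file per stage into ``out_dir``.

    Returns a bundle with the in-memory stage outputs and file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design_seed, cohort_seed = _child_seeds(config.seed, 2)
    provenance = {"seed": config.seed, "config_hash": config.config_hash(),
                  "package_version": __version__}

    stage = "design"
    try:
        layouts = build_layouts(config.design.n_versions, seed=design_seed)
        by_key = {(l.version, l.task): l for l in layouts}
        designs = {
            task: realize_design(task, by_key[(config.design.version, task)],
                                 seed=design_seed + i,
                                 sd_tolerance=config.design.sd_tolerance,
                                 max_restarts=config.design.max_restarts)
            for i, task in enumerate(TASKS)
        }
        design_path = out / "design.json"
        design_path.write_text(design_to_json(designs, provenance))
        log.info("stage=design trials=%d versions=%d seed=%d",
                 sum(map(len, designs.values())), config.design.n_versions,
                 design_seed)

        stage = "simulate"
        trials, observers = simulate_study(config.cohort, designs[LENGTH],
                                           designs[ORIENTATION], seed=cohort_seed)
        trials.to_csv(out / "trials.csv", index=False)
        truth = [dataclasses.asdict(o) for o in observers]
        (out / "cohort_truth.json").write_text(json.dumps(
            {"provenance": provenance, "observers": truth}, indent=1))
        log.info("stage=simulate observers=%d rows=%d seed=%d",
                 len(observers), len(trials), cohort_seed)

        stage = "score"
        scores = score_table(trials)
        scores.to_csv(out / "scores.csv", index=False)
        log.info("stage=score rows=%d", len(scores))

        stage = "screen"
        reports = apply_exclusion(
            trials, chance=config.screening.chance_level,
            fit_threshold=config.screening.fit_threshold,
            manual_exclude=config.screening.manual_exclude)
        kept = included_ids(reports)
        alphas = {t: _safe_alpha(trials, t, kept) for t in TASKS}
        (out / "screening.json").write_text(reports_to_json(reports, alphas,
                                                            provenance))
        log.info("stage=screen included=%d/%d alpha_length=%.3f "
                 "alpha_orientation=%.3f", len(kept), len(reports),
                 alphas[LENGTH], alphas[ORIENTATION])

        stage = "analyze"
        pairs = error_score_pairs(scores[scores["observer_id"].isin(kept)])
        alpha_pair = (alphas[LENGTH], alphas[ORIENTATION])
        result = correlate(pairs[LENGTH], pairs[ORIENTATION],
                           kappa=config.prior.kappa,
                           alphas=alpha_pair if all(
                               a == a for a in alpha_pair) else None)
        seq: SequentialResult | None = None
        seq_note = ""
        if config.sequential.enabled and not result.degenerate:
            if len(pairs) >= config.sequential.n_start:
                seq = sequential_run(
                    pairs[LENGTH], pairs[ORIENTATION],
                    n_start=config.sequential.n_start,
                    threshold_high=config.sequential.threshold_high,
                    threshold_low=config.sequential.threshold_low,
                    kappa=config.prior.kappa, batch=config.sequential.batch)
            else:
                seq_note = (f"only {len(pairs)} included pairs, below the "
                            f"sequential starting n {config.sequential.n_start}")
        (out / "result.json").write_text(
            result_to_json(result, seq, alphas, provenance, seq_note))
        log.info("stage=analyze n=%d r=%.4f bf=%.4g", result.n, result.r,
                 result.bf_plus0)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise StageError(stage, exc) from exc

    return {"designs": designs, "trials": trials, "scores": scores,
            "reports": reports, "alphas": alphas, "result": result,
            "sequential": seq, "out_dir": out, "provenance": provenance}


class IngestError(ValueError):
    """External CSV failed validation; carries row-level messages."""

    def __init__(self, problems: list[str]):
        super().__init__("external trial table failed validation:\n  "
                         + "\n  ".join(problems[:50]))
        self.problems = problems


def ingest_external(path: str | Path,
                    column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a third-party trial CSV into the internal layout.

    ``column_map`` maps external header names onto the internal schema
    (observer_id, task, trial_index, true_mean, response). Derived columns
    (error, correct) are recomputed. Rows with responses or true means
    outside the task's probe set are reported with their 1-based data line
    numbers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["observer_id", "task", "trial_index", "true_mean", "response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError([f"missing required column(s): {', '.join(missing)}"])
    problems = []
    bad_task = ~df["task"].isin(TASKS)
    for line in df.index[bad_task]:
        problems.append(f"line {line + 2}: unknown task {df.at[line, 'task']!r}")
    for task in TASKS:
        probes = PROBES[task]
        sub = df[(df["task"] == task)]
        for col in ("true_mean", "response"):
            vals = sub[col].astype(float)
            ok = np.isclose(vals.to_numpy()[:, None], np.array(probes)).any(axis=1)
            for line, value in zip(sub.index[~ok], vals[~ok]):
                problems.append(f"line {line + 2}: {col}={value} not in the "
                                f"{task} probe set {probes}")
    if problems:
        raise IngestError(problems)
    df = df[required].copy()
    df["error"] = (df["response"] - df["true_mean"]).abs()
    df["correct"] = (df["error"] == 0).astype(int)
    return df.reset_index(drop=True)
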