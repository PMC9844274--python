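"""Participant screening and reliability of the error measures.

Inclusion follows a two-route rule. A participant is kept on a task if they
are above chance there (proportion correct > 1/5 on a 5-AFC), or — failing
that — if their trial-by-trial correctness correlates at least 0.15 with
trial easiness (the proportion of above-chance participants answering each
trial correctly). The person-fit route keeps effortful-but-poor performers:
someone who is trying tends to succeed on trials that are easy for everyone,
even when their overall accuracy sits at chance. Correlations are computed
per task, against that task's own easiness vector, and easiness is computed
once from the initial above-chance subset (a single pass, not iterated).

Note the chance route is a noisy screen: a truly random clicker still passes
``accuracy > 0.2`` on one 120-trial task with probability ~0.45 (binomial),
so roughly a fifth of random responders slip through on both tasks. See
``docs/methods.md`` for the operating characteristics.

Reliability of the trial-level absolute errors is summarized by Cronbach's
alpha with the 120 trials of a task as items, which upper-bounds (via the
attenuation formula) the observable correlation between the two tasks' mean
error scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import TASKS

CHANCE_LEVEL = 0.2
FIT_THRESHOLD = 0.15

REASON_ABOVE_CHANCE = "above-chance-both"
REASON_PERSON_FIT = "person-fit"
REASON_LOW_FIT = "low-person-fit"
REASON_MANUAL = "manual"


@dataclass(frozen=True)
class ExclusionReport:
    observer_id: int
    above_chance_length: bool
    above_chance_orientation: bool
    person_fit_length: float  # nan when undefined (constant correctness)
    person_fit_orientation: float
    included: bool
    reason: str


@dataclass(frozen=True)
class ReliabilityResult:
    task: str
    alpha: float
    n_items: int
    n_cases: int


def correctness_matrix(trials: pd.DataFrame, task: str) -> pd.DataFrame:
    """Observers x trials 0/1 matrix for one task."""
    sub = trials[trials["task"] == task]
    return sub.pivot(index="observer_id", columns="trial_index", values="correct")


def trial_difficulty(trials: pd.DataFrame, task: str,
                     chance: float = CHANCE_LEVEL) -> np.ndarray:
    """Per-trial proportion correct among above-chance participants only.

    (Despite the name this is an easiness vector: higher means easier.)
    """
    mat = correctness_matrix(trials, task)
    above = mat.mean(axis=1) > chance
    if not above.any():
        raise ValueError(f"no above-chance participants on the {task} task")
    return mat.loc[above].mean(axis=0).to_numpy(dtype=float)


def person_fit(correctness: Sequence[float], difficulty: Sequence[float]) -> float:
    """Pearson correlation between an observer's 0/1 correctness and trial
    easiness; nan (undefined) when either vector is constant."""
    c = np.asarray(correctness, dtype=float)
    d = np.asarray(difficulty, dtype=float)
    if c.shape != d.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {d.shape}")
    if np.std(c) == 0 or np.std(d) == 0:
        return float("nan")
    return float(np.corrcoef(c, d)[0, 1])


def decide_inclusion(accuracy: dict[str, float], fits: dict[str, float],
                     chance: float = CHANCE_LEVEL,
                     fit_threshold: float = FIT_THRESHOLD) -> tuple[bool, str]:
    """Apply the two-route rule. Per task: pass if above chance, else if the
    person-fit correlation reaches the threshold (nan fits fail — an
    all-incorrect record carries no evidence of effort)."""
    above = {t: accuracy[t] > chance for t in TASKS}
    if all(above.values()):
        return True, REASON_ABOVE_CHANCE
    for t in TASKS:
        if not above[t]:
            fit = fits[t]
            if not (fit == fit and fit >= fit_threshold):  # nan-safe
                return False, REASON_LOW_FIT
    return True, REASON_PERSON_FIT


def apply_exclusion(trials: pd.DataFrame,
                    chance: float = CHANCE_LEVEL,
                    fit_threshold: float = FIT_THRESHOLD,
                    manual_exclude: Iterable[int] = ()) -> list[ExclusionReport]:
    """Screen every observer in a trial table.

    Easiness vectors are computed once per task from the above-chance
    subset; manual exclusions (technical problems, misunderstood
    instructions — not algorithmically definable) are applied last.
    """
    manual = set(manual_exclude)
    mats = {t: correctness_matrix(trials, t) for t in TASKS}
    difficulty = {t: trial_difficulty(trials, t, chance) for t in TASKS}
    observers = mats[TASKS[0]].index
    reports = []
    for obs in observers:
        acc = {t: float(mats[t].loc[obs].mean()) for t in TASKS}
        fits = {t: person_fit(mats[t].loc[obs].to_numpy(), difficulty[t])
                for t in TASKS}
        included, reason = decide_inclusion(acc, fits, chance, fit_threshold)
        if obs in manual:
            included, reason = False, REASON_MANUAL
        reports.append(ExclusionReport(
            observer_id=int(obs),
            above_chance_length=acc["length"] > chance,
            above_chance_orientation=acc["orientation"] > chance,
            person_fit_length=fits["length"],
            person_fit_orientation=fits["orientation"],
            included=included,
            reason=reason,
        ))
    return reports


def included_ids(reports: Iterable[ExclusionReport]) -> list[int]:
    return [r.observer_id for r in reports if r.included]


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame,
                   task: str = "") -> ReliabilityResult:
    """Cronbach's alpha of a cases x items score matrix:
    alpha = k/(k-1) * (1 - sum(item variances) / variance(row sums)),
    sample variances (n-1 denominator) throughout."""
    mat = np.asarray(item_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 cases and 2 items")
    if np.isnan(mat).any():
        raise ValueError("item matrix contains missing cells")
    k = mat.shape[1]
    total_var = np.var(mat.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    item_var = np.var(mat, axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1 - item_var / total_var)
    return ReliabilityResult(task=task, alpha=float(alpha),
                             n_items=k, n_cases=mat.shape[0])


def task_reliability(trials: pd.DataFrame, task: str,
                     observer_ids: Sequence[int] | None = None) -> ReliabilityResult:
    """Alpha of per-trial absolute errors (items = the task's 120 trials),
    optionally restricted to the included observers."""
    sub = trials[trials["task"] == task]
    if observer_ids is not None:
        sub = sub[sub["observer_id"].isin(observer_ids)]
    mat = sub.pivot(index="observer_id", columns="trial_index", values="error")
    return cronbach_alpha(mat, task=task)
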