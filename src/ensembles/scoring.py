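"""Trial-level error scoring and per-participant summaries.

The headline measure is the mean absolute error: the distance, in feature
units, between the chosen probe and the true ensemble mean, averaged over a
participant's 120 trials of a task. Because probes are evenly spaced, errors
live on {0, 1, 2, 3, 4} probe spacings (0/12/24/36/48 px; 0/13.5/27/40.5/54
deg). The SD of *signed* errors is kept as a bias-robust secondary measure:
a response bias (e.g. overweighting salient long lines) shifts signed errors
without inflating their spread, whereas it inflates the absolute measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PROBES
from .observers import TRIALS_PER_TASK


@dataclass(frozen=True)
class ParticipantScore:
    observer_id: int
    task: str
    accuracy: float
    mean_abs_error: float
    sd_error: float
    sd_abs_error: float
    n_trials: int


def score_trial(true_mean: float, chosen_probe: float, task: str) -> tuple[float, bool]:
    """Absolute error and correctness of one response.

    Both values must belong to the task's probe set (which doubles as the
    set of possible true means), otherwise the trial is malformed.
    """
    probes = PROBES[task]
    for name, value in (("true_mean", true_mean), ("chosen_probe", chosen_probe)):
        if not any(np.isclose(value, p) for p in probes):
            raise ValueError(f"{name}={value} not in the {task} probe set {probes}")
    error = abs(chosen_probe - true_mean)
    return error, error == 0


def participant_summary(records: pd.DataFrame) -> ParticipantScore:
    """Summary score for one observer on one task."""
    if records.empty:
        raise ValueError("empty record set")
    for col in ("observer_id", "task"):
        if records[col].nunique() != 1:
            raise ValueError(f"records mix several values of {col}")
    signed = records["response"].to_numpy() - records["true_mean"].to_numpy()
    abs_err = np.abs(signed)
    n = len(records)
    return ParticipantScore(
        observer_id=records["observer_id"].iloc[0],
        task=records["task"].iloc[0],
        accuracy=float((abs_err == 0).mean()),
        mean_abs_error=float(abs_err.mean()),
        sd_error=float(np.std(signed, ddof=1)) if n > 1 else 0.0,
        sd_abs_error=float(np.std(abs_err, ddof=1)) if n > 1 else 0.0,
        n_trials=n,
    )


def score_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per observer x task scores for a whole trial table."""
    signed = trials["response"] - trials["true_mean"]
    work = trials.assign(_signed=signed, _abs=signed.abs())
    grouped = work.groupby(["observer_id", "task"], sort=True)
    scores = grouped.agg(
        accuracy=("correct", "mean"),
        mean_abs_error=("_abs", "mean"),
        sd_error=("_signed", lambda s: s.std(ddof=1)),
        sd_abs_error=("_abs", lambda s: s.std(ddof=1)),
        n_trials=("_abs", "size"),
    ).reset_index()
    return scores


def error_score_pairs(scores: pd.DataFrame,
                      measure: str = "mean_abs_error") -> pd.DataFrame:
    """Wide table with one row per observer and one column per task for the
    chosen error measure; observers missing a task are dropped."""
    wide = scores.pivot(index="observer_id", columns="task", values=measure)
    return wide.dropna()


def random_responder_expected_error(task: str) -> float:
    """Expected mean absolute error of a uniform random clicker on a design
    balanced over the 5 true means, by enumeration of all 25 (true, response)
    probe pairs. Evaluates to 1.6 probe spacings: 19.2 px / 21.6 deg."""
    probes = np.asarray(PROBES[task])
    return float(np.abs(probes[:, None] - probes[None, :]).mean())


def full_session(scores: pd.DataFrame) -> pd.DataFrame:
    """Restrict to observer x task scores based on complete 120-trial runs."""
    return scores[scores["n_trials"] == TRIALS_PER_TASK]
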