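import numpy as np
import pandas as pd
import pytest

from ensembles.design import LENGTH, ORIENTATION, build_task_design, build_value_grid
from ensembles.observers import CohortParams, simulate_study


@pytest.fixture(scope="session")
def grids():
    return {f: build_value_grid(f) for f in (LENGTH, ORIENTATION)}


@pytest.fixture(scope="session")
def designs():
    """Spec-level designs (true means only; realization tested separately)."""
    return {t: build_task_design(t, order_seed=7) for t in (LENGTH, ORIENTATION)}


@pytest.fixture(scope="session")
def default_trials(designs):
    """One simulated session of the calibrated default cohort."""
    cohort = CohortParams(seed=11)
    trials, observers = simulate_study(cohort, designs[LENGTH],
                                       designs[ORIENTATION])
    return trials, observers


def simulate_cohort_trials(cohort: CohortParams, designs, seed: int):
    trials, observers = simulate_study(cohort, designs[LENGTH],
                                       designs[ORIENTATION], seed=seed)
    return trials, observers


def make_trials(rows):
    """Tiny hand-built trial table: (observer, task, trial, true, response)."""
    df = pd.DataFrame(rows, columns=["observer_id", "task", "trial_index",
                                     "true_mean", "response"])
    df["error"] = (df["response"] - df["true_mean"]).abs()
    df["correct"] = (df["error"] == 0).astype(int)
    return df
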