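"""Inclusion rule, person fit, trial difficulty, Cronbach's alpha."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ensembles.design import LENGTH, ORIENTATION
from ensembles.observers import recruitment_cohort
from ensembles.screening import (REASON_ABOVE_CHANCE, REASON_LOW_FIT,
                                 REASON_MANUAL, REASON_PERSON_FIT,
                                 apply_exclusion, cronbach_alpha,
                                 decide_inclusion, included_ids, person_fit,
                                 task_reliability, trial_difficulty)
from tests.conftest import make_trials, simulate_cohort_trials


def _both(length, orientation):
    return {LENGTH: length, ORIENTATION: orientation}


@pytest.mark.parametrize("acc, fits, included, reason", [
    ((0.43, 0.50), (0.5, 0.5), True, REASON_ABOVE_CHANCE),
    ((0.18, 0.15), (0.10, 0.08), False, REASON_LOW_FIT),
    ((0.18, 0.30), (0.30, 0.02), True, REASON_PERSON_FIT),
    ((0.30, 0.18), (0.02, 0.149), False, REASON_LOW_FIT),  # just under threshold
    ((0.18, 0.18), (0.15, 0.15), True, REASON_PERSON_FIT),  # at threshold: kept
    ((0.18, 0.50), (float("nan"), 0.5), False, REASON_LOW_FIT),  # undefined fit
])
def test_inclusion_rule(acc, fits, included, reason):
    got = decide_inclusion(_both(*acc), _both(*fits))
    assert got == (included, reason)


def _difficulty_table():
    # observers 0-2 above chance on 5 length trials; observer 3 at chance
    rows = []
    correct_pattern = {
        0: [1, 1, 1, 0, 1],
        1: [1, 1, 0, 0, 1],
        2: [0, 1, 1, 0, 0],
        3: [1, 0, 0, 0, 0],  # accuracy 0.2, not above chance
    }
    for obs, pattern in correct_pattern.items():
        for t, ok in enumerate(pattern):
            rows.append((obs, LENGTH, t, 80.0, 80.0 if ok else 56.0))
    return make_trials(rows)


def test_trial_difficulty_uses_above_chance_subset_only():
    trials = _difficulty_table()
    diff = trial_difficulty(trials, LENGTH)
    assert diff == pytest.approx([2 / 3, 1.0, 2 / 3, 0.0, 2 / 3])
    # perturbing the below-chance observer's responses changes nothing
    flipped = trials.copy()
    mask = flipped.observer_id == 3
    flipped.loc[mask, "response"] = 104.0
    flipped.loc[mask, "error"] = (flipped.loc[mask, "response"]
                                  - flipped.loc[mask, "true_mean"]).abs()
    flipped.loc[mask, "correct"] = 0
    assert trial_difficulty(flipped, LENGTH) == pytest.approx(diff)


def test_trial_difficulty_needs_above_chance_participants():
    rows = [(0, LENGTH, t, 80.0, 56.0) for t in range(5)]
    with pytest.raises(ValueError, match="no above-chance"):
        trial_difficulty(make_trials(rows), LENGTH)


def test_person_fit_sign_and_degeneracy():
    difficulty = np.linspace(0.1, 0.9, 20)
    easiest_half = (difficulty > 0.5).astype(float)
    assert person_fit(easiest_half, difficulty) > 0
    assert person_fit(1 - easiest_half, difficulty) < 0
    assert np.isnan(person_fit(np.ones(20), difficulty))
    assert np.isnan(person_fit(easiest_half, np.full(20, 0.5)))
    with pytest.raises(ValueError, match="length mismatch"):
        person_fit(np.ones(5), difficulty)


def test_apply_exclusion_end_to_end_and_idempotence(designs):
    cohort = recruitment_cohort(seed=5)
    trials, observers = simulate_cohort_trials(cohort, designs, seed=5)
    reports = apply_exclusion(trials)
    assert len(reports) == cohort.n_observers
    by_id = {r.observer_id: r for r in reports}
    for o in observers:
        if not o.inattentive:  # calibrated noise keeps attentive well above chance
            assert by_id[o.observer_id].included
    # manual exclusion overrides
    first = reports[0].observer_id
    manual = apply_exclusion(trials, manual_exclude=[first])
    assert manual[0].included is False and manual[0].reason == REASON_MANUAL
    # idempotence: screening the included subset excludes no one further
    kept = included_ids(reports)
    sub = trials[trials.observer_id.isin(kept)]
    again = apply_exclusion(sub)
    assert included_ids(again) == kept


def test_screening_operating_characteristics(designs):
    """The screen's false-inclusion rate for uniform responders matches an
    independent Monte-Carlo oracle of the rule itself.

    The oracle draws Bernoulli(0.2) correctness vectors, applies the
    written rule (accuracy > 0.2, else person-fit >= 0.15 against a fixed
    easiness vector) and squares the per-task pass rate (tasks are
    independent for a uniform responder). The chance route alone passes a
    task with P(Bin(120, 0.2) > 24) =~ 0.446, so roughly a quarter of
    uniform responders are expected through the full screen — the pipeline
    must agree with that operating characteristic. Attentive observers
    under the calibrated preset are essentially always retained."""
    inattentive_included = attentive_included = 0
    n_inattentive = n_attentive = 0
    for seed in range(25):
        cohort = recruitment_cohort(seed=seed)
        trials, observers = simulate_cohort_trials(cohort, designs, seed=seed)
        by_id = {r.observer_id: r.included for r in apply_exclusion(trials)}
        for o in observers:
            if o.inattentive:
                n_inattentive += 1
                inattentive_included += by_id[o.observer_id]
            else:
                n_attentive += 1
                attentive_included += by_id[o.observer_id]

    # oracle: rule semantics only, no package screening code; per-task pass
    # probabilities multiply because a uniform responder's two task runs
    # are independent
    rng = np.random.default_rng(0)
    trials0, _ = simulate_cohort_trials(recruitment_cohort(seed=0), designs, 0)
    predicted = 1.0
    for task in (LENGTH, ORIENTATION):
        easiness = trial_difficulty(trials0, task)
        correctness = (rng.random((20_000, 120)) < 0.2).astype(float)
        acc = correctness.mean(axis=1)
        centered = easiness - easiness.mean()
        denom = (correctness.std(axis=1) * easiness.std()) * 120
        with np.errstate(invalid="ignore"):
            fit = (correctness - acc[:, None]) @ centered / denom
        p_task = np.mean((acc > 0.2) | (np.nan_to_num(fit, nan=-1) >= 0.15))
        assert p_task > stats.binom.sf(24, 120, 0.2)  # fit route only adds
        predicted *= p_task
    rate = inattentive_included / n_inattentive
    # ~640 inattentive observers: 0.055 is ~3 binomial sigma
    assert rate == pytest.approx(predicted, abs=0.055)
    assert attentive_included / n_attentive >= 0.95


def test_cronbach_alpha_against_independent_implementation():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    mat = rng.normal(size=(9, 5)) + rng.normal(size=(9, 1))  # correlated items
    ours = cronbach_alpha(mat).alpha
    theirs = pingouin.cronbach_alpha(data=pd.DataFrame(mat))[0]
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_cronbach_alpha_extremes_and_errors():
    base = np.random.default_rng(1).normal(size=(40, 1))
    identical = np.repeat(base, 120, axis=1)
    assert cronbach_alpha(identical).alpha == pytest.approx(1.0)
    independent = np.random.default_rng(2).normal(size=(5000, 30))
    assert abs(cronbach_alpha(independent).alpha) < 0.05
    with pytest.raises(ValueError, match="at least 2"):
        cronbach_alpha(np.ones((1, 5)))
    with pytest.raises(ValueError, match="zero total-score variance"):
        cronbach_alpha(np.ones((4, 5)))
    with pytest.raises(ValueError, match="missing"):
        cronbach_alpha(np.array([[1.0, np.nan], [2.0, 3.0]]))


def test_alpha_parallel_duplication_never_decreases():
    rng = np.random.default_rng(3)
    for _ in range(5):
        mat = rng.normal(size=(25, 8)) + 0.5 * rng.normal(size=(25, 1))
        a1 = cronbach_alpha(mat).alpha
        a2 = cronbach_alpha(np.hstack([mat, mat])).alpha
        assert a2 >= a1 - 1e-12  # Spearman-Brown direction


def test_task_reliability_is_high_for_calibrated_cohort(default_trials):
    trials, _ = default_trials
    for task in (LENGTH, ORIENTATION):
        rel = task_reliability(trials, task)
        assert rel.n_items == 120
        assert rel.alpha > 0.7  # strongly reliable individual differences
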