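"""Factorial stimulus designs for the line-averaging tasks.

Each trial of either task shows an ensemble of 12 lines that jointly realize
target summary statistics: the task-relevant feature mean is hit *exactly*
(so the error metric is well defined against the probe set) and both feature
SDs are hit to within a configurable tolerance on the discrete value grids.
Line positions come from fixed per-version spatial layouts on a 5-column by
4-row grid, constant across all trials of a task so that locations are fully
predictable to the observer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
import numpy as np

LENGTH = "length"
ORIENTATION = "orientation"
TASKS = (LENGTH, ORIENTATION)

N_LINES = 12
N_GRID_ROWS = 4
N_GRID_COLS = 5
LINES_PER_ROW = 3

#: display timing, recorded as metadata only (rendering is out of scope)
EXPOSURE_MS = 200
FIXATION_MS = 1500

# relevant-feature probe values double as the possible true means
LENGTH_MEANS = (56.0, 68.0, 80.0, 92.0, 104.0)
ORIENTATION_MEANS = (18.0, 31.5, 45.0, 58.5, 72.0)
LENGTH_SDS = (8.0, 12.0)
ORIENTATION_SDS = (9.0, 13.5)
# irrelevant-feature levels (the 3 central means of the other task)
LENGTH_MEANS_IRRELEVANT = (68.0, 80.0, 92.0)
ORIENTATION_MEANS_IRRELEVANT = (31.5, 45.0, 58.5)
N_REPETITIONS = 2

PRACTICE_SD = {LENGTH: 4.0, ORIENTATION: 4.5}
PRACTICE_COLUMNS = (1, 3, 5)
N_PRACTICE_TRIALS = 10

PROBES = {LENGTH: LENGTH_MEANS, ORIENTATION: ORIENTATION_MEANS}

_GRID_PARAMS = {LENGTH: (44.0, 4.0, 19), ORIENTATION: (4.5, 4.5, 19)}


@dataclass(frozen=True)
class ValueGrid:
    """Discrete set of allowed values for one line feature."""

    feature: str
    values: tuple[float, ...]
    step: float

    def __contains__(self, value: float) -> bool:
        return any(np.isclose(value, v) for v in self.values)


@dataclass(frozen=True)
class EnsembleSpec:
    """Target summary statistics for one trial's ensemble."""

    task: str
    mean_length: float
    sd_length: float
    mean_orientation: float
    sd_orientation: float
    repetition: int

    @property
    def relevant_mean(self) -> float:
        return self.mean_length if self.task == LENGTH else self.mean_orientation

    @property
    def relevant_sd(self) -> float:
        return self.sd_length if self.task == LENGTH else self.sd_orientation

    def factor_key(self) -> tuple[float, float, float, float]:
        return (self.mean_length, self.sd_length,
                self.mean_orientation, self.sd_orientation)


@dataclass(frozen=True)
class SpatialLayout:
    """Fixed positions of the 12 lines: (row, column) cells, 1-based."""

    version: int
    task: str
    cells: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.cells) != N_LINES:
            raise ValueError(f"layout needs {N_LINES} cells, got {len(self.cells)}")
        if len(set(self.cells)) != N_LINES:
            raise ValueError("layout contains duplicate cells")
        rows = [r for r, _ in self.cells]
        for r in range(1, N_GRID_ROWS + 1):
            if rows.count(r) != LINES_PER_ROW:
                raise ValueError(f"row {r} must hold exactly {LINES_PER_ROW} lines")


@dataclass(frozen=True)
class LineEnsemble:
    """A realized trial: 12 (length, orientation, cell) triples."""

    spec: EnsembleSpec
    lengths: tuple[float, ...]
    orientations: tuple[float, ...]
    layout: SpatialLayout


def build_value_grid(feature: str) -> ValueGrid:
    """Return the allowed feature values: 19 lengths (44..116 px, step 4)
    or 19 orientations (4.5..85.5 deg clockwise from vertical, step 4.5)."""
    try:
        start, step, count = _GRID_PARAMS[feature]
    except KeyError:
        raise ValueError(f"unknown feature {feature!r}; expected one of {TASKS}")
    values = tuple(start + step * i for i in range(count))
    return ValueGrid(feature=feature, values=values, step=step)


def build_task_design(task: str, order_seed: int | None = None) -> list[EnsembleSpec]:
    """Full factorial design of one task: 5 relevant means x 2 relevant SDs
    x 3 irrelevant means x 2 irrelevant SDs x 2 repetitions = 120 specs.

    With ``order_seed`` the specs are shuffled into a single fixed trial
    order (every participant sees the same order); otherwise factorial order.
    """
    if task == LENGTH:
        cross = itertools.product(LENGTH_MEANS, LENGTH_SDS,
                                  ORIENTATION_MEANS_IRRELEVANT, ORIENTATION_SDS,
                                  range(1, N_REPETITIONS + 1))
        specs = [EnsembleSpec(task, ml, sl, mo, so, rep)
                 for ml, sl, mo, so, rep in cross]
    elif task == ORIENTATION:
        cross = itertools.product(ORIENTATION_MEANS, ORIENTATION_SDS,
                                  LENGTH_MEANS_IRRELEVANT, LENGTH_SDS,
                                  range(1, N_REPETITIONS + 1))
        specs = [EnsembleSpec(task, ml, sl, mo, so, rep)
                 for mo, so, ml, sl, rep in cross]
    else:
        raise ValueError(f"unknown task {task!r}")
    if order_seed is not None:
        rng = np.random.default_rng(order_seed)
        specs = [specs[i] for i in rng.permutation(len(specs))]
    return specs


def mean_is_representable(grid: ValueGrid, mean: float, n: int = N_LINES) -> bool:
    """A target mean is reachable iff n*mean sits on the grid-sum lattice."""
    total_steps = (mean - grid.values[0]) * n / grid.step
    if not np.isclose(total_steps, round(total_steps)):
        return False
    return 0 <= round(total_steps) <= (len(grid.values) - 1) * n


def sample_feature_values(
    grid: ValueGrid,
    n: int,
    mean: float,
    sd: float,
    rng: np.random.Generator,
    sd_tolerance: float = 0.5,
    max_restarts: int = 10_000,
) -> np.ndarray:
    """Draw ``n`` grid values with sample mean exactly ``mean`` and sample SD
    (n-1 denominator) within ``sd_tolerance`` of ``sd``.

    Works on the integer index lattice: moves mass between two entries keeps
    the sum (hence the mean) invariant, while random-restart hill climbing
    drives the sum of squared deviations toward the target. Exact SDs are
    often unattainable on a discrete grid (the attainable squared-deviation
    sums have fixed parity), hence the tolerance.
    """
    if not mean_is_representable(grid, mean, n):
        raise ValueError(f"mean {mean} not representable as a mean of {n} "
                         f"values on the {grid.feature} grid")
    m = len(grid.values) - 1
    total = round((mean - grid.values[0]) * n / grid.step)
    # target sum of squared index deviations for the sample SD
    target_ss = (n - 1) * (sd / grid.step) ** 2
    max_iter = 40 * n

    best = None
    best_err = np.inf
    for _ in range(max_restarts):
        k = _random_fixed_sum(n, total, m, rng)
        err = _ss_error(k, total / n, target_ss)
        for _ in range(max_iter):
            i, j = rng.integers(0, n, size=2)
            if k[i] >= m or k[j] <= 0 or i == j:
                continue
            k[i] += 1
            k[j] -= 1
            new_err = _ss_error(k, total / n, target_ss)
            if new_err <= err:
                err = new_err
            else:
                k[i] -= 1
                k[j] += 1
            if err == 0.0:
                break
        if err < best_err:
            best, best_err = k.copy(), err
        values = grid.values[0] + grid.step * best
        achieved_sd = float(np.std(values, ddof=1))
        if abs(achieved_sd - sd) <= sd_tolerance:
            return rng.permutation(values)
    raise RuntimeError(
        f"no {grid.feature} multiset with mean {mean} and SD within "
        f"{sd_tolerance} of {sd} found in {max_restarts} restarts")


def _random_fixed_sum(n: int, total: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Random integer vector in [0, m]^n with the given sum."""
    k = np.full(n, total // n, dtype=int)
    k[: total % n] += 1
    for _ in range(3 * n):  # randomizing pair moves, sum-preserving
        i, j = rng.integers(0, n, size=2)
        d = int(rng.integers(1, m // 2 + 1))
        if k[i] + d <= m and k[j] - d >= 0:
            k[i] += d
            k[j] -= d
    return k


def _ss_error(k: np.ndarray, kbar: float, target_ss: float) -> float:
    dev = k - kbar
    return abs(float(dev @ dev) - target_ss)


def sample_ensemble(
    spec: EnsembleSpec,
    grids: dict[str, ValueGrid],
    layout: SpatialLayout,
    rng: np.random.Generator,
    sd_tolerance: float = 0.5,
    max_restarts: int = 10_000,
) -> LineEnsemble:
    """Realize a spec as 12 lines; lengths and orientations are solved and
    shuffled independently, so the two features are uncorrelated across lines."""
    lengths = sample_feature_values(grids[LENGTH], N_LINES, spec.mean_length,
                                    spec.sd_length, rng, sd_tolerance, max_restarts)
    orientations = sample_feature_values(grids[ORIENTATION], N_LINES,
                                         spec.mean_orientation, spec.sd_orientation,
                                         rng, sd_tolerance, max_restarts)
    return LineEnsemble(spec=spec, lengths=tuple(lengths),
                        orientations=tuple(orientations), layout=layout)


def build_layouts(n_versions: int, seed: int | None = None) -> list[SpatialLayout]:
    """One fixed layout per (version, task): 12 cells on the 5x4 grid with
    exactly 3 lines per row, drawn by seeded sampling of 3 columns per row."""
    if n_versions < 1:
        raise ValueError("n_versions must be >= 1")
    rng = np.random.default_rng(seed)
    layouts = []
    for version in range(1, n_versions + 1):
        for task in TASKS:
            cells = []
            for row in range(1, N_GRID_ROWS + 1):
                cols = rng.choice(N_GRID_COLS, size=LINES_PER_ROW, replace=False)
                cells.extend((row, int(c) + 1) for c in sorted(cols))
            layouts.append(SpatialLayout(version=version, task=task,
                                         cells=tuple(cells)))
    return layouts


@dataclass(frozen=True)
class PracticeTrial:
    """Practice spec plus its (columns 1/3/5) layout override."""

    spec: EnsembleSpec
    layout: SpatialLayout


def practice_layout(task: str) -> SpatialLayout:
    """All 12 cells of columns 1, 3 and 5 — fully occupied, easy to group."""
    cells = tuple((row, col) for row in range(1, N_GRID_ROWS + 1)
                  for col in PRACTICE_COLUMNS)
    return SpatialLayout(version=0, task=task, cells=cells)


def build_practice_design(task: str, seed: int | None = None) -> list[PracticeTrial]:
    """10 easier warm-up trials: relevant mean sampled from the 5 main probe
    values, relevant SD reduced to 4 px / 4.5 deg, lines in columns 1/3/5."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    layout = practice_layout(task)
    rel_means = PROBES[task]
    if task == LENGTH:
        irr_means, irr_sds = ORIENTATION_MEANS_IRRELEVANT, ORIENTATION_SDS
    else:
        irr_means, irr_sds = LENGTH_MEANS_IRRELEVANT, LENGTH_SDS
    trials = []
    for _ in range(N_PRACTICE_TRIALS):
        rel_mean = float(rng.choice(rel_means))
        irr_mean = float(rng.choice(irr_means))
        irr_sd = float(rng.choice(irr_sds))
        if task == LENGTH:
            spec = EnsembleSpec(task, rel_mean, PRACTICE_SD[LENGTH],
                                irr_mean, irr_sd, repetition=1)
        else:
            spec = EnsembleSpec(task, irr_mean, irr_sd,
                                rel_mean, PRACTICE_SD[ORIENTATION], repetition=1)
        trials.append(PracticeTrial(spec=spec, layout=layout))
    return trials


def realize_design(
    task: str,
    layout: SpatialLayout,
    seed: int | None = None,
    sd_tolerance: float = 0.5,
    max_restarts: int = 10_000,
) -> list[LineEnsemble]:
    """Build, order and realize the full 120-trial design of one task."""
    rng = np.random.default_rng(seed)
    specs = build_task_design(task, order_seed=seed)
    grids = {f: build_value_grid(f) for f in TASKS}
    return [sample_ensemble(s, grids, layout, rng, sd_tolerance, max_restarts)
            for s in specs]
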