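"""Spotted hyena optimizer (SHO) with adaptive stopping, plus wrapper
feature selection on top of it.

The continuous optimizer mimics pack hunting: every member ("hyena") moves
relative to the best-so-far solution ("prey") through randomized coefficient
vectors Y and Z, where Z shrinks with a control value ``l`` that decays
linearly from 5 to 0 over the run.  Each iteration a cluster of the best
members encircles the prey and the remaining members jump to the cluster
centroid.  Members whose Z coefficients are large (mean |Z| > 1) explore by
referencing a random point in the box instead of the prey.  The best-so-far
solution is tracked separately (elitism), so the best-fitness trace is
monotone non-increasing.  The run stops early once the best value improves
by less than ``epsilon`` for ``patience`` consecutive iterations.

Feature selection binarizes each continuous position through a stochastic
sigmoid transfer into a feature mask and scores the mask with a weighted
fitness combining the wrapper classifier's cross-validated error E(X) with a
subset-size term: alpha * E + beta * |R|/|N| (minimized; the historical
"1 - |R|/|N|" form, which rewards larger subsets under minimization, is
available behind the ``as_printed`` flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .table import FeatureMask, FeatureTable

__all__ = [
    "SHOAConfig",
    "ControlParams",
    "HyenaSwarm",
    "SHOAResult",
    "control_schedule",
    "control_params",
    "encircle_update",
    "cluster_and_attack",
    "shoa_minimize",
    "binarize",
    "FSFitnessSpec",
    "fs_fitness",
    "knn_cv_error",
    "select_features",
]


@dataclass
class SHOAConfig:
    """Optimizer settings; ``bounds`` is one (lower, upper) pair per dimension.

    ``patience`` enables the adaptive stop: quit once the best value improves
    by less than ``epsilon`` for that many consecutive iterations.  It is off
    by default (None): the linear 5 -> 0 control schedule makes progress
    end-loaded — early iterations explore without improving the incumbent —
    so a small patience would halt the run before exploitation begins.
    """

    bounds: Sequence[tuple[float, float]]
    pop_size: int = 20
    max_iter: int = 100
    epsilon: float = 1e-10
    patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be >= 1 (or None to disable)")
        lb, ub = self.box()
        if np.any(lb >= ub):
            raise ValueError("each lower bound must be below its upper bound")

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.bounds, dtype=float)
        return arr[:, 0], arr[:, 1]


@dataclass
class ControlParams:
    """One member's randomized coefficients for a single update."""

    l: float
    Y: np.ndarray
    Z: np.ndarray
    r1: np.ndarray
    r2: np.ndarray


def control_schedule(iteration: int, max_iter: int) -> float:
    """Linear decay of the control value: l = 5 - iteration * (5 / max_iter)."""
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    if not 0 <= iteration <= max_iter:
        raise ValueError("iteration must lie in [0, max_iter]")
    return 5.0 - iteration * (5.0 / max_iter)


def control_params(iteration: int, max_iter: int, rng: np.random.Generator, dim: int = 1) -> ControlParams:
    """Draw Y = 2 r1 and Z = 2 l r2 - l at the scheduled control value."""
    l = control_schedule(iteration, max_iter)
    r1 = rng.uniform(size=dim)
    r2 = rng.uniform(size=dim)
    return ControlParams(l=l, Y=2.0 * r1, Z=2.0 * l * r2 - l, r1=r1, r2=r2)


def encircle_update(
    position: np.ndarray,
    reference: np.ndarray,
    params: ControlParams,
    lb: np.ndarray,
    ub: np.ndarray,
) -> np.ndarray:
    """Move toward (or around) a reference point: new = ref - Z * |Y*ref - pos|."""
    distance = np.abs(params.Y * reference - position)
    return np.clip(reference - params.Z * distance, lb, ub)


@dataclass
class HyenaSwarm:
    positions: np.ndarray  # (pop, dim)
    fitness: np.ndarray  # (pop,)
    prey: np.ndarray  # best-so-far position
    prey_value: float


def _evaluate(objective: Callable, x: np.ndarray) -> float:
    v = float(objective(x))
    if not np.isfinite(v):
        raise ValueError(f"objective returned non-finite value {v!r} at {x!r}")
    return v


def cluster_and_attack(
    swarm: HyenaSwarm,
    objective: Callable,
    l: float,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """One full iteration, in place.

    Draw order (fixed for reproducibility and oracle comparison):

    1. one scalar G ~ U(0.5, 1);
    2. cluster membership: members whose fitness lies within G*|f_best| of
       the best-so-far value (at least one: the current argmin);
    3. per cluster member, ascending index: r1 and r2 vectors; then, if the
       member explores (mean |Z| > 1), a random reference point in the box;
    4. encircle update for each cluster member;
    5. every non-member jumps to the centroid of the updated cluster;
    6. all members re-evaluated, best-so-far refreshed (elitism).
    """
    pop, dim = swarm.positions.shape
    G = rng.uniform(0.5, 1.0)
    member = np.abs(swarm.fitness - swarm.prey_value) <= G * abs(swarm.prey_value)
    if not member.any():
        member[int(np.argmin(swarm.fitness))] = True

    for i in range(pop):
        if not member[i]:
            continue
        params = _draw_member_params(l, dim, rng)
        if np.mean(np.abs(params.Z)) > 1.0:  # exploration: random reference
            reference = rng.uniform(lb, ub)
        else:
            reference = swarm.prey
        swarm.positions[i] = encircle_update(swarm.positions[i], reference, params, lb, ub)

    centroid = swarm.positions[member].mean(axis=0)
    swarm.positions[~member] = centroid

    for i in range(pop):
        swarm.fitness[i] = _evaluate(objective, swarm.positions[i])
    best = int(np.argmin(swarm.fitness))
    if swarm.fitness[best] < swarm.prey_value:
        swarm.prey = swarm.positions[best].copy()
        swarm.prey_value = float(swarm.fitness[best])


def _draw_member_params(l: float, dim: int, rng: np.random.Generator) -> ControlParams:
    r1 = rng.uniform(size=dim)
    r2 = rng.uniform(size=dim)
    return ControlParams(l=l, Y=2.0 * r1, Z=2.0 * l * r2 - l, r1=r1, r2=r2)


@dataclass
class SHOAResult:
    best_position: np.ndarray
    best_value: float
    history: list  # best value after init and after each iteration
    n_iterations: int
    stopped_early: bool


def shoa_minimize(objective: Callable, config: SHOAConfig) -> SHOAResult:
    """Minimize a finite objective on a box.

    The history starts with the initial population's best and appends the
    best-so-far after each iteration; it is monotone non-increasing.
    """
    lb, ub = config.box()
    dim = lb.size
    rng = np.random.default_rng(config.seed)

    positions = rng.uniform(lb, ub, size=(config.pop_size, dim))
    fitness = np.array([_evaluate(objective, p) for p in positions])
    best = int(np.argmin(fitness))
    swarm = HyenaSwarm(positions, fitness, positions[best].copy(), float(fitness[best]))

    history = [swarm.prey_value]
    streak = 0
    stopped = False
    it = 0
    for it in range(1, config.max_iter + 1):
        l = control_schedule(it, config.max_iter)
        cluster_and_attack(swarm, objective, l, lb, ub, rng)
        history.append(swarm.prey_value)
        if config.patience is not None:
            if abs(history[-1] - history[-2]) < config.epsilon:
                streak += 1
                if streak >= config.patience:
                    stopped = True
                    break
            else:
                streak = 0
    return SHOAResult(swarm.prey.copy(), swarm.prey_value, history, it, stopped)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binarize(
    position: np.ndarray, rng: np.random.Generator, feature_names: list[str] | None = None
) -> FeatureMask:
    """Stochastic sigmoid transfer from a continuous position to a mask.

    bit_j = 1 iff sigmoid(x_j) > u_j with u_j ~ U(0,1); an all-zero draw is
    repaired by setting the single bit with the largest sigmoid value.
    """
    position = np.asarray(position, dtype=float)
    probs = _sigmoid(position)
    bits = (probs > rng.uniform(size=position.size)).astype(int)
    if bits.sum() == 0:
        bits[int(np.argmax(probs))] = 1
    return FeatureMask(bits, feature_names=feature_names)


@dataclass
class FSFitnessSpec:
    """Weights and error estimator for the feature-selection fitness.

    ``error_estimator`` maps a mask to a classification error in [0, 1].
    Defaults weight error heavily (alpha = 0.99) so parsimony only breaks
    ties; alpha + beta must equal 1.
    """

    error_estimator: Callable[[FeatureMask], float]
    n_total: int
    alpha: float = 0.99
    beta: float = 0.01
    as_printed: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha and beta must be nonnegative and sum to 1")


def fs_fitness(mask: FeatureMask, spec: FSFitnessSpec) -> float:
    """alpha * E(X) + beta * |R|/|N| (default), minimized.

    With ``as_printed`` the size term flips to beta * (1 - |R|/|N|).
    """
    if mask.selected_count == 0:
        raise ValueError("empty mask cannot be scored")
    err = float(spec.error_estimator(mask))
    ratio = mask.selected_count / spec.n_total
    size_term = (1.0 - ratio) if spec.as_printed else ratio
    return spec.alpha * err + spec.beta * size_term


def knn_cv_error(
    table: FeatureTable, k: int = 5, n_splits: int = 5, n_repeats: int = 3, seed: int = 0
) -> Callable[[FeatureMask], float]:
    """Wrapper error estimator: repeated stratified k-fold CV error of a k-NN
    classifier restricted to the masked columns.

    Repetition damps fold-assignment noise, which otherwise can reorder
    near-tied subsets and mislead the search.
    """
    from sklearn.model_selection import RepeatedStratifiedKFold
    from sklearn.neighbors import KNeighborsClassifier

    X = table.values()
    y = table.y

    def estimate(mask: FeatureMask) -> float:
        cols = mask.selected_indices()
        if cols.size == 0:
            return 1.0
        Xm = X[:, cols]
        cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
        errs = [
            1.0 - KNeighborsClassifier(n_neighbors=k).fit(Xm[tr], y[tr]).score(Xm[te], y[te])
            for tr, te in cv.split(Xm, y)
        ]
        return float(np.mean(errs))

    return estimate


@dataclass
class FSResult:
    mask: FeatureMask
    best_fitness: float
    history: list
    n_evaluations: int

    def trace_rows(self) -> list[tuple[int, float, int]]:
        return [(i, f, self.mask.selected_count) for i, f in enumerate(self.history)]


def select_features(
    table: FeatureTable,
    config: SHOAConfig | None = None,
    spec: FSFitnessSpec | None = None,
) -> FSResult:
    """Search feature masks by optimizing continuous positions that are
    binarized per evaluation.  The label column is never a candidate."""
    d = table.n_features
    if d < 2:
        raise ValueError("need at least 2 candidate features")
    if config is None:
        config = SHOAConfig(bounds=[(-4.0, 4.0)] * d, pop_size=10, max_iter=30)
    if spec is None:
        spec = FSFitnessSpec(error_estimator=knn_cv_error(table), n_total=d)

    bin_rng = np.random.default_rng([config.seed, 0x5E1EC7])
    cache: dict[bytes, float] = {}
    best = {"fitness": np.inf, "mask": None, "evals": 0}

    def objective(x: np.ndarray) -> float:
        mask = binarize(x, bin_rng, feature_names=table.feature_names)
        key = mask.bits.tobytes()
        if key not in cache:
            cache[key] = float(spec.error_estimator(mask))
            best["evals"] += 1
        err = cache[key]
        ratio = mask.selected_count / spec.n_total
        size_term = (1.0 - ratio) if spec.as_printed else ratio
        fit = spec.alpha * err + spec.beta * size_term
        if fit < best["fitness"]:
            best["fitness"] = fit
            best["mask"] = mask
        return fit

    result = shoa_minimize(objective, config)
    return FSResult(best["mask"], best["fitness"], result.history, best["evals"])


def write_trace_csv(path, result: FSResult) -> None:
    """Convergence trace as CSV: iteration, best_fitness, n_selected."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("iteration,best_fitness,n_selected\n")
        for it, fit, n in result.trace_rows():
            fh.write(f"{it},{fit!r},{n}\n")


def write_mask_json(path, mask: FeatureMask) -> None:
    """Selected feature names as a JSON list."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(mask.selected_names(), fh, indent=2)
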