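"""Coati optimization algorithm (COA) with a dynamic-opposite-learning (DOL)
modification, plus the hyperparameter-tuning harness for the recurrent
classifier.

Each iteration runs up to three stages over an even-sized population on a
box, every proposal accepted only if it strictly improves that member
(greedy acceptance, so per-member fitness is monotone non-increasing):

* **Phase 1 (predation)** — the first half of the population moves toward the
  best-so-far solution; a random "iguana" point is dropped into the box and
  the second half moves toward it if it is better than they are, away
  otherwise.
* **Phase 2 (predator escape)** — every member takes a small random jump
  inside local bounds lb/t, ub/t that shrink with the 1-based iteration t.
* **DOL stage (the modification)** — members are paired across the
  population halves; each member proposes a dynamically weighted move toward
  the box-opposite (lb + ub - x) of its partner.  Disabling the stage
  reproduces the plain COA draw-for-draw.

Hyperparameter tuning decodes optimizer positions in the unit cube into
learning rate (log scale), hidden size, dropout and batch size, trains the
classifier on the training split, and scores validation precision
P = TP / (TP + FP) by default (switchable to accuracy), maximized by
minimizing 1 - P.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .table import FeatureTable

__all__ = [
    "COAConfig",
    "CoatiSwarm",
    "COAResult",
    "phase1_update",
    "phase2_update",
    "escape_bounds",
    "opposite",
    "dynamic_opposite",
    "dol_update",
    "mcoa_minimize",
    "HyperDim",
    "HyperparamSpace",
    "default_space",
    "BASELINE_HYPERPARAMS",
    "TuneResult",
    "tune_abigru",
]


@dataclass
class COAConfig:
    bounds: Sequence[tuple[float, float]]
    pop_size: int = 20
    max_iter: int = 100
    seed: int = 0
    dol_enabled: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 4 (the stages split the population in half)")
        lb, ub = self.box()
        if np.any(lb >= ub):
            raise ValueError("each lower bound must be below its upper bound")

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.bounds, dtype=float)
        return arr[:, 0], arr[:, 1]


@dataclass
class CoatiSwarm:
    positions: np.ndarray  # (pop, dim)
    fitness: np.ndarray  # (pop,)
    best: np.ndarray
    best_value: float
    iteration: int = 1  # 1-based; phase-2 local bounds divide by it


def _evaluate(objective: Callable, x: np.ndarray) -> float:
    v = float(objective(x))
    if not np.isfinite(v):
        raise ValueError(f"objective returned non-finite value {v!r} at {x!r}")
    return v


def _refresh_best(swarm: CoatiSwarm) -> None:
    i = int(np.argmin(swarm.fitness))
    if swarm.fitness[i] < swarm.best_value:
        swarm.best = swarm.positions[i].copy()
        swarm.best_value = float(swarm.fitness[i])


def _greedy(swarm: CoatiSwarm, i: int, proposal: np.ndarray, objective: Callable) -> None:
    f = _evaluate(objective, proposal)
    if f < swarm.fitness[i]:
        swarm.positions[i] = proposal
        swarm.fitness[i] = f


def phase1_update(
    swarm: CoatiSwarm,
    objective: Callable,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Predation stage, in place.

    Draw order: per first-half member ascending, a scalar I in {1, 2} then a
    per-dimension r; then one iguana point; then per second-half member
    ascending, a scalar I and a per-dimension r.
    """
    pop, dim = swarm.positions.shape
    half = pop // 2
    for i in range(half):
        I = int(rng.integers(1, 3))
        r = rng.uniform(size=dim)
        prop = swarm.positions[i] + r * (swarm.best - I * swarm.positions[i])
        _greedy(swarm, i, np.clip(prop, lb, ub), objective)
    iguana = lb + rng.uniform(size=dim) * (ub - lb)
    f_iguana = _evaluate(objective, iguana)
    for i in range(half, pop):
        I = int(rng.integers(1, 3))
        r = rng.uniform(size=dim)
        if f_iguana < swarm.fitness[i]:
            prop = swarm.positions[i] + r * (iguana - I * swarm.positions[i])
        else:
            prop = swarm.positions[i] + r * (swarm.positions[i] - iguana)
        _greedy(swarm, i, np.clip(prop, lb, ub), objective)
    _refresh_best(swarm)


def escape_bounds(lb: np.ndarray, ub: np.ndarray, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Iteration-shrinking local escape range lb/t, ub/t (t is 1-based)."""
    if t < 1:
        raise ValueError("iteration t must be >= 1")
    return lb / t, ub / t


def phase2_update(
    swarm: CoatiSwarm,
    objective: Callable,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Predator-escape stage: per member ascending, one per-dimension r used
    both in the (1 - 2r) factor and inside the local-range term."""
    pop, dim = swarm.positions.shape
    lb_loc, ub_loc = escape_bounds(lb, ub, swarm.iteration)
    for i in range(pop):
        r = rng.uniform(size=dim)
        prop = swarm.positions[i] + (1.0 - 2.0 * r) * (lb_loc + r * (ub_loc - lb_loc))
        _greedy(swarm, i, np.clip(prop, lb, ub), objective)
    _refresh_best(swarm)


def opposite(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Opposition point within bounds [a, b]: x_o = a + b - x."""
    return a + b - x


def dynamic_opposite(x: np.ndarray, x_o: np.ndarray, r1, r2) -> np.ndarray:
    """Dynamic opposite move: x + r1 * (r2 * x_o - x)."""
    return x + r1 * (r2 * x_o - x)


def dol_update(
    swarm: CoatiSwarm,
    objective: Callable,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Dynamic-opposite-learning stage, in place.

    Member i is paired with member i + pop/2 (mod pop): the i-th member of
    the first half opposes against the i-th member of the second half and
    vice versa.  Per member ascending, two fresh per-dimension uniforms are
    drawn; the proposal is x_i + rc1 * (rc2 * (lb + ub - x_op) - x_op),
    clamped and accepted greedily.  Partners are read live (already-updated
    positions are seen by later members).
    """
    pop, dim = swarm.positions.shape
    half = pop // 2
    for i in range(pop):
        partner = swarm.positions[(i + half) % pop]
        rc1 = rng.uniform(size=dim)
        rc2 = rng.uniform(size=dim)
        prop = swarm.positions[i] + rc1 * (rc2 * opposite(partner, lb, ub) - partner)
        _greedy(swarm, i, np.clip(prop, lb, ub), objective)
    _refresh_best(swarm)


@dataclass
class COAResult:
    best_position: np.ndarray
    best_value: float
    history: list
    n_iterations: int


def mcoa_minimize(
    objective: Callable, config: COAConfig, initial: np.ndarray | None = None
) -> COAResult:
    """Run phase 1 -> phase 2 -> (if enabled) DOL for max_iter iterations.

    With ``dol_enabled=False`` this is the plain COA, draw-for-draw: the DOL
    stage consumes its random numbers after the two phases, so disabling it
    leaves the phase draws untouched.  ``initial`` optionally warm-starts the
    search: its rows replace the first members of the random initial
    population (clamped to the box), guaranteeing those points are visited.
    """
    lb, ub = config.box()
    dim = lb.size
    rng = np.random.default_rng(config.seed)

    positions = rng.uniform(lb, ub, size=(config.pop_size, dim))
    if initial is not None:
        initial = np.atleast_2d(np.asarray(initial, dtype=float))
        k = min(len(initial), config.pop_size)
        positions[:k] = np.clip(initial[:k], lb, ub)
    fitness = np.array([_evaluate(objective, p) for p in positions])
    best = int(np.argmin(fitness))
    swarm = CoatiSwarm(positions, fitness, positions[best].copy(), float(fitness[best]))

    history = [swarm.best_value]
    for t in range(1, config.max_iter + 1):
        swarm.iteration = t
        phase1_update(swarm, objective, lb, ub, rng)
        phase2_update(swarm, objective, lb, ub, rng)
        if config.dol_enabled:
            dol_update(swarm, objective, lb, ub, rng)
        history.append(swarm.best_value)
    return COAResult(swarm.best.copy(), swarm.best_value, history, config.max_iter)


# ---------------------------------------------------------------------------
# hyperparameter tuning harness


@dataclass(frozen=True)
class HyperDim:
    name: str
    lower: float
    upper: float
    scale: str = "linear"  # "linear" | "log"
    integer: bool = False

    def decode(self, u: float) -> float:
        u = float(np.clip(u, 0.0, 1.0))
        if self.scale == "log":
            lo, hi = np.log(self.lower), np.log(self.upper)
            v = float(np.exp(lo + u * (hi - lo)))
        else:
            v = self.lower + u * (self.upper - self.lower)
        if self.integer:
            v = int(round(v))
            v = int(np.clip(v, self.lower, self.upper))
        return v

    def encode(self, value: float) -> float:
        """Inverse of :meth:`decode` (up to integer rounding)."""
        if self.scale == "log":
            lo, hi = np.log(self.lower), np.log(self.upper)
            span = hi - lo
            u = (np.log(value) - lo) / span if span else 0.5
        else:
            span = self.upper - self.lower
            u = (value - self.lower) / span if span else 0.5
        return float(np.clip(u, 0.0, 1.0))


@dataclass
class HyperparamSpace:
    """Named tunable dimensions; optimizer positions live in the unit cube."""

    dims: list

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def decode(self, position: np.ndarray) -> dict:
        if len(position) != self.n_dims:
            raise ValueError("position length does not match the space")
        return {d.name: d.decode(u) for d, u in zip(self.dims, position)}

    def encode(self, params: dict) -> np.ndarray:
        """Unit-cube position for a named parameter dict (missing names sit
        at the dimension's midpoint)."""
        return np.array([d.encode(params[d.name]) if d.name in params else 0.5
                         for d in self.dims])

    def unit_bounds(self) -> list[tuple[float, float]]:
        return [(0.0, 1.0)] * self.n_dims


# fixed reference configuration: lr 0.01, dropout 0.5, batch size 5, 50 epochs
BASELINE_HYPERPARAMS = {
    "learning_rate": 0.01,
    "hidden_size": 8,
    "dropout": 0.5,
    "batch_size": 5,
}


def default_space() -> HyperparamSpace:
    """Search space centered on the reference configuration."""
    return HyperparamSpace(
        dims=[
            HyperDim("learning_rate", 1e-3, 1e-1, scale="log"),
            HyperDim("hidden_size", 4, 32, integer=True),
            HyperDim("dropout", 0.0, 0.8),
            HyperDim("batch_size", 2, 16, integer=True),
        ]
    )


@dataclass
class TuneResult:
    best_params: dict
    best_fitness: float  # 1 - metric on validation
    best_metric: float
    history: list
    metric: str


def tune_abigru(
    space: HyperparamSpace,
    train: FeatureTable,
    val: FeatureTable,
    config: COAConfig | None = None,
    metric: str = "precision",
    epochs: int = 50,
    train_seed: int = 0,
) -> TuneResult:
    """Tune the recurrent classifier's hyperparameters on a held-out split.

    Each candidate position decodes to hyperparameters, a fresh classifier is
    trained on ``train`` and scored on ``val``; fitness is 1 - P with
    P = TP/(TP+FP) (or 1 - accuracy with ``metric="accuracy"``).  A candidate
    whose training fails scores worst (fitness 1) and the search continues.
    """
    from . import abigru
    from .metrics import accuracy as overall_accuracy
    from .metrics import confusion_counts, precision

    if metric not in ("precision", "accuracy"):
        raise ValueError("metric must be 'precision' or 'accuracy'")
    if space.n_dims == 0:
        raise ValueError("empty hyperparameter space")
    if config is None:
        config = COAConfig(bounds=space.unit_bounds(), pop_size=6, max_iter=5)
    else:
        config = replace(config, bounds=space.unit_bounds())

    def fitness_of(params: dict) -> float:
        cfg = abigru.TrainConfig(
            learning_rate=params.get("learning_rate", BASELINE_HYPERPARAMS["learning_rate"]),
            epochs=epochs,
            dropout=params.get("dropout", BASELINE_HYPERPARAMS["dropout"]),
            batch_size=int(params.get("batch_size", BASELINE_HYPERPARAMS["batch_size"])),
            seed=train_seed,
        )
        model = abigru.ABiGRUModel.initialize(
            n_features=train.n_features,
            hidden_size=int(params.get("hidden_size", BASELINE_HYPERPARAMS["hidden_size"])),
            seed=train_seed,
        )
        try:
            abigru.train(model, train, cfg)
            _, labels = abigru.predict(model, val)
        except (FloatingPointError, ValueError, OverflowError, RuntimeError):
            return 1.0
        counts = confusion_counts(val.y, labels, positive=val.positive)
        score = precision(counts) if metric == "precision" else overall_accuracy(counts)
        return 1.0 - float(score)

    cache: dict[tuple, float] = {}

    def objective(position: np.ndarray) -> float:
        params = space.decode(position)
        key = tuple(sorted(params.items()))
        if key not in cache:
            cache[key] = fitness_of(params)
        return cache[key]

    # warm-start with the reference configuration so the returned settings
    # can never score below it on the validation split
    result = mcoa_minimize(objective, config, initial=space.encode(BASELINE_HYPERPARAMS))
    best_params = space.decode(result.best_position)
    return TuneResult(
        best_params=best_params,
        best_fitness=result.best_value,
        best_metric=1.0 - result.best_value,
        history=result.history,
        metric=metric,
    )
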