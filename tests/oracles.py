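"""Independent straight-line transcriptions of one optimizer iteration.

These re-derive each update rule with plain Python loops and scalars, sharing
only the documented random-draw protocol with the library code.  The tests
assert that one full iteration of the library implementation is bit-equal to
these transcriptions.
"""

from __future__ import annotations

import numpy as np


def shoa_iteration_oracle(positions, fitness, prey, prey_value, l, lb, ub, objective, rng):
    """One spotted-hyena iteration: encircle/hunt/attack plus elitist prey
    tracking, written as literal loops over members and dimensions."""
    positions = [row.astype(float).copy() for row in positions]
    fitness = [float(f) for f in fitness]
    prey = prey.astype(float).copy()
    prey_value = float(prey_value)
    pop = len(positions)
    dim = prey.size

    G = rng.uniform(0.5, 1.0)
    member = [abs(f - prey_value) <= G * abs(prey_value) for f in fitness]
    if not any(member):
        member[int(np.argmin(fitness))] = True

    for i in range(pop):
        if not member[i]:
            continue
        r1 = rng.uniform(size=dim)
        r2 = rng.uniform(size=dim)
        Y = 2.0 * r1
        Z = 2.0 * l * r2 - l
        if np.mean(np.abs(Z)) > 1.0:
            reference = rng.uniform(lb, ub)
        else:
            reference = prey
        new = np.empty(dim)
        for j in range(dim):
            distance = abs(Y[j] * reference[j] - positions[i][j])
            new[j] = reference[j] - Z[j] * distance
            new[j] = min(max(new[j], lb[j]), ub[j])
        positions[i] = new

    cluster = [positions[i] for i in range(pop) if member[i]]
    centroid = np.zeros(dim)
    for p in cluster:
        centroid = centroid + p
    centroid = centroid / len(cluster)
    for i in range(pop):
        if not member[i]:
            positions[i] = centroid.copy()

    for i in range(pop):
        fitness[i] = float(objective(positions[i]))
    best = int(np.argmin(fitness))
    if fitness[best] < prey_value:
        prey = positions[best].copy()
        prey_value = fitness[best]
    return np.array(positions), np.array(fitness), prey, prey_value


def coa_iteration_oracle(positions, fitness, best, best_value, t, lb, ub, objective, rng, dol):
    """One coati iteration (predation, escape, optional dynamic-opposite
    stage) transcribed with per-member loops and greedy acceptance."""
    positions = [row.astype(float).copy() for row in positions]
    fitness = [float(f) for f in fitness]
    best = best.astype(float).copy()
    best_value = float(best_value)
    pop = len(positions)
    half = pop // 2
    dim = best.size

    def clamp(x):
        return np.minimum(np.maximum(x, lb), ub)

    def greedy(i, prop):
        nonlocal positions, fitness
        f = float(objective(prop))
        if f < fitness[i]:
            positions[i] = prop
            fitness[i] = f

    def refresh():
        nonlocal best, best_value
        i = int(np.argmin(fitness))
        if fitness[i] < best_value:
            best = positions[i].copy()
            best_value = fitness[i]

    # phase 1: first half climbs toward the best solution
    for i in range(half):
        I = int(rng.integers(1, 3))
        r = rng.uniform(size=dim)
        prop = positions[i] + r * (best - I * positions[i])
        greedy(i, clamp(prop))
    # one random iguana for the ground half
    iguana = lb + rng.uniform(size=dim) * (ub - lb)
    f_iguana = float(objective(iguana))
    for i in range(half, pop):
        I = int(rng.integers(1, 3))
        r = rng.uniform(size=dim)
        if f_iguana < fitness[i]:
            prop = positions[i] + r * (iguana - I * positions[i])
        else:
            prop = positions[i] + r * (positions[i] - iguana)
        greedy(i, clamp(prop))
    refresh()

    # phase 2: escape jumps inside lb/t, ub/t
    lb_loc = lb / t
    ub_loc = ub / t
    for i in range(pop):
        r = rng.uniform(size=dim)
        prop = positions[i] + (1.0 - 2.0 * r) * (lb_loc + r * (ub_loc - lb_loc))
        greedy(i, clamp(prop))
    refresh()

    if dol:
        for i in range(pop):
            partner = positions[(i + half) % pop]
            rc1 = rng.uniform(size=dim)
            rc2 = rng.uniform(size=dim)
            opposite = lb + ub - partner
            prop = positions[i] + rc1 * (rc2 * opposite - partner)
            greedy(i, clamp(prop))
        refresh()

    return np.array(positions), np.array(fitness), best, best_value
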