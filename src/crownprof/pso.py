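"""Canonical particle swarm optimisation for box-constrained minimisation.

Velocity update with inertia, cognitive and social terms; positions are
clamped to the bounds and selected dimensions are rounded to integers before
every objective evaluation.  Deterministic under the seed.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def minimize(
    objective: Callable[[np.ndarray], float],
    lb: np.ndarray,
    ub: np.ndarray,
    swarm_size: int = 10,
    iterations: int = 20,
    seed: int = 0,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
    integer_dims: Sequence[int] = (),
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimise ``objective`` over the box [lb, ub].

    Returns ``(best_x, best_f, trace)`` where ``trace[i]`` is the best
    objective value seen up to iteration i (monotone nonincreasing; entry 0
    is the best of the initial swarm).
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if lb.shape != ub.shape or np.any(ub < lb):
        raise ValueError("invalid bounds")
    ndim = lb.size
    rng = np.random.default_rng(seed)

    def repair(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, lb, ub)
        for d in integer_dims:
            x[d] = np.clip(round(x[d]), lb[d], ub[d])
        return x

    pos = rng.uniform(lb, ub, (swarm_size, ndim))
    vel = rng.uniform(-(ub - lb), ub - lb, (swarm_size, ndim)) * 0.1
    pbest = pos.copy()
    pbest_f = np.array([objective(repair(p.copy())) for p in pos])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    trace = [gbest_f]

    for _ in range(iterations):
        r1 = rng.uniform(size=(swarm_size, ndim))
        r2 = rng.uniform(size=(swarm_size, ndim))
        vel = (inertia * vel
               + cognitive * r1 * (pbest - pos)
               + social * r2 * (gbest - pos))
        pos = np.clip(pos + vel, lb, ub)
        for p in range(swarm_size):
            f = objective(repair(pos[p].copy()))
            if f < pbest_f[p]:
                pbest[p], pbest_f[p] = pos[p].copy(), f
                if f < gbest_f:
                    gbest, gbest_f = pos[p].copy(), float(f)
        trace.append(gbest_f)

    return repair(gbest.copy()), gbest_f, np.array(trace)
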