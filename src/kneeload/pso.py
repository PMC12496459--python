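"""Particle swarm optimization: generic bounded minimizer plus a
hyperparameter-search wrapper over ModelConfig."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ArgumentError
from .model import ModelConfig


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_f: float
    history: list[float]  # best objective after each iteration
    n_evaluations: int


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    n_particles: int = 20,
    n_iterations: int = 50,
    seed: int = 0,
    inertia: float = 0.72,
    cognitive: float = 1.49,
    social: float = 1.49,
) -> PSOResult:
    """Standard global-best PSO with inertia, cognitive, and social terms.

    Positions are clipped to the box, so every evaluated point stays within
    bounds; the trajectory is fully determined by ``seed``.
    """
    bounds_arr = np.asarray(bounds, dtype=float)
    if bounds_arr.ndim != 2 or bounds_arr.shape[1] != 2 or bounds_arr.shape[0] == 0:
        raise ArgumentError("bounds must be a nonempty sequence of (low, high)")
    if np.any(bounds_arr[:, 0] > bounds_arr[:, 1]):
        raise ArgumentError("each bound must satisfy low <= high")
    if n_particles < 1 or n_iterations < 0:
        raise ArgumentError("need >= 1 particle and >= 0 iterations")

    lo, hi = bounds_arr[:, 0], bounds_arr[:, 1]
    span = hi - lo
    dim = len(bounds_arr)
    rng = np.random.default_rng(seed)

    x = lo + rng.uniform(size=(n_particles, dim)) * span
    v = rng.uniform(-1.0, 1.0, size=(n_particles, dim)) * span * 0.1
    f = np.array([objective(xi) for xi in x])
    n_eval = n_particles

    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])
    history = [gbest_f]

    for _ in range(n_iterations):
        r1 = rng.uniform(size=(n_particles, dim))
        r2 = rng.uniform(size=(n_particles, dim))
        v = (
            inertia * v
            + cognitive * r1 * (pbest_x - x)
            + social * r2 * (gbest_x - x)
        )
        x = np.clip(x + v, lo, hi)
        f = np.array([objective(xi) for xi in x])
        n_eval += n_particles
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        history.append(gbest_f)

    return PSOResult(best_x=gbest_x, best_f=gbest_f, history=history, n_evaluations=n_eval)


DEFAULT_SEARCH_SPACE = {
    "learning_rate": ("log", 1e-4, 1e-2),
    "gcn_width": ("choice", (16, 32, 64, 128)),
    "gru_width": ("choice", (16, 32, 64, 128)),
    "n_gcn_layers": ("choice", (1, 2, 3)),
}


def _decode(x: np.ndarray, space: dict) -> dict:
    out = {}
    for value, (name, spec) in zip(x, space.items()):
        kind = spec[0]
        if kind == "log":
            out[name] = float(10.0**value)
        elif kind == "linear":
            out[name] = float(value)
        elif kind == "choice":
            choices = spec[1]
            idx = int(np.clip(np.floor(value), 0, len(choices) - 1))
            out[name] = choices[idx]
        else:
            raise ArgumentError(f"unknown search dimension kind {kind!r}")
    return out


def _bounds(space: dict) -> list[tuple[float, float]]:
    bounds = []
    for spec in space.values():
        kind = spec[0]
        if kind == "log":
            bounds.append((np.log10(spec[1]), np.log10(spec[2])))
        elif kind == "linear":
            bounds.append((spec[1], spec[2]))
        elif kind == "choice":
            # upper bound just below len so floor() stays in range
            bounds.append((0.0, len(spec[1]) - 1e-9))
        else:
            raise ArgumentError(f"unknown search dimension kind {kind!r}")
    return bounds


def pso_tune(
    objective: Callable[[ModelConfig], float],
    base_config: ModelConfig | None = None,
    search_space: dict | None = None,
    swarm_size: int = 10,
    iterations: int = 10,
    seed: int = 0,
) -> tuple[ModelConfig, PSOResult]:
    """Search ModelConfig space for the lowest validation objective.

    ``search_space`` maps config field names to ("log", lo, hi),
    ("linear", lo, hi) or ("choice", options).
    """
    space = DEFAULT_SEARCH_SPACE if search_space is None else search_space
    if not space:
        raise ArgumentError("search space is empty")
    base = base_config if base_config is not None else ModelConfig()

    def wrapped(x: np.ndarray) -> float:
        return float(objective(replace(base, **_decode(x, space))))

    result = pso_minimize(
        wrapped,
        _bounds(space),
        n_particles=swarm_size,
        n_iterations=iterations,
        seed=seed,
    )
    return replace(base, **_decode(result.best_x, space)), result
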