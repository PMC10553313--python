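"""Adaptive-inertia particle swarm optimization of ensemble fusion weights.

The cascade produces five pooling-level class-probability predictions
P1..P5.  The final classifier is their convex combination
f(I) = w1*P1 + ... + w5*P5; the weight vector is found by a particle swarm
whose inertia adapts to the fraction of particles that improved in the
last iteration:

    v_i(t) = w(t) v_i(t-1) + M r1 [x_i^best - x_i(t-1)] + L r2 [x^best - x_i(t-1)]
    x_i(t) = x_i(t-1) + v_i(t)
    w(t)   = (w_max - w_min) Ps(t) + w_min

with cognitive/social coefficients M = L = 2, r1, r2 ~ U(0, 1) drawn fresh
per particle per iteration, w_max = 1.0, w_min = 0.3, and Ps(t) the strict
improvement fraction (Ps := 1 on the first iteration, giving the maximal
initial inertia).  Fitness is validation accuracy of the fused classifier;
raw positions are mapped to the simplex by clipping at zero and
renormalizing.  Positions are kept in [0, 1]^5 by reflection and velocities
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Particle",
    "SwarmConfig",
    "FusionWeights",
    "velocity_update",
    "position_update",
    "adaptive_inertia",
    "improvement_fraction",
    "normalize_weights",
    "fuse_probs",
    "fusion_fitness",
    "optimize_weights",
    "final_predict",
    "sphere_fitness",
]

N_HEADS = 5


@dataclass
class Particle:
    x: np.ndarray
    v: np.ndarray
    x_best: np.ndarray
    best_fitness: float = -np.inf
    fitness: float = -np.inf


@dataclass(frozen=True)
class SwarmConfig:
    n_particles: int = 30
    n_iterations: int = 100
    cognitive_coeff: float = 2.0   # M
    social_coeff: float = 2.0      # L
    omega_max: float = 1.0
    omega_min: float = 0.3
    velocity_clamp: float = 0.5
    position_low: float = 0.0
    position_high: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.omega_min < self.omega_max:
            raise ValueError("omega_min must be < omega_max")
        if self.cognitive_coeff < 0 or self.social_coeff < 0:
            raise ValueError("coefficients must be >= 0")


@dataclass(frozen=True)
class FusionWeights:
    """Nonnegative 5-vector on the simplex."""

    w: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.w)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("fusion weights must be a simplex point")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=np.float64)


def velocity_update(p: Particle, x_best: np.ndarray, omega: float,
                    cfg: SwarmConfig, r1: float, r2: float) -> np.ndarray:
    """One velocity step, then clamped to +-velocity_clamp componentwise."""
    v = (omega * p.v
         + cfg.cognitive_coeff * r1 * (p.x_best - p.x)
         + cfg.social_coeff * r2 * (x_best - p.x))
    return np.clip(v, -cfg.velocity_clamp, cfg.velocity_clamp)


def position_update(p: Particle, cfg: SwarmConfig) -> np.ndarray:
    """x + v, reflected back into [position_low, position_high]."""
    x = p.x + p.v
    lo, hi = cfg.position_low, cfg.position_high
    span = hi - lo
    # reflect: fold the coordinate into [lo, hi]
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def adaptive_inertia(ps: float, omega_max: float = 1.0,
                     omega_min: float = 0.3) -> float:
    """Linear map of the improvement fraction into [omega_min, omega_max]."""
    if not 0.0 <= ps <= 1.0:
        raise ValueError(f"improvement fraction must be in [0, 1], got {ps}")
    return (omega_max - omega_min) * ps + omega_min


def improvement_fraction(fitness_now: Sequence[float],
                         fitness_prev: Sequence[float]) -> float:
    """Fraction of particles whose fitness strictly improved."""
    now = np.asarray(fitness_now, dtype=np.float64)
    prev = np.asarray(fitness_prev, dtype=np.float64)
    if now.size == 0 or now.shape != prev.shape:
        raise ValueError("need equal-length, nonempty fitness lists")
    return float(np.mean(now > prev))


def normalize_weights(raw: np.ndarray) -> np.ndarray:
    """Clip at zero and renormalize to the simplex; all-zero falls back to
    uniform (logged upstream by callers that care)."""
    w = np.clip(np.asarray(raw, dtype=np.float64), 0.0, None)
    s = w.sum()
    if s <= 0:
        return np.full(w.shape, 1.0 / w.size)
    return w / s


def fuse_probs(pool_probs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Convex combination of the five heads.

    pool_probs: (n_samples, 5, C); weights: simplex 5-vector -> (n_samples, C).
    """
    return np.tensordot(np.asarray(pool_probs, np.float64), weights, axes=(1, 0))


def fusion_fitness(raw_weights: np.ndarray, pool_probs: np.ndarray,
                   labels: np.ndarray) -> float:
    """Validation accuracy of the classifier fused with (normalized)
    raw_weights; invariant to positive rescaling of the raw vector."""
    w = normalize_weights(raw_weights)
    fused = fuse_probs(pool_probs, w)
    pred = np.argmax(fused, axis=1)
    return float(np.mean(pred == np.asarray(labels)))


def optimize_weights(pool_probs: np.ndarray, labels: np.ndarray,
                     cfg: SwarmConfig | None = None,
                     fitness_fn: Callable[[np.ndarray], float] | None = None,
                     dim: int = N_HEADS):
    """Full PSO loop; returns (FusionWeights | best position, trace).

    With the default fitness (validation accuracy of the fused classifier)
    the normalized global best is returned as FusionWeights.  Passing a
    custom `fitness_fn` (e.g. the sphere self-test) returns the raw best
    position instead.  trace is the per-iteration global-best fitness,
    nondecreasing by construction.
    """
    cfg = cfg or SwarmConfig()
    rng = np.random.default_rng(cfg.seed)
    if fitness_fn is None:
        if pool_probs is None or len(pool_probs) == 0:
            raise ValueError("need nonempty validation predictions")
        pool_probs = np.asarray(pool_probs, dtype=np.float64)
        labels = np.asarray(labels)
        fitness_fn = lambda x: fusion_fitness(x, pool_probs, labels)

    particles = []
    for _ in range(cfg.n_particles):
        x = rng.uniform(cfg.position_low, cfg.position_high, size=dim)
        particles.append(Particle(x=x, v=np.zeros(dim), x_best=x.copy()))

    g_best_x, g_best_f = None, -np.inf
    prev_fitness = None
    trace = []
    for it in range(cfg.n_iterations):
        fits = []
        for p in particles:
            p.fitness = fitness_fn(p.x)
            fits.append(p.fitness)
            if p.fitness > p.best_fitness:
                p.best_fitness = p.fitness
                p.x_best = p.x.copy()
            if p.fitness > g_best_f:
                g_best_f = p.fitness
                g_best_x = p.x.copy()
        ps = 1.0 if prev_fitness is None else improvement_fraction(fits, prev_fitness)
        omega = adaptive_inertia(ps, cfg.omega_max, cfg.omega_min)
        prev_fitness = fits
        for p in particles:
            r1, r2 = rng.random(), rng.random()
            p.v = velocity_update(p, g_best_x, omega, cfg, r1, r2)
            p.x = position_update(p, cfg)
        trace.append(g_best_f)

    if pool_probs is None:
        return g_best_x, np.asarray(trace)
    return FusionWeights(tuple(normalize_weights(g_best_x))), np.asarray(trace)


def final_predict(pool_probs: np.ndarray, weights: FusionWeights
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Fused probability vectors and argmax labels (ties -> lowest index).

    pool_probs: (n_samples, 5, C) or (5, C) for a single sample.
    """
    single = np.asarray(pool_probs).ndim == 2
    pp = np.asarray(pool_probs, np.float64)[None] if single else np.asarray(pool_probs, np.float64)
    fused = fuse_probs(pp, weights.as_array())
    labels = np.argmax(fused, axis=1)
    if single:
        return labels[0], fused[0]
    return labels, fused


def sphere_fitness(center: float = 0.3) -> Callable[[np.ndarray], float]:
    """Negated 5-D sphere benchmark with known optimum at (center, ...)."""
    def f(x: np.ndarray) -> float:
        return -float(np.sum((np.asarray(x) - center) ** 2))
    return f
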