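"""Binary Modified Ant Lion Optimizer (MALO).

The ant lion optimizer is a population metaheuristic that mimics ant lions
trapping randomly walking ants: ants perform ±1 random walks, ant lions hold
positions proportional to their fitness, and the walk radius shrinks over
iterations to shift the search from exploration to exploitation.  The
*modified* variant adds three ingredients suited to feature selection over
bit-masks:

* Levy-flight perturbation of walk positions (heavy-tailed jumps that escape
  local optima),
* a tanh transfer function mapping continuous positions to bits, and
* per-bit uniform crossover between a walk guided by a roulette-selected ant
  lion and a walk guided by the elite (best-so-far) ant lion.

All randomness flows through a single ``numpy.random.Generator`` seeded from
``MALOConfig.seed``, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MALOConfig",
    "MALOResult",
    "TrapBounds",
    "MALOError",
    "stochastic_step",
    "random_walk",
    "shrink_bounds",
    "normalize_walk",
    "levy_step",
    "binarize",
    "roulette_select",
    "crossover",
    "run_malo",
]

# Steps per generated random walk.  Each ant's continuous position, per
# dimension, is the endpoint of a fresh min-max-normalized ±1 walk of this
# length; longer walks only change the endpoint distribution marginally while
# costing proportionally more draws.
_WALK_STEPS = 16

# Roulette weight floor so the worst candidate stays selectable.
_ROULETTE_EPS = 1e-12


class MALOError(RuntimeError):
    """Raised when the optimizer encounters an invalid state (e.g. a fitness
    function returning a non-finite value)."""


@dataclass(frozen=True)
class MALOConfig:
    """Configuration of the binary MALO run.

    Parameters
    ----------
    n_ants:
        Population size (>= 2).
    n_dims:
        Length of the bit-mask being optimized.
    max_iters:
        Number of iterations K (>= 1).
    levy_alpha:
        Step-size multiplier of the Levy-flight perturbation; the reference
        setting is 1.
    levy_exponent:
        Stability exponent of the Levy step distribution, in (0, 2].
    crossover_rate:
        Per-bit probability of inheriting from the roulette-guided walk
        rather than the elite-guided walk.
    seed:
        Seed of the single random generator driving the run.
    walk_bounds:
        Per-dimension (lower, upper) base bounds of the normalized walk
        excursion around its guide; shrunk over iterations.  A single pair
        is broadcast to all dimensions.
    """

    n_ants: int
    n_dims: int
    max_iters: int
    levy_alpha: float = 1.0
    levy_exponent: float = 1.5
    crossover_rate: float = 0.5
    seed: int = 0
    walk_bounds: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_ants < 2:
            raise ValueError(f"n_ants must be >= 2, got {self.n_ants}")
        if self.n_dims < 1:
            raise ValueError(f"n_dims must be >= 1, got {self.n_dims}")
        if self.max_iters < 1:
            raise ValueError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.levy_alpha < 0:
            raise ValueError("levy_alpha must be nonnegative")
        if not (0.0 < self.levy_exponent <= 2.0):
            raise ValueError("levy_exponent must lie in (0, 2]")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("crossover_rate must lie in [0, 1]")
        lo, hi = self.walk_bounds
        if not (math.isfinite(lo) and math.isfinite(hi)) or not lo < hi:
            raise ValueError("walk_bounds must be finite with lower < upper")


@dataclass(frozen=True)
class TrapBounds:
    """Shrunken walk bounds at one iteration: ``r <= t`` elementwise, with
    shrink factor ``J >= 1`` and schedule exponent ``omega``."""

    r: np.ndarray
    t: np.ndarray
    shrink: float
    omega: int


@dataclass
class MALOResult:
    best_mask: np.ndarray
    best_fitness: float
    elite_history: np.ndarray
    evaluations: int


def stochastic_step(rdm: float) -> int:
    """Binary stochastic function of the ant walk: 1 iff ``rdm > 0.5``."""
    if not 0.0 <= rdm <= 1.0:
        raise ValueError(f"rdm must lie in [0, 1], got {rdm}")
    return 1 if rdm > 0.5 else 0


def random_walk(n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative ±1 random walk of ``n_steps`` steps, starting at 0.

    Step i is ``2*s(rdm_i) - 1`` where ``s`` is :func:`stochastic_step` on a
    uniform draw; the returned path has length ``n_steps + 1``.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rdm = rng.random(n_steps)
    steps = np.where(rdm > 0.5, 1.0, -1.0)
    path = np.empty(n_steps + 1)
    path[0] = 0.0
    np.cumsum(steps, out=path[1:])
    return path


def _omega(k: int, K: int) -> int:
    """Exploitation exponent from the iteration-fraction schedule; later
    thresholds take precedence."""
    frac = k / K
    if frac > 0.95:
        return 6
    if frac > 0.9:
        return 5
    if frac > 0.75:
        return 4
    if frac > 0.5:
        return 3
    if frac > 0.1:
        return 2
    # Pre-shrink regime: no radius reduction yet.
    return 1


def shrink_bounds(
    k: int,
    K: int,
    base_lower: float | np.ndarray,
    base_upper: float | np.ndarray,
) -> TrapBounds:
    """Reduce the walk radius at iteration ``k`` of ``K``.

    The shrink factor is J = 10^ω · k/K once k exceeds 0.1·K (with ω stepping
    through 2..6 as the run progresses) and J = 1 before that, so early
    iterations explore at full radius and late iterations collapse the trap
    around the guiding ant lion.
    """
    if not 1 <= k <= K:
        raise ValueError(f"iteration k={k} outside [1, {K}]")
    w = _omega(k, K)
    if k / K > 0.1:
        J = (10.0**w) * k / K
    else:
        J = 1.0
    lower = np.asarray(base_lower, dtype=float)
    upper = np.asarray(base_upper, dtype=float)
    return TrapBounds(r=lower / J, t=upper / J, shrink=J, omega=w)


def normalize_walk(
    walk: Sequence[float] | np.ndarray,
    r: float,
    t: float,
) -> np.ndarray:
    """Min–max normalize a walk so its own range [min, max] maps onto [r, t].

    A constant walk (zero range) maps to the midpoint (r + t) / 2.
    """
    w = np.asarray(walk, dtype=float)
    if w.size == 0:
        raise ValueError("walk must be nonempty")
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.full_like(w, (r + t) / 2.0)
    return (w - lo) / (hi - lo) * (t - r) + r


def _mantegna_sigma(lam: float) -> float:
    """Scale of the numerator Gaussian in Mantegna's Levy-stable sampler."""
    num = math.gamma(1.0 + lam) * math.sin(math.pi * lam / 2.0)
    den = math.gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0)
    return (num / den) ** (1.0 / lam)


def levy_step(
    position: np.ndarray,
    alpha: float,
    lam: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb ``position`` by an elementwise Levy-flight step of exponent
    ``lam`` (Mantegna construction), scaled by ``alpha``."""
    pos = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("position must be finite")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if not (0.0 < lam <= 2.0):
        raise ValueError("levy exponent must lie in (0, 2]")
    if alpha == 0.0:
        return pos.copy()
    sigma = _mantegna_sigma(lam)
    u = rng.normal(0.0, sigma, size=pos.shape)
    v = rng.normal(0.0, 1.0, size=pos.shape)
    step = u / np.abs(v) ** (1.0 / lam)
    return pos + alpha * step


def binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """tanh transfer function: bit_j = 1 iff rdm_j < |tanh(position_j)|."""
    pos = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("position must be finite")
    prob = np.abs(np.tanh(pos))
    return (rng.random(pos.shape) < prob).astype(np.int8)


def roulette_select(fitnesses: Sequence[float] | np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional selection for minimization.

    Weights are the max-shift transform ``(max_f - f_i) + eps`` renormalized
    to sum to 1: lower fitness gets strictly higher selection probability,
    and the worst candidate remains selectable through the eps floor.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("fitnesses must be nonempty")
    if not np.all(np.isfinite(f)):
        raise ValueError("fitnesses must be finite")
    w = (f.max() - f) + _ROULETTE_EPS
    w /= w.sum()
    return int(rng.choice(f.size, p=w))


def crossover(
    walk_a: np.ndarray,
    walk_b: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-bit uniform crossover: inherit from ``walk_a`` with probability
    ``rate``, else from ``walk_b``."""
    a = np.asarray(walk_a)
    b = np.asarray(walk_b)
    if a.shape != b.shape:
        raise ValueError(f"parent length mismatch: {a.shape} vs {b.shape}")
    take_a = rng.random(a.shape) < rate
    return np.where(take_a, a, b).astype(np.int8)


def _guided_positions(
    guide_bits: np.ndarray,
    bounds: TrapBounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous position around a binary guide: one normalized ±1 walk per
    dimension, its endpoint mapped into the shrunken bounds, offset by the
    guide's bits."""
    n_dims = guide_bits.size
    rdm = rng.random((_WALK_STEPS, n_dims))
    steps = np.where(rdm > 0.5, 1.0, -1.0)
    paths = np.vstack([np.zeros((1, n_dims)), np.cumsum(steps, axis=0)])
    lo = paths.min(axis=0)
    hi = paths.max(axis=0)
    span = hi - lo
    r = np.broadcast_to(bounds.r, (n_dims,))
    t = np.broadcast_to(bounds.t, (n_dims,))
    end = paths[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(
            span > 0,
            (end - lo) / np.where(span > 0, span, 1.0) * (t - r) + r,
            (r + t) / 2.0,
        )
    return guide_bits.astype(float) + scaled


def _evaluate(fitness: Callable[[np.ndarray], float], mask: np.ndarray) -> float:
    value = float(fitness(mask))
    if not math.isfinite(value):
        raise MALOError(f"fitness returned non-finite value {value} for mask {mask.tolist()}")
    return value


def run_malo(fitness: Callable[[np.ndarray], float], config: MALOConfig) -> MALOResult:
    """Run the binary MALO and return the best bit-mask found.

    Each iteration, every ant crosses over two binarized, Levy-perturbed
    walks — one trapped around a roulette-selected ant lion, one around the
    elite — inside bounds that shrink with the iteration count.  An ant lion
    is replaced by the ant at its index when the ant's fitness is strictly
    better; the elite is the best ant lion ever seen (incumbent retained on
    ties), so the elite fitness history is non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    n, d, K = config.n_ants, config.n_dims, config.max_iters

    antlions = (rng.random((n, d)) < 0.5).astype(np.int8)
    antlion_fit = np.array([_evaluate(fitness, antlions[i]) for i in range(n)])
    evaluations = n

    best_idx = int(np.argmin(antlion_fit))
    elite = antlions[best_idx].copy()
    elite_fit = float(antlion_fit[best_idx])

    elite_history = np.empty(K)
    base_lo, base_hi = config.walk_bounds

    for k in range(1, K + 1):
        bounds = shrink_bounds(k, K, base_lo, base_hi)
        # Levy step size lives on the current trap scale: full-strength
        # exploration early, vanishing perturbation as the bounds collapse.
        alpha_k = config.levy_alpha / bounds.shrink
        for i in range(n):
            j = roulette_select(antlion_fit, rng)
            pos_lion = _guided_positions(antlions[j], bounds, rng)
            pos_elite = _guided_positions(elite, bounds, rng)
            pos_lion = levy_step(pos_lion, alpha_k, config.levy_exponent, rng)
            pos_elite = levy_step(pos_elite, alpha_k, config.levy_exponent, rng)
            s_lion = binarize(pos_lion, rng)
            s_elite = binarize(pos_elite, rng)
            ant = crossover(s_lion, s_elite, config.crossover_rate, rng)
            ant_fit = _evaluate(fitness, ant)
            evaluations += 1
            # catch-and-rebuild: strict improvement replaces the ant lion
            if ant_fit < antlion_fit[i]:
                antlions[i] = ant
                antlion_fit[i] = ant_fit
        k_best = int(np.argmin(antlion_fit))
        if antlion_fit[k_best] < elite_fit:
            elite = antlions[k_best].copy()
            elite_fit = float(antlion_fit[k_best])
        elite_history[k - 1] = elite_fit

    return MALOResult(
        best_mask=elite,
        best_fitness=elite_fit,
        elite_history=elite_history,
        evaluations=evaluations,
    )
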