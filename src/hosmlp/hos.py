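"""Hypercube optimization search (HOS): a derivative-free population minimizer.

HOS searches a box-bounded continuous domain by repeatedly sampling a
population of points uniformly inside an axis-aligned hypercube, re-centering
the hypercube on the best point found so far, and contracting its per-dimension
half-size by a factor that depends on how far the best point moved between
iterations.  Small movements of the best point are read as evidence that the
search has localized a minimum, so the contraction is stronger; large
movements keep the hypercube wide.  The best point is additionally polished
each iteration by a greedy finite-difference local-search step.

The public entry point is :func:`hos_minimize`; the individual stages
(initialization, displacement-shrink, search-area update) are exposed as
small, independently testable functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "BoundsError",
    "DegenerateDimensionError",
    "DimensionError",
    "EvaluatedPopulation",
    "EvaluationError",
    "HOSConfig",
    "Hypercube",
    "OptimizationTrace",
    "evaluate_population",
    "hos_minimize",
    "init_hypercube",
    "local_search",
    "mean_point_fitness",
    "normalized_displacement",
    "rastrigin",
    "rosenbrock",
    "sample_population",
    "shrink_factor",
    "sphere",
    "trace_to_csv",
    "update_center",
    "update_hypercube",
    "TEST_OBJECTIVES",
]

Objective = Callable[[np.ndarray], float]


class DimensionError(ValueError):
    """Vector arguments disagree in length."""


class BoundsError(ValueError):
    """Lower bound exceeds upper bound in some coordinate."""


class EvaluationError(RuntimeError):
    """The objective returned a non-finite value.

    Attributes
    ----------
    row_index : int or None
        Index of the offending population row, when applicable.
    """

    def __init__(self, message: str, row_index: Optional[int] = None):
        super().__init__(message)
        self.row_index = row_index


class DegenerateDimensionError(ValueError):
    """A normalization interval is zero or negative in some coordinate."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Hypercube:
    """Axis-aligned search region: a center vector plus per-dimension half-size.

    The hypercube is always interpreted relative to the fixed global search
    box ``[global_lower, global_upper]``; sampled points are clamped into the
    global box, so the effective region is the intersection of the two.
    """

    center: np.ndarray
    half_size: np.ndarray
    global_lower: np.ndarray
    global_upper: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.half_size = np.atleast_1d(np.asarray(self.half_size, dtype=float))
        self.global_lower = np.atleast_1d(np.asarray(self.global_lower, dtype=float))
        self.global_upper = np.atleast_1d(np.asarray(self.global_upper, dtype=float))
        m = self.center.shape[0]
        for name in ("half_size", "global_lower", "global_upper"):
            if getattr(self, name).shape != (m,):
                raise DimensionError(
                    f"{name} has shape {getattr(self, name).shape}, expected ({m},)"
                )
        if np.any(self.half_size < 0):
            raise BoundsError("half_size must be elementwise nonnegative")
        if np.any(self.global_lower > self.global_upper):
            raise BoundsError("global_lower exceeds global_upper")
        lo = np.maximum(self.center - self.half_size, self.global_lower)
        hi = np.minimum(self.center + self.half_size, self.global_upper)
        if np.any(lo > hi):
            raise BoundsError("hypercube does not intersect the global bounds")

    @property
    def dimension(self) -> int:
        return self.center.shape[0]

    @property
    def lower(self) -> np.ndarray:
        """Lower corner of the hypercube clamped to the global box."""
        return np.maximum(self.center - self.half_size, self.global_lower)

    @property
    def upper(self) -> np.ndarray:
        """Upper corner of the hypercube clamped to the global box."""
        return np.minimum(self.center + self.half_size, self.global_upper)


@dataclass
class HOSConfig:
    """Tunable parameters of the HOS run.

    Defaults follow the standard benchmarking setup for this optimizer:
    population of 70 points, 250 iterations, fitness tolerance 1e-9 and
    half-size-norm tolerance 1e-1, local-search rate 0.5.
    """

    population_size: int = 70
    max_iterations: int = 250
    tol_fitness: float = 1e-9
    tol_x: float = 1e-1
    local_search_rate: float = 0.5
    seed: Optional[int] = None
    # step used by the finite-difference local search, as a fraction of the
    # current per-dimension half-size
    local_search_step_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tol_fitness < 0 or self.tol_x < 0:
            raise ValueError("tolerances must be nonnegative")
        if not 0.0 <= self.local_search_rate <= 1.0:
            raise ValueError("local_search_rate must lie in [0, 1]")


@dataclass
class EvaluatedPopulation:
    """A population of candidate points together with their fitness values."""

    points: np.ndarray
    fitness: np.ndarray
    best_index: int
    best_point: np.ndarray
    best_fitness: float


@dataclass
class OptimizationTrace:
    """Per-iteration diagnostics of a HOS run."""

    best_fitness_per_iteration: np.ndarray
    hypercube_half_size_norm_per_iteration: np.ndarray
    dnn_per_iteration: np.ndarray
    iterations_run: int
    termination_reason: str  # one of {"max_iterations", "tol_fitness", "tol_x"}
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# stage A: initialization
# ---------------------------------------------------------------------------


def init_hypercube(lower: Sequence[float], upper: Sequence[float]) -> Hypercube:
    """Build the initial hypercube spanning the global search box.

    The center is the box midpoint and the half-size is half the box width in
    each coordinate.
    """
    lo = np.atleast_1d(np.asarray(lower, dtype=float))
    hi = np.atleast_1d(np.asarray(upper, dtype=float))
    if lo.shape != hi.shape or lo.ndim != 1:
        raise DimensionError(
            f"lower and upper must be 1-D vectors of equal length, got shapes "
            f"{lo.shape} and {hi.shape}"
        )
    if np.any(lo > hi):
        bad = int(np.argmax(lo > hi))
        raise BoundsError(f"lower > upper at coordinate {bad}")
    center = (hi + lo) / 2.0
    half = np.abs(hi - lo) / 2.0
    return Hypercube(center=center, half_size=half, global_lower=lo, global_upper=hi)


def sample_population(
    hc: Hypercube, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points uniformly inside the hypercube, clamped to the global box.

    Returns the raw (n, m) point matrix; fitness is attached by
    :func:`evaluate_population`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = hc.center - hc.half_size
    hi = hc.center + hc.half_size
    pts = rng.uniform(size=(n, hc.dimension)) * (hi - lo) + lo
    np.clip(pts, hc.global_lower, hc.global_upper, out=pts)
    return pts


def evaluate_population(points: np.ndarray, objective: Objective) -> EvaluatedPopulation:
    """Evaluate the objective on every row and locate the best (minimum) one.

    Ties are broken by the lowest row index.  A non-finite objective value
    raises :class:`EvaluationError` carrying the offending row index.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    fitness = np.empty(pts.shape[0], dtype=float)
    for i, row in enumerate(pts):
        val = float(objective(row))
        if not math.isfinite(val):
            raise EvaluationError(
                f"objective returned non-finite value {val!r} at row {i}", row_index=i
            )
        fitness[i] = val
    best = int(np.argmin(fitness))  # argmin returns the first minimum: low index wins
    return EvaluatedPopulation(
        points=pts,
        fitness=fitness,
        best_index=best,
        best_point=pts[best].copy(),
        best_fitness=float(fitness[best]),
    )


def local_search(
    x_best: np.ndarray,
    objective: Objective,
    rate: float,
    step_scale: float,
    rng: Optional[np.random.Generator] = None,
    *,
    half_size: Optional[np.ndarray] = None,
    lower: Optional[np.ndarray] = None,
    upper: Optional[np.ndarray] = None,
    f_best: Optional[float] = None,
    n_backtracks: int = 10,
    n_rounds: int = 3,
) -> np.ndarray:
    """Greedy descent step on the incumbent best point.

    A one-sided finite-difference slope of the objective is estimated at
    ``x_best`` with per-coordinate probe steps ``step_scale * half_size``.
    A trial step of length ``rate * ||half_size||`` is taken against the
    normalized slope, halving the length until the objective improves
    (backtracking).  The one-sided slope carries an O(h) bias, so when an
    entire backtracking round fails the probe and trial steps are reduced
    tenfold and the slope re-estimated, up to ``n_rounds`` times; if nothing
    improves, ``x_best`` is returned unchanged.  The output therefore never
    has a worse objective value than the input.

    ``rate = 0`` disables the step entirely.  ``rng`` is accepted for
    interface uniformity with the sampling stage; this implementation is
    deterministic given its inputs.
    """
    x = np.atleast_1d(np.asarray(x_best, dtype=float)).copy()
    if rate == 0.0:
        return x
    if step_scale <= 0:
        raise ValueError("step_scale must be positive")
    if half_size is None:
        half_size = np.ones_like(x)
    half_size = np.asarray(half_size, dtype=float)
    if f_best is None:
        f_best = float(objective(x))

    base_h = np.where(half_size > 0, step_scale * half_size, 1e-12)
    base_t = rate * float(np.linalg.norm(half_size))
    if base_t <= 0:
        return x

    for round_ in range(n_rounds):
        shrink = 10.0**round_
        h = base_h / shrink

        grad = np.empty_like(x)
        for i in range(x.size):
            step = h[i]
            # probe backwards when a forward probe would leave the global box
            if upper is not None and x[i] + step > upper[i]:
                step = -step
            probe = x.copy()
            probe[i] += step
            grad[i] = (float(objective(probe)) - f_best) / step

        norm = float(np.linalg.norm(grad))
        if norm == 0.0 or not math.isfinite(norm):
            return x
        direction = -grad / norm

        t = base_t / shrink
        for _ in range(n_backtracks):
            cand = x + t * direction
            if lower is not None:
                np.clip(cand, lower, upper, out=cand)
            if float(objective(cand)) < f_best:
                return cand
            t /= 2.0
    return x


# ---------------------------------------------------------------------------
# stage B: displacement-shrink
# ---------------------------------------------------------------------------


def update_center(x_best_new: np.ndarray, old_center: np.ndarray) -> np.ndarray:
    """Midpoint of the new best point and the previous hypercube center."""
    a = np.atleast_1d(np.asarray(x_best_new, dtype=float))
    b = np.atleast_1d(np.asarray(old_center, dtype=float))
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


def mean_point_fitness(
    x_best: np.ndarray, last_center: np.ndarray, objective: Objective
) -> float:
    """Objective value at the midpoint of the best point and the last center."""
    return float(objective(update_center(x_best, last_center)))


def normalized_displacement(
    x_prev_best: np.ndarray,
    x_curr_best: np.ndarray,
    center: np.ndarray,
    interval: np.ndarray,
    m: int,
    displaced: bool,
) -> float:
    """Doubly normalized movement of the best point between iterations (d_nn).

    When ``displaced`` is False (no displacement occurred this iteration) the
    sentinel value 1 is returned, which leaves the hypercube size unchanged
    downstream.  Otherwise both best points are mapped to unit coordinates by
    subtracting the hypercube center and dividing elementwise by the
    per-dimension interval length; the Euclidean norm of their difference is
    then divided once more by the dimension ``m``.
    """
    if not displaced:
        return 1.0
    iv = np.atleast_1d(np.asarray(interval, dtype=float))
    if np.any(iv <= 0):
        bad = int(np.argmax(iv <= 0))
        raise DegenerateDimensionError(
            f"normalization interval is <= 0 at coordinate {bad}"
        )
    c = np.atleast_1d(np.asarray(center, dtype=float))
    x_n = (np.atleast_1d(np.asarray(x_prev_best, dtype=float)) - c) / iv
    x_min_n = (np.atleast_1d(np.asarray(x_curr_best, dtype=float)) - c) / iv
    d_n = float(np.linalg.norm(x_n - x_min_n))
    return d_n / float(m)


# ---------------------------------------------------------------------------
# stage C: search-area update
# ---------------------------------------------------------------------------


def shrink_factor(d_nn: float) -> float:
    """Contraction factor S = 1 - 0.2 * exp(-3 * d_nn), in [0.8, 1).

    Strictly increasing in the displacement: the smaller the movement of the
    best point, the stronger the contraction of the hypercube.
    """
    if d_nn < 0:
        raise ValueError("d_nn must be nonnegative")
    s = 1.0 - 0.2 * math.exp(-3.0 * d_nn)
    # the exponential underflows for large d_nn; keep the bound strict
    return min(s, math.nextafter(1.0, 0.0))


def update_hypercube(hc: Hypercube, x_best: np.ndarray, d_nn: float) -> Hypercube:
    """Re-center the hypercube on the best point and contract it.

    The half-size is multiplied by :func:`shrink_factor` when a genuine
    displacement was measured (``d_nn < 1``); the sentinel ``d_nn >= 1``
    leaves the size unchanged.  The half-size therefore never increases.
    """
    new_center = np.clip(
        np.atleast_1d(np.asarray(x_best, dtype=float)),
        hc.global_lower,
        hc.global_upper,
    )
    if d_nn < 1.0:
        new_half = hc.half_size * shrink_factor(d_nn)
    else:
        new_half = hc.half_size.copy()
    return Hypercube(
        center=new_center,
        half_size=new_half,
        global_lower=hc.global_lower,
        global_upper=hc.global_upper,
    )


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

_TOL_WINDOW = 10  # iterations over which the relative fitness improvement is measured


def hos_minimize(
    objective: Objective,
    lower: Sequence[float],
    upper: Sequence[float],
    config: Optional[HOSConfig] = None,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Minimize ``objective`` over the box ``[lower, upper]`` with HOS.

    Each iteration (i) samples a fresh population inside the current
    hypercube and keeps the best point ever evaluated, (ii) polishes the
    incumbent with a greedy local-search step, (iii) evaluates the midpoint
    between the incumbent and the previous center — if the midpoint beats
    the iteration's population best, a displacement is registered and its
    doubly normalized magnitude d_nn is computed, otherwise d_nn is set to
    the no-shrink sentinel 1 — and (iv) re-centers the hypercube on the
    incumbent, contracting it by S(d_nn) when a displacement occurred.

    Termination: iteration budget exhausted; relative best-fitness
    improvement over a 10-iteration window below ``tol_fitness``; or the
    Euclidean norm of the half-size vector below ``tol_x``.

    Returns the best point ever evaluated, its fitness, and the trace.
    """
    if config is None:
        config = HOSConfig()
    hc = init_hypercube(lower, upper)
    m = hc.dimension
    rng = np.random.default_rng(config.seed)
    # the "beginning interval" used to express displacements in unit coordinates;
    # degenerate (zero-width) dimensions cannot displace, so a unit placeholder
    # keeps the normalization well defined
    interval = hc.global_upper - hc.global_lower
    interval = np.where(interval > 0, interval, 1.0)

    best_x: Optional[np.ndarray] = None
    best_f = math.inf
    prev_best_x: Optional[np.ndarray] = None

    fit_hist: list[float] = []
    half_hist: list[float] = []
    dnn_hist: list[float] = []
    reason = "max_iterations"
    iterations = 0

    for _ in range(config.max_iterations):
        iterations += 1

        # stage A: sample + evaluate + local search
        pts = sample_population(hc, config.population_size, rng)
        pop = evaluate_population(pts, objective)
        if pop.best_fitness < best_f:
            best_f = pop.best_fitness
            best_x = pop.best_point.copy()
        assert best_x is not None
        improved = local_search(
            best_x,
            objective,
            config.local_search_rate,
            config.local_search_step_scale,
            rng,
            half_size=hc.half_size,
            lower=hc.global_lower,
            upper=hc.global_upper,
            f_best=best_f,
        )
        f_improved = float(objective(improved))
        if not math.isfinite(f_improved):
            raise EvaluationError("objective returned non-finite value in local search")
        if f_improved < best_f:
            best_f = f_improved
            best_x = improved

        # stage B: midpoint comparison and displacement normalization.
        # F_best in the comparison is the population best of THIS iteration:
        # the midpoint beating a fresh sample is the evidence that the region
        # between the incumbent and the old center is worth contracting into.
        midpoint = update_center(best_x, hc.center)
        f_mean = float(objective(midpoint))
        displaced = f_mean < pop.best_fitness
        if prev_best_x is None:
            prev_best_x = best_x.copy()
        d_nn = normalized_displacement(
            prev_best_x, best_x, hc.center, interval, m, displaced
        )
        if f_mean < best_f:  # the midpoint was evaluated: keep it if it is the best
            best_f = f_mean
            best_x = midpoint
        prev_best_x = best_x.copy()

        # stage C: re-center and contract
        hc = update_hypercube(hc, best_x, d_nn)

        fit_hist.append(best_f)
        half_hist.append(float(np.linalg.norm(hc.half_size)))
        dnn_hist.append(d_nn)

        if half_hist[-1] < config.tol_x:
            reason = "tol_x"
            break
        if len(fit_hist) > _TOL_WINDOW:
            prev = fit_hist[-_TOL_WINDOW - 1]
            rel_gain = (prev - fit_hist[-1]) / max(abs(prev), 1e-300)
            if rel_gain < config.tol_fitness:
                reason = "tol_fitness"
                break

    trace = OptimizationTrace(
        best_fitness_per_iteration=np.asarray(fit_hist),
        hypercube_half_size_norm_per_iteration=np.asarray(half_hist),
        dnn_per_iteration=np.asarray(dnn_hist),
        iterations_run=iterations,
        termination_reason=reason,
        seed=config.seed,
    )
    assert best_x is not None
    return best_x, best_f, trace


def trace_to_csv(trace: OptimizationTrace, path) -> None:
    """Write the per-iteration trace as delimited text."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "iteration": np.arange(trace.iterations_run),
            "best_fitness": trace.best_fitness_per_iteration,
            "half_size_norm": trace.hypercube_half_size_norm_per_iteration,
            "d_nn": trace.dnn_per_iteration,
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# built-in benchmark objectives
# ---------------------------------------------------------------------------


def sphere(x: np.ndarray) -> float:
    """Sum of squares; global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def rosenbrock(x: np.ndarray) -> float:
    """Banana-valley function; global minimum 0 at (1, ..., 1)."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def rastrigin(x: np.ndarray) -> float:
    """Highly multimodal separable function; global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


TEST_OBJECTIVES: dict[str, Objective] = {
    "sphere": sphere,
    "rosenbrock": rosenbrock,
    "rastrigin": rastrigin,
}
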