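"""Real-coded genetic algorithm over candidate movements.

The outer optimization step searches the 16-dimensional knot space (five
interior fingertip-x knots, five fingertip-y knots, six wrist knots — the
final wrist knot is free, so the final posture is selected by the search).
Endpoint knots are fixed by construction and never mutated.

Operators: tournament selection, BLX-alpha blend crossover, per-gene
Gaussian mutation with per-channel scales and optional geometric annealing,
elitism.  Reachability violations are handled by an additive penalty rather
than rejection so the population can skirt the workspace boundary.  The
search is repeated over independent restarts (three by default) and the best
restart wins; near-identical restart optima are a convergence diagnostic,
exposed by :func:`compare_restarts`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import arm_model as am
from . import objectives as obj
from .exceptions import ConvergenceError, InvalidArgumentError
from .muscle_model import MuscleSelection
from .trajectory import (
    Individual,
    MovementTask,
    individual_to_arm_trajectory,
    seed_individual,
)

__all__ = ["GAConfig", "OptimizationResult", "evaluate", "ga_optimize", "compare_restarts"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    ``mutation_scale`` is the per-channel Gaussian step (fingertip x m,
    fingertip y m, wrist rad); ``mutation_decay`` multiplies it each
    generation (1.0 = constant).  ``init_scale`` is the per-channel spread
    used to scatter the initial population around the straight-line seed.

    Besides independent per-gene mutation, whole channels receive *smooth*
    mutations — a random ramp-plus-bump profile added across a channel's
    knots with probability ``smooth_mutation_rate`` and coefficient spread
    ``smooth_mutation_scale``.  Independent knot noise produces wiggly,
    expensive candidates that selection removes before coordinated
    low-frequency moves (a net wrist rotation, a lateral path bow) can be
    discovered; the smooth moves explore those modes directly and
    symmetrically.  The same profiles (with the same spread) are mixed into
    the initial population.
    """

    population_size: int = 200
    generations: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    mutation_scale: tuple = (0.005, 0.005, 0.05)
    mutation_decay: float = 1.0
    elite_count: int = 2
    tournament_size: int = 3
    restarts: int = 3
    seed: int = 0
    penalty_weight: float = 1e6
    blx_alpha: float = 0.5
    init_scale: tuple = (0.01, 0.01, 0.1)
    smooth_mutation_rate: float = 0.25
    smooth_mutation_scale: tuple = (0.01, 0.01, 0.15)
    lock_wrist: bool = False

    def __post_init__(self):
        if self.population_size < 4:
            raise InvalidArgumentError("population_size must be >= 4")
        if self.restarts < 1:
            raise InvalidArgumentError("restarts must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1]")
        if self.elite_count < 0 or self.elite_count >= self.population_size:
            raise InvalidArgumentError("elite_count must be in [0, population_size)")
        if self.generations < 1:
            raise InvalidArgumentError("generations must be >= 1")


@dataclass
class OptimizationResult:
    best: Individual
    best_cost: obj.CostBreakdown
    history: list                      # per restart: list of per-generation dicts
    per_restart_bests: list            # (Individual, CostBreakdown) per restart
    model: str = ""
    task: MovementTask | None = None


# genome layout: 5 interior x knots, 5 interior y knots, 6 free wrist knots
_N_GENES = 16


def _genome_channels(lock_wrist: bool) -> np.ndarray:
    ch = np.array([0] * 5 + [1] * 5 + [2] * 6)
    return ch if not lock_wrist else ch[:10]


def _to_genome(ind: Individual, lock_wrist: bool) -> np.ndarray:
    parts = [ind.x_knots[1:6], ind.y_knots[1:6]]
    if not lock_wrist:
        parts.append(ind.wrist_knots[1:7])
    return np.concatenate(parts)


def _from_genome(g: np.ndarray, task: MovementTask, lock_wrist: bool) -> Individual:
    wrist = np.full(7, task.initial_wrist)
    if not lock_wrist:
        wrist[1:7] = g[10:16]
    return Individual(
        x_knots=np.concatenate([[task.start[0]], g[0:5], [task.target[0]]]),
        y_knots=np.concatenate([[task.start[1]], g[5:10], [task.target[1]]]),
        wrist_knots=wrist,
    )


def evaluate(
    ind: Individual,
    task: MovementTask,
    arm: am.ArmParameters,
    sel: MuscleSelection | None,
    cond: am.ViscosityCondition | None,
    model: str,
    dt: float | None = None,
    ends: str = "clamped",
    branch: str = "elbow-cw",
    penalty_weight: float = 1e6,
) -> obj.CostBreakdown:
    """Cost of one candidate under a given model.

    Builds the dense trajectory, resolves viscosity and attaches torques when
    the model needs them (TC, MSC), and dispatches to the model's cost.
    Reachability violations do not raise: they contribute
    ``penalty_weight × mean annulus excess`` so the optimizer sees a finite,
    strictly worse cost.  Deterministic: same inputs, same cost, bit for bit.
    """
    if model not in ("HJ", "AJ", "TC", "MSC"):
        raise InvalidArgumentError(f"model must be one of HJ/AJ/TC/MSC, got {model!r}")
    needs_torque = model in ("TC", "MSC")
    if needs_torque and cond is None:
        raise InvalidArgumentError(f"model {model} requires a viscosity condition")
    if model == "MSC" and sel is None:
        raise InvalidArgumentError("model MSC requires a muscle selection")

    try:
        built = individual_to_arm_trajectory(
            ind, task, arm, dt=dt, cond=cond if needs_torque else None,
            branch=branch, ends=ends, penalty_mode=True)
    except ConvergenceError as exc:
        # the torque-dependent viscosity fixed point is contractive only for
        # physically plausible speeds; candidates wild enough to break it are
        # penalized out rather than crashing the search
        residual = exc.residual if exc.residual is not None else 1.0
        return obj.CostBreakdown(
            model=model, value=penalty_weight * (1.0 + residual),
            per_channel=np.zeros(8 if model == "MSC" else 3), feasible=False,
            penalty=penalty_weight * (1.0 + residual))

    if model == "HJ":
        value, per_channel = obj.cost_hj(built.fingertip, built.traj.dt,
                                         jerk=built.fingertip_jerk)
    elif model == "AJ":
        value, per_channel = obj.cost_aj(built.traj)
    elif model == "TC":
        value, per_channel = obj.cost_tc(built.traj)
    else:
        value, per_channel = obj.cost_msc(built.traj, sel)

    penalty = penalty_weight * built.violation
    return obj.CostBreakdown(
        model=model, value=value + penalty, per_channel=per_channel,
        feasible=built.violation == 0.0, penalty=penalty,
        extras={"built": built})


def _check_endpoints(task: MovementTask, arm: am.ArmParameters):
    lower, upper, _, _ = am.reachable_bounds(task.initial_wrist, arm)
    d0 = float(np.linalg.norm(task.start))
    if not lower <= d0 <= upper:
        raise InvalidArgumentError(
            f"task start at distance {d0:.3f} m unreachable with the initial "
            f"wrist angle (annulus [{lower:.3f}, {upper:.3f}] m)")
    # the final wrist angle is free: the target only needs to fall inside the
    # union of annuli over a plausible wrist range
    th3 = np.linspace(-np.pi / 2, np.pi / 2, 91)
    lo, up, _, _ = am.reachable_bounds(th3, arm)
    d1 = float(np.linalg.norm(task.target))
    if not np.any((lo <= d1) & (d1 <= up)):
        raise InvalidArgumentError(
            f"task target at distance {d1:.3f} m unreachable for any wrist angle")


def ga_optimize(
    task: MovementTask,
    arm: am.ArmParameters,
    sel: MuscleSelection | None,
    cond: am.ViscosityCondition | None,
    model: str,
    config: GAConfig = GAConfig(),
    dt: float | None = None,
    ends: str = "clamped",
    branch: str = "elbow-cw",
    progress=None,
) -> OptimizationResult:
    """Search for the model-optimal movement with a real-coded GA.

    Runs ``config.restarts`` independent, separately seeded searches and
    returns the best.  ``progress``, if given, is called per generation with
    ``(restart, generation, best_cost, mean_cost, feasible_fraction)``.
    """
    _check_endpoints(task, arm)
    lock = config.lock_wrist
    n_genes = 10 if lock else _N_GENES
    channels = _genome_channels(lock)
    mut_scale = np.asarray(config.mutation_scale, dtype=float)[channels]
    init_scale = np.asarray(config.init_scale, dtype=float)[channels]
    seed_g = _to_genome(seed_individual(task), lock)

    # per-channel smooth profiles: gene indices, normalized knot times and
    # the ramp/sin shapes evaluated there
    smooth_scale = np.asarray(config.smooth_mutation_scale, dtype=float)
    channel_profiles = []
    for c in range(3 if not lock else 2):
        idx = np.flatnonzero(channels == c)
        s_knots = (np.arange(idx.size) + 1) / 6.0
        channel_profiles.append(
            (idx, np.stack([s_knots, np.sin(np.pi * s_knots)]), smooth_scale[c]))

    def smooth_noise(rng, count, anneal=1.0):
        """(count, n_genes) array of random ramp+bump channel profiles."""
        out = np.zeros((count, n_genes))
        for idx, shapes, scale in channel_profiles:
            coeff = rng.normal(0.0, scale * anneal, size=(count, 2))
            out[:, idx] = coeff @ shapes
        return out

    def cost_of(genome):
        ind = _from_genome(genome, task, lock)
        return evaluate(ind, task, arm, sel, cond, model, dt=dt, ends=ends,
                        branch=branch, penalty_weight=config.penalty_weight)

    history_all, restart_bests = [], []
    for restart in range(config.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, restart]))
        pop = seed_g + rng.normal(0.0, init_scale,
                                  size=(config.population_size, n_genes))
        pop += smooth_noise(rng, config.population_size)
        pop[0] = seed_g  # keep the unperturbed seed in the gene pool
        costs_full = [cost_of(g) for g in pop]
        costs = np.array([c.value for c in costs_full])
        history = []
        scale = mut_scale.copy()

        for gen in range(config.generations):
            order = np.argsort(costs, kind="stable")
            elite = pop[order[: config.elite_count]]
            elite_costs_full = [costs_full[i] for i in order[: config.elite_count]]
            elite_costs = costs[order[: config.elite_count]]

            n_children = config.population_size - config.elite_count
            # tournament selection of two parent pools
            picks = rng.integers(0, config.population_size,
                                 size=(2, n_children, config.tournament_size))
            parents = pop[np.take_along_axis(
                picks, np.argmin(costs[picks], axis=2)[..., None], axis=2)[..., 0]]
            p1, p2 = parents[0], parents[1]

            # BLX-alpha blend crossover (per gene), else clone parent 1
            lo = np.minimum(p1, p2)
            hi = np.maximum(p1, p2)
            span = hi - lo
            blend = rng.uniform(lo - config.blx_alpha * span,
                                hi + config.blx_alpha * span)
            do_cross = rng.random(n_children) < config.crossover_rate
            children = np.where(do_cross[:, None], blend, p1)

            # Gaussian mutation with per-channel scale
            mask = rng.random(children.shape) < config.mutation_rate
            children = children + mask * rng.normal(0.0, 1.0, children.shape) * scale
            # smooth whole-channel mutation (annealed with the same decay)
            if config.smooth_mutation_rate > 0.0:
                anneal = scale[0] / mut_scale[0]
                smooth = smooth_noise(rng, n_children, anneal=anneal)
                smask = rng.random(n_children) < config.smooth_mutation_rate
                children = children + smask[:, None] * smooth
            scale = scale * config.mutation_decay

            child_costs_full = [cost_of(g) for g in children]
            pop = np.vstack([elite, children])
            costs_full = elite_costs_full + child_costs_full
            costs = np.concatenate([elite_costs,
                                    [c.value for c in child_costs_full]])

            i_best = int(np.argmin(costs))
            feas = np.mean([c.feasible for c in costs_full])
            history.append({
                "generation": gen, "best": float(costs[i_best]),
                "mean": float(np.mean(costs)), "feasible_fraction": float(feas),
            })
            if progress is not None:
                progress(restart, gen, float(costs[i_best]),
                         float(np.mean(costs)), float(feas))

        i_best = int(np.argmin(costs))
        restart_bests.append((_from_genome(pop[i_best], task, lock),
                              costs_full[i_best]))
        history_all.append(history)

    winner = int(np.argmin([c.value for _, c in restart_bests]))
    best, best_cost = restart_bests[winner]
    return OptimizationResult(best=best, best_cost=best_cost, history=history_all,
                              per_restart_bests=restart_bests, model=model, task=task)


def compare_restarts(
    result: OptimizationResult,
    task: MovementTask,
    arm: am.ArmParameters,
    dt: float | None = None,
    ends: str = "clamped",
    branch: str = "elbow-cw",
) -> float:
    """Maximum pairwise fingertip-path RMS distance between restart bests (m).

    Small values indicate the restarts found (nearly) the same optimum; the
    metric is reported regardless of its size, as a convergence diagnostic.
    """
    if len(result.per_restart_bests) < 2:
        raise InvalidArgumentError("need at least 2 restarts to compare")
    paths = []
    for ind, _ in result.per_restart_bests:
        built = individual_to_arm_trajectory(ind, task, arm, dt=dt, ends=ends,
                                             branch=branch, penalty_mode=True)
        paths.append(built.fingertip)
    worst = 0.0
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            rms = float(np.sqrt(np.mean(np.sum((paths[i] - paths[j]) ** 2, axis=1))))
            worst = max(worst, rms)
    return worst
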