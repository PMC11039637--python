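"""Sparrow search algorithm (SpaSA) over bounded real vectors.

The population plays three roles each iteration:

* **producers** — the best ``producer_fraction`` of the flock.  When the
  random alarm value is below the safety threshold a producer contracts its
  position multiplicatively (``x * exp(-i / (alpha * T))``, ``alpha ~ U(0,1]``);
  otherwise it takes a Gaussian step.
* **scroungers** — the rest follow the best-known food source:
  ``x <- x_p + |x - x_p| * D`` with ``D`` a random sign vector scaled by
  ``1/2``, so a flock sitting on a single point stays put while the spread
  of a dispersed flock halves each iteration.
* **scouts** — a random ``scout_fraction`` reacts to danger: birds worse
  than the global best jump toward it with a Gaussian factor; the best bird
  itself takes a bounded random step away from the worst position.

Positions are clipped to the search-space bounds after every move and the
best-ever (elitist) record never decreases.  Fitness is maximised; the
architecture objective is the smoothed-Jaccard fitness summed over
evaluation images.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence

import numpy as np

from .exceptions import ValidationError
from .fcedn import (FCEDN, HyperparameterVector, SearchSpace, TrainConfig,
                    VectorLayout, decode)
from .image import LabeledImage

__all__ = [
    "OptimizerConfig", "Population", "FitnessContext", "initialize_population",
    "evaluate_fitness", "producer_update", "scrounger_update", "scout_update",
    "optimize", "SparrowSearch", "SearchResults", "ArchitectureObjective",
]


@dataclass(frozen=True)
class OptimizerConfig:
    population_size: int = 10
    iterations: int = 10
    producer_fraction: float = 0.2
    scout_fraction: float = 0.1
    safety_threshold: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 4:
            raise ValidationError(f"population_size must be >= 4, got {self.population_size}")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not 0.0 < self.producer_fraction < 1.0:
            raise ValidationError("producer_fraction must be in (0,1)")
        if not 0.0 <= self.scout_fraction < 1.0:
            raise ValidationError("scout_fraction must be in [0,1)")
        if not 0.5 <= self.safety_threshold <= 1.0:
            raise ValidationError("safety_threshold must be in [0.5,1]")


@dataclass
class Population:
    positions: np.ndarray            # (n, k)
    fitnesses: np.ndarray            # (n,)
    best_position: np.ndarray        # elitist record
    best_fitness: float
    iteration: int = 0

    @property
    def size(self) -> int:
        return int(self.positions.shape[0])

    def record_best(self) -> None:
        i = int(np.argmax(self.fitnesses))
        if self.fitnesses[i] > self.best_fitness:
            self.best_fitness = float(self.fitnesses[i])
            self.best_position = self.positions[i].copy()


@dataclass
class FitnessContext:
    """Everything :func:`evaluate_fitness` needs: data, training config and
    the smoothing parameter of the Jaccard fitness."""

    train_images: Sequence[LabeledImage]
    eval_images: Sequence[LabeledImage]
    train_cfg: TrainConfig = TrainConfig(epochs=5)
    epsilon: float = 1.0
    layout: Optional[VectorLayout] = None
    space: Optional[SearchSpace] = None
    input_channels: int = 3

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError(f"epsilon must be > 0, got {self.epsilon}")


def initialize_population(space: SearchSpace, cfg: OptimizerConfig,
                          rng: Optional[np.random.Generator] = None) -> Population:
    """Uniform random positions within bounds (unevaluated: fitness -inf)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pos = space.sample(cfg.population_size, rng)
    return Population(
        positions=pos,
        fitnesses=np.full(cfg.population_size, -np.inf),
        best_position=pos[0].copy(),
        best_fitness=-np.inf,
    )


def evaluate_fitness(position: HyperparameterVector | np.ndarray,
                     ctx: FitnessContext) -> float:
    """Decode -> build -> train -> smoothed-Jaccard fitness summed over the
    evaluation images:

    ``f(x) = sum_m (eps + |P_m & T_m|) / (eps + |T_m| + |P_m| - |P_m & T_m|)``

    so a perfect predictor scores the number of evaluation images and an
    all-background predictor scores ~0 for small ``eps``.
    """
    from .fcedn import default_layout  # local import avoids cycle at module load
    layout = ctx.layout or default_layout()
    space = ctx.space or SearchSpace.from_layout(layout)
    first = ctx.train_images[0]
    spec = decode(position, space, layout, input_height=first.height,
                  input_width=first.width, input_channels=ctx.input_channels)
    model = FCEDN(spec, seed=ctx.train_cfg.seed)
    model.fit(ctx.train_images, ctx.train_cfg)
    total = 0.0
    for img in ctx.eval_images:
        pred = model.predict_mask(img)
        inter = float(np.sum((pred == 1) & (img.mask == 1)))
        den = ctx.epsilon + float(img.mask.sum()) + float(pred.sum()) - inter
        total += (ctx.epsilon + inter) / den
    return total


class ArchitectureObjective:
    """Callable objective with a cache keyed by the rounded/clipped genome.

    Build failures (e.g. pool products that do not divide the input) score
    ``-inf`` so the flock simply routes around infeasible corners of the
    integer lattice.
    """

    def __init__(self, ctx: FitnessContext, space: SearchSpace,
                 layout: VectorLayout) -> None:
        self.ctx = replace(ctx, layout=layout, space=space)
        self.space = space
        self.layout = layout
        self.cache: dict[tuple, float] = {}
        self.n_trained = 0

    def __call__(self, position: np.ndarray) -> float:
        key = tuple(self.space.round_clip(np.asarray(position)))
        if key in self.cache:
            return self.cache[key]
        try:
            value = evaluate_fitness(np.asarray(key), self.ctx)
            self.n_trained += 1
        except ValidationError:
            value = -np.inf
        self.cache[key] = value
        return value


def _sorted_indices(pop: Population) -> np.ndarray:
    return np.argsort(-pop.fitnesses, kind="stable")


def _n_producers(cfg: OptimizerConfig, n: int) -> int:
    return max(1, int(np.ceil(cfg.producer_fraction * n)))


def producer_update(pop: Population, cfg: OptimizerConfig, rng: np.random.Generator,
                    space: SearchSpace, total_iterations: Optional[int] = None) -> Population:
    """Move the top ``producer_fraction`` sparrows (exponential contraction
    under a quiet alarm, Gaussian step otherwise)."""
    order = _sorted_indices(pop)
    T = total_iterations or max(cfg.iterations, 1)
    for rank, idx in enumerate(order[:_n_producers(cfg, pop.size)], start=1):
        if rng.random() < cfg.safety_threshold:
            alpha = rng.random() or 1e-12
            pop.positions[idx] = pop.positions[idx] * np.exp(-rank / (alpha * T))
        else:
            pop.positions[idx] = pop.positions[idx] + rng.standard_normal(
                pop.positions.shape[1])
    pop.positions = space.clip(pop.positions)
    return pop


def scrounger_update(pop: Population, cfg: OptimizerConfig, rng: np.random.Generator,
                     space: SearchSpace) -> Population:
    """Non-producers follow the best producer: ``x <- x_p + |x - x_p| * D``
    with ``D`` random signs scaled by ``1/2`` (zero displacement when the
    flock has collapsed onto one point)."""
    order = _sorted_indices(pop)
    n_prod = _n_producers(cfg, pop.size)
    # the producer position worth following is the best-known food source
    # (elitist record); following the just-moved top producer would let the
    # whole flock drift with it
    xp = (pop.best_position.copy() if np.isfinite(pop.best_fitness)
          else pop.positions[order[0]].copy())
    k = pop.positions.shape[1]
    # halving reflection: each scrounger lands half its gap away from the
    # best position with random per-gene signs, so the flock's spread
    # contracts geometrically while still probing both sides of the optimum
    for idx in order[n_prod:]:
        signs = rng.choice((-1.0, 1.0), size=k)
        pop.positions[idx] = xp + np.abs(pop.positions[idx] - xp) * signs / 2.0
    pop.positions = space.clip(pop.positions)
    return pop


def scout_update(pop: Population, cfg: OptimizerConfig, rng: np.random.Generator,
                 space: SearchSpace) -> Population:
    """A random ``scout_fraction`` of the flock reacts to danger.

    Birds worse than the best-known position jump toward it with per-gene
    Gaussian factors.  The jump scale never falls below a range-proportional
    floor that decays over the run (1% of the gene range early, 0.1% late),
    so the flock keeps probing the neighbourhood of the optimum even after
    it has collapsed onto it instead of stalling at the first consensus.
    """
    n_scouts = int(round(cfg.scout_fraction * pop.size))
    if n_scouts == 0:
        return pop
    span = space.upper - space.lower
    progress = min(pop.iteration / max(cfg.iterations, 1), 1.0)
    floor = span * (0.01 * (1.0 - progress) + 0.001)
    worst = int(np.argmin(pop.fitnesses))
    chosen = rng.choice(pop.size, size=n_scouts, replace=False)
    for idx in chosen:
        if pop.fitnesses[idx] < pop.best_fitness:
            k = pop.positions.shape[1]
            beta = rng.standard_normal(k)
            # sparse probing: only a few genes move per scout, so late-stage
            # refinements of one gene do not disturb the already-correct ones
            active = rng.random(k) < max(3.0 / k, 1.0 / k)
            if not active.any():
                active[rng.integers(k)] = True
            scale = np.maximum(np.abs(pop.positions[idx] - pop.best_position), floor)
            pop.positions[idx] = pop.best_position + beta * scale * active
        else:
            K = rng.uniform(-1.0, 1.0)
            gap = pop.fitnesses[idx] - pop.fitnesses[worst] + 1e-50
            pop.positions[idx] = pop.positions[idx] + K * (
                np.abs(pop.positions[idx] - pop.positions[worst]) / gap)
    pop.positions = space.clip(pop.positions)
    return pop


def _evaluate_all(pop: Population, objective: Callable[[np.ndarray], float]) -> None:
    for i in range(pop.size):
        value = objective(pop.positions[i])
        pop.fitnesses[i] = value if np.isfinite(value) else -np.inf
    pop.record_best()


def optimize(space: SearchSpace, objective: Callable[[np.ndarray], float],
             cfg: OptimizerConfig) -> tuple[np.ndarray, float, List[float]]:
    """Run initialise -> [producer, scrounger, scout, evaluate] x iterations.

    Returns ``(best_position, best_fitness, per-iteration elitist trace)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pop = initialize_population(space, cfg, rng)
    _evaluate_all(pop, objective)
    trace: List[float] = [pop.best_fitness]
    for it in range(cfg.iterations):
        pop.iteration = it + 1
        producer_update(pop, cfg, rng, space, total_iterations=cfg.iterations)
        scrounger_update(pop, cfg, rng, space)
        scout_update(pop, cfg, rng, space)
        _evaluate_all(pop, objective)
        trace.append(pop.best_fitness)
    return pop.best_position.copy(), pop.best_fitness, trace


@dataclass
class SearchResults:
    best_position: np.ndarray
    best_fitness: float
    trace: List[float]
    config: OptimizerConfig
    space: SearchSpace

    def summary(self) -> str:
        lines = [
            "Sparrow search results",
            "======================",
            f"population:   {self.config.population_size}",
            f"iterations:   {self.config.iterations}",
            f"best fitness: {self.best_fitness:.6g}",
            f"trace:        {self.trace[0]:.4g} -> {self.trace[-1]:.4g}",
        ]
        return "\n".join(lines)

    def best_genome(self) -> np.ndarray:
        return self.space.round_clip(self.best_position)


class SparrowSearch:
    """Model-style facade: ``SparrowSearch(space, objective, cfg).fit()``."""

    def __init__(self, space: SearchSpace, objective: Callable[[np.ndarray], float],
                 cfg: OptimizerConfig = OptimizerConfig()) -> None:
        self.space = space
        self.objective = objective
        self.cfg = cfg

    def fit(self) -> SearchResults:
        best, fitness, trace = optimize(self.space, self.objective, self.cfg)
        return SearchResults(best_position=best, best_fitness=fitness,
                             trace=trace, config=self.cfg, space=self.space)
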