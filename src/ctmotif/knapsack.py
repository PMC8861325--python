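"""0/1 knapsack selection of response motifs from significant modules.

Each significant module becomes a knapsack item: maximise the total value
``V = sum v_i x_i`` subject to ``W = sum w_i x_i <= C`` with binary ``x_i``.
The production solver is a genetic algorithm (roulette selection, two-point
crossover, per-bit mutation, elitism); an exact solver ships as the test
oracle.

Item values/weights are configurable: by default a module's value is the
number of its targets annotated in the disease table and its weight is its
node count; the capacity is a fraction of the total weight.  All choices are
recorded in the instance's provenance block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DiseaseGeneTable
from .mapeq import SDFM

VALUE_STRATEGIES = ("disease_count", "relevance_sum")


@dataclass(frozen=True)
class KnapsackInstance:
    items: tuple  # of (module_id, value, weight)
    capacity: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("instance needs >= 1 item")
        for mid, v, w in self.items:
            if v < 0:
                raise ValueError(f"item {mid}: value must be >= 0, got {v}")
            if not w > 0:
                raise ValueError(f"item {mid}: weight must be > 0, got {w}")
        if not self.capacity > 0:
            raise ValueError(f"capacity must be > 0, got {self.capacity}")

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v, _ in self.items], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.items], dtype=float)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 200
    crossover_prob: float = 0.8
    mutation_prob: float | None = None  # default 1/n per bit
    elitism: int = 1
    stagnation: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2 != 0:
            raise ValueError("population_size must be even and >= 2")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob outside [0, 1]")
        if self.mutation_prob is not None and not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob outside [0, 1]")
        if self.elitism < 0:
            raise ValueError("elitism must be >= 0")


@dataclass(frozen=True)
class KnapsackSolution:
    x: tuple  # binary selection vector
    V: float
    W: float
    history: tuple = ()  # best value per generation (GA only)

    @classmethod
    def from_vector(cls, inst: KnapsackInstance, x, history=()) -> "KnapsackSolution":
        x = tuple(int(b) for b in x)
        if len(x) != inst.n or any(b not in (0, 1) for b in x):
            raise ValueError("selection vector must be binary of length n")
        V = float(np.dot(inst.values, x))
        W = float(np.dot(inst.weights, x))
        if W > inst.capacity + 1e-9:
            raise ValueError(f"infeasible solution: W={W} > C={inst.capacity}")
        return cls(x=x, V=V, W=W, history=tuple(history))


# ---------------------------------------------------------------------------
# Instance construction
# ---------------------------------------------------------------------------


def build_instance(sdfms, disease: DiseaseGeneTable,
                   strategy: str = "disease_count",
                   capacity_frac: float = 0.5) -> KnapsackInstance:
    """Turn significant modules into a knapsack instance.

    value strategies:
      * ``disease_count`` — number of module targets present in the disease table
      * ``relevance_sum`` — summed relevance score of module targets

    weight = module node count; capacity = ``capacity_frac`` x total weight.
    """
    sdfms = list(sdfms)
    if not sdfms:
        raise ValueError("no modules to build an instance from")
    if not 0.0 < capacity_frac <= 1.0:
        raise ValueError(f"capacity_frac must be in (0, 1], got {capacity_frac}")
    if strategy not in VALUE_STRATEGIES:
        raise ValueError(f"unknown value strategy {strategy!r}")
    if len(disease) == 0:
        raise ValueError(f"value strategy {strategy!r} requires a non-empty disease table")
    relevance = disease.relevance()
    items = []
    for s in sdfms:
        annotated = s.targets & disease.genes
        if strategy == "disease_count":
            v = float(len(annotated))
        else:
            v = float(sum(relevance[g] for g in annotated))
        items.append((s.module_id, v, float(len(s.members))))
    total_w = sum(w for _, _, w in items)
    return KnapsackInstance(
        items=tuple(items),
        capacity=capacity_frac * total_w,
        provenance={
            "value_strategy": strategy,
            "weight": "module node count",
            "capacity_frac": capacity_frac,
            "capacity": capacity_frac * total_w,
            "n_items": len(items),
        },
    )


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------


def solve_exact(inst: KnapsackInstance) -> KnapsackSolution:
    """Provably optimal solution for small / integer-weight instances.

    Integer weights use classic DP over the capacity; fractional weights use
    Pareto-front enumeration and are refused above n = 25.
    """
    w = inst.weights
    v = inst.values
    n = inst.n
    integral = np.all(np.abs(w - np.round(w)) < 1e-9)
    if not integral and n > 25:
        raise ValueError("exact solver refuses n > 25 with non-integral weights")
    if integral:
        wi = np.round(w).astype(int)
        C = int(np.floor(inst.capacity + 1e-9))
        best = np.zeros(C + 1)
        choice = np.zeros((n, C + 1), dtype=bool)
        for i in range(n):
            if wi[i] <= C:
                cand = np.concatenate([np.zeros(wi[i]), best[: C + 1 - wi[i]] + v[i]])
                take = cand > best + 1e-12
                choice[i] = take
                best = np.where(take, cand, best)
        x = [0] * n
        c = int(np.argmax(best))
        for i in range(n - 1, -1, -1):
            if choice[i, c]:
                x[i] = 1
                c -= wi[i]
        return KnapsackSolution.from_vector(inst, x)
    # Pareto-front sweep: states are (weight, value, bitmask), dominated pruned
    states = [(0.0, 0.0, 0)]
    for i in range(n):
        extended = [
            (sw + w[i], sv + v[i], mask | (1 << i))
            for sw, sv, mask in states
            if sw + w[i] <= inst.capacity + 1e-12
        ]
        merged = sorted(states + extended)
        states = []
        best_v = -1.0
        for sw, sv, mask in merged:
            if sv > best_v + 1e-15:
                states.append((sw, sv, mask))
                best_v = sv
    _, _, mask = max(states, key=lambda s: s[1])
    x = [(mask >> i) & 1 for i in range(n)]
    return KnapsackSolution.from_vector(inst, x)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def _repair(pop: np.ndarray, inst: KnapsackInstance, rng: np.random.Generator) -> int:
    """Remove random selected items from infeasible rows until feasible.

    Returns the number of repaired individuals.
    """
    w = inst.weights
    repaired = 0
    W = pop @ w
    for r in np.nonzero(W > inst.capacity + 1e-12)[0]:
        repaired += 1
        while W[r] > inst.capacity + 1e-12:
            sel = np.nonzero(pop[r])[0]
            drop = sel[rng.integers(0, len(sel))]
            pop[r, drop] = 0
            W[r] -= w[drop]
    return repaired


def solve_ga(inst: KnapsackInstance, cfg: GAConfig | None = None) -> KnapsackSolution:
    """Genetic-algorithm solver; deterministic for a fixed config seed.

    Infeasible offspring are repaired by random removal (keeps roulette
    fitness non-negative); the best-ever individual is tracked and returned,
    so the per-generation best in ``history`` is non-decreasing.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    n = inst.n
    v = inst.values
    mut_p = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / n
    pop = rng.integers(0, 2, size=(cfg.population_size, n)).astype(np.int8)
    _repair(pop, inst, rng)
    best_x, best_V = None, -1.0
    history = []
    stagnant = 0
    for _ in range(cfg.generations):
        fitness = pop @ v
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_V + 1e-12:
            best_V = float(fitness[gen_best])
            best_x = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_V)
        if stagnant >= cfg.stagnation:
            break
        # roulette selection
        total = fitness.sum()
        probs = fitness / total if total > 0 else np.full(len(pop), 1.0 / len(pop))
        idx = rng.choice(len(pop), size=cfg.population_size, p=probs)
        nxt = pop[idx].copy()
        # two-point crossover on consecutive pairs
        for a in range(0, cfg.population_size, 2):
            if rng.random() < cfg.crossover_prob and n > 1:
                lo, hi = sorted(rng.integers(0, n + 1, size=2))
                if lo < hi:
                    tmp = nxt[a, lo:hi].copy()
                    nxt[a, lo:hi] = nxt[a + 1, lo:hi]
                    nxt[a + 1, lo:hi] = tmp
        # per-bit mutation
        flips = rng.random(nxt.shape) < mut_p
        nxt[flips] ^= 1
        _repair(nxt, inst, rng)
        # elitism: re-insert the best-ever individual
        for e in range(min(cfg.elitism, cfg.population_size)):
            if best_x is not None:
                nxt[e] = best_x
        pop = nxt
    if best_x is None:  # pragma: no cover - generations >= 1 in practice
        best_x = np.zeros(n, dtype=np.int8)
    return KnapsackSolution.from_vector(inst, best_x, history=history)


def frms_from_solution(sdfms, sol: KnapsackSolution) -> list:
    """Selected modules carried over as response motifs, value order preserved."""
    sdfms = list(sdfms)
    if len(sdfms) != len(sol.x):
        raise ValueError("solution length does not match module list")
    selected = [s for s, b in zip(sdfms, sol.x) if b]
    if not selected:
        warnings.warn("knapsack solution selects no modules", stacklevel=2)
    return selected
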