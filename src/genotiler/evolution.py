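"""Two-stage compilation: exhaustive candidate search or directed evolution.

For libraries small enough, the compiler enumerates every pre-filtered
candidate subset and unifies each exhaustively.  Beyond the exhaustive
threshold a *directed* genetic algorithm searches the candidate space: an
individual is one component choice per goal rule, genes are drawn only from
that rule's association set, and offspring violating the agent constraints
are rejected and resampled — the pre-selection steers the search away from
subsets that would obviously fail unification.

Fitness is lexicographic: feasibility first, then the number of goal rules
unified (maximized), then the number of distinct components used
(minimized).  Elitism makes the best-so-far fitness monotone; every GA
result is re-verified by full unification plus the observability check, so
the evolutionary path can never emit a solution the exhaustive path would
reject.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import NoSolutionError
from .lang import Program, constants_of, normalize, variables_of
from .matching import (AssociationMap, Component, ComponentLibrary,
                       agent_constraints_ok, associate, candidate_subsets)
from .unification import (Counters, EMPTY_SUBSTITUTION, Substitution,
                          SynthesisResult, aci_unify, unify_rule)


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the compiler; defaults are conventional GA settings.

    ``exhaustive_threshold`` — largest library compiled by full enumeration.
    ``exhaustive_cap`` — largest pre-filter population enumerated before the
    compiler falls back to the evolutionary stage regardless of library size.
    """

    seed: Optional[int] = None
    population: int = 50
    tournament: int = 3
    crossover: float = 0.8
    mutation: float = 0.1
    generations: int = 200
    stagnation: int = 20
    exhaustive_threshold: int = 12
    exhaustive_cap: int = 100_000
    repair_attempts: int = 10
    eval_node_cap: int = 20_000
    stop_when_feasible: bool = False


DEFAULT_CONFIG = SearchConfig(seed=0)


@dataclass(frozen=True)
class Fitness:
    feasible: bool
    n_unified_rules: int
    n_components: int

    def sort_key(self) -> tuple:
        """Ascending order = better first."""
        return (not self.feasible, -self.n_unified_rules, self.n_components)

    def __lt__(self, other: "Fitness") -> bool:
        return self.sort_key() < other.sort_key()


@dataclass
class Individual:
    genes: Tuple[str, ...]
    fitness: Optional[Fitness] = None


@dataclass
class CompileReport:
    stage: str                       # "exhaustive" | "evolutionary"
    solutions: List[SynthesisResult]
    counters: Counters
    seed: Optional[int]
    generations_run: int = 0
    population_size: int = 0
    survivors: int = 0
    diagnosis: Optional[str] = None
    best_fitness_log: List[tuple] = field(default_factory=list)
    wall_time: float = 0.0

    @property
    def success(self) -> bool:
        return bool(self.solutions)


# --------------------------------------------------------------------------- #
# evaluation


def _max_cover(goal: Program, components: Sequence[Component],
               counters: Counters, node_cap: int
               ) -> Tuple[int, int, List[SynthesisResult]]:
    """Largest unifiable subset of goal rules over the component set, with a
    capped backtracking search; returns (best rule count, components used in
    the best partial, full-cover results if any)."""
    g = normalize(goal)
    gvars = variables_of(g)
    forbidden = constants_of(g)
    uniq = list({c.name: c for c in components}.values())
    hosts = [[(c, q) for c in uniq for q in c.normalized.rules] for _ in g.rules]
    n = len(g.rules)
    best = {"count": -1, "ncomp": 0}
    nodes = [0]

    def rec(i: int, covered: int, subst: Substitution, used: List[Component]):
        nodes[0] += 1
        counters.unify_nodes += 1
        if nodes[0] > node_cap or covered + (n - i) <= best["count"]:
            return
        if i == n:
            ncomp = len({c.name for c in used})
            if covered > best["count"] or (covered == best["count"]
                                           and ncomp < best["ncomp"]):
                best.update(count=covered, ncomp=ncomp)
            return
        for c, q in hosts[i]:
            for ext in unify_rule(g.rules[i], q, subst, forbidden, g, c.normalized):
                used.append(c)
                rec(i + 1, covered + 1, ext, used)
                used.pop()
        rec(i + 1, covered, subst, used)  # leave rule i uncovered

    rec(0, 0, EMPTY_SUBSTITUTION, [])
    full: List[SynthesisResult] = []
    if best["count"] == n:
        full = aci_unify(goal, uniq, counters=counters, node_cap=node_cap)
    return max(best["count"], 0), best["ncomp"], full


def evaluate(ind: Individual, goal: Program, lib: ComponentLibrary,
             counters: Counters, cfg: SearchConfig,
             cache: Optional[Dict] = None
             ) -> Tuple[Fitness, List[SynthesisResult]]:
    """Fitness of one individual: run (capped) unification restricted to its
    components; feasible iff the whole goal is covered by an observable
    assembly."""
    key = tuple(sorted(set(ind.genes)))
    if cache is not None and key in cache:
        fit, sols = cache[key]
        ind.fitness = fit
        return fit, sols
    counters.ga_evaluations += 1
    comps = [lib.get(n) for n in key]
    if not normalize(goal).rules:
        fit, sols = Fitness(True, 0, 0), aci_unify(goal, [])
    else:
        n_best, ncomp, full = _max_cover(goal, comps, counters, cfg.eval_node_cap)
        if full:
            fit = Fitness(True, len(normalize(goal).rules),
                          min(len(r.components) for r in full))
            sols = full
        else:
            fit, sols = Fitness(False, n_best, ncomp), []
    if cache is not None:
        cache[key] = (fit, sols)
    ind.fitness = fit
    return fit, sols


# --------------------------------------------------------------------------- #
# genetic operators


def _random_individual(amap: AssociationMap, lib: ComponentLibrary,
                       rng: random.Random, cfg: SearchConfig,
                       counters: Counters) -> Individual:
    for _ in range(cfg.repair_attempts):
        genes = tuple(rng.choice(options) for options in amap.per_rule)
        ok, _ = agent_constraints_ok(amap.goal, [lib.get(n) for n in set(genes)])
        if ok:
            return Individual(genes)
        counters.agent_rejections += 1
    return Individual(genes)  # rare: accepted but will score infeasible


def _tournament(pop: List[Individual], rng: random.Random, k: int) -> Individual:
    picks = [pop[rng.randrange(len(pop))] for _ in range(k)]
    return min(picks, key=lambda i: i.fitness.sort_key())


def evolve_step(pop: List[Individual], amap: AssociationMap, lib: ComponentLibrary,
                goal: Program, rng: random.Random, cfg: SearchConfig,
                counters: Counters, cache: Optional[Dict] = None
                ) -> List[Individual]:
    """One generation: elitist, tournament selection, one-point crossover,
    per-gene mutation resampled from the rule's association set; offspring
    failing the agent constraints are rejected and redrawn (directedness).
    Fully reproducible from the rng state."""
    for ind in pop:
        if ind.fitness is None:
            evaluate(ind, goal, lib, counters, cfg, cache)
    elite = min(pop, key=lambda i: i.fitness.sort_key())
    nxt: List[Individual] = [Individual(elite.genes, elite.fitness)]
    n_genes = len(amap.per_rule)
    while len(nxt) < len(pop):
        child: Optional[Individual] = None
        for _ in range(cfg.repair_attempts):
            a = _tournament(pop, rng, cfg.tournament)
            b = _tournament(pop, rng, cfg.tournament)
            genes = list(a.genes)
            if n_genes > 1 and rng.random() < cfg.crossover:
                cut = rng.randrange(1, n_genes)
                genes = list(a.genes[:cut] + b.genes[cut:])
            for gi in range(n_genes):
                if rng.random() < cfg.mutation:
                    genes[gi] = rng.choice(amap.per_rule[gi])
            ok, _ = agent_constraints_ok(
                amap.goal, [lib.get(n) for n in set(genes)])
            if ok:
                child = Individual(tuple(genes))
                break
            counters.agent_rejections += 1
        if child is None:
            child = _random_individual(amap, lib, rng, cfg, counters)
        evaluate(child, goal, lib, counters, cfg, cache)
        nxt.append(child)
    return nxt


# --------------------------------------------------------------------------- #
# the compiler front door


def compile(goal: Program, lib: ComponentLibrary,
            cfg: SearchConfig = DEFAULT_CONFIG) -> CompileReport:
    """Full pipeline: associate -> pre-filter -> unify (exhaustively for
    small libraries, by directed evolution otherwise).  Returns all distinct
    solutions found, fitness-ordered (fewest components first, then names).

    Raises :class:`NoSolutionError` (carrying the diagnosis and the partial
    report) when no covering assembly exists or none was found.
    """
    t0 = time.perf_counter()
    counters = Counters()
    goal_n = normalize(goal)
    amap = associate(goal, lib)
    if amap.has_orphan:
        diag = ("no component locally associates with goal rule(s) "
                + ", ".join(str(i + 1) for i in amap.orphans))
        report = CompileReport("exhaustive", [], counters, cfg.seed, diagnosis=diag,
                               wall_time=time.perf_counter() - t0)
        raise NoSolutionError(diag, diagnosis=diag, report=report)

    use_exhaustive = (len(lib) <= cfg.exhaustive_threshold
                      and amap.population_size() <= cfg.exhaustive_cap)
    solutions: Dict[tuple, SynthesisResult] = {}

    if use_exhaustive:
        survivors = 0
        for names in candidate_subsets(goal, lib, amap, counters):
            survivors += 1
            for res in aci_unify(goal, [lib.get(n) for n in names], counters=counters):
                solutions.setdefault(res.key(), res)
        report = CompileReport("exhaustive", _ordered(solutions), counters, cfg.seed,
                               survivors=survivors,
                               population_size=amap.population_size(),
                               wall_time=time.perf_counter() - t0)
    else:
        if cfg.seed is None:
            raise ValueError("a seed is required for the evolutionary stage")
        rng = random.Random(cfg.seed)
        cache: Dict = {}
        pop = [_random_individual(amap, lib, rng, cfg, counters)
               for _ in range(cfg.population)]
        best: Optional[Fitness] = None
        stagnant = 0
        gens = 0
        log: List[tuple] = []
        for gen in range(cfg.generations):
            pop = evolve_step(pop, amap, lib, goal, rng, cfg, counters, cache)
            gens = gen + 1
            for fit, sols in cache.values():
                for res in sols:
                    solutions.setdefault(res.key(), res)
            gen_best = min(i.fitness for i in pop)
            log.append((gen + 1, gen_best.feasible, gen_best.n_unified_rules,
                        gen_best.n_components))
            if best is None or gen_best < best:
                best, stagnant = gen_best, 0
            else:
                stagnant += 1
            if solutions and cfg.stop_when_feasible:
                break
            if stagnant >= cfg.stagnation:
                break
        report = CompileReport("evolutionary", _ordered(solutions), counters, cfg.seed,
                               generations_run=gens, population_size=cfg.population,
                               best_fitness_log=log,
                               wall_time=time.perf_counter() - t0)

    if not report.solutions:
        diag = "no candidate subset unifies with the goal"
        report.diagnosis = diag
        raise NoSolutionError(diag, diagnosis=diag, report=report)
    return report


def _ordered(solutions: Dict[tuple, SynthesisResult]) -> List[SynthesisResult]:
    return sorted(solutions.values(),
                  key=lambda r: (len(r.components), r.components, r.substitution.items))
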