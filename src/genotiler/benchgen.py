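"""Synthetic benchmark instances: random component libraries and goal
programs solvable by construction.

A library of ``n_components`` random ground components is drawn over a pool
of ``n_constants`` agents; the goal is then built by sampling components,
copying ``n_goal_rules`` of their rules, and abstracting ``n_variables``
distinct constants into fresh variables (every occurrence of an abstracted
constant is renamed, so the constant no longer occurs in the goal — which is
exactly what the compiler's freshness rule on substitutions requires).  The
inverse renaming is a witness substitution, so every generated pair
compiles; the generator is fully deterministic in its seed.

The scaling harness measures compilation *effort* in hardware-independent
search counters (candidate subsets examined, unification nodes, GA
evaluations); wall-clock seconds are recorded for information only.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import InfeasibleConfigError, NoSolutionError
from .lang import (AgentRef, CausalRule, Program, RuleKind, StateLiteral,
                   constants_of, PRIMITIVE_KINDS)
from .matching import Component, ComponentLibrary
from .evolution import CompileReport, SearchConfig, compile as compile_program


@dataclass(frozen=True)
class BenchConfig:
    """Shape of one random instance; defaults follow the benchmark design of
    100-component libraries with 10-rule goal programs."""

    n_components: int = 100
    rules_per_component: Tuple[int, int] = (1, 2)
    n_goal_rules: int = 10
    n_variables: int = 3
    n_constants: int = 20
    cause_size: Tuple[int, int] = (1, 2)
    effect_size: Tuple[int, int] = (1, 2)
    negative_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_components", "n_goal_rules", "n_variables", "n_constants"):
            if getattr(self, name) < 0:
                raise InfeasibleConfigError(f"{name} must be >= 0")
        if self.n_constants == 0 and self.n_components > 0:
            raise InfeasibleConfigError("a non-empty library needs constants")


def _random_rule(rng: random.Random, pool: Sequence[AgentRef],
                 cfg: BenchConfig) -> CausalRule:
    kind = rng.choice(PRIMITIVE_KINDS)

    def side(lo_hi: Tuple[int, int]) -> frozenset:
        k = min(rng.randint(*lo_hi), len(pool))
        agents = rng.sample(list(pool), k)
        return frozenset(StateLiteral(a, rng.random() >= cfg.negative_rate)
                         for a in agents)

    return CausalRule(kind, side(cfg.cause_size), side(cfg.effect_size))


def generate(cfg: BenchConfig) -> Tuple[ComponentLibrary, Program]:
    """Draw one (library, goal) pair; the goal is guaranteed compilable
    against the library.  Identical configs (seed included) give structurally
    identical output."""
    rng = random.Random(cfg.seed)
    pool = [AgentRef(f"C{i}") for i in range(1, cfg.n_constants + 1)]
    comps: List[Component] = []
    for j in range(cfg.n_components):
        rules: List[CausalRule] = []
        for _ in range(rng.randint(*cfg.rules_per_component)):
            for _attempt in range(20):
                r = _random_rule(rng, pool, cfg)
                if r not in rules:
                    rules.append(r)
                    break
        comps.append(Component(f"B{j + 1:03d}", Program(tuple(rules))))
    lib = ComponentLibrary(tuple(comps), source=f"<benchgen seed={cfg.seed}>")

    order = list(range(len(comps)))
    rng.shuffle(order)
    goal_rules: List[CausalRule] = []
    for j in order:
        if len(goal_rules) == cfg.n_goal_rules:
            break
        for r in comps[j].normalized.rules:
            if len(goal_rules) == cfg.n_goal_rules:
                break
            if r not in goal_rules:
                goal_rules.append(r)
    if len(goal_rules) < cfg.n_goal_rules:
        raise InfeasibleConfigError(
            f"the selected components supply only {len(goal_rules)} distinct rules "
            f"for a {cfg.n_goal_rules}-rule goal")

    goal = Program(tuple(goal_rules))
    goal_consts = sorted(constants_of(goal), key=lambda a: a.name)
    if len(goal_consts) < cfg.n_variables:
        raise InfeasibleConfigError(
            f"goal has {len(goal_consts)} distinct constants, cannot abstract "
            f"{cfg.n_variables} variables")
    abstracted = rng.sample(goal_consts, cfg.n_variables)
    renaming: Dict[AgentRef, AgentRef] = {
        k: AgentRef(f"v{i + 1}") for i, k in enumerate(abstracted)}

    def rn(l: StateLiteral) -> StateLiteral:
        tgt = renaming.get(l.agent)
        return l if tgt is None else StateLiteral(tgt, l.positive, l.qualifier,
                                                  l.compartment)

    goal = Program(tuple(
        CausalRule(r.kind, frozenset(rn(l) for l in r.cause),
                   frozenset(rn(l) for l in r.effect), r.scope)
        for r in goal_rules))
    return lib, goal


def random_program(cfg: BenchConfig, rng: random.Random,
                   n_rules: int, n_variables: int) -> Program:
    """A goal drawn independently of any library (no solvability guarantee);
    used to exercise the unsolvable side of the compiler in tests."""
    pool = ([AgentRef(f"C{i}") for i in range(1, cfg.n_constants + 1)]
            + [AgentRef(f"v{i}") for i in range(1, n_variables + 1)])
    rules: List[CausalRule] = []
    for _ in range(n_rules):
        for _attempt in range(20):
            r = _random_rule(rng, pool, cfg)
            if r not in rules:
                rules.append(r)
                break
    return Program(tuple(rules))


# --------------------------------------------------------------------------- #
# scaling harness


def run_instance(bench: BenchConfig, search: SearchConfig) -> dict:
    """Generate one instance, compile it, and report a result row."""
    lib, goal = generate(bench)
    t0 = time.perf_counter()
    try:
        report = compile_program(goal, lib, search)
        success, stage = True, report.stage
        counters, n_solutions = report.counters, len(report.solutions)
    except NoSolutionError as e:
        success, stage = False, e.report.stage if e.report else "unknown"
        counters = e.report.counters if e.report else None
        n_solutions = 0
    return {
        "n_components": bench.n_components,
        "n_goal_rules": bench.n_goal_rules,
        "n_variables": bench.n_variables,
        "n_constants": bench.n_constants,
        "seed": bench.seed,
        "success": success,
        "stage": stage,
        "n_solutions": n_solutions,
        "effort": counters.effort() if counters else 0,
        "unify_nodes": counters.unify_nodes if counters else 0,
        "ga_evaluations": counters.ga_evaluations if counters else 0,
        "wall_time_s": time.perf_counter() - t0,
    }


def scaling_harness(configs: Iterable[BenchConfig],
                    search: SearchConfig) -> pd.DataFrame:
    """Run a grid of benchmark configs and tabulate success and effort."""
    return pd.DataFrame([run_instance(b, replace(search, seed=b.seed))
                         for b in configs])


def grid(n_variables: Sequence[int], n_constants: Sequence[int],
         seeds: Sequence[int], base: BenchConfig = BenchConfig()
         ) -> List[BenchConfig]:
    return [replace(base, n_variables=v, n_constants=c, seed=s)
            for v in n_variables for c in n_constants for s in seeds]


def effort_trend(df: pd.DataFrame, column: str = "n_variables") -> float:
    """Spearman rank correlation between a size column and the mean effort
    per level — the hardware-independent stand-in for timing curves."""
    from scipy.stats import spearmanr

    means = df.groupby(column)["effort"].mean()
    if len(means) < 2:
        return 0.0
    rho = spearmanr(means.index.to_numpy(), means.to_numpy()).statistic
    return float(rho)
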