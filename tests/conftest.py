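import random

import pytest

import genotiler as gt


@pytest.fixture(scope="session")
def fx():
    return gt.fixtures()


@pytest.fixture(scope="session")
def repressilator(fx):
    return fx["repressilator_goal"], fx["repressilator_lib5"]


def small_instance(seed: int):
    """A desk-scale random (library, goal) pair: <=4 components, 3-rule goal,
    2 variables; skips seeds whose draw is infeasible."""
    cfg = gt.BenchConfig(n_components=4, rules_per_component=(1, 2),
                         n_goal_rules=3, n_variables=2, n_constants=5,
                         seed=seed)
    try:
        return gt.generate(cfg)
    except gt.InfeasibleConfigError:
        return None


def pipeline_solution_set(goal, lib, seed=0):
    """Canonical (component set, substitution) pairs found by the compiler,
    empty set when compilation fails."""
    try:
        report = gt.compile(goal, lib, gt.SearchConfig(seed=seed))
    except gt.NoSolutionError:
        return set()
    return {(frozenset(r.components), r.substitution.items)
            for r in report.solutions}


def model(*worlds):
    """Shorthand: a linear model from iterables of literals."""
    return gt.LinearKripkeModel(tuple(frozenset(w) for w in worlds))
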