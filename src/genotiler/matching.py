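"""Conservative pre-selection of library components.

Before any unification is attempted, two families of necessary conditions
prune the candidate space:

* **causal-relation constraints** (:func:`rule_associates`) relate one goal
  rule to one component rule — same primitive kind, the goal's constants
  present on their respective sides, side cardinalities no smaller, an
  injective per-side counterpart assignment compatible with the declared
  attribute orders, and attribute counts no larger on the goal side;
* **agent constraints** (:func:`agent_constraints_ok`) act on a whole
  candidate subset — every goal constant occurs at least as often in the
  subset (per side), and every goal variable has at least one admissible
  fresh constant to be substituted with (a constant of the subset that is
  *not* a goal constant, occurring at least as often per side, with
  compatible attribute order and count).

Both filters are sound: a candidate they reject can never unify (the
brute-force oracle equality is property-tested), but survivors may still
fail at unification.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

from .errors import ValidationError
from .lang import (AgentRef, AttributeDecl, CausalRule, Label, Program,
                   StateLiteral, constants_of, normalize, variables_of)


@dataclass(frozen=True)
class Component:
    """A named library entry: a program fragment describing one device."""

    name: str
    program: Program

    def __post_init__(self):
        object.__setattr__(self, "normalized", normalize(self.program))

    normalized: Program = field(init=False, repr=False, compare=False)


@dataclass(frozen=True)
class ComponentLibrary:
    components: Tuple[Component, ...]
    source: Optional[str] = None

    def __post_init__(self):
        names = [c.name for c in self.components]
        dupes = [n for n, k in Counter(names).items() if k > 1]
        if dupes:
            raise ValidationError(f"duplicate component name(s): {', '.join(sorted(dupes))}")

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def get(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(c.name for c in self.components)


def library(pairs, source: Optional[str] = None) -> ComponentLibrary:
    return ComponentLibrary(tuple(Component(n, p) for n, p in pairs), source)


# --------------------------------------------------------------------------- #
# attribute-order compatibility


def _is_subsequence(short: Sequence[str], long: Sequence[str]) -> bool:
    it = iter(long)
    return all(x in it for x in short)


def attrs_compatible(p_decl: Optional[AttributeDecl],
                     q_decl: Optional[AttributeDecl]) -> bool:
    """The goal agent's declared attribute structure must embed into the
    counterpart's: the chain as a subsequence, unequal pairs preserved, and
    no more attributes overall."""
    if p_decl is None or p_decl.n_attributes == 0:
        return True
    if q_decl is None:
        return False
    return (p_decl.n_attributes <= q_decl.n_attributes
            and _is_subsequence(p_decl.chain, q_decl.chain)
            and p_decl.unequal <= q_decl.unequal)


def _counterpart_ok(pl: StateLiteral, ql: StateLiteral,
                    goal: Program, comp: Program) -> bool:
    if pl.positive != ql.positive or pl.compartment != ql.compartment:
        return False
    if pl.agent.is_constant:
        return ql == pl
    if pl.qualifier != ql.qualifier:
        return False
    return attrs_compatible(goal.decl_for(pl.agent), comp.decl_for(ql.agent))


def _injective_assignment(p_lits: List[StateLiteral], q_lits: List[StateLiteral],
                          goal: Program, comp: Program) -> bool:
    """Backtracking search for an injective counterpart map (tiny sides)."""
    if not p_lits:
        return True
    pl, rest = p_lits[0], p_lits[1:]
    for i, ql in enumerate(q_lits):
        if _counterpart_ok(pl, ql, goal, comp):
            if _injective_assignment(rest, q_lits[:i] + q_lits[i + 1:], goal, comp):
                return True
    return False


def rule_associates(p: CausalRule, q: CausalRule,
                    goal: Program = Program(), comp: Program = Program()) -> bool:
    """Local causal association between a (normalized) goal rule and a
    component rule; a necessary condition for the two to unify."""
    if p.kind is not q.kind:
        return False
    for p_side, q_side in ((p.cause, q.cause), (p.effect, q.effect)):
        const_lits = {l for l in p_side if l.agent.is_constant}
        if not const_lits <= q_side:
            return False
        if len(q_side) < len(p_side):
            return False
        if not _injective_assignment(sorted(p_side, key=lambda l: l.sort_key()),
                                     sorted(q_side, key=lambda l: l.sort_key()),
                                     goal, comp):
            return False
    return True


# --------------------------------------------------------------------------- #
# association map


@dataclass(frozen=True)
class AssociationMap:
    """For each goal rule (by index in the normalized goal), the components
    holding at least one locally associated rule."""

    goal: Program                      # normalized
    per_rule: Tuple[Tuple[str, ...], ...]   # component names, library order
    pairs: Tuple[Tuple[Tuple[str, int], ...], ...]  # (component, rule index) detail

    @property
    def orphans(self) -> Tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.per_rule) if not s)

    @property
    def has_orphan(self) -> bool:
        return bool(self.orphans)

    def population_size(self) -> int:
        n = 1
        for s in self.per_rule:
            n *= len(s)
        return n


def associate(goal: Program, lib: ComponentLibrary) -> AssociationMap:
    """Compute the local causal association of every goal rule with every
    library component; an empty set for any rule guarantees global failure."""
    g = normalize(goal)
    per_rule: List[Tuple[str, ...]] = []
    pairs: List[Tuple[Tuple[str, int], ...]] = []
    for p in g.rules:
        names: List[str] = []
        detail: List[Tuple[str, int]] = []
        for comp in lib:
            hit = False
            for qi, q in enumerate(comp.normalized.rules):
                if rule_associates(p, q, g, comp.normalized):
                    detail.append((comp.name, qi))
                    hit = True
            if hit:
                names.append(comp.name)
        per_rule.append(tuple(names))
        pairs.append(tuple(detail))
    return AssociationMap(g, tuple(per_rule), tuple(pairs))


# --------------------------------------------------------------------------- #
# agent constraints


def _side_counts(rules: FrozenSet[CausalRule]) -> Dict[AgentRef, Counter]:
    counts: Dict[AgentRef, Counter] = {}
    for r in rules:
        for side, lits in (("cause", r.cause), ("effect", r.effect)):
            for l in lits:
                counts.setdefault(l.agent, Counter())[side] += 1
    return counts


def agent_constraints_ok(goal: Program, components: Sequence[Component]
                         ) -> Tuple[bool, str]:
    """Necessary conditions on agent occurrences for a candidate subset.

    Occurrences are counted per side (cause vs effect) over the *distinct*
    rules of the goal and of the subset union (duplicate components and
    duplicated rules contract, mirroring the idempotence of assembly).
    """
    g = normalize(goal)
    uniq = {c.name: c for c in components}
    union_rules = frozenset(r for c in uniq.values() for r in c.normalized.rules)
    goal_rules = frozenset(g.rules)
    cq = _side_counts(union_rules)
    cp = _side_counts(goal_rules)
    goal_consts = constants_of(g)

    for a, need in cp.items():
        if a.is_variable:
            continue
        have = cq.get(a, Counter())
        for side in ("cause", "effect"):
            if need[side] > have[side]:
                return False, (f"constant {a.name} occurs {need[side]}x as {side} in the "
                               f"goal but only {have[side]}x in the subset")

    subset_decls = {d.agent: d for c in uniq.values()
                    for d in c.normalized.declarations}
    for v, need in cp.items():
        if v.is_constant:
            continue
        v_labels = {l.qualifier.value for r in goal_rules for l in r.literals()
                    if l.agent == v and isinstance(l.qualifier, Label)}
        candidates = []
        for k, have in cq.items():
            if k.is_variable or k in goal_consts:
                continue
            if any(need[s] > have[s] for s in ("cause", "effect")):
                continue
            k_decl = subset_decls.get(k)
            if v_labels and (k_decl is None or not v_labels <= k_decl.labels):
                continue
            if not attrs_compatible(g.decl_for(v), k_decl):
                continue
            candidates.append(k)
        if not candidates:
            return False, (f"variable {v.name} has no admissible fresh constant "
                           f"(needs cause>={need['cause']}, effect>={need['effect']}, "
                           f"not among the goal constants)")
    return True, ""


# --------------------------------------------------------------------------- #
# candidate enumeration


def candidate_population(amap: AssociationMap) -> Iterator[Tuple[str, ...]]:
    """The raw pre-filter population: one associated component per goal rule,
    repetitions allowed, in lexicographic order of library indices."""
    yield from itertools.product(*amap.per_rule)


def candidate_subsets(goal: Program, lib: ComponentLibrary, amap: AssociationMap,
                      counters=None) -> Iterator[Tuple[str, ...]]:
    """Stream of candidate component tuples surviving the agent constraints.

    Raises :class:`ValidationError` when some goal rule has no associated
    component (guaranteed global failure).
    """
    if amap.has_orphan:
        raise ValidationError(
            "goal rule(s) with empty association set: "
            + ", ".join(str(i + 1) for i in amap.orphans))
    for names in candidate_population(amap):
        if counters is not None:
            counters.candidates_examined += 1
        ok, _ = agent_constraints_ok(goal, [lib.get(n) for n in names])
        if ok:
            yield names
        elif counters is not None:
            counters.agent_rejections += 1
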