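"""ACI-unification of a goal program against library components.

Programs are conjunctions of causal rules; assembly of components is
associative, commutative and idempotent, so unification works modulo
reordering and contraction of duplicate rules.  A goal rule unifies with a
component rule when a substitution of the goal's variables by constants
makes the two rules *textually equal* (same primitive kind, same compartment
scope, equal cause and effect literal sets).  The functional-synthesis
calculus behind the implementation:

* **Inst.** — an observable instance of a part of a library component (any
  sub-collection of its rules) synthesizes the matched goal part; the device
  nevertheless enters the assembly whole.
* **Com. / Cont.** — assemblies are order-insensitive and duplicate
  components/rules contract; results are canonicalized accordingly.
* **Asm.** — two partial syntheses merge when their substitutions agree on
  shared variables, and the merged assembly is rechecked for observability.

Substitutions are injective on the goal's variables and never map a variable
to a constant that already occurs in the goal (a variable abstracts a *new*
part, distinct from every named one).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Set, Tuple

from .errors import (ResourceGuardExceeded, SubstitutionConflictError,
                     UnobservableError)
from .lang import (AgentRef, CausalRule, Program, StateLiteral, constants_of,
                   normalize, variables_of)
from .matching import Component, ComponentLibrary, attrs_compatible
from .semantics import observable


@dataclass(frozen=True)
class Substitution:
    """Finite map from variable agents to constant (or variable) agents."""

    items: Tuple[Tuple[str, AgentRef], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(sorted(self.items)))
        keys = [k for k, _ in self.items]
        if len(set(keys)) != len(keys):
            raise SubstitutionConflictError("variable bound twice")
        for k, tgt in self.items:
            if AgentRef(k).is_constant:
                raise SubstitutionConflictError(f"cannot substitute constant {k}")
            if tgt.is_variable and any(k2 == tgt.name for k2, _ in self.items):
                raise SubstitutionConflictError(f"substitution chain through {tgt.name}")

    @property
    def mapping(self) -> Dict[str, AgentRef]:
        return dict(self.items)

    def get(self, v: AgentRef) -> Optional[AgentRef]:
        return self.mapping.get(v.name)

    def bind(self, v: AgentRef, target: AgentRef) -> Optional["Substitution"]:
        """Extend with v -> target; None on conflict or non-injectivity."""
        cur = self.get(v)
        if cur is not None:
            return self if cur == target else None
        if any(tgt == target for _, tgt in self.items):  # injectivity
            return None
        return Substitution(self.items + ((v.name, target),))

    def merge(self, other: "Substitution") -> "Substitution":
        """Union of two substitutions; raises on disagreement over a shared
        variable or loss of injectivity."""
        out = self
        for k, tgt in other.items:
            nxt = out.bind(AgentRef(k), tgt)
            if nxt is None:
                raise SubstitutionConflictError(
                    f"substitutions conflict on {k} ({out.get(AgentRef(k))} vs {tgt})")
            out = nxt
        return out

    def restrict(self, variables: Set[AgentRef]) -> "Substitution":
        names = {v.name for v in variables}
        return Substitution(tuple((k, t) for k, t in self.items if k in names))

    def apply_literal(self, l: StateLiteral) -> StateLiteral:
        tgt = self.get(l.agent) if l.agent.is_variable else None
        return l if tgt is None else StateLiteral(tgt, l.positive, l.qualifier, l.compartment)

    def apply_rule(self, r: CausalRule) -> CausalRule:
        return CausalRule(r.kind,
                          frozenset(self.apply_literal(l) for l in r.cause),
                          frozenset(self.apply_literal(l) for l in r.effect),
                          r.scope)

    def apply(self, p: Program) -> Program:
        return Program(tuple(self.apply_rule(r) for r in p.rules),
                       p.declarations, p.spots)

    def as_dict(self) -> Dict[str, str]:
        return {k: t.name for k, t in self.items}

    def __len__(self) -> int:
        return len(self.items)


EMPTY_SUBSTITUTION = Substitution()


@dataclass
class Counters:
    """Hardware-independent effort counters accumulated along a compilation."""

    candidates_examined: int = 0
    agent_rejections: int = 0
    unify_nodes: int = 0
    ga_evaluations: int = 0

    def effort(self) -> int:
        return self.candidates_examined + self.unify_nodes + self.ga_evaluations

    def as_dict(self) -> Dict[str, int]:
        return {"candidates_examined": self.candidates_examined,
                "agent_rejections": self.agent_rejections,
                "unify_nodes": self.unify_nodes,
                "ga_evaluations": self.ga_evaluations,
                "effort": self.effort()}


# --------------------------------------------------------------------------- #
# rule-level unification


def _match_sets(p_lits: List[StateLiteral], q_lits: List[StateLiteral],
                subst: Substitution, goal: Program, comp: Program
                ) -> Iterator[Substitution]:
    """All substitution extensions making the two literal sets equal
    (bijective correspondence)."""
    if not p_lits:
        if not q_lits:
            yield subst
        return
    pl, rest = p_lits[0], p_lits[1:]
    for i, ql in enumerate(q_lits):
        if pl.positive != ql.positive or pl.compartment != ql.compartment:
            continue
        if pl.agent.is_constant:
            if ql != pl:
                continue
            yield from _match_sets(rest, q_lits[:i] + q_lits[i + 1:], subst, goal, comp)
        else:
            if pl.qualifier != ql.qualifier:
                continue
            if not attrs_compatible(goal.decl_for(pl.agent), comp.decl_for(ql.agent)):
                continue
            ext = subst.bind(pl.agent, ql.agent)
            if ext is None:
                continue
            yield from _match_sets(rest, q_lits[:i] + q_lits[i + 1:], ext, goal, comp)


def unify_rule(p: CausalRule, q: CausalRule, subst: Substitution = EMPTY_SUBSTITUTION,
               forbidden: FrozenSet[AgentRef] = frozenset(),
               goal: Program = Program(), comp: Program = Program()
               ) -> List[Substitution]:
    """All extensions of ``subst`` under which ``p`` becomes textually equal
    to ``q``: same kind, and cause/effect sets in bijection preserving
    polarity, qualifier, compartment and attribute compatibility.

    ``forbidden`` carries the goal's constants: a variable may never be bound
    to one of them.  Returns the empty list when the rules do not unify.
    """
    if p.kind is not q.kind:
        return []
    if len(p.cause) != len(q.cause) or len(p.effect) != len(q.effect):
        return []
    out: List[Substitution] = []
    seen = set()
    pc = sorted(p.cause, key=lambda l: l.sort_key())
    qc = sorted(q.cause, key=lambda l: l.sort_key())
    pe = sorted(p.effect, key=lambda l: l.sort_key())
    qe = sorted(q.effect, key=lambda l: l.sort_key())
    for s1 in _match_sets(pc, qc, subst, goal, comp):
        for s2 in _match_sets(pe, qe, s1, goal, comp):
            if any(tgt in forbidden for _, tgt in s2.items):
                continue
            if s2.items not in seen:
                seen.add(s2.items)
                out.append(s2)
    return out


# --------------------------------------------------------------------------- #
# synthesis results


@dataclass(frozen=True)
class SynthesisResult:
    """A covering of the goal: the components used, the substitution, the
    derivation skeleton and the assembled ground program."""

    components: Tuple[str, ...]
    substitution: Substitution
    derivation: Tuple[str, ...]
    assembly: Program

    def key(self) -> tuple:
        return (frozenset(self.components), self.substitution.items)


def union_program(components: Sequence[Component]) -> Program:
    """Assembly of whole components: concatenated rules with duplicates
    contracted, merged declarations and spots (normalized form)."""
    rules: List[CausalRule] = []
    seen_rules = set()
    decls = {}
    spots = {}
    for c in components:
        n = c.normalized
        for r in n.rules:
            if r not in seen_rules:
                seen_rules.add(r)
                rules.append(r)
        for d in n.declarations:
            decls.setdefault(d.agent.name, d)
        for s in n.spots:
            spots.setdefault(s.label, s)
    return Program(tuple(rules), tuple(decls.values()), tuple(spots.values()))


def _mk_result(goal_vars, used: Sequence[Component], subst: Substitution,
               had_duplicates: bool, observability_bound: Optional[int],
               check_observable: bool = True) -> Optional[SynthesisResult]:
    used = sorted({c.name: c for c in used}.values(), key=lambda c: c.name)
    assembly = union_program(used)
    if check_observable and not observable(assembly, observability_bound):
        return None
    derivation = tuple(f"Inst({c.name})" for c in used)
    if had_duplicates:
        derivation += ("Cont",)
    derivation += ("Asm",) * max(0, len(used) - 1)
    return SynthesisResult(tuple(c.name for c in used),
                           subst.restrict(goal_vars), derivation, assembly)


def aci_unify(goal: Program, components: Sequence[Component],
              counters: Optional[Counters] = None,
              node_cap: Optional[int] = None,
              observability_bound: Optional[int] = None,
              check_observable: bool = True) -> List[SynthesisResult]:
    """Exhaustive backtracking unification of the goal against a candidate
    subset of components (treated as a set: any member may host any rule, so
    results are invariant under permutation and duplication of the input).

    Every returned result is canonical (sorted component names, substitution
    restricted to the goal's variables) and observable.
    """
    g = normalize(goal)
    goal_vars = variables_of(g)
    forbidden = constants_of(g)
    uniq = list({c.name: c for c in components}.values())
    had_duplicates = len(uniq) < len(components)
    hosts: List[List[Tuple[Component, CausalRule]]] = []
    for p in g.rules:
        hosts.append([(c, q) for c in uniq for q in c.normalized.rules])

    results: Dict[tuple, SynthesisResult] = {}
    nodes = [0]

    def rec(i: int, subst: Substitution, used: List[Component]):
        nodes[0] += 1
        if counters is not None:
            counters.unify_nodes += 1
        if node_cap is not None and nodes[0] > node_cap:
            raise ResourceGuardExceeded(f"unification exceeded {node_cap} nodes")
        if i == len(g.rules):
            res = _mk_result(goal_vars, used, subst, had_duplicates,
                             observability_bound, check_observable)
            if res is not None:
                results.setdefault(res.key(), res)
            return
        for c, q in hosts[i]:
            for ext in unify_rule(g.rules[i], q, subst, forbidden, g, c.normalized):
                used.append(c)
                rec(i + 1, ext, used)
                used.pop()

    rec(0, EMPTY_SUBSTITUTION, [])
    return sorted(results.values(),
                  key=lambda r: (len(r.components), r.components, r.substitution.items))


def apply_inst(component: Component, subst: Substitution = EMPTY_SUBSTITUTION,
               observability_bound: Optional[int] = None) -> Program:
    """Instantiate a library component under a substitution; the instance is
    accepted only if observable (components are normally ground, so the
    substitution usually acts on goal variables only)."""
    inst = subst.apply(component.normalized)
    if not observable(inst, observability_bound):
        raise UnobservableError(f"instance of {component.name} is unobservable")
    return inst


def assemble(r1: SynthesisResult, r2: SynthesisResult, lib: ComponentLibrary,
             observability_bound: Optional[int] = None) -> SynthesisResult:
    """Merge two partial syntheses (Asm.): substitutions must agree on shared
    variables; the merged assembly contracts duplicates and is rechecked for
    observability.  Commutative after canonicalization."""
    subst = r1.substitution.merge(r2.substitution)
    names = sorted(set(r1.components) | set(r2.components))
    comps = [lib.get(n) for n in names]
    assembly = union_program(comps)
    if not observable(assembly, observability_bound):
        raise UnobservableError("merged assembly is unobservable")
    derivation = tuple(dict.fromkeys(r1.derivation + r2.derivation)) + ("Asm",)
    return SynthesisResult(tuple(names), subst, derivation, assembly)


# --------------------------------------------------------------------------- #
# brute-force oracle (testing only)


def brute_force_oracle(goal: Program, lib: ComponentLibrary, max_subset: int,
                       check_observable: bool = True) -> Set[tuple]:
    """Reference result set computed the slow way: enumerate every injective,
    freshness-respecting substitution over the library's constants, then every
    per-rule hosting assignment, with no pre-filters and no backtracking.

    Returns canonical ``(frozenset of component names, substitution items)``
    pairs.  Guarded to desk scale; intended for tests.
    """
    g = normalize(goal)
    gvars = sorted(variables_of(g), key=lambda a: a.name)
    if len(lib) > 8 or len(gvars) > 4:
        raise ResourceGuardExceeded("oracle is restricted to <=8 components, <=4 variables")
    lib_consts = sorted({a for c in lib for a in constants_of(c.normalized)},
                        key=lambda a: a.name)
    fresh = [k for k in lib_consts if k not in constants_of(g)]
    out: Set[tuple] = set()
    for images in itertools.permutations(fresh, len(gvars)):
        subst = Substitution(tuple((v.name, k) for v, k in zip(gvars, images)))
        ground = subst.apply(g)
        hosts = []
        ok = True
        for r in ground.rules:
            hs = [c for c in lib if r in set(c.normalized.rules)]
            if not hs:
                ok = False
                break
            hosts.append(hs)
        if not ok:
            continue
        for assignment in itertools.product(*hosts):
            names = frozenset(c.name for c in assignment)
            if len(names) > max_subset:
                continue
            key = (names, subst.items)
            if key in out:
                continue
            comps = sorted({c.name: c for c in assignment}.values(), key=lambda c: c.name)
            if check_observable and not observable(union_program(comps)):
                continue
            out.add(key)
    if not g.rules:
        out.add((frozenset(), ()))
    return out
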