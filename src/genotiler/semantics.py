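"""Linear Kripke semantics of causal behaviour programs.

An experimental *trace* is a sequence of timed symbolic observations.  A
*chronological division* groups its instants into periods; the per-period
distinct events form a *history*, which is read as a linear Kripke model
(one world per period, implicit successor accessibility).  A program is
validated against such a model by :func:`satisfies`.

Satisfaction of the three primitives on a path ``w_1 .. w_n`` (a cause or
effect *set* holds in a world when every one of its literals does):

* normal ``c -> e``     — every world where the effect set holds is preceded
  by a strictly earlier world where the cause set holds.
* persistent ``c o-> e`` — normal, and the cause set also holds in the
  effect's world.
* remnant ``c +-> e``   — every effect world is either preceded (strictly)
  by a cause world, or carries the effect over from the immediately
  preceding world; an effect in the first world requires the cause there.

These readings give the strength chain persistent => normal => remnant,
which :func:`subsumption_check` verifies by exhaustive bounded enumeration.

*Observability* (bounded satisfiability) and *behavioural inclusion*
(bounded logical consequence, Definition-style: every model of Q is a model
of P) are implemented over all linear models up to a world bound whose
worlds are built from the programs' own literals.  Inclusion first tries a
sound syntactic subsumption test (P's rules and spots textually contained in
Q's), falling back to enumeration; both procedures are bounded, not full,
logical consequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

from .errors import DivisionError, NotGroundError, ParseError, ResourceGuardExceeded
from .lang import (CausalRule, Interval, Label, Point, Program, Qualifier,
                   RuleKind, StateLiteral, normalize, variables_of)

World = FrozenSet[StateLiteral]

DEFAULT_NODE_BUDGET = 2_000_000


def _check_consistent(worlds: Sequence[World], what: str) -> None:
    for i, w in enumerate(worlds):
        atoms = {}
        for l in w:
            prev = atoms.setdefault(l.atom, l.positive)
            if prev != l.positive:
                raise DivisionError(
                    f"inconsistent {what}: world {i + 1} contains a literal and its negation")


@dataclass(frozen=True)
class Trace:
    """Raw timed observations, one event set per instant (1-indexed)."""

    events: Tuple[World, ...]

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(frozenset(e) for e in self.events))
        if not self.events:
            raise DivisionError("a trace needs at least one instant")
        _check_consistent(self.events, "trace event")

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class ChronologicalDivision:
    """Ordered, non-overlapping closed integer periods covering a prefix 1..k."""

    periods: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "periods", tuple((int(a), int(b)) for a, b in self.periods))
        if not self.periods:
            raise DivisionError("a division needs at least one period")
        prev_end = 0
        for a, b in self.periods:
            if a > b:
                raise DivisionError(f"period [{a}, {b}] has a > b")
            if a != prev_end + 1:
                raise DivisionError(
                    f"periods must be contiguous from instant 1; got [{a}, {b}] "
                    f"after instant {prev_end}")
            prev_end = b

    @property
    def end(self) -> int:
        return self.periods[-1][1]


@dataclass(frozen=True)
class History:
    """Milestone events of a trace: one world of distinct literals per period."""

    worlds: Tuple[World, ...]

    def __post_init__(self):
        object.__setattr__(self, "worlds", tuple(frozenset(w) for w in self.worlds))
        if not self.worlds:
            raise DivisionError("a history needs at least one world")
        _check_consistent(self.worlds, "history world")

    def to_model(self) -> "LinearKripkeModel":
        return LinearKripkeModel(self.worlds)

    def __len__(self) -> int:
        return len(self.worlds)


@dataclass(frozen=True)
class LinearKripkeModel(History):
    """A history read as a Kripke model: worlds on a single path, world i
    accessible from world i-1 only (linearity)."""


def extract_history(trace: Trace, division: ChronologicalDivision) -> History:
    """Collapse each period of the trace into one world of distinct literals;
    repetition inside a period is irrelevant and dropped."""
    if division.end > len(trace):
        raise DivisionError(
            f"division ends at instant {division.end} but the trace has {len(trace)}")
    worlds = []
    for a, b in division.periods:
        merged = frozenset(l for t in range(a, b + 1) for l in trace.events[t - 1])
        worlds.append(merged)
    return History(tuple(worlds))


# --------------------------------------------------------------------------- #
# literal entailment and satisfaction


def _qual_entails(have: Qualifier, want: Qualifier) -> bool:
    """Does an observed qualifier discharge a required one?

    A required bare presence is discharged by any observation of the agent; a
    numeric point discharges an interval when it lies inside it; an interval
    discharges a wider one when contained.  Symbolic labels match literally.
    """
    if want is None:
        return True
    if isinstance(want, Label):
        return isinstance(have, Label) and have.value == want.value
    if isinstance(want, Point):
        return isinstance(have, Point) and have.value == want.value
    if isinstance(have, Point):
        return want.lo <= have.value <= want.hi
    if isinstance(have, Interval):
        return want.lo <= have.lo and have.hi <= want.hi
    return False


def holds(world: World, literal: StateLiteral) -> bool:
    """True when some observation in the world discharges ``literal``.

    Negative literals are matched on the exact qualifier: observing absence
    at one activity level says nothing about the others.
    """
    for l in world:
        if l.agent != literal.agent or l.compartment != literal.compartment:
            continue
        if l.positive != literal.positive:
            continue
        if literal.positive:
            if _qual_entails(l.qualifier, literal.qualifier):
                return True
        elif l.qualifier == literal.qualifier:
            return True
    return False


def set_holds(world: World, literals: Iterable[StateLiteral]) -> bool:
    return all(holds(world, l) for l in literals)


def _rule_ok_at(worlds: Sequence[World], i: int, r: CausalRule, cause_before: bool) -> bool:
    """Is rule ``r`` still satisfied once world ``i`` is in place?

    ``cause_before`` caches whether the cause set held in any world < i, so
    incremental path enumeration stays linear per step.
    """
    w = worlds[i]
    if not set_holds(w, r.effect):
        return True
    if r.kind is RuleKind.NORMAL:
        return cause_before
    if r.kind is RuleKind.PERSISTENT:
        return cause_before and set_holds(w, r.cause)
    # remnant: carried-over effect or a cause that appeared earlier
    if i == 0:
        return set_holds(w, r.cause)
    return cause_before or set_holds(worlds[i - 1], r.effect)


@dataclass(frozen=True)
class Failure:
    kind: str            # "rule" | "spot"
    index: int           # rule index or spot index within the program
    world: Optional[int]  # 1-based world of the violation, None for spots
    message: str


@dataclass(frozen=True)
class SatisfactionReport:
    ok: bool
    failures: Tuple[Failure, ...]

    def __bool__(self) -> bool:
        return self.ok


def satisfies(model: History, program: Program) -> SatisfactionReport:
    """Check every rule and observation spot of ``program`` on ``model``,
    reporting each violation.  The program is normalized first (macros must
    already be expanded; contexts/compartments are folded automatically)."""
    program.require_expanded()
    p = normalize(program)
    worlds = model.worlds
    failures: List[Failure] = []
    for ri, r in enumerate(p.rules):
        cause_before = False
        for i in range(len(worlds)):
            if not _rule_ok_at(worlds, i, r, cause_before):
                failures.append(Failure(
                    "rule", ri, i + 1,
                    f"rule {ri + 1} ({r.kind.value}) violated at world {i + 1}"))
                break
            cause_before = cause_before or set_holds(worlds[i], r.cause)
    for si, s in enumerate(p.spots):
        if not any(holds(w, s.observed) for w in worlds):
            failures.append(Failure(
                "spot", si, None, f"observation spot {s.label!r} never holds"))
    return SatisfactionReport(not failures, tuple(failures))


# --------------------------------------------------------------------------- #
# bounded model enumeration


def _candidate_worlds(alphabet: Iterable[StateLiteral]) -> List[World]:
    """All internally consistent worlds over the given literals: each
    underlying fact is asserted, denied or left unspecified."""
    by_atom: Dict[tuple, List[Optional[StateLiteral]]] = {}
    for l in sorted(set(alphabet), key=lambda x: x.sort_key()):
        by_atom.setdefault(l.atom, [None]).append(l)
    options = [by_atom[a] for a in sorted(by_atom)]
    worlds = [frozenset(l for l in combo if l is not None)
              for combo in itertools.product(*options)]
    worlds.sort(key=lambda w: (len(w), tuple(sorted(l.sort_key() for l in w))))
    return worlds


def program_alphabet(*programs: Program) -> FrozenSet[StateLiteral]:
    out = set()
    for p in programs:
        out.update(normalize(p).literals())
    return frozenset(out)


def iter_models(program: Program, bound: int,
                alphabet: Optional[Iterable[StateLiteral]] = None,
                node_budget: int = DEFAULT_NODE_BUDGET,
                world_order=None) -> Iterator[Tuple[World, ...]]:
    """Depth-first enumeration of every linear model with at most ``bound``
    worlds (over the program's literals unless ``alphabet`` is given) that
    satisfies the program's rules and observation spots.

    Rule violations are permanent along a path, so prefixes that already
    break a rule are pruned wholesale; spots are checked per emitted model.
    """
    p = normalize(program)
    worlds_pool = _candidate_worlds(alphabet if alphabet is not None
                                    else program_alphabet(program))
    if world_order is not None:
        worlds_pool = sorted(worlds_pool, key=world_order)
    rules = p.rules
    spot_lits = [s.observed for s in p.spots]
    budget = [node_budget]

    def rec(prefix: List[World], cause_before: List[bool],
            covered: List[bool]) -> Iterator[Tuple[World, ...]]:
        for w in worlds_pool:
            budget[0] -= 1
            if budget[0] < 0:
                raise ResourceGuardExceeded(
                    f"model enumeration exceeded {node_budget} nodes")
            prefix.append(w)
            ok = True
            i = len(prefix) - 1
            for ri, r in enumerate(rules):
                if not _rule_ok_at(prefix, i, r, cause_before[ri]):
                    ok = False
                    break
            if ok:
                new_cb = [cb or set_holds(w, r.cause) for cb, r in zip(cause_before, rules)]
                new_cov = [c or holds(w, l) for c, l in zip(covered, spot_lits)]
                if all(new_cov):
                    yield tuple(prefix)
                if len(prefix) < bound:
                    yield from rec(prefix, new_cb, new_cov)
            prefix.pop()

    yield from rec([], [False] * len(rules), [False] * len(spot_lits))


def observable(program: Program, bound: Optional[int] = None,
               node_budget: int = DEFAULT_NODE_BUDGET) -> bool:
    """Bounded satisfiability: does some linear model with at most ``bound``
    worlds (default: number of rules + 2) satisfy the program?  Candidate
    worlds that cover observation spots are explored first."""
    if variables_of(program):
        raise NotGroundError("observability is defined for ground programs only")
    p = normalize(program)
    if not p.spots:
        # closed-form witness: in the one-world empty model no (non-empty)
        # effect set holds, so every causal rule is vacuously satisfied
        return True
    if bound is None:
        bound = len(p.rules) + 2
    spot_lits = [s.observed for s in p.spots]

    def order(w: World) -> tuple:
        hits = sum(1 for l in spot_lits if holds(w, l))
        return (-hits, len(w), tuple(sorted(x.sort_key() for x in w)))

    for _ in iter_models(p, bound, node_budget=node_budget, world_order=order):
        return True
    return False


def behaviourally_includes(q: Program, p: Program, bound: Optional[int] = None,
                           node_budget: int = DEFAULT_NODE_BUDGET) -> bool:
    """Bounded behavioural inclusion: every linear model with at most
    ``bound`` worlds (default: |rules of q| + 2) over the union alphabet that
    satisfies ``q`` also satisfies ``p``.

    When ``p``'s rules and spots are textually contained in ``q``'s (after
    normalization) inclusion holds outright — any model satisfying all of
    ``q``'s constraints satisfies the subset that interprets ``p`` — and the
    enumeration is skipped.
    """
    for prog in (q, p):
        if variables_of(prog):
            raise NotGroundError("behavioural inclusion is defined for ground programs")
    qn, pn = normalize(q), normalize(p)
    if set(pn.rules) <= set(qn.rules) and set(pn.spots) <= set(qn.spots):
        return True
    if bound is None:
        bound = len(qn.rules) + 2
    alphabet = program_alphabet(q, p)
    for model in iter_models(qn, bound, alphabet=alphabet, node_budget=node_budget):
        if not satisfies(History(model), pn).ok:
            return False
    return True


def subsumption_check(strong: RuleKind, weak: RuleKind, bound: int,
                      node_budget: int = DEFAULT_NODE_BUDGET
                      ) -> Tuple[bool, Optional[History]]:
    """Enumerate every linear model up to ``bound`` worlds over the literals
    {c, e, !c, !e} and test whether each model satisfying the ``strong``
    primitive also satisfies the ``weak`` one; on failure the first
    counterexample model is returned."""
    if bound < 1:
        raise ValueError("bound must be >= 1")
    c, e = StateLiteral(_agent("C")), StateLiteral(_agent("E"))
    alphabet = [c, c.negated(), e, e.negated()]
    strong_p = Program((CausalRule(strong, frozenset([c]), frozenset([e])),))
    weak_r = CausalRule(weak, frozenset([c]), frozenset([e]))
    weak_p = Program((weak_r,))
    for model in iter_models(strong_p, bound, alphabet=alphabet, node_budget=node_budget):
        if not satisfies(History(model), weak_p).ok:
            return False, History(model)
    return True, None


def _agent(name: str):
    from .lang import AgentRef
    return AgentRef(name)


# --------------------------------------------------------------------------- #
# trace / division text formats (TSV trace, "a-b,c-d" divisions)


def parse_trace(text: str) -> Trace:
    """One instant per line; whitespace/tab-separated literal tokens in DSL
    literal syntax; ``-`` (or an empty line) denotes an instant with no
    recorded event."""
    from .parser import _parse_literal

    events = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        tokens = [t for t in line.split() if t != "-"]
        events.append(frozenset(_parse_literal(t, line_no) for t in tokens))
    while events and not events[-1] and len(events) > 1:
        events.pop()
    if not events:
        raise ParseError("empty trace")
    return Trace(tuple(events))


def parse_division(text: str) -> ChronologicalDivision:
    periods = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        a, sep, b = part.partition("-")
        try:
            periods.append((int(a), int(b if sep else a)))
        except ValueError as exc:
            raise DivisionError(f"malformed period {part!r}") from exc
    return ChronologicalDivision(tuple(periods))
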