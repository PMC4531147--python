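"""Abstract syntax of the causal behaviour language (CBL).

A program specifies an engineered biological function as *observations of
causal relations* between agent states, rather than as an explicit process
chain.  Agents are genes, proteins or signals; a **constant** agent names a
concrete part (``TetR_lite``, first letter upper-case) while a **variable**
agent (``g1``, lower-case) abstracts over a class of parts and is bound to a
constant by the compiler.

Causal relations come in three primitive strengths, read counterfactually
("if the effect is observed, the cause occurred"):

``->``   normal      — the cause held in some strictly earlier observation.
``o->``  persistent  — additionally, the cause still holds when the effect is
                       observed.
``+->``  remnant     — the effect either persists from the immediately
                       preceding observation or its cause appeared earlier.

Two macro relations, strong activation ``-+`` and strong inhibition ``--``,
expand into pairs of primitives (:func:`expand_macros`).  Rules can be scoped
by a *context* ``[k]{...}`` (a gating stimulus) and by *compartments*
``Name{...}`` (spatial locality).  :func:`normalize` rewrites a program into
the scope-free form the compiler and the semantics operate on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import FrozenSet, Iterable, Iterator, Optional, Sequence, Tuple, Union

from .errors import NotExpandedError, ValidationError

_IDENT_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*\Z")


@dataclass(frozen=True, order=True)
class AgentRef:
    """A named agent; its kind (constant/variable) is carried by the case of
    the first letter of its name."""

    name: str

    def __post_init__(self):
        if not _IDENT_RE.match(self.name):
            raise ValidationError(f"invalid agent name {self.name!r}")

    @property
    def is_constant(self) -> bool:
        return self.name[0].isupper()

    @property
    def is_variable(self) -> bool:
        return not self.is_constant

    @property
    def kind(self) -> str:
        return "constant" if self.is_constant else "variable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def const(name: str) -> AgentRef:
    a = AgentRef(name)
    if not a.is_constant:
        raise ValidationError(f"{name!r} is not a constant (must start upper-case)")
    return a


def var(name: str) -> AgentRef:
    a = AgentRef(name)
    if not a.is_variable:
        raise ValidationError(f"{name!r} is not a variable (must start lower-case)")
    return a


# --------------------------------------------------------------------------- #
# qualifiers


@dataclass(frozen=True)
class Label:
    """Symbolic activity level, declared in an attribute chain."""

    value: str

    def __post_init__(self):
        if not _IDENT_RE.match(self.value):
            raise ValidationError(f"invalid attribute label {self.value!r}")


@dataclass(frozen=True)
class Point:
    """Numeric activity level, e.g. a concentration measurement."""

    value: float


@dataclass(frozen=True)
class Interval:
    """Closed numeric range in which the agent is active."""

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValidationError(f"interval [{self.lo}, {self.hi}] has lo > hi")


Qualifier = Union[Label, Point, Interval, None]


def _qual_key(q: Qualifier) -> tuple:
    if q is None:
        return (0,)
    if isinstance(q, Label):
        return (1, q.value)
    if isinstance(q, Point):
        return (2, q.value)
    return (3, q.lo, q.hi)


@dataclass(frozen=True)
class StateLiteral:
    """One observable fact: an agent present (or absent), possibly at a given
    activity level, possibly localized to a compartment path."""

    agent: AgentRef
    positive: bool = True
    qualifier: Qualifier = None
    compartment: Tuple[str, ...] = ()

    def negated(self) -> "StateLiteral":
        return replace(self, positive=not self.positive)

    @property
    def atom(self) -> tuple:
        """Identity of the underlying fact, polarity stripped."""
        return (self.compartment, self.agent, _qual_key(self.qualifier))

    def sort_key(self) -> tuple:
        return (self.compartment, self.agent.name, not self.positive, _qual_key(self.qualifier))


def lit(name: str, positive: bool = True, qualifier: Qualifier = None) -> StateLiteral:
    return StateLiteral(AgentRef(name), positive, qualifier)


class RuleKind(Enum):
    NORMAL = "->"
    PERSISTENT = "o->"
    REMNANT = "+->"
    STRONG_ACT = "-+"
    STRONG_INH = "--"

    @property
    def is_primitive(self) -> bool:
        return self in (RuleKind.NORMAL, RuleKind.PERSISTENT, RuleKind.REMNANT)


PRIMITIVE_KINDS = (RuleKind.NORMAL, RuleKind.PERSISTENT, RuleKind.REMNANT)


@dataclass(frozen=True)
class Scope:
    """Nested gating contexts (outermost first) and compartment path."""

    contexts: Tuple[AgentRef, ...] = ()
    compartments: Tuple[str, ...] = ()

    @property
    def is_top(self) -> bool:
        return not self.contexts and not self.compartments


TOP = Scope()


@dataclass(frozen=True)
class CausalRule:
    kind: RuleKind
    cause: FrozenSet[StateLiteral]
    effect: FrozenSet[StateLiteral]
    scope: Scope = TOP

    def __post_init__(self):
        if not self.cause or not self.effect:
            raise ValidationError("cause and effect sets must be non-empty")
        object.__setattr__(self, "cause", frozenset(self.cause))
        object.__setattr__(self, "effect", frozenset(self.effect))

    def literals(self) -> Iterator[StateLiteral]:
        yield from self.cause
        yield from self.effect

    def sort_key(self) -> tuple:
        return (
            self.kind.value,
            tuple(sorted(l.sort_key() for l in self.cause)),
            tuple(sorted(l.sort_key() for l in self.effect)),
            self.scope.compartments,
            tuple(a.name for a in self.scope.contexts),
        )


def rule(kind: RuleKind, cause: Iterable[StateLiteral], effect: Iterable[StateLiteral],
         scope: Scope = TOP) -> CausalRule:
    return CausalRule(kind, frozenset(cause), frozenset(effect), scope)


@dataclass(frozen=True)
class AttributeDecl:
    """Declared activity levels of one agent: a strict capacity chain
    (least first) plus pairs of mutually incomparable levels."""

    agent: AgentRef
    chain: Tuple[str, ...] = ()
    unequal: FrozenSet[Tuple[str, str]] = frozenset()

    def __post_init__(self):
        if len(set(self.chain)) != len(self.chain):
            raise ValidationError(f"duplicate label in attribute chain of {self.agent}")
        norm = frozenset(tuple(sorted(p)) for p in self.unequal)
        object.__setattr__(self, "unequal", norm)
        order = {(a, b) for i, a in enumerate(self.chain) for b in self.chain[i + 1:]}
        for a, b in norm:
            if (a, b) in order or (b, a) in order:
                raise ValidationError(
                    f"labels {a!r},{b!r} of {self.agent} appear both ordered and unequal")

    @property
    def labels(self) -> FrozenSet[str]:
        return frozenset(self.chain) | frozenset(x for p in self.unequal for x in p)

    @property
    def n_attributes(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ObservationSpot:
    """A labelled literal that any validating experimental history must show."""

    label: str
    observed: StateLiteral


@dataclass(frozen=True)
class Program:
    """Ordered causal rules plus attribute declarations and observation spots.

    Declarations and spots are canonically sorted so that structural equality
    is set-like for them while rule order is preserved.
    """

    rules: Tuple[CausalRule, ...] = ()
    declarations: Tuple[AttributeDecl, ...] = ()
    spots: Tuple[ObservationSpot, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        decls = tuple(sorted(self.declarations, key=lambda d: d.agent.name))
        object.__setattr__(self, "declarations", decls)
        spots = tuple(sorted(self.spots, key=lambda s: s.label))
        object.__setattr__(self, "spots", spots)
        names = [d.agent.name for d in decls]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate attribute declaration")
        labels = [s.label for s in spots]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate observation spot label")
        declared = {d.agent.name: d.labels for d in decls}
        for l in self.literals():
            if l.agent.is_constant and isinstance(l.qualifier, Label):
                if l.qualifier.value not in declared.get(l.agent.name, frozenset()):
                    raise ValidationError(
                        f"constant {l.agent.name} used with undeclared "
                        f"attribute label {l.qualifier.value!r}")

    # -- traversal ---------------------------------------------------------- #

    def literals(self) -> Iterator[StateLiteral]:
        for r in self.rules:
            yield from r.literals()
        for s in self.spots:
            yield s.observed

    def decl_for(self, agent: AgentRef) -> Optional[AttributeDecl]:
        for d in self.declarations:
            if d.agent == agent:
                return d
        return None

    @property
    def is_expanded(self) -> bool:
        return all(r.kind.is_primitive for r in self.rules)

    @property
    def is_ground(self) -> bool:
        return not variables_of(self)

    def require_expanded(self):
        if not self.is_expanded:
            raise NotExpandedError("program contains unexpanded macro rules")


EMPTY_PROGRAM = Program()


def agents_of(p: Program) -> FrozenSet[AgentRef]:
    out = {l.agent for l in p.literals()}
    for r in p.rules:
        out.update(r.scope.contexts)
    return frozenset(out)


def variables_of(p: Program) -> FrozenSet[AgentRef]:
    """The variable agents occurring in any literal (or context) of ``p``."""
    return frozenset(a for a in agents_of(p) if a.is_variable)


def constants_of(p: Program) -> FrozenSet[AgentRef]:
    return frozenset(a for a in agents_of(p) if a.is_constant)


# --------------------------------------------------------------------------- #
# macro expansion and normalization


def _expand_one(r: CausalRule) -> Tuple[CausalRule, ...]:
    neg = lambda s: frozenset(l.negated() for l in s)
    if r.kind is RuleKind.STRONG_INH:
        # a -- b  =>  a o-> !b ; !a -> b
        return (
            CausalRule(RuleKind.PERSISTENT, r.cause, neg(r.effect), r.scope),
            CausalRule(RuleKind.NORMAL, neg(r.cause), r.effect, r.scope),
        )
    if r.kind is RuleKind.STRONG_ACT:
        # a -+ b  =>  a o-> b ; !a -> !b
        return (
            CausalRule(RuleKind.PERSISTENT, r.cause, r.effect, r.scope),
            CausalRule(RuleKind.NORMAL, neg(r.cause), neg(r.effect), r.scope),
        )
    return (r,)


def expand_macros(p: Program) -> Program:
    """Replace every strong activation/inhibition by its defining pair of
    primitive rules; idempotent on already-expanded programs."""
    out = []
    for r in p.rules:
        out.extend(_expand_one(r))
    return Program(tuple(out), p.declarations, p.spots)


def normalize(p: Program) -> Program:
    """Scope-free compiler form: macros expanded, each context agent folded
    into its rule's cause set, compartment paths pushed onto the literals."""
    p = expand_macros(p)
    out = []
    for r in p.rules:
        comp = r.scope.compartments
        tag = lambda s: frozenset(replace(l, compartment=comp + l.compartment) for l in s)
        cause = set(tag(r.cause))
        for k in r.scope.contexts:
            cause.add(StateLiteral(k, True, None, comp))
        out.append(CausalRule(r.kind, frozenset(cause), tag(r.effect), TOP))
    return Program(tuple(out), p.declarations, p.spots)
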