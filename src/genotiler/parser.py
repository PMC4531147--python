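"""Concrete textual dialect: parsing and canonical serialization.

The dialect is line-oriented (one declaration, rule or observation spot per
line); the full grammar ships in ``docs/grammar.ebnf``.  In short::

    Cro:{low<high}              # attribute declaration (chain and /~ pairs)
    Cro(low) -- CI(high)        # strong inhibition macro   (-+ : activation)
    g1 o-> !g2                  # persistent causal relation (->, +-> likewise)
    a & B(0.3) -> !C[0.1,0.4]   # literal sets joined with &, negation with !
    obs_1:: Cro(high)           # observation spot
    [k]{ ... }                  # context block, k gates the enclosed rules
    Cyto{ ... }                 # compartment block, rules become local

``parse_program`` and ``serialize_program`` are mutually inverse up to the
canonical ordering of declarations, spots and literal sets; rule order is
preserved exactly.
"""

from __future__ import annotations

import re
from typing import List, Tuple

from .errors import ParseError, ValidationError
from .lang import (AgentRef, AttributeDecl, CausalRule, Interval, Label,
                   ObservationSpot, Point, Program, Qualifier, RuleKind, Scope,
                   StateLiteral)

_ARROW_RE = re.compile(r"\s+(o->|\+->|-\+|--|->)\s+")
_DECL_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*)\s*:\s*\{(.*)\}\s*$")
_OBS_RE = re.compile(r"^obs_([A-Za-z0-9_]+)\s*::\s*(.+)$")
_CTX_OPEN_RE = re.compile(r"^\[\s*([A-Za-z][A-Za-z0-9_]*)\s*\]\s*\{\s*$")
_COMP_OPEN_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*)\s*\{\s*$")
_LIT_RE = re.compile(
    r"^(!)?([A-Za-z][A-Za-z0-9_]*)"
    r"(?:\(([^()]*)\)|\[\s*([^\[\],]+)\s*,\s*([^\[\],]+)\s*\])?$")
_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_IDENT_ONLY_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

_KIND_BY_TOKEN = {k.value: k for k in RuleKind}


def _parse_literal(text: str, line_no: int) -> StateLiteral:
    m = _LIT_RE.match(text.strip())
    if not m:
        raise ParseError(f"malformed literal {text.strip()!r}", line_no)
    bang, name, paren, lo, hi = m.groups()
    qual: Qualifier = None
    try:
        if paren is not None:
            paren = paren.strip()
            if not paren:
                raise ValidationError("empty qualifier")
            qual = Point(float(paren)) if _NUM_RE.match(paren) else Label(paren)
        elif lo is not None:
            if not (_NUM_RE.match(lo.strip()) and _NUM_RE.match(hi.strip())):
                raise ValidationError(f"interval bounds must be numeric in {text!r}")
            qual = Interval(float(lo), float(hi))
        return StateLiteral(AgentRef(name), bang is None, qual)
    except ValidationError as e:
        raise ParseError(str(e), line_no) from e


def _parse_literal_set(text: str, line_no: int) -> frozenset:
    parts = [p for p in (s.strip() for s in text.split("&")) if p]
    if not parts:
        raise ParseError("empty literal set", line_no)
    return frozenset(_parse_literal(p, line_no) for p in parts)


def _parse_decl(agent: str, body: str, line_no: int) -> AttributeDecl:
    chain: Tuple[str, ...] = ()
    unequal = set()
    for group in (g.strip() for g in body.split(",")):
        if not group:
            continue
        if "/~" in group:
            a, _, b = group.partition("/~")
            a, b = a.strip(), b.strip()
            if not a or not b:
                raise ParseError(f"malformed unequal pair {group!r}", line_no)
            unequal.add((a, b))
        elif "<" in group or _IDENT_ONLY_RE.match(group):
            if chain:
                raise ParseError("an attribute declaration may hold one chain only", line_no)
            chain = tuple(x.strip() for x in group.split("<"))
            if any(not x for x in chain):
                raise ParseError(f"malformed attribute chain {group!r}", line_no)
        else:
            raise ParseError(f"malformed attribute group {group!r}", line_no)
    try:
        return AttributeDecl(AgentRef(agent), chain, frozenset(unequal))
    except ValidationError as e:
        raise ParseError(str(e), line_no) from e


def parse_program(text: str) -> Program:
    """Parse DSL source into a :class:`~genotiler.lang.Program`.

    Raises :class:`~genotiler.errors.ParseError` with a line number on syntax
    errors, case-convention violations and undeclared attribute labels on
    constant agents.
    """
    rules: List[CausalRule] = []
    decls: List[AttributeDecl] = []
    spots: List[ObservationSpot] = []
    stack: List[tuple] = []  # ("ctx", AgentRef) | ("comp", str)

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line == "}":
            if not stack:
                raise ParseError("unbalanced '}'", line_no)
            stack.pop()
            continue
        m = _CTX_OPEN_RE.match(line)
        if m:
            stack.append(("ctx", AgentRef(m.group(1))))
            continue
        m = _OBS_RE.match(line)
        if m:
            if stack:
                raise ParseError("observation spots must be declared at top level", line_no)
            spots.append(ObservationSpot(m.group(1), _parse_literal(m.group(2), line_no)))
            continue
        m = _ARROW_RE.search(line)
        if m:
            kind = _KIND_BY_TOKEN[m.group(1)]
            lhs, rhs = line[:m.start()], line[m.end():]
            scope = Scope(
                contexts=tuple(a for t, a in stack if t == "ctx"),
                compartments=tuple(a for t, a in stack if t == "comp"),
            )
            try:
                rules.append(CausalRule(kind, _parse_literal_set(lhs, line_no),
                                        _parse_literal_set(rhs, line_no), scope))
            except ValidationError as e:
                raise ParseError(str(e), line_no) from e
            continue
        m = _DECL_RE.match(line)
        if m:
            decls.append(_parse_decl(m.group(1), m.group(2), line_no))
            continue
        m = _COMP_OPEN_RE.match(line)
        if m:
            stack.append(("comp", m.group(1)))
            continue
        raise ParseError(f"cannot parse line {line!r}", line_no)

    if stack:
        raise ParseError("unclosed scope block at end of input")
    try:
        return Program(tuple(rules), tuple(decls), tuple(spots))
    except ValidationError as e:
        raise ParseError(str(e)) from e


# --------------------------------------------------------------------------- #
# serialization


def _fmt_num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)


def format_literal(l: StateLiteral) -> str:
    q = l.qualifier
    if q is None:
        s = l.agent.name
    elif isinstance(q, Label):
        s = f"{l.agent.name}({q.value})"
    elif isinstance(q, Point):
        s = f"{l.agent.name}({_fmt_num(q.value)})"
    else:
        s = f"{l.agent.name}[{_fmt_num(q.lo)},{_fmt_num(q.hi)}]"
    return s if l.positive else "!" + s


def _fmt_set(lits) -> str:
    return " & ".join(format_literal(l) for l in sorted(lits, key=lambda x: x.sort_key()))


def _fmt_decl(d: AttributeDecl) -> str:
    groups = []
    if d.chain:
        groups.append("<".join(d.chain))
    groups.extend(f"{a}/~{b}" for a, b in sorted(d.unequal))
    return f"{d.agent.name}:{{{', '.join(groups)}}}"


def _rule_emit_scope(r: CausalRule) -> Tuple[Scope, CausalRule]:
    """Scope under which to print a rule.

    Normalized rules carry their compartment on the literals instead of the
    scope; recover it so the assembly of a compilation result still prints as
    nested blocks, stripping the tags for the printed literals.
    """
    if not r.scope.is_top:
        return r.scope, r
    comps = {l.compartment for l in r.literals()}
    if len(comps) == 1 and () not in comps:
        comp = next(iter(comps))
        strip = lambda s: frozenset(
            StateLiteral(l.agent, l.positive, l.qualifier, ()) for l in s)
        return Scope((), comp), CausalRule(r.kind, strip(r.cause), strip(r.effect))
    return r.scope, r


def serialize_program(p: Program) -> str:
    """Canonical DSL text; ``parse_program`` of the result reproduces ``p``
    (for normalized programs, up to re-normalization of compartment tags)."""
    lines: List[str] = [_fmt_decl(d) for d in p.declarations]
    open_chain: List[tuple] = []
    for r in p.rules:
        scope, r = _rule_emit_scope(r)
        chain = [("ctx", a) for a in scope.contexts] + [("comp", c) for c in scope.compartments]
        k = 0
        while k < len(open_chain) and k < len(chain) and open_chain[k] == chain[k]:
            k += 1
        for _ in range(len(open_chain) - k):
            open_chain.pop()
            lines.append("}")
        for entry in chain[k:]:
            lines.append(f"[{entry[1].name}]{{" if entry[0] == "ctx" else f"{entry[1]}{{")
            open_chain.append(entry)
        lines.append(f"{_fmt_set(r.cause)} {r.kind.value} {_fmt_set(r.effect)}")
    while open_chain:
        open_chain.pop()
        lines.append("}")
    lines.extend(f"obs_{s.label}:: {format_literal(s.observed)}" for s in p.spots)
    return "\n".join(lines) + ("\n" if lines else "")
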