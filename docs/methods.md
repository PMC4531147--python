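# Methods

This note records the scientific and numerical choices behind `genotiler`:
the semantics the compiler certifies against, the matching calculus, the
search machinery, the synthetic benchmark, and the places where the design
was genuinely open.

## Language and normal form

A program is a sequence of causal rules plus attribute declarations and
observation spots (`docs/grammar.ebnf` has the concrete grammar). Cause and
effect are *sets* of state literals; a set holds in a world when all of its
literals do. Before any semantic or matching operation a program is put in
a scope-free **normal form**: macros are expanded, each gating context
agent `[k]` is folded into its rules' cause sets as a presence literal, and
compartment paths are pushed onto the literals so that a compartment-local
fact is a different atom from its top-level namesake. This is the minimal
reading of "triggered only if the context is present" and "making rules
local": contexts behave like extra causes, compartments partition the
alphabet (literals in different compartments never co-unify and never
discharge one another).

Macro orientation: strong inhibition `a -- b` expands to
`{a o-> !b, !a -> b}` and strong activation `a -+ b` to
`{a o-> b, !a -> !b}`. The persistent half carries the positive trigger;
this matches the shape of the worked repressor-ring rules (cause positive,
effect negated, persistent). The other printed orientation of the
inhibition macro is a notational variant; the choice is a convention and is
fixed here once.

Attribute declarations may hold one capacity chain and any number of
incomparable (`/~`) pairs; a label may not appear in both (the overlap is
rejected rather than silently ordered).

## Satisfaction on linear models

Histories are linear Kripke models; satisfaction of a rule scans the path
once, caching whether the cause set has held strictly earlier:

* **normal** — every world where the effect set holds is preceded by a
  strictly earlier world where the cause set holds ("recent past" is read
  as unbounded).
* **persistent** — normal, plus the cause set holds in the effect's world.
* **remnant** — every effect world is discharged either by the effect set
  holding in the immediately preceding world (the carried-over reading) or
  by the cause set holding in *some* strictly earlier world; an effect in
  the first world requires the cause co-present there.

The remnant cause-disjunct is deliberately unbounded, like normal's: with a
one-step cause window the strength chain *persistent ⇒ normal ⇒ remnant*
would fail (a model placing the cause two worlds before the effect
satisfies normal but not the one-step reading). The chain is the anchor
property of the three primitives and is verified exhaustively by
`subsumption_check` at every bound ≤ 6 over `{c, e, !c, !e}`.

Negative literals are explicit facts: `!X` holds only where it is recorded
(observed absence), not wherever `X` is missing — histories are partial
observations, not complete states. Positive bare literals are discharged by
any observation of the agent; negative literals match on the exact
qualifier. Numerically, a point discharges an interval when inside it and
an interval discharges a wider one when contained ("active in this
concentration range").

## Observability and behavioural inclusion

Both are **bounded** procedures, documented as such (no tableau prover, no
unbounded satisfiability): worlds are built from the programs' own literals
(each underlying fact asserted, denied or absent), paths are enumerated
depth-first up to a world bound (default: rule count + 2), and prefixes
that already violate a rule are pruned — rule violations are permanent
along a path, only observation spots need the full model. Two closed-form
cases are decided without enumeration, both theorems of the satisfaction
relation above: a spot-free program is always observable (in the one-world
empty model no non-empty effect set holds, so every rule is vacuous), and
`Q` behaviourally includes `P` whenever `P`'s rules and spots are textually
contained in `Q`'s (any model meeting all of `Q`'s constraints meets the
subset interpreting `P`). The enumeration fallback carries a node budget
(default 2·10⁶) and raises rather than silently truncating.

## Matching calculus

Unification is **textual modulo ACI**: a goal rule unifies with a component
rule when a substitution makes them equal — same primitive kind, same
compartment, cause and effect sets in bijection — with assembly
associative, commutative and idempotent (results are canonical under
permutation and duplication of the candidate tuple, which is treated as a
component *set*; "components used" are those hosting at least one goal
rule). Substitutions are injective on the goal's variables and never map a
variable to a constant already occurring in the goal: a variable abstracts
a part *distinct* from every named one (non-injective substitutions would
collapse the repressor ring). Rule-level equality rather than sub-literal
embedding is what makes the calculus sound: a component rule with a strictly
larger effect set does not behaviourally include the smaller rule (a model
may show one effect literal alone and owe nothing), whereas with equality
the assembly textually contains the substituted goal and inclusion holds by
construction. It also makes the occurrence-count pre-filters genuinely
conservative (distinct goal rules have distinct substituted images, hence
distinct hosts).

The two pre-filters are necessary conditions only. Local causal
association keeps the printed `≥`-cardinality form (a component rule may be
bigger and still fail later at unification — the filter is allowed to
over-approximate, never to under-approximate). Agent constraints are
refined per side: constants are counted separately as causes and as
effects over the *distinct* rules of goal and subset union, and each
variable needs an admissible fresh constant meeting both side counts with
compatible attribute order (chain embeds as a subsequence) and count. The
per-side refinement is what eliminates the subsets whose constants appear
on only one side of the relation.

A brute-force oracle (enumerate every injective fresh substitution over the
library's constants, then every per-rule hosting assignment, no filters)
serves as the independent reference; pipeline-equals-oracle is asserted on
a 200-instance random matrix. The oracle is restricted to goals without
variable attribute declarations (the pipeline additionally checks
declaration compatibility, which the textual oracle cannot see); the
benchmark generator produces exactly that class.

## Search

Libraries up to `exhaustive_threshold` (default 12) components — and
pre-filter populations up to `exhaustive_cap` (default 10⁵) — are compiled
by full enumeration of candidate tuples. Beyond that a directed GA runs
with conventional defaults, all exposed in `SearchConfig`: population 50,
tournament 3, one-point crossover 0.8, per-gene mutation 0.1, at most 200
generations or 20 stagnant ones, elitism 1, mandatory seed. Genes are drawn
only from each rule's association set and offspring failing the agent
constraints are rejected and redrawn (up to 10 attempts) — the
"directedness" that keeps the search inside the space the filters admit.
Fitness is lexicographic: feasibility, then rules unified (maximized), then
distinct components used (minimized); the partial-cover count is a capped
backtracking maximum (20 000 nodes per evaluation), since infeasible
individuals still need a gradient. Evaluations are cached per component
set — an optimization, not a semantic change. Every GA solution is
re-verified by full unification plus observability, so the evolutionary
stage can only ever return a subset of what exhaustion would.

## Synthetic benchmark

The generator emulates compiler benchmarking at scale: libraries of
`n_components` (default 100) random ground components over a pool of
`n_constants` agents, rule kinds uniform over the three primitives,
cause/effect sizes 1–2, literal polarity negative with rate 0.3 (the
distributions are documented defaults, not claims about any particular
catalogue); goals copy `n_goal_rules` (default 10) distinct rules from
randomly selected components and abstract `n_variables` constants into
fresh variables, renaming every occurrence so the freshness rule is
respected by construction. The inverse renaming witnesses solvability, so
compile success is guaranteed in principle; the GA is asserted to find a
solution on every seeded grid cell. What the generator does **not**
emulate: attribute declarations and numeric levels on random parts,
contexts/compartments, observation spots, or any biological plausibility of
the random wiring — passing these tests shows the search machinery scales
and stays sound, not that real catalogues behave like uniform random ones.

Effort is reported in search counters (candidate subsets examined,
unification nodes, GA evaluations), never seconds, so the scaling claims
are hardware-independent; the acceptance run asserts a positive Spearman
trend of mean effort in the number of variables and no comparable growth in
the constant-pool size. Desk-scale problem sizes throughout (five-component
worked example, ≤5-component oracle instances, 100-component GA grids with
10 seeds per cell) are the package's chosen test scale.

## Known limitations

* Inclusion and observability are bounded checks: a `True` at bound *b*
  certifies all linear models with ≤ *b* worlds, nothing beyond.
* Multiple histories are checked independently; gathering several partial
  histories into one richer model is future work.
* Whether observability must hold at every intermediate assembly step or
  only for the final device is not semantically forced; the implementation
  checks every step (stricter, and what `assemble` documents).
* No rewriting of behaviours into equivalent alternates when no component
  matches textually; no DNA-level output, SBOL import/export, or diagram
  rendering.
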