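# genotiler

A behavioural specification language and component-selection compiler for
synthetic genetic circuits.

Synthetic-biology designers increasingly want to state *what a construct
should do* — the observations an experiment must exhibit — and leave the
choice of concrete parts to software. `genotiler` implements that workflow:
a program describes the expected behaviour of a function as **causal
relations between agent states**, a part library describes each available
component the same way, and the compiler selects and assembles components
whose collective described behaviour *covers* the programmed one.

## The model

A program is a set of attribute declarations, observation spots and causal
relations over *agents* (genes, proteins, signals). A **constant** agent
(`TetR_lite`) names a concrete part; a **variable** agent (`g1`) abstracts a
class of parts for the compiler to instantiate. Literals assert presence
(`Cro`), absence (`!Cro`), a symbolic activity level (`Cro(low)`, levels
ordered by a declared capacity chain `Cro:{low<high}`), or a numeric one
(`LacI(0.3)`, `LacI[0.1,0.4]`). Causal relations come in three
counterfactual strengths, interpreted over *linear Kripke models* — the
histories obtained by dividing an experimental trace into periods:

| relation | reading on a history `w_1 .. w_n` |
|---|---|
| `c -> e` (normal) | every world showing `e` has a strictly earlier world showing `c` |
| `c o-> e` (persistent) | as normal, and `c` also holds in `e`'s world |
| `c +-> e` (remnant) | `e` either persists from the preceding world or some earlier world showed `c` |

These give the strength chain *persistent ⇒ normal ⇒ remnant*, which the
package verifies by exhaustive bounded enumeration. Macros `a -+ b` (strong
activation) and `a -- b` (strong inhibition) expand to pairs of primitives;
contexts `[k]{…}` gate rules on a stimulus and compartments `Name{…}` make
them local.

Compilation is behaviour tiling. A device `Q = {Q_j}` *behaviourally
includes* a program `P` under substitution `σ` when every model of `Q`'s
interpretation is a model of `P[σ]`'s (`Q ⊢_σ P[σ]`). The compiler realises
this with a functional-synthesis calculus (instantiation of a part of a
component; commutativity, contraction and assembly of partial syntheses,
with an *observability* — bounded satisfiability — check on every
assembly), implemented as an ACI-unification: goal rules are matched
textually, modulo associativity/commutativity/idempotence of assembly, to
component rules, binding variables injectively to constants that do not
already occur in the goal. Two conservative pre-filters (per-rule *local
causal association* and subset-level *agent constraints*) prune candidates
that provably cannot unify, and for libraries too large to enumerate a
*directed evolutionary search* — individuals are per-rule component
choices, bred only within the filtered space — takes over.

## Worked example

The classic three-gene repressor ring, with two genes left abstract:

```python
import genotiler as gt

fx = gt.fixtures()
goal, lib = fx["repressilator_goal"], fx["repressilator_lib5"]
print(gt.serialize_program(goal))
report = gt.compile(goal, lib, gt.SearchConfig(seed=0))
sol = report.solutions[0]
print(sol.components, sol.substitution.as_dict())
```

prints

```
g1 o-> !g2
g2 o-> !TetR_lite
TetR_lite o-> !g1

('Q1', 'Q2', 'Q3') {'g1': 'CI', 'g2': 'LacI'}
```

The staged run (`python examples/compile_repressilator.py`) shows the whole
selection narrative: rule 1 associates with all five library parts, rule 2
only with `Q1` (the only part repressing `TetR_lite`), rule 3 with
`{Q3, Q4}`; the pre-filter population holds 10 candidate triples, the agent
constraints leave `{(Q2,Q1,Q3), (Q2,Q1,Q4)}`, unification rejects
`(Q2,Q1,Q4)` (the variable `g1` would need two different constants), and the
unique solution instantiates `g1 ↦ CI`, `g2 ↦ LacI` — the biological
repressilator. The same pipeline is available from the shell:

```
genotiler compile goal.cbl library.xml --seed 1 --out report.json
genotiler check program.cbl trace.tsv --periods 1-2,3-5,6-6
genotiler bench --n-components 50 --variables 1-4
genotiler validate-lib library.xml
```

Each script in `examples/` demonstrates one capability (staged compilation,
trace checking, the subsumption chain, macro expansion and observability,
benchmark scaling) and prints what the numbers mean.

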