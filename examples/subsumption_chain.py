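"""The strength chain of the three causal primitives, checked by exhaustive
enumeration of linear models.

Persistent causality (cause still present with the effect) is stronger than
normal causality (cause strictly earlier), which is stronger than remnant
causality (effect carried over, or a cause that appeared before).
"""

import genotiler as gt
from genotiler.lang import RuleKind

for strong, weak in ((RuleKind.PERSISTENT, RuleKind.NORMAL),
                     (RuleKind.NORMAL, RuleKind.REMNANT),
                     (RuleKind.PERSISTENT, RuleKind.REMNANT)):
    ok, _ = gt.subsumption_check(strong, weak, bound=4)
    print(f"every model of 'C {strong.value} E' satisfies "
          f"'C {weak.value} E' (4 worlds): {ok}")

ok, witness = gt.subsumption_check(RuleKind.REMNANT, RuleKind.PERSISTENT, bound=3)
print("\nremnant implies persistent:", ok)
print("separating witness:",
      [sorted(gt.format_literal(l) for l in w) for w in witness.worlds])
# In the witness the effect persists from one world to the next without its
# cause being co-present, which remnant causality tolerates and persistent
# causality forbids.
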