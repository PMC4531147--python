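"""The lysis/lysogeny switch of phage lambda: macros and observability.

Two strong-inhibition macros (Cro at low level suppresses CI at high level,
and vice versa) expand into four primitive relations; three observation
spots demand that both Cro levels and the low CI level actually show up in
some feasible experiment.
"""

import genotiler as gt

lam = gt.fixtures()["lambda_switch"]
print("surface program:")
print(gt.serialize_program(lam))

expanded = gt.expand_macros(lam)
print(f"after macro expansion: {len(expanded.rules)} primitive rules")
for r in expanded.rules:
    one = gt.Program((r,), expanded.declarations)      # keep the label decls
    print("  ", gt.serialize_program(one).splitlines()[-1])

print("\nobservable within 6 worlds:", gt.observable(expanded, 6))
# True: some bounded linear model realises all three observation spots while
# respecting every causal relation, i.e. the switch's described behaviour is
# not self-contradictory.
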