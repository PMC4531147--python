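"""Validate a program against an experimental trace.

A six-instant trace of one gene climbing from Low to High is collapsed by a
chronological division into a three-event history, which is then checked
against a program demanding that each level causally precedes the next.
"""

import genotiler as gt

fx = gt.fixtures()
trace, division = fx["eq1_trace"], fx["eq1_division"]

history = gt.extract_history(trace, division)
print(f"trace: {len(trace)} instants; division {division.periods}")
print("history worlds:",
      [sorted(gt.format_literal(l) for l in w) for w in history.worlds])

program = gt.parse_program(
    "G:{Low<Mid<High}\n"
    "G(Low) -> G(Mid)\n"
    "G(Mid) -> G(High)\n")
report = gt.satisfies(history.to_model(), program)
print("program satisfied:", report.ok)
# The three milestone events Low, Mid, High appear in causal order, so both
# normal causal relations hold: each effect world is preceded by its cause.

broken = gt.parse_program("G:{Low<Mid<High}\nG(High) -> G(Low)\n")
report = gt.satisfies(history.to_model(), broken)
print("reversed causality satisfied:", report.ok,
      "-", report.failures[0].message)
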