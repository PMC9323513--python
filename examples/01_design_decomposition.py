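"""Decompose multi-phase designs into adjacent AB comparisons.

A modified withdrawal/reversal design such as ABCAC is analysed one
adjacent phase pair at a time; each pair becomes a standalone blinded
AB graph per dependent variable.
"""

from sced import build_phase_comparisons

designs = {"ABCAC": 2, "ABCDEAE": 3, "ABCDEFAF": 1}
n_variables = 6

total_pairs = 0
for design, count in designs.items():
    comps = build_phase_comparisons(design)
    total_pairs += len(comps) * count
    print(f"{design}: {[c.label for c in comps]}  x {count} participant(s)")

print(f"\nadjacent phase pairs across all evaluations: {total_pairs}")
print(f"AB graphs with {n_variables} variables per comparison: {total_pairs * n_variables}")
# 33 adjacent pairs -> 198 AB graphs: the unit count every later stage
# (CDC, classifier, rater panel) operates on.
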