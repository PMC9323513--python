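"""Apply the conservative dual-criteria method to two small graphs.

The CDC method projects the baseline mean and trend lines (shifted by
0.25 baseline SD toward the expected change) into phase B and asks
whether a binomially improbable number of points clears both.
"""

from sced import ABGraph, cdc_decision

# A flat baseline followed by a clear level shift upward.
clear = ABGraph("clear-shift", phase_a=[2, 2, 2], phase_b=[5, 5, 5, 5, 5], direction=1)
res = cdc_decision(clear)
print(f"{res.id}: {res.n_beyond}/{len(clear.phase_b)} points beyond both lines, "
      f"cutoff {res.cutoff} -> effect={res.effect}")

# The same phase-B data, but the baseline was already rising steeply:
# the projected trend line overtakes phase B, so no effect is declared.
trending = ABGraph("rising-baseline", phase_a=[2, 4, 6], phase_b=[5, 5, 5, 5, 5], direction=1)
res = cdc_decision(trending)
print(f"{res.id}: trend line projects to {[round(float(v), 1) for v in res.trend_line]}")
print(f"{res.id}: {res.n_beyond} points beyond -> effect={res.effect}")
# The trend criterion is what protects the method against mistaking a
# pre-existing baseline trajectory for a treatment effect.
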