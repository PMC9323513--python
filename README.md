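# sced

Objective analysis of single-case AB phase comparisons.

Behaviour analysts evaluate single-case experimental designs (SCEDs) —
repeated measurements of one subject across baseline and treatment
phases — mostly by visual inspection, which is known to be unreliable
between raters. This package implements the objective decision aids
used alongside visual inspection and the analytics used to study their
agreement with raters:

- **Design decomposition** — a multi-phase withdrawal/reversal design
  (ABCAC, ABCDEAE, …) is split into adjacent phase pairs, each a
  standalone blinded AB comparison with an expected direction of change
  (+1 increase, −1 decrease).
- **Conservative dual-criteria (CDC) method** — projects the baseline
  mean and OLS trend lines into phase B, shifts both by 0.25 baseline
  SD toward the expected change, and declares an effect when the number
  of phase-B points beyond *both* lines reaches the Binomial(n_B, ½)
  cutoff at α = .05.
- **Support-vector classifier** — reduces each graph to eight features
  of its pooled, direction-adjusted z-scores (per-phase mean, SD,
  intercept, slope ↔ level, variability, immediacy, trend) and reports
  a calibrated probability of a clear change; P ≥ 0.5 counts as a
  change. Trained on a synthetic corpus with known ground truth.
- **Agreement analytics** — pairwise percent agreement, Cohen's κ with
  Landis–Koch interpretation, Spearman ρ between 0–10 confidence
  scores and classifier probabilities, agreement stratified by the
  method's effect call, majority-vote (k-of-m) disagreement grouping,
  and phase-length tabulation of the groups.
- **Synthetic data** — AR(1)-plus-trend AB graphs with standardized
  effect sizes and simulated rater panels (class-specific error rates,
  0–10 scores consistent with the 4/5 yes/no boundary), so the whole
  pipeline is testable without clinical data.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from sced import ABGraph, cdc_decision

# flat baseline, clear upward shift
clear = ABGraph("clear-shift", phase_a=[2, 2, 2], phase_b=[5, 5, 5, 5, 5], direction=1)
res = cdc_decision(clear)
print(res.n_beyond, res.cutoff, res.effect)
# 5 5 True  — all five B points clear both lines; 5 of 5 beats the
#            binomial cutoff (P(X>=5) = 1/32 < .05), so: effect.

# same B data, but the baseline was already rising
trending = ABGraph("rising-baseline", phase_a=[2, 4, 6], phase_b=[5, 5, 5, 5, 5], direction=1)
res = cdc_decision(trending)
print([round(float(v), 1) for v in res.trend_line], res.effect)
# [8.5, 10.5, 12.5, 14.5, 16.5] False — the projected trend line
# overtakes phase B, so the shift is explained by the baseline trend.
```

A full synthetic agreement study (`python examples/04_agreement_study.py`)
generates 198 AB graphs at 35% effect prevalence, simulates five raters
with 10% error rates, runs both objective methods and prints:

```
mean interrater agreement: 83.8% (kappa 0.65, substantial)
CDC vs raters: 82.8% (kappa 0.59)
SVC vs raters: 88.1% (kappa 0.74)
CDC effect rate: 24.2%, SVC effect rate: 33.3%
visual consensus (>=4 of 5 raters) on 184 graphs; CDC disagrees with that consensus on 18, SVC on 6
```

i.e. the objective methods agree with the simulated panel about as
often as the raters agree among themselves — the qualitative pattern
the analytics are built to measure. The other scripts in `examples/`
cover design decomposition, single CDC decisions, and classifier
training/evaluation.

A thin CLI mirrors the pipeline stages
(`sced simulate | construct | cdc | train | classify | agree | render`);
run `sced --help`.

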