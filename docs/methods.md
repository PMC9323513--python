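# Methods

`sced` implements the objective-analysis side of single-case
experimental design (SCED) evaluation: given repeated measurements of a
behaviour across adjacent phases, decide whether the second phase shows
a clear change in the expected direction, and quantify how well such
decisions agree — between human raters, and between raters and two
objective methods.

## The unit of analysis

A multi-phase withdrawal/reversal design (e.g. ABCAC) is decomposed
into its adjacent phase pairs, each rendered as a standalone AB
comparison: `phase_a` (first phase), `phase_b` (second phase), and an
expected direction `d ∈ {+1, −1}` (+1 when the treatment should
increase the behaviour). Occurrence indexing (A1, A2, …) keeps
reversals unambiguous. Phase A needs at least 2 points (a trend must be
fit); phases shorter than 3 points trigger an advisory warning because
they are below what clinical series typically contain.

Direction for comparisons that *enter* a baseline (treatment
withdrawn, e.g. C1→A2) is a data decision: behaviour is usually
expected to move against the treatment direction there, and the helper
`baseline_return_direction` applies exactly that flip, but the reader
never applies it implicitly because conventions vary across datasets.

## Conservative dual-criteria (CDC) decisions

From the raw phase-A values the method fits the mean `m`, sample
standard deviation `s` (n−1 denominator throughout the package), and an
OLS trend `a + b·t` against session index `t = 1..nA`. Both lines are
projected over the phase-B sessions `t = nA+1..nA+nB` and shifted by
`d · 0.25 · s` — toward the expected change, which makes the test more
conservative. A phase-B point counts only if it is *strictly* beyond
both lines in the expected direction; points exactly on a line do not
count.

The count is compared with a cutoff from Binomial(nB, ½): under the
null that phase B continues the baseline process, each point is equally
likely to fall on either side of a projected line. Two conventions are
provided:

- `strict` (default): smallest k with P(X ≥ k) < α. For α = .05 no
  such k exists when nB ≤ 4, so the sentinel nB + 1 is returned and an
  effect is unattainable on very short phases.
- `quantile`: smallest k with CDF(k) ≥ 1 − α (the binomial quantile),
  which permits effects on phases as short as 3 points. Provided
  because short clinical phases are common and published cutoff tables
  differ in exactly this regime.

Defaults: `shift_multiplier = 0.25`, `alpha = 0.05`. Setting the shift
to 0 recovers the plain dual-criteria variant (exposed, not studied).
Under the default null simulation (iid Gaussian noise, no trend,
nB ∈ [5, 15], 2000 graphs) the empirical type-I rate is ≈ 1–2%, well
below α — the 0.25·SD shift is what buys the conservatism.

## The 8-feature support-vector classifier

Each graph is standardized: pooled over both phases,
`z_t = d · (x_t − mean) / sd`. The z-scores are dimensionless and
invariant to positive affine transforms of the raw series, so the
classifier never sees the measurement scale; multiplying by `d` mirrors
decrease-direction graphs so improvement is always "up". A constant
raw series maps to all-zero z-scores (the all-equal check is done on
values, not on `sd == 0`, because the mean of identical floats can be
one ulp off).

Eight features are extracted, in fixed order A before B, and per phase
mean, sd, intercept, slope. They correspond to what a visual inspector
attends to: level change (mean), variability (sd), immediacy of change
(intercept), trend (slope). Per-phase OLS regresses z on the
*graph-wide* session index (phase B on nA+1..nA+nB); the intercept is
reported at the phase's first session, so it measures the fitted level
where the phase begins rather than an extrapolation back to session 0.
Single-point phases get slope 0 and intercept equal to the point.

The classifier is an RBF-kernel SVC (C = 1, gamma = "scale") behind a
StandardScaler, with probabilities from Platt (sigmoid) calibration via
5-fold cross-validated calibration (`ensemble=False`). These
hyperparameters are package defaults, visible in `ClassifierConfig`;
they are not asserted to match any previously published model, whose
weights are not available. Probabilities ≥ 0.5 (inclusive) are a
"clear change". No pre-trained weights ship: training draws a
synthetic corpus (default 2000 graphs, balanced classes) from the
generator below, holds out 20% for an accuracy estimate, and records
the full training descriptor (generator config, size, seed,
calibration method) in a provenance sidecar, so any fitted model can be
reproduced exactly or replaced by externally supplied weights.

## Agreement analytics

- Percent agreement: share of graphs with identical binary labels.
- Cohen's kappa: (p_o − p_e)/(1 − p_e) with product-of-marginals p_e;
  when both raters are constant and identical (p_e = 1) kappa is
  defined as 1. Implemented directly to control this edge case and
  cross-checked against scikit-learn in the tests.
- Landis–Koch bands are closed on their printed two-decimal bounds
  (0.20 → "slight", 0.21 → "fair"); unrounded values between bounds
  fall upward (0.205 → "fair"). Negative kappa is "poor (below
  chance)".
- Spearman rho (scipy, average ranks for ties) relates 0–10 confidence
  scores to classifier probabilities; the CDC method produces no
  probability and is excluded. Constant inputs yield NaN ("undefined")
  and are excluded from means.
- Interrater summaries average over all rater *pairs* (10 pairs for 5
  raters), unweighted; a per-rater averaging alternative is also
  computed since reported means in the literature rarely state the
  scheme.
- Stratified agreement splits each rater's agreement with a method by
  the method's own effect/no-effect call; empty strata are NaN.
- Majority grouping: graphs where ≥ k of m raters concur (default
  k = 4 of 5) form the visual-agreement group, the rest the
  disagreement group; within the agreement group, graphs where the CDC
  (resp. SVC) decision differs from the rater majority form the method
  disagreement subsets. k must exceed m/2; exact even splits (even m)
  are flagged `no_majority`.
- Phase-length tabulation bins each group's graphs by phase length
  (exactly 3, 4–5, 6–9, 10+ for phase A and B separately; lengths
  below 3 fold into the first bin). Nonempty rows sum to 1.

## Synthetic data: what it emulates and what it does not

The generator produces baseline series
`x_t = level + trend·t + e_t`, with AR(1) noise
`e_t = φ·e_{t−1} + w_t` started from its stationary distribution. With
probability `effect_prob` the graph has a true effect: every phase-B
point is shifted by `d·σ·(size + slope_change·j)` where σ is the
stationary noise sd, `size ~ U(effect_size_range)` and `j` counts
sessions since the phase change — so effect sizes are standardized
shifts and CDC power curves are interpretable. With probability
`flat_equal_prob` the graph is instead two flat lines of equal level
(a behaviour that never occurs), labelled no-effect.

Defaults: phase lengths uniform on 3–20 (both phases), level 10, no
baseline trend, noise sd 1, φ = 0.2, effect sizes 1–4 σ, slope change
0–0.2 σ/session, flat-equal probability 0.05, balanced directions, and
balanced classes (effect_prob 0.5) because the primary consumer of the
default configuration is classifier training. An optional clip layer
(off by default) imposes metric realism such as percentage bounds;
it is off so that the affine-invariance properties hold exactly in
tests.

Simulated raters flip the ground truth with class-specific false
positive/negative rates (default 0.1 each — a rate that yields pairwise
agreement `ε² + (1−ε)² ≈ 0.82`, the neighbourhood reported for expert
panels) and draw a 0–10 score on the side of the 4/5 boundary
consistent with the emitted label, at Beta(c, 1)-distributed distance
from the boundary (c = `score_concentration`, default 2).

What this generator does **not** emulate: response-guided stopping
(clinicians end phases when data stabilize, which concentrates clinical
phase lengths at 3 and correlates length with stability), floor/ceiling
effects of bounded metrics (unless clipping is enabled), extinction
bursts, and rater errors that depend on graph difficulty rather than
class alone. Passing tests therefore show the pipeline is correct and
well-behaved under a plausible data-generating family, not that its
agreement levels transfer to any particular clinical population.

## Numerical and design choices

- Sample (n−1) sd everywhere; session indices restart at 1 per graph.
- OLS via `np.polyfit`; no robust fitting (the decision methods under
  study are defined on OLS-style lines).
- Tie-breaks: points exactly on a criterion line never count; the
  probability threshold 0.5 is inclusive ("≥").
- Determinism: every stochastic component takes a seed or a
  `numpy.random.Generator`; fixed seeds reproduce corpora, panels and
  trained models bit-for-bit.
- Degenerate inputs: constant graphs → zero features and (with zero
  baseline sd) unshifted criterion lines; single-label training
  corpora, empty phases, and out-of-range scores raise; inconsistent
  label/score pairs are logged, not fatal.

## Problem sizes

The test suite and acceptance script use 198-graph study emulations,
2000-graph null and training corpora, and 1000-graph evaluation sets —
sizes at which the binomial sampling error of the quantities checked is
comfortably inside the asserted bounds while the whole suite runs in
well under a minute of compute per stage.

## Known limitations

- Agreement with simulated raters measures internal consistency of the
  pipeline, not validity against human judgment.
- The classifier's reported operating characteristics are specific to
  the synthetic family; no claim is made about the published
  pre-trained model it structurally mirrors.
- Only the support vector classifier is implemented; no other
  algorithm families, no weighted kappa, no confidence intervals on
  kappa.
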