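"""Train the support-vector classifier and classify new graphs.

The classifier reduces each graph to eight features of the pooled,
direction-adjusted z-scores (per-phase mean, sd, intercept, slope) and
reports the probability of a clear change; 0.5 or above counts as a
change.
"""

import dataclasses

from sced import ABGraph, ClassifierConfig, SynthConfig, classify, generate_dataset, train_classifier

model = train_classifier(ClassifierConfig())
print(f"held-out accuracy on the synthetic training corpus: "
      f"{model.provenance['holdout_accuracy']:.3f}")

# A graph with an obvious upward shift, and a flat no-change graph.
shifted = ABGraph("shifted", [3, 4, 3, 4], [9, 10, 9, 10, 9], direction=1)
flat = ABGraph("flat", [5, 5, 5, 5], [5, 5, 5, 5, 5], direction=1)
for g in (shifted, flat):
    d = classify(model, g)
    print(f"{d.id}: P(clear change) = {d.probability:.3f} -> change={d.change}")

# Accuracy on fresh graphs with a 2-sd effect versus none:
eff_cfg = dataclasses.replace(SynthConfig(), effect_prob=1.0,
                              effect_size_range=(2.0, 2.0), flat_equal_prob=0.0, seed=7)
nul_cfg = dataclasses.replace(SynthConfig(), effect_prob=0.0, seed=8)
eff, _ = generate_dataset(200, eff_cfg)
nul, _ = generate_dataset(200, nul_cfg)
print(f"sensitivity at d=2: {(model.predict_proba(eff) >= 0.5).mean():.3f}")
print(f"specificity at d=0: {(model.predict_proba(nul) < 0.5).mean():.3f}")
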