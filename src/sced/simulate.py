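"""Synthetic AB graphs and simulated rater panels with known ground truth.

Clinical single-case data cannot be redistributed, so every pipeline
stage (CDC decisions, classifier training, agreement analytics) is
exercised on synthetic graphs drawn from an AR(1)-plus-trend family that
covers the qualitative features of clinical series: varying phase
lengths, baseline trends, autocorrelated session-to-session noise,
direction-signed level and slope changes of varying size, and the
degenerate "two flat lines of equal level" graphs that occur when a
behaviour never appears.

Rater panels are simulated by flipping the ground-truth label with
class-specific error rates and drawing a 0-10 confidence score on the
side of the 4/5 boundary consistent with the emitted label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .agreement import RatingPanel
from .graphs import ABGraph

__all__ = [
    "SynthConfig",
    "RaterModel",
    "generate_ab_graph",
    "generate_dataset",
    "simulate_panel",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic AB-graph generator.

    Phase lengths are drawn uniformly from inclusive integer ranges
    spanning the short (3-point) through long (20-point) phases seen in
    response-guided clinical practice.  Noise is AR(1):
    ``e_t = phi * e_{t-1} + w_t`` with white innovations of standard
    deviation ``noise_sd``; ``ar1_phi = 0`` gives independent draws.
    A true effect shifts every phase-B point by ``d * size * sigma``
    (sigma the stationary noise sd, d the expected direction) plus an
    optional per-session slope change, so effect sizes are standardized
    shifts.  With probability ``flat_equal_prob`` the graph is instead a
    constant line across both phases (no effect by construction).
    """

    nA_range: tuple[int, int] = (3, 20)
    nB_range: tuple[int, int] = (3, 20)
    baseline_level: float = 10.0
    baseline_trend: float = 0.0
    noise_sd: float = 1.0
    ar1_phi: float = 0.2
    effect_prob: float = 0.5
    effect_size_range: tuple[float, float] = (1.0, 4.0)
    slope_change_range: tuple[float, float] = (0.0, 0.2)
    flat_equal_prob: float = 0.05
    direction_prob: float = 0.5
    clip_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nA_range", "nB_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a nonempty positive range")
        if self.nA_range[0] < 2:
            raise ValueError("nA_range minimum is 2 (baseline trend fit)")
        for name in ("effect_prob", "flat_equal_prob", "direction_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not -1 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in (-1, 1)")

    @property
    def stationary_sd(self) -> float:
        """Marginal sd of the AR(1) noise process."""
        return self.noise_sd / np.sqrt(1.0 - self.ar1_phi**2)


@dataclass(frozen=True)
class RaterModel:
    """Error model of one simulated visual rater.

    ``false_positive_rate`` is the probability of labelling a no-effect
    graph "yes"; ``false_negative_rate`` of labelling a true-effect
    graph "no".  ``score_concentration`` controls how far the 0-10
    confidence score sits from the 4/5 yes/no boundary (larger = more
    confident; scores are drawn as Beta(c, 1) distances from the
    boundary toward the label's extreme).
    """

    false_positive_rate: float = 0.1
    false_negative_rate: float = 0.1
    score_concentration: float = 2.0

    def __post_init__(self) -> None:
        for name in ("false_positive_rate", "false_negative_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.score_concentration <= 0:
            raise ValueError("score_concentration must be > 0")


def _ar1_noise(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    e = np.empty(n)
    # stationary start so the marginal variance is constant over the series
    e[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
    w = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + w[t - 1]
    return e


def generate_ab_graph(
    config: SynthConfig, rng: np.random.Generator, graph_id: str = "synth"
) -> tuple[ABGraph, bool]:
    """Draw one synthetic AB graph and its ground-truth label."""
    direction = 1 if rng.random() < config.direction_prob else -1
    n_a = int(rng.integers(config.nA_range[0], config.nA_range[1] + 1))
    n_b = int(rng.integers(config.nB_range[0], config.nB_range[1] + 1))

    if rng.random() < config.flat_equal_prob:
        level = config.baseline_level
        graph = ABGraph(
            id=graph_id,
            phase_a=[level] * n_a,
            phase_b=[level] * n_b,
            direction=direction,
            meta={"synthetic": True, "flat_equal": True},
        )
        return graph, False

    n = n_a + n_b
    t = np.arange(1, n + 1, dtype=float)
    x = (
        config.baseline_level
        + config.baseline_trend * t
        + _ar1_noise(n, config.ar1_phi, config.noise_sd, rng)
    )

    true_effect = rng.random() < config.effect_prob
    if true_effect:
        size = rng.uniform(*config.effect_size_range)
        slope_change = rng.uniform(*config.slope_change_range)
        sigma = config.stationary_sd
        j = np.arange(n_b, dtype=float)  # sessions since phase change
        x[n_a:] += direction * sigma * (size + slope_change * j)
    if config.clip_range is not None:
        x = np.clip(x, *config.clip_range)

    graph = ABGraph(
        id=graph_id,
        phase_a=x[:n_a],
        phase_b=x[n_a:],
        direction=direction,
        meta={"synthetic": True, "flat_equal": False},
    )
    return graph, true_effect


def generate_dataset(
    n: int, config: SynthConfig | None = None
) -> tuple[list[ABGraph], np.ndarray]:
    """Draw ``n`` independent labelled graphs.

    The generator is seeded from ``config.seed``, so a fixed config
    reproduces the corpus bit-for-bit.

    Returns
    -------
    graphs : list of ABGraph
    labels : ndarray of bool
        Ground-truth effect labels, aligned with ``graphs``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    graphs: list[ABGraph] = []
    labels = np.empty(n, dtype=bool)
    width = len(str(n))
    for i in range(n):
        g, y = generate_ab_graph(config, rng, graph_id=f"synth_{i:0{width}d}")
        graphs.append(g)
        labels[i] = y
    return graphs, labels


def simulate_panel(
    graphs: Sequence[ABGraph],
    labels: Sequence[bool],
    raters: Sequence[RaterModel],
    rng: np.random.Generator,
    rater_names: Sequence[str] | None = None,
) -> RatingPanel:
    """Simulate a panel of visual raters for a labelled dataset.

    Each rater flips the ground truth with their class-appropriate error
    rate and then reports a 0-10 score on the side of the 4/5 boundary
    consistent with the emitted binary label: "no" scores lie in [0, 4],
    "yes" scores in [5, 10].
    """
    if len(raters) < 1:
        raise ValueError("need at least one rater")
    if len(graphs) != len(labels):
        raise ValueError("graphs and labels must be aligned")
    if rater_names is None:
        rater_names = [f"rater_{chr(ord('A') + i)}" for i in range(len(raters))]

    truth = np.asarray(labels, dtype=bool)
    ids = [g.id for g in graphs]
    label_cols = {}
    score_cols = {}
    for name, rater in zip(rater_names, raters):
        flip_p = np.where(truth, rater.false_negative_rate, rater.false_positive_rate)
        flipped = rng.random(truth.size) < flip_p
        said_yes = truth ^ flipped
        # distance from the 4/5 boundary toward the label's extreme
        u = rng.beta(rater.score_concentration, 1.0, size=truth.size)
        scores = np.where(said_yes, 5.0 + 5.0 * u, 4.0 * (1.0 - u))
        label_cols[name] = said_yes.astype(int)
        score_cols[name] = np.round(scores, 2)
    return RatingPanel.from_arrays(ids, label_cols, score_cols)
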