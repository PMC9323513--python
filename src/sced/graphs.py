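"""Domain types for AB phase comparisons and blinded-graph construction.

A single-case experimental design (SCED) measures one subject repeatedly
across phases (baseline A, treatment B, further conditions C, D, ...).
The unit of analysis here is the *AB phase comparison*: two adjacent
phases of a design, re-labelled A (first) and B (second), together with
the expected direction of change (+1 the treatment should increase the
behaviour, -1 it should decrease it).

A multi-phase design such as ABCAC is decomposed into its adjacent pairs
(A1B1, B1C1, C1A2, A2C2), each of which becomes a standalone blinded
comparison graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ABGraph",
    "PhaseComparison",
    "StandardizedGraph",
    "ShortPhaseWarning",
    "build_phase_comparisons",
    "make_ab_graphs",
    "standardize",
    "baseline_return_direction",
]

#: Phase length below which a warning (not an error) is emitted.  Clinical
#: SCED datasets rarely contain phases shorter than 3 sessions.
MIN_TYPICAL_PHASE_LENGTH = 3


class ShortPhaseWarning(UserWarning):
    """A phase is shorter than the typical clinical minimum of 3 points."""


@dataclass(frozen=True)
class ABGraph:
    """One adjacent-phase comparison.

    Parameters
    ----------
    id : str
        Unique identifier for the comparison graph.
    phase_a, phase_b : sequence of float
        Per-session measurements of the first and second phase, in
        session order.
    direction : int
        Expected direction of the treatment effect: ``+1`` for an
        intended increase, ``-1`` for an intended decrease.
    meta : dict
        Optional participant / variable / phase-pair labels.  Never
        rendered on blinded graphs.
    """

    id: str
    phase_a: tuple[float, ...]
    phase_b: tuple[float, ...]
    direction: int
    meta: dict = field(default_factory=dict, compare=False)

    def __init__(self, id, phase_a, phase_b, direction, meta=None):
        object.__setattr__(self, "id", str(id))
        object.__setattr__(self, "phase_a", tuple(float(v) for v in phase_a))
        object.__setattr__(self, "phase_b", tuple(float(v) for v in phase_b))
        object.__setattr__(self, "direction", int(direction))
        object.__setattr__(self, "meta", dict(meta) if meta else {})
        self._validate()

    def _validate(self) -> None:
        if len(self.phase_a) < 2:
            raise ValueError(
                f"graph {self.id!r}: phase A needs >= 2 points to fit a "
                f"baseline trend, got {len(self.phase_a)}"
            )
        if len(self.phase_b) < 1:
            raise ValueError(f"graph {self.id!r}: empty phase B")
        if self.direction not in (1, -1):
            raise ValueError(
                f"graph {self.id!r}: direction must be +1 or -1, got "
                f"{self.direction}"
            )
        if not all(np.isfinite(self.phase_a + self.phase_b)):
            raise ValueError(f"graph {self.id!r}: non-finite measurement")
        short = min(len(self.phase_a), len(self.phase_b))
        if short < MIN_TYPICAL_PHASE_LENGTH:
            warnings.warn(
                f"graph {self.id!r}: phase of length {short} is below the "
                f"typical clinical minimum of {MIN_TYPICAL_PHASE_LENGTH}",
                ShortPhaseWarning,
                stacklevel=3,
            )

    @property
    def n_a(self) -> int:
        return len(self.phase_a)

    @property
    def n_b(self) -> int:
        return len(self.phase_b)

    @property
    def values(self) -> np.ndarray:
        """Pooled raw series, phase A then phase B."""
        return np.asarray(self.phase_a + self.phase_b, dtype=float)


@dataclass(frozen=True)
class PhaseComparison:
    """An adjacent pair of occurrence-indexed phase labels, e.g. C1 -> A2."""

    first_label: str
    second_label: str

    @property
    def label(self) -> str:
        return f"{self.first_label}{self.second_label}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class StandardizedGraph:
    """Direction-adjusted z-scores of an AB graph.

    z_t = direction * (x_t - mean) / sd over the pooled series; a constant
    raw series maps to all-zero z-scores.  Session indices run 1..nA for
    phase A and nA+1..nA+nB for phase B.
    """

    z_a: tuple[float, ...]
    z_b: tuple[float, ...]
    session_index_a: tuple[int, ...]
    session_index_b: tuple[int, ...]

    @property
    def z(self) -> np.ndarray:
        return np.asarray(self.z_a + self.z_b, dtype=float)

    @property
    def sessions(self) -> np.ndarray:
        return np.asarray(self.session_index_a + self.session_index_b)


def build_phase_comparisons(design: Sequence[str]) -> list[PhaseComparison]:
    """Decompose a design sequence into its adjacent phase comparisons.

    Phase letters are occurrence-indexed so reversals are unambiguous:
    ``"ABCAC"`` becomes A1, B1, C1, A2, C2 and yields the comparisons
    A1B1, B1C1, C1A2, A2C2.

    Parameters
    ----------
    design : str or sequence of str
        Ordered phase letters, e.g. ``"ABCAC"`` or ``["A", "B", "A"]``.

    Returns
    -------
    list of PhaseComparison
        One comparison per adjacent pair; always ``len(design) - 1`` long.
    """
    letters = list(design)
    if len(letters) < 2:
        raise ValueError("design too short: need at least 2 phases")
    counts: dict[str, int] = {}
    indexed: list[str] = []
    for letter in letters:
        counts[letter] = counts.get(letter, 0) + 1
        indexed.append(f"{letter}{counts[letter]}")
    return [
        PhaseComparison(indexed[i], indexed[i + 1])
        for i in range(len(indexed) - 1)
    ]


def baseline_return_direction(canonical: int, comparison: PhaseComparison) -> int:
    """Direction convention helper for return-to-baseline comparisons.

    When the second phase of a comparison is a baseline (letter ``A``,
    i.e. the treatment has been withdrawn), the behaviour is expected to
    move *against* the variable's canonical treatment direction.  This
    helper flips the canonical direction in that case and returns it
    unchanged otherwise.  Whether a given dataset adopted this convention
    is an input-data decision; the reader never applies it implicitly.
    """
    if comparison.second_label[0] == "A":
        return -canonical
    return canonical


def _comparison_slug(participant: str, variable: str, comp: PhaseComparison) -> str:
    return f"{participant}_{variable}_{comp.label}"


def make_ab_graphs(
    sessions: pd.DataFrame,
    directions: Mapping,
) -> list[ABGraph]:
    """Build one ABGraph per (adjacent phase pair x variable).

    Parameters
    ----------
    sessions : DataFrame
        Long-format table with columns ``participant``, ``variable``,
        ``phase_label`` (plain letters; repeats mark reversals),
        ``session`` (integer order) and ``value``.  The design sequence
        is recovered from the session-ordered run of phase labels.
    directions : mapping
        Expected direction per comparison.  Keys may be
        ``(participant, variable, comparison_label)`` (e.g.
        ``("p1", "latency", "C1A2")``) for per-comparison control, or
        ``(participant, variable)`` for a single canonical direction
        applied to every comparison of that variable.  Values are +1/-1.

    Returns
    -------
    list of ABGraph
        Ordered by participant, variable, then position in the design.
    """
    required = {"participant", "variable", "phase_label", "session", "value"}
    missing = required - set(sessions.columns)
    if missing:
        raise ValueError(f"sessions table missing columns: {sorted(missing)}")

    graphs: list[ABGraph] = []
    for (participant, variable), part in sessions.groupby(
        ["participant", "variable"], sort=True
    ):
        part = part.sort_values("session")
        # compress the session-ordered labels into the design sequence
        labels = part["phase_label"].tolist()
        design: list[str] = []
        run_values: list[list[float]] = []
        for label, value in zip(labels, part["value"]):
            if not design or label != design[-1]:
                design.append(label)
                run_values.append([])
            run_values[-1].append(float(value))
        if any(len(v) == 0 for v in run_values):
            raise ValueError(f"{participant}/{variable}: empty phase")
        comparisons = build_phase_comparisons(design)
        occ_values = dict(zip([c.first_label for c in comparisons], run_values))
        occ_values[comparisons[-1].second_label] = run_values[-1]
        for comp in comparisons:
            key_full = (participant, variable, comp.label)
            if key_full in directions:
                direction = directions[key_full]
            elif (participant, variable) in directions:
                direction = directions[(participant, variable)]
            else:
                raise KeyError(
                    f"direction unspecified for {participant}/{variable}/"
                    f"{comp.label}"
                )
            graphs.append(
                ABGraph(
                    id=_comparison_slug(participant, variable, comp),
                    phase_a=occ_values[comp.first_label],
                    phase_b=occ_values[comp.second_label],
                    direction=direction,
                    meta={
                        "participant": participant,
                        "variable": variable,
                        "comparison": comp.label,
                    },
                )
            )
    return graphs


def standardize(graph: ABGraph) -> StandardizedGraph:
    """Pool both phases, z-score, and adjust for the expected direction.

    Each point becomes ``direction * (x - mean) / sd`` where mean and sd
    (sample, n-1 denominator) are computed over the pooled series.  A
    decrease-direction graph is thereby mirrored so that "improvement"
    is always upward in z-space.  A constant series has sd 0 and maps to
    all-zero z-scores.
    """
    x = graph.values
    sd = float(np.std(x, ddof=1))
    # all-equal check, not sd == 0: the mean of identical floats can be
    # off by one ulp, leaving identical nonzero deviations
    if np.all(x == x[0]) or sd == 0.0:
        z = np.zeros_like(x)
    else:
        z = graph.direction * (x - x.mean()) / sd
    n_a = graph.n_a
    return StandardizedGraph(
        z_a=tuple(z[:n_a]),
        z_b=tuple(z[n_a:]),
        session_index_a=tuple(range(1, n_a + 1)),
        session_index_b=tuple(range(n_a + 1, n_a + graph.n_b + 1)),
    )
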