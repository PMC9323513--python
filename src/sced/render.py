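"""Blinded comparison-graph rendering.

Raters judge only the relative change between phases, so the rendered
graph strips everything that could bias them: the title carries only
the expected direction ("1.0" or "-1.0"), the y-axis is labelled
generically "Behavior" with unlabelled tick marks, and no participant,
variable or phase information appears anywhere.  A vertical phase line
separates the two phases.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .graphs import ABGraph

__all__ = ["render_blinded_graph"]


def render_blinded_graph(graph: ABGraph, path=None):
    """Render one blinded AB graph; save to ``path`` if given.

    Returns the matplotlib Figure so the content contract (labels,
    blinding, phase-line placement) can be inspected programmatically.
    """
    n_a = graph.n_a
    sessions_a = range(1, n_a + 1)
    sessions_b = range(n_a + 1, n_a + graph.n_b + 1)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(list(sessions_a), graph.phase_a, "o-", color="black")
    ax.plot(list(sessions_b), graph.phase_b, "o-", color="black")
    ax.axvline(n_a + 0.5, color="black", linestyle="--", linewidth=1)
    ax.set_title(f"{float(graph.direction):.1f}")
    ax.set_xlabel("Session")
    ax.set_ylabel("Behavior")
    ax.set_yticklabels([])
    ax.tick_params(axis="y", length=3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
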