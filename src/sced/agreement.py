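"""Interrater and intermethod agreement analytics.

Covers the comparison layer of the pipeline: pairwise percent
agreement, Cohen's kappa with its conventional Landis-Koch verbal
interpretation, Spearman rank correlation between confidence scores and
classifier probabilities, agreement stratified by whether an objective
method called an effect, majority-vote disagreement grouping, and the
tabulation of phase lengths within those groups.

Undefined statistics (empty strata, constant score vectors) propagate
as NaN and are excluded from means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import ABGraph

__all__ = [
    "RatingPanel",
    "AgreementResult",
    "DisagreementGroups",
    "percent_agreement",
    "cohens_kappa",
    "kappa_interpretation",
    "spearman_rho",
    "pairwise_agreement_table",
    "mean_pairwise_agreement",
    "method_vs_panel_agreement",
    "stratified_agreement",
    "majority_groups",
    "phase_length_table",
    "DEFAULT_PHASE_BINS",
]

logger = logging.getLogger(__name__)

#: Yes/no boundary of the 0-10 confidence scale: scores of 5 and above
#: correspond to a "yes" (effect) answer, 4 and below to "no".
SCORE_YES_BOUNDARY = 5.0

#: Phase-length bins used for disagreement tabulation: exactly 3 points,
#: 4-5, 6-9, and 10 or more.
DEFAULT_PHASE_BINS: tuple[tuple[int, float], ...] = (
    (3, 3),
    (4, 5),
    (6, 9),
    (10, float("inf")),
)


@dataclass(frozen=True)
class RatingPanel:
    """Binary labels and 0-10 confidence scores from a panel of raters.

    ``labels`` and ``scores`` are DataFrames indexed by graph id with one
    column per rater; labels are 0/1 and scores lie in [0, 10].  A label
    of 1 ("yes") should come with a score in [5, 10] and a label of 0
    with a score in [0, 4]; violations are flagged, not fatal.
    """

    labels: pd.DataFrame
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.labels.index.equals(self.scores.index):
            raise ValueError("labels and scores must share graph ids")
        if list(self.labels.columns) != list(self.scores.columns):
            raise ValueError("labels and scores must share rater names")
        bad = (self.scores.values < 0) | (self.scores.values > 10)
        if bad.any():
            raise ValueError("scores must lie in [0, 10]")

    @classmethod
    def from_arrays(
        cls,
        graph_ids: Sequence[str],
        labels: Mapping[str, Sequence[int]],
        scores: Mapping[str, Sequence[float]],
    ) -> "RatingPanel":
        idx = pd.Index(graph_ids, name="id")
        return cls(
            labels=pd.DataFrame(dict(labels), index=idx).astype(int),
            scores=pd.DataFrame(dict(scores), index=idx).astype(float),
        )

    @property
    def rater_names(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def n_graphs(self) -> int:
        return len(self.labels)

    @property
    def n_raters(self) -> int:
        return len(self.labels.columns)

    def consistency_violations(self) -> pd.DataFrame:
        """Rows where a rater's binary label contradicts their score."""
        implied = (self.scores >= SCORE_YES_BOUNDARY).astype(int)
        mask = implied != self.labels
        n = int(mask.values.sum())
        if n:
            logger.warning(
                "%d rating(s) have a binary label inconsistent with the "
                "0-10 score (4/5 boundary)",
                n,
            )
        return mask

    def majority_labels(self) -> pd.Series:
        """Per-graph majority binary label (ties -> NaN)."""
        yes = self.labels.sum(axis=1)
        m = self.n_raters
        out = pd.Series(np.nan, index=self.labels.index)
        out[yes > m / 2] = 1
        out[yes < m / 2] = 0
        return out


@dataclass(frozen=True)
class AgreementResult:
    """Pairwise agreement between two binary label sequences."""

    proportion: float
    kappa: float
    interpretation: str
    n: int


@dataclass(frozen=True)
class DisagreementGroups:
    """Majority-vote grouping of graphs for disagreement analysis.

    ``visual_agreement`` holds the graphs where at least k of m raters
    concur (with the majority label recorded), ``visual_disagreement``
    the rest.  ``cdc_disagree`` / ``svc_disagree`` are the subsets of
    ``visual_agreement`` where the respective objective method differs
    from the rater majority.
    """

    visual_agreement: tuple[str, ...]
    visual_disagreement: tuple[str, ...]
    cdc_disagree: tuple[str, ...]
    svc_disagree: tuple[str, ...]
    majority_label: dict = field(default_factory=dict, compare=False)
    no_majority: tuple[str, ...] = ()


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty input")
    return a, b


def percent_agreement(labels_1: Sequence, labels_2: Sequence) -> float:
    """Fraction of graphs on which two binary raters give the same label."""
    a, b = _check_pair(labels_1, labels_2)
    return float(np.mean(a == b))


def cohens_kappa(labels_1: Sequence, labels_2: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    p_e is the product-of-marginals chance agreement.  When both raters
    are constant and identical, p_e = 1 and kappa is defined as 1.0
    (perfect agreement with no room for chance correction).
    """
    a, b = _check_pair(labels_1, labels_2)
    a = a.astype(int)
    b = b.astype(int)
    n = a.size
    p_o = float(np.mean(a == b))
    p1 = a.mean()
    p2 = b.mean()
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if p_e == 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_interpretation(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value.

    Bands are closed on their printed two-decimal bounds (0.20 is
    "slight", 0.21 is "fair"); unrounded values between printed bounds
    fall into the upper band (0.205 -> "fair").  Negative kappas are
    below-chance agreement.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    if kappa < 0:
        return "poor (below chance)"
    for hi, label in [
        (0.20, "slight"),
        (0.40, "fair"),
        (0.60, "moderate"),
        (0.80, "substantial"),
        (1.00, "almost perfect"),
    ]:
        if kappa <= hi:
            return label
    return "almost perfect"  # pragma: no cover


def spearman_rho(scores_1: Sequence[float], scores_2: Sequence[float]) -> float:
    """Spearman rank correlation with averaged tied ranks.

    Returns NaN (an "undefined correlation" marker, excluded from
    averages) when either sequence is constant.
    """
    a, b = _check_pair(scores_1, scores_2)
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def agreement_result(labels_1: Sequence, labels_2: Sequence) -> AgreementResult:
    """Bundle proportion, kappa and its interpretation for one pair."""
    a, b = _check_pair(labels_1, labels_2)
    p = percent_agreement(a, b)
    k = cohens_kappa(a, b)
    return AgreementResult(
        proportion=p,
        kappa=k,
        interpretation=kappa_interpretation(max(-1.0, min(1.0, k))),
        n=int(a.size),
    )


def pairwise_agreement_table(
    columns: Mapping[str, Sequence[int]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportion and kappa matrices over all pairs of label columns.

    ``columns`` maps a rater or method name to its binary label
    sequence (all aligned on the same graphs).  Returns symmetric
    DataFrames (proportion, kappa) with NaN on the diagonal.
    """
    names = list(columns)
    prop = pd.DataFrame(np.nan, index=names, columns=names)
    kap = pd.DataFrame(np.nan, index=names, columns=names)
    for u, v in combinations(names, 2):
        res = agreement_result(columns[u], columns[v])
        prop.loc[u, v] = prop.loc[v, u] = res.proportion
        kap.loc[u, v] = kap.loc[v, u] = res.kappa
    return prop, kap


def mean_pairwise_agreement(panel: RatingPanel) -> dict:
    """Interrater agreement averaged over all rater pairs.

    For m raters there are m(m-1)/2 pairs (10 for five raters); the
    unweighted mean over pairs is reported along with the range, for
    both proportion and kappa.  A per-rater averaging alternative (mean
    of each rater's pairwise values) is included for comparison.
    """
    cols = {r: panel.labels[r].to_numpy() for r in panel.rater_names}
    prop, kap = pairwise_agreement_table(cols)
    iu = np.triu_indices(len(cols), k=1)
    props = prop.to_numpy()[iu]
    kaps = kap.to_numpy()[iu]
    per_rater_prop = np.nanmean(prop.to_numpy(), axis=1)
    return {
        "mean_proportion": float(np.mean(props)),
        "range_proportion": (float(props.min()), float(props.max())),
        "mean_kappa": float(np.mean(kaps)),
        "range_kappa": (float(kaps.min()), float(kaps.max())),
        "mean_proportion_per_rater": float(np.mean(per_rater_prop)),
        "n_pairs": int(props.size),
    }


def method_vs_panel_agreement(
    method_labels: Sequence[int], panel: RatingPanel
) -> dict:
    """A method's mean agreement (proportion and kappa) with each rater."""
    m = np.asarray(method_labels)
    props, kaps = [], []
    for r in panel.rater_names:
        res = agreement_result(m, panel.labels[r].to_numpy())
        props.append(res.proportion)
        kaps.append(res.kappa)
    return {
        "mean_proportion": float(np.mean(props)),
        "range_proportion": (float(min(props)), float(max(props))),
        "mean_kappa": float(np.mean(kaps)),
        "range_kappa": (float(min(kaps)), float(max(kaps))),
        "per_rater_proportion": dict(zip(panel.rater_names, props)),
    }


def stratified_agreement(
    method_decisions: Sequence[int], panel: RatingPanel
) -> pd.DataFrame:
    """Per-rater agreement split by the method's effect / no-effect call.

    Returns a DataFrame indexed by rater (plus a ``mean`` row) with
    columns ``effect`` and ``no_effect``: each entry is the rater's
    percent agreement with the method restricted to the graphs the
    method called effect (resp. no effect).  An empty stratum yields
    NaN and is excluded from the mean.
    """
    m = np.asarray(method_decisions).astype(bool)
    if m.size != panel.n_graphs:
        raise ValueError("method decisions not aligned with panel")
    rows = {}
    for r in panel.rater_names:
        lab = panel.labels[r].to_numpy().astype(bool)
        rows[r] = {
            "effect": float(np.mean(lab[m] == m[m])) if m.any() else float("nan"),
            "no_effect": (
                float(np.mean(lab[~m] == m[~m])) if (~m).any() else float("nan")
            ),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["mean"] = df.mean(axis=0, skipna=True)
    return df


def majority_groups(
    panel: RatingPanel,
    cdc: Sequence[int],
    svc: Sequence[int],
    k: int = 4,
) -> DisagreementGroups:
    """Partition graphs by rater consensus and method disagreement.

    A graph joins ``visual_agreement`` when at least ``k`` of the m
    raters gave the same label; otherwise ``visual_disagreement``.
    Within the agreement group, graphs where the CDC (resp. SVC)
    decision differs from the rater majority form ``cdc_disagree``
    (resp. ``svc_disagree``).  Exact even splits (possible only for even
    m) have no majority and are flagged as well as counted as
    disagreement.
    """
    m = panel.n_raters
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}]")
    if k <= m / 2:
        raise ValueError("k must exceed half the panel to define a majority")
    cdc = np.asarray(cdc).astype(int)
    svc = np.asarray(svc).astype(int)
    if cdc.size != panel.n_graphs or svc.size != panel.n_graphs:
        raise ValueError("method decisions not aligned with panel")

    yes = panel.labels.sum(axis=1).to_numpy()
    agree_ids, disagree_ids, cdc_dis, svc_dis, no_majority = [], [], [], [], []
    majority: dict[str, int] = {}
    for i, gid in enumerate(panel.labels.index):
        concordant = max(yes[i], m - yes[i])
        if yes[i] * 2 == m:
            no_majority.append(gid)
        if concordant >= k:
            label = 1 if yes[i] > m - yes[i] else 0
            agree_ids.append(gid)
            majority[gid] = label
            if cdc[i] != label:
                cdc_dis.append(gid)
            if svc[i] != label:
                svc_dis.append(gid)
        else:
            disagree_ids.append(gid)
    return DisagreementGroups(
        visual_agreement=tuple(agree_ids),
        visual_disagreement=tuple(disagree_ids),
        cdc_disagree=tuple(cdc_dis),
        svc_disagree=tuple(svc_dis),
        majority_label=majority,
        no_majority=tuple(no_majority),
    )


def phase_length_table(
    groups: DisagreementGroups,
    graphs: Sequence[ABGraph],
    bins: Sequence[tuple[int, float]] = DEFAULT_PHASE_BINS,
) -> pd.DataFrame:
    """Distribution of phase lengths within each disagreement group.

    For Phase A and Phase B separately, each group's graphs are
    distributed over the length bins (default: exactly 3, 4-5, 6-9,
    10+; lengths below the first bin are folded into it).  Rows of
    nonempty groups sum to 1; empty groups yield NaN rows.
    """
    by_id = {g.id: g for g in graphs}
    labels = [
        f"{int(lo)}" if lo == hi else (f"{int(lo)}+" if np.isinf(hi) else f"{int(lo)}-{int(hi)}")
        for lo, hi in bins
    ]

    def bin_of(length: int) -> int:
        for i, (lo, hi) in enumerate(bins):
            if length <= hi:
                return i
        return len(bins) - 1  # pragma: no cover

    group_map = {
        "visual_agreement": groups.visual_agreement,
        "visual_disagreement": groups.visual_disagreement,
        "cdc_disagree": groups.cdc_disagree,
        "svc_disagree": groups.svc_disagree,
    }
    rows = {}
    for phase in ("A", "B"):
        for name, ids in group_map.items():
            counts = np.zeros(len(bins))
            for gid in ids:
                g = by_id[gid]
                length = g.n_a if phase == "A" else g.n_b
                counts[bin_of(length)] += 1
            total = counts.sum()
            rows[(phase, name)] = (
                counts / total if total else np.full(len(bins), np.nan)
            )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["phase", "group"])
    return df
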