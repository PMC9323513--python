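"""Readers and writers for the pipeline's tabular artifacts.

Canonical interchange is plain CSV.  Graphs travel in a long format
(one row per session), ratings in a wide format (one row per graph,
two columns per rater), and results as flat tables.  The spreadsheet
layout with one workbook per rater is supported read-only through a
merge utility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement import SCORE_YES_BOUNDARY, RatingPanel
from .cdc import CDCParams
from .classifier import ClassifierConfig
from .graphs import ABGraph
from .simulate import SynthConfig

__all__ = [
    "read_graphs",
    "write_graphs",
    "read_ratings",
    "write_ratings",
    "merge_rater_files",
    "read_truth",
    "write_truth",
    "RunConfig",
    "write_provenance",
]

logger = logging.getLogger(__name__)

GRAPH_COLUMNS = ["id", "phase", "session", "value", "direction"]


def _parse_direction(raw) -> int:
    """Accept 1, -1, "1.0", "-1.0" and similar numeric spellings."""
    try:
        d = float(raw)
    except (TypeError, ValueError):
        raise ValueError(f"direction must be +1 or -1, got {raw!r}") from None
    if d not in (1.0, -1.0):
        raise ValueError(f"direction must be +1 or -1, got {raw!r}")
    return int(d)


def write_graphs(graphs: Iterable[ABGraph], path) -> None:
    """Write graphs to long-format CSV (id, phase, session, value, direction)."""
    rows = []
    for g in graphs:
        for t, v in enumerate(g.phase_a, start=1):
            rows.append((g.id, "A", t, v, g.direction))
        for t, v in enumerate(g.phase_b, start=len(g.phase_a) + 1):
            rows.append((g.id, "B", t, v, g.direction))
    pd.DataFrame(rows, columns=GRAPH_COLUMNS).to_csv(path, index=False)


def read_graphs(path) -> list[ABGraph]:
    """Read a long-format graphs CSV back into validated ABGraphs.

    Rows are ordered by session within each phase; the direction column
    may use the "1.0" / "-1.0" text encoding.  Errors name the missing
    column or the offending row.
    """
    df = pd.read_csv(path)
    missing = set(GRAPH_COLUMNS) - set(df.columns)
    if missing:
        if "direction" in missing:
            raise ValueError("direction unspecified: missing 'direction' column")
        raise ValueError(f"missing column(s): {sorted(missing)}")
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any() or df["value"].isna().any():
        row = int(df.index[bad | df["value"].isna()][0])
        raise ValueError(f"non-numeric value at row {row}")

    graphs = []
    for gid, sub in df.groupby("id", sort=False):
        directions = {_parse_direction(d) for d in sub["direction"]}
        if len(directions) != 1:
            raise ValueError(f"graph {gid!r}: inconsistent directions")
        sub = sub.sort_values("session")
        a = sub.loc[sub["phase"].str.upper() == "A", "value"].astype(float)
        b = sub.loc[sub["phase"].str.upper() == "B", "value"].astype(float)
        if a.empty or b.empty:
            raise ValueError(f"graph {gid!r}: empty phase")
        graphs.append(
            ABGraph(
                id=gid,
                phase_a=a.tolist(),
                phase_b=b.tolist(),
                direction=directions.pop(),
            )
        )
    return graphs


def write_ratings(panel: RatingPanel, path) -> None:
    """Write a panel to wide CSV: id, then <rater>_label, <rater>_score."""
    out = pd.DataFrame(index=panel.labels.index)
    for r in panel.rater_names:
        out[f"{r}_label"] = panel.labels[r]
        out[f"{r}_score"] = panel.scores[r]
    out.to_csv(path)


def read_ratings(path_or_paths) -> RatingPanel:
    """Read a rating panel from a merged CSV or a list of per-rater files.

    The merged layout has one row per graph: an ``id`` column plus
    ``<rater>_label`` / ``<rater>_score`` pairs.  A list of paths is
    forwarded to :func:`merge_rater_files`.  Binary labels inconsistent
    with the 4/5 score boundary are logged, not fatal; scores outside
    [0, 10] are errors.
    """
    if isinstance(path_or_paths, (list, tuple)):
        return merge_rater_files(path_or_paths)
    df = pd.read_csv(path_or_paths).set_index("id")
    raters = sorted({c[: -len("_label")] for c in df.columns if c.endswith("_label")})
    if not raters:
        raise ValueError("no <rater>_label columns found")
    labels = {r: df[f"{r}_label"].to_numpy() for r in raters}
    scores = {r: df[f"{r}_score"].to_numpy() for r in raters}
    panel = RatingPanel.from_arrays(df.index.tolist(), labels, scores)
    panel.consistency_violations()
    return panel


def _read_single_rater(path) -> pd.DataFrame:
    """One rater's file: columns id, answer (yes/no or 0/1), score."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"id", "answer", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path.name}: need columns {sorted(required)}")
    answer = df["answer"]
    if answer.dtype == object:
        answer = answer.str.strip().str.lower().map({"yes": 1, "no": 0})
        if answer.isna().any():
            raise ValueError(f"{path.name}: answers must be yes/no or 0/1")
    return pd.DataFrame(
        {"id": df["id"], "label": answer.astype(int), "score": df["score"].astype(float)}
    )


def merge_rater_files(paths: Sequence, names: Sequence[str] | None = None) -> RatingPanel:
    """Merge one-file-per-rater tables into a single aligned panel."""
    if names is None:
        names = [Path(p).stem for p in paths]
    frames = [_read_single_rater(p) for p in paths]
    ids = frames[0]["id"].tolist()
    for name, f in zip(names, frames):
        if f["id"].tolist() != ids:
            raise ValueError(f"rater {name!r}: graph ids do not match the first file")
    panel = RatingPanel.from_arrays(
        ids,
        {n: f["label"].to_numpy() for n, f in zip(names, frames)},
        {n: f["score"].to_numpy() for n, f in zip(names, frames)},
    )
    panel.consistency_violations()
    return panel


def write_truth(ids: Sequence[str], labels: Sequence[bool], path) -> None:
    pd.DataFrame({"id": ids, "true_effect": np.asarray(labels).astype(int)}).to_csv(
        path, index=False
    )


def read_truth(path) -> pd.Series:
    df = pd.read_csv(path)
    return df.set_index("id")["true_effect"].astype(bool)


@dataclasses.dataclass
class RunConfig:
    """Bundled configuration of one pipeline run.

    Defaults follow the published protocol: 0.25 SD criterion shift,
    alpha .05, probability threshold 0.5, and a 4-of-5 rater consensus
    for the visual-agreement group.
    """

    cdc: CDCParams = dataclasses.field(default_factory=CDCParams)
    classifier: ClassifierConfig = dataclasses.field(default_factory=ClassifierConfig)
    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    agreement_k: int = 4
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        raw = raw or {}

        def tuplify(d):
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        kwargs = {}
        if "cdc" in raw:
            kwargs["cdc"] = CDCParams(**raw["cdc"])
        if "synth" in raw:
            kwargs["synth"] = SynthConfig(**tuplify(raw["synth"]))
        if "classifier" in raw:
            c = dict(raw["classifier"])
            if isinstance(c.get("synth"), dict):
                c["synth"] = SynthConfig(**tuplify(c["synth"]))
            kwargs["classifier"] = ClassifierConfig(**c)
        for key in ("agreement_k", "seed", "verbosity"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_provenance(path, config, seed: int | None = None, **extra) -> None:
    """Record config, seed and package version next to any output."""
    from . import __version__

    record = {
        "package_version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
    }
    record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
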