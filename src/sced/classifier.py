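"""Support-vector classification of AB graphs from eight summary features.

Each comparison graph is reduced to the mean, standard deviation,
intercept and slope of each phase, computed on the pooled,
direction-adjusted z-scores.  The four quantities map onto the four
properties a visual inspector attends to: mean -> level change, sd ->
variability, intercept -> immediacy of change, slope -> trend.  A
support vector classifier with a radial-basis kernel separates
effect from no-effect graphs in this 8-dimensional feature space and
reports a calibrated probability of a clear change in the expected
direction; probabilities at or above 0.5 are categorized as a change.

No pre-trained weights ship with the package: the classifier is trained
on a synthetic corpus with known ground truth, and the full training
descriptor (generator config, corpus size, seed) is recorded so any
fitted model can be re-created exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .graphs import ABGraph, standardize

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "ClassifierConfig",
    "TrainedModel",
    "Decision",
    "extract_features",
    "features_matrix",
    "train_classifier",
    "classify",
    "classify_batch",
]

#: Fixed serialization order of the eight features: phase A before
#: phase B; within a phase mean, sd, intercept, slope.
FEATURE_NAMES = (
    "a_mean",
    "a_sd",
    "a_intercept",
    "a_slope",
    "b_mean",
    "b_sd",
    "b_intercept",
    "b_slope",
)


@dataclass(frozen=True)
class FeatureVector:
    """Eight per-phase summary statistics of a standardized AB graph."""

    a_mean: float
    a_sd: float
    a_intercept: float
    a_slope: float
    b_mean: float
    b_sd: float
    b_intercept: float
    b_slope: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass(frozen=True)
class Decision:
    """Binary change verdict with the probability behind it."""

    id: str
    probability: float
    change: bool


@dataclass(frozen=True)
class ClassifierConfig:
    """Everything that determines a trained classifier.

    kernel / C / gamma parameterize the support vector machine
    (radial-basis kernel by default: the higher-dimensional projection
    that makes nonlinearly separable classes separable by a hyperplane).
    ``threshold`` is the probability cutpoint: probabilities >= threshold
    are a "clear change" (the boundary itself counts as change).
    ``synth`` (a ``sced.simulate.SynthConfig``), ``n_train`` and ``seed``
    fully describe the training corpus; a fixed descriptor yields an
    identical model.  Probabilities come from Platt (sigmoid) scaling
    fitted by cross-validated calibration during training.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    calibrate: bool = True
    threshold: float = 0.5
    synth: object = None  # SynthConfig; resolved lazily to avoid a cycle
    n_train: int = 2000
    holdout_fraction: float = 0.2
    seed: int = 12345

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_train < 10:
            raise ValueError("n_train too small to fit a classifier")


def _phase_features(z: np.ndarray, sessions: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sd, intercept-at-first-session and slope of one phase.

    The slope is an OLS fit of z against the graph-wide session index;
    the intercept is the fitted value at the phase's first session.  A
    single-point phase has slope 0 and intercept equal to the point.
    """
    mean = float(z.mean())
    sd = float(np.std(z, ddof=1)) if z.size > 1 else 0.0
    if z.size > 1 and not np.allclose(z, z[0]):
        slope, b0 = np.polyfit(sessions.astype(float), z, 1)
        intercept = float(b0 + slope * sessions[0])
        slope = float(slope)
    elif z.size > 1:
        slope, intercept = 0.0, float(z[0])
    else:
        slope, intercept = 0.0, float(z[0])
    return mean, sd, intercept, slope


def extract_features(graph: ABGraph) -> FeatureVector:
    """Compute the eight z-score features of one AB graph.

    All features are invariant to positive affine transforms of the raw
    series (inherited from the z-score standardization) and all eight
    are exactly zero for a constant raw graph.
    """
    std = standardize(graph)
    z_a = np.asarray(std.z_a)
    z_b = np.asarray(std.z_b)
    s_a = np.asarray(std.session_index_a)
    s_b = np.asarray(std.session_index_b)
    a = _phase_features(z_a, s_a)
    b = _phase_features(z_b, s_b)
    return FeatureVector(*a, *b)


def features_matrix(graphs: Iterable[ABGraph]) -> np.ndarray:
    """Stack extract_features over a batch into an (n, 8) array."""
    return np.vstack([extract_features(g).to_array() for g in graphs])


@dataclass
class TrainedModel:
    """A fitted support vector classifier plus its provenance.

    ``provenance`` records the config, the training-corpus descriptor
    and the held-out accuracy measured during training; it is written as
    a JSON sidecar on save so a model file is always accompanied by the
    recipe that produced it.
    """

    pipeline: Pipeline
    config: ClassifierConfig
    provenance: dict

    def predict_proba(self, graphs: Sequence[ABGraph]) -> np.ndarray:
        """Probability of a clear change for each graph."""
        X = features_matrix(graphs)
        return self.pipeline.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        joblib.dump({"pipeline": self.pipeline, "config": dataclasses.asdict(self.config)}, path)
        sidecar = str(path) + ".provenance.json"
        with open(sidecar, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        cfg_dict = blob["config"]
        synth = cfg_dict.pop("synth", None)
        if isinstance(synth, dict):
            from .simulate import SynthConfig

            synth = SynthConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in synth.items()})
        config = ClassifierConfig(synth=synth, **cfg_dict)
        sidecar = str(path) + ".provenance.json"
        try:
            with open(sidecar) as fh:
                provenance = json.load(fh)
        except FileNotFoundError:
            provenance = {}
        return cls(pipeline=blob["pipeline"], config=config, provenance=provenance)


def train_classifier(config: ClassifierConfig | None = None) -> TrainedModel:
    """Train the classifier on a synthetic corpus with known labels.

    The corpus is drawn from ``config.synth`` (package defaults when
    omitted), split into a training part and a held-out part whose
    accuracy is recorded in the provenance, and the model is fitted on
    the training part.  A corpus that contains only one label raises
    ``ValueError`` ("degenerate training set").
    """
    from .simulate import SynthConfig, generate_dataset

    config = config or ClassifierConfig()
    synth = config.synth or SynthConfig(seed=config.seed)
    graphs, labels = generate_dataset(config.n_train, synth)
    if labels.all() or not labels.any():
        raise ValueError("degenerate training set: only one label present")

    X = features_matrix(graphs)
    y = labels.astype(int)
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X,
        y,
        test_size=config.holdout_fraction,
        random_state=config.seed,
        stratify=y,
    )
    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        random_state=config.seed,
    )
    estimator = (
        CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
        if config.calibrate
        else svc
    )
    pipeline = Pipeline([("scale", StandardScaler()), ("svc", estimator)])
    pipeline.fit(X_tr, y_tr)
    holdout_accuracy = float(pipeline.score(X_ho, y_ho))
    provenance = {
        "config": dataclasses.asdict(config),
        "synth": dataclasses.asdict(synth),
        "n_train": config.n_train,
        "seed": config.seed,
        "holdout_accuracy": holdout_accuracy,
        "calibration": (
            "Platt scaling (sigmoid CalibratedClassifierCV, 5-fold, ensemble=False)"
            if config.calibrate
            else "none (decision function only)"
        ),
        "feature_order": list(FEATURE_NAMES),
    }
    return TrainedModel(pipeline=pipeline, config=config, provenance=provenance)


def classify(model: TrainedModel, graph: ABGraph) -> Decision:
    """Classify one graph: probability of change and the 0.5-rule verdict."""
    try:
        p = float(model.predict_proba([graph])[0])
    except Exception as exc:  # sklearn NotFittedError
        raise RuntimeError("model not fitted") from exc
    return Decision(id=graph.id, probability=p, change=p >= model.config.threshold)


def classify_batch(model: TrainedModel, graphs: Sequence[ABGraph]):
    """Vectorized classify; returns a DataFrame (id, probability, change)."""
    import pandas as pd

    p = model.predict_proba(graphs)
    df = pd.DataFrame(
        {
            "id": [g.id for g in graphs],
            "probability": p,
            "change": p >= model.config.threshold,
        }
    )
    df.attrs["effect_proportion"] = float(df["change"].mean()) if len(df) else float("nan")
    return df
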