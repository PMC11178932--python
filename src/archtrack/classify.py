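"""Frame-level binary lameness classification and per-animal aggregation.

The unit of learning is one frame's 7-number feature vector labelled sound
(locomotion level 1) or lame (levels 2–3); the unit of decision is the
animal: a completed transit yields a folder of frames, each frame gets a
lame-probability, and the animal's verdict is the mean of those scores
against a 0.5 threshold. Averaging across a transit's frames suppresses
single-frame segmentation noise that would whipsaw a per-frame decision.

Five classical learners are supported: SVM (RBF), random forest, decision
tree, AdaBoost and SGD (linear hinge). Library defaults are used throughout,
seeded for reproducibility; margin-only learners get a logistic squash of
the decision function so every model emits a [0, 1] score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "LABELS",
    "ALGORITHMS",
    "FrameSample",
    "ClassifierSpec",
    "TrainedModel",
    "AnimalVerdict",
    "split_dataset",
    "split_by_animal",
    "train",
    "predict_frames",
    "aggregate_animal",
    "evaluate_classifier",
]

LABELS = ("sound", "lame")
ALGORITHMS = ("svm", "random_forest", "decision_tree", "adaboost", "sgd")

#: default train fraction: 690 of 1031 frames
DEFAULT_TRAIN_FRACTION = 690 / 1031


@dataclass(frozen=True)
class FrameSample:
    features: tuple[float, ...]
    label: str
    animal_id: Optional[int] = None
    lameness_level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.lameness_level is not None:
            expected = "sound" if self.lameness_level == 1 else "lame"
            if self.lameness_level in (1, 2, 3) and self.label != expected:
                raise ValueError(
                    f"label {self.label!r} inconsistent with level {self.lameness_level}"
                )

    @classmethod
    def from_vector(
        cls,
        vec: FeatureVector,
        label: str,
        animal_id: Optional[int] = None,
        lameness_level: Optional[int] = None,
    ) -> "FrameSample":
        return cls(vec.as_tuple(), label, animal_id, lameness_level)


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: str = "adaboost"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "svm":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(random_state=spec.seed, **hp))]
        )
    if spec.algorithm == "sgd":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SGDClassifier(random_state=spec.seed, **hp))]
        )
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    return AdaBoostClassifier(random_state=spec.seed, **hp)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    n_features: int

    def save(self, path: str | Path) -> None:
        """Persist as a joblib blob with the spec embedded as JSON."""
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(
            {
                "format_version": 1,
                "spec": json.dumps(
                    {
                        "algorithm": self.spec.algorithm,
                        "hyperparameters": self.spec.hyperparameters,
                        "seed": self.spec.seed,
                    }
                ),
                "n_features": self.n_features,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        meta = json.loads(blob["spec"])
        spec = ClassifierSpec(meta["algorithm"], meta["hyperparameters"], meta["seed"])
        return cls(spec=spec, estimator=blob["estimator"], n_features=blob["n_features"])


@dataclass(frozen=True)
class AnimalVerdict:
    animal_id: Optional[int]
    lame_probability: float
    label: str
    n_frames: int


def _xy(samples: Sequence[FrameSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([s.features for s in samples], dtype=float)
    y = np.array([1 if s.label == "lame" else 0 for s in samples], dtype=int)
    return X, y


def split_dataset(
    samples: Sequence[FrameSample],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[list[FrameSample], list[FrameSample]]:
    """Seeded stratified split into train/test frame sets."""
    if len(samples) < 2:
        raise ValueError("need at least two samples to split")
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise ValueError("both classes must be present for a stratified split")
    n_train = round(train_fraction * len(samples))
    if n_train < 2 or len(samples) - n_train < 2:
        raise ValueError("split must leave at least one sample per class on each side")
    idx = np.arange(len(samples))
    strat = [s.label for s in samples]
    tr, te = train_test_split(
        idx, train_size=n_train, random_state=seed, stratify=strat, shuffle=True
    )
    return [samples[i] for i in sorted(tr)], [samples[i] for i in sorted(te)]


def split_by_animal(
    samples: Sequence[FrameSample],
    train_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[FrameSample], list[FrameSample]]:
    """Animal-disjoint split: whole transits go to one side or the other.

    The per-frame split is right for benchmarking frame classification, but
    generalisation to unseen animals needs the test animals absent from
    training; this is the split the animal-level verdict should be judged
    on.
    """
    ids = sorted({s.animal_id for s in samples})
    if None in ids:
        raise ValueError("all samples need an animal_id for a grouped split")
    by_label: dict[str, list] = {}
    for aid in ids:
        lab = next(s.label for s in samples if s.animal_id == aid)
        by_label.setdefault(lab, []).append(aid)
    rng = np.random.default_rng(seed)
    train_ids: set = set()
    for lab in sorted(by_label):
        group = by_label[lab]
        perm = rng.permutation(len(group))
        n_tr = max(1, round(train_fraction * len(group)))
        train_ids.update(group[i] for i in perm[:n_tr])
    tr = [s for s in samples if s.animal_id in train_ids]
    te = [s for s in samples if s.animal_id not in train_ids]
    return tr, te


def train(train_samples: Sequence[FrameSample], spec: ClassifierSpec) -> TrainedModel:
    """Fit a seeded frame-level binary model."""
    X, y = _xy(train_samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    est = _build_estimator(spec)
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, n_features=X.shape[1])


def _scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    est = model.estimator
    if hasattr(est, "predict_proba"):
        try:
            return est.predict_proba(X)[:, 1]
        except AttributeError:
            pass
    margin = est.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margin))  # logistic squash to [0, 1]


def predict_frames(
    model: TrainedModel, samples: Sequence[FrameSample]
) -> list[tuple[str, float]]:
    """Per-frame (label, lame-score in [0,1]) for each sample."""
    X, _ = _xy(samples)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model's {model.n_features}"
        )
    labels = model.estimator.predict(X)
    scores = _scores(model, X)
    return [("lame" if l == 1 else "sound", float(s)) for l, s in zip(labels, scores)]


def aggregate_animal(
    frame_predictions: Sequence[tuple[str, float]],
    threshold: float = 0.5,
    animal_id: Optional[int] = None,
) -> AnimalVerdict:
    """Animal verdict: mean lame-score across the transit's frames."""
    if len(frame_predictions) == 0:
        raise ValueError("cannot aggregate an empty track")
    p = float(np.mean([s for _, s in frame_predictions]))
    return AnimalVerdict(
        animal_id=animal_id,
        lame_probability=p,
        label="lame" if p >= threshold else "sound",
        n_frames=len(frame_predictions),
    )


def evaluate_classifier(model: TrainedModel, test_samples: Sequence[FrameSample]) -> float:
    """Frame-level accuracy percentage on a labelled test set, 2 decimals."""
    if len(test_samples) == 0:
        raise ValueError("empty test set")
    preds = predict_frames(model, test_samples)
    correct = sum(p[0] == s.label for p, s in zip(preds, test_samples))
    from .metrics import _round_half_up

    return _round_half_up(100.0 * correct / len(test_samples), 2)
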