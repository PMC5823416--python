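"""The Judge: frame classification and boundary estimation.

When the Monitor flags a suspicious window pair, the Judge classifies the
sampled frames of three target windows — the pair plus its preceding window,
giving context on both sides of a boundary sitting near either window edge —
with a radial-basis-kernel support-vector machine over CTVP descriptors
(features standardized to zero mean / unit variance with training-set
statistics; RBF kernels are scale-sensitive).

The predicted 0/1 label sequence is reduced to a boundary by the minimum-
misclassification step fit: the split index ``s`` minimizing

    (# labels 1 before s) + (# labels 0 at or after s)

over all splits leaving both sides non-empty, earliest index on ties. The
verdict is *accepted* when both classes are present among the predictions
and the split cost does not exceed ``accept_fraction`` of the judged frames;
otherwise the Monitor escalates and continues.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .csd import VROFMask
from .features import CTVP_LAYOUT, GLCMParams, PCParams, ctvp

__all__ = [
    "JudgeParams",
    "TrainedModel",
    "BoundaryEstimate",
    "train",
    "best_split",
    "estimate_boundary",
    "judge_pair",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class JudgeParams:
    """Classifier hyperparameters and the verdict-acceptance threshold."""

    C: float = 10.0
    gamma: str | float = "scale"
    accept_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.accept_fraction < 1:
            raise ValueError("accept_fraction must lie in (0, 1)")


def _layout_hash(layout: Sequence[str]) -> str:
    return hashlib.sha256("|".join(layout).encode()).hexdigest()[:16]


@dataclass
class TrainedModel:
    """Fitted standardize-then-SVC pipeline with its feature layout."""

    pipeline: Pipeline
    classes: np.ndarray
    feature_layout: tuple[str, ...] = CTVP_LAYOUT

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.atleast_2d(features))

    @property
    def layout_hash(self) -> str:
        return _layout_hash(self.feature_layout)


@dataclass
class BoundaryEstimate:
    """A candidate pylorus position with its supporting evidence."""

    boundary_frame: Optional[int]
    labels: np.ndarray
    split_cost: int
    accepted: bool
    judged_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def train(
    features: np.ndarray,
    labels: Sequence[int],
    params: JudgeParams | None = None,
) -> TrainedModel:
    """Fit the RBF-kernel classifier on CTVP descriptors.

    Deterministic for fixed hyperparameters and data order. Raises on
    single-class input — a boundary detector needs both organ classes.
    """
    params = params or JudgeParams()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be (n_samples, n_features) aligned with labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=params.C, gamma=params.gamma)),
        ]
    )
    pipe.fit(x, y)
    return TrainedModel(pipeline=pipe, classes=np.unique(y))


def best_split(labels: Sequence[int]) -> tuple[int, int]:
    """Minimum-misclassification step split of a 0/1 label sequence.

    Searches splits ``s`` in ``[1, n-1]`` (both sides non-empty); returns
    ``(s, cost)`` where ``cost = ones before s + zeros at/after s``, taking
    the earliest ``s`` on ties.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two labels to split")
    ones_before = np.concatenate([[0], np.cumsum(y)])  # ones in y[:s]
    zeros_after = np.concatenate([np.cumsum((1 - y)[::-1])[::-1], [0]])  # zeros in y[s:]
    costs = ones_before + zeros_after  # indexed by s = 0..n
    s = int(np.argmin(costs[1:n])) + 1  # earliest minimum in [1, n-1]
    return s, int(costs[s])


def estimate_boundary(
    labels: Sequence[int],
    frame_indices: Sequence[int],
    params: JudgeParams | None = None,
) -> BoundaryEstimate:
    """Turn predicted labels over sampled frames into a verdict.

    The chosen split maps back to the original frame index of the first
    frame on the intestinal side. Rejected when the predictions are
    single-class (no boundary evidence) or the split cost exceeds the
    acceptance fraction.
    """
    params = params or JudgeParams()
    y = np.asarray(labels, dtype=int)
    idx = np.asarray(frame_indices, dtype=int)
    if len(y) != len(idx):
        raise ValueError("labels and frame_indices must align")
    if len(y) < 2:
        raise ValueError("judged span too short")
    s, cost = best_split(y)
    both_classes = 0 in y and 1 in y
    accepted = both_classes and cost <= params.accept_fraction * len(y)
    return BoundaryEstimate(
        boundary_frame=int(idx[s]) if accepted else None,
        labels=y,
        split_cost=cost,
        accepted=accepted,
        judged_indices=idx,
    )


def judge_pair(
    frames: Sequence[np.ndarray],
    frame_indices: Sequence[int],
    model: TrainedModel,
    masks: Sequence[VROFMask],
    params: JudgeParams | None = None,
    *,
    pc_params: PCParams | None = None,
    glcm_params: GLCMParams | None = None,
) -> BoundaryEstimate:
    """Classify the sampled frames of a judged span and fit the step split.

    ``frames``/``masks``/``frame_indices`` are aligned: the sampled frames of
    the three target windows, their (reused) valid-region masks and their
    positions in the original sequence.
    """
    if model is None:
        raise ValueError("judge_pair requires a trained model")
    if not (len(frames) == len(frame_indices) == len(masks)):
        raise ValueError("frames, frame_indices and masks must align")
    feats = np.stack(
        [ctvp(f, m, pc_params, glcm_params).values for f, m in zip(frames, masks)]
    )
    labels = model.predict(feats)
    return estimate_boundary(labels, frame_indices, params)


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model with a format version and layout hash."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "layout": list(model.feature_layout),
            "layout_hash": model.layout_hash,
            "classes": model.classes,
            "pipeline": model.pipeline,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    layout = tuple(payload["layout"])
    if _layout_hash(layout) != payload["layout_hash"]:
        raise ValueError("model feature layout hash mismatch")
    return TrainedModel(
        pipeline=payload["pipeline"], classes=payload["classes"], feature_layout=layout
    )
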