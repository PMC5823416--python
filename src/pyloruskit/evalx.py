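"""Evaluation utilities: confusion-matrix metrics and boundary-error summaries.

Frame labels follow the convention 0 = stomach (before the pylorus),
1 = intestine (after). The counts are P_T (actually-positive frames
predicted positive), N_T (actually-negative predicted negative), P_F
(actually-positive predicted negative) and N_F (actually-negative predicted
positive).

Two metric conventions are offered. The default reproduces the printed
formulation verbatim:

    accuracy    = (P_T + N_T) / (P_T + P_F + N_T + N_F)
    sensitivity = N_T / (P_F + N_T)
    specificity = P_T / (N_F + P_T)

whose sensitivity/specificity assignments are unconventional (they read as
textbook definitions only under a specific labelling of which class is
"positive"). ``convention="standard"`` gives the textbook forms
sensitivity = P_T/(P_T+P_F), specificity = N_T/(N_T+N_F).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "LocationError",
    "confusion_from_labels",
    "metrics",
    "location_error",
]


@dataclass(frozen=True)
class ConfusionCounts:
    p_t: int  # positives predicted positive
    n_t: int  # negatives predicted negative
    p_f: int  # positives predicted negative
    n_f: int  # negatives predicted positive

    def __post_init__(self) -> None:
        if min(self.p_t, self.n_t, self.p_f, self.n_f) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.p_t + self.n_t + self.p_f + self.n_f


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_from_labels(
    true: Sequence[int], pred: Sequence[int], positive_label: int = 1
) -> ConfusionCounts:
    """Tally a 2-class confusion table from aligned label sequences."""
    t = np.asarray(true)
    p = np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError("label sequences must align")
    pos = t == positive_label
    return ConfusionCounts(
        p_t=int((pos & (p == positive_label)).sum()),
        n_t=int((~pos & (p != positive_label)).sum()),
        p_f=int((pos & (p != positive_label)).sum()),
        n_f=int((~pos & (p == positive_label)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    """Safe ratio; an empty denominator yields NaN as the undefined flag."""
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionCounts, convention: str = "printed") -> Metrics:
    """Accuracy, sensitivity and specificity of a confusion table."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (c.p_t + c.n_t) / c.total
    if convention == "printed":
        sensitivity = _ratio(c.n_t, c.p_f + c.n_t)
        specificity = _ratio(c.p_t, c.n_f + c.p_t)
    elif convention == "standard":
        sensitivity = _ratio(c.p_t, c.p_t + c.p_f)
        specificity = _ratio(c.n_t, c.n_t + c.n_f)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return Metrics(accuracy=accuracy, sensitivity=sensitivity, specificity=specificity)


@dataclass(frozen=True)
class LocationError:
    """Absolute boundary-frame errors across videos, with summaries.

    The median is reported alongside the mean because a single badly
    localized video dominates the mean while leaving the median untouched.
    """

    per_video_errors: tuple[int, ...]
    mean_error: float
    median_error: float


def location_error(
    estimates: Sequence[int], truths: Sequence[int]
) -> LocationError:
    """Per-video absolute frame errors between estimated and true boundaries."""
    est = np.asarray(estimates)
    tru = np.asarray(truths)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must align")
    if est.size == 0:
        raise ValueError("no videos to evaluate")
    errors = np.abs(est - tru)
    return LocationError(
        per_video_errors=tuple(int(e) for e in errors),
        mean_error=float(errors.mean()),
        median_error=float(np.median(errors)),
    )
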