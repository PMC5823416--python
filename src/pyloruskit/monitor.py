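"""The Monitor: sliding-window colour-dissimilarity trigger.

The frame sequence is cut into consecutive non-overlapping windows of ``m``
frames. For each window a mean Lab chroma ``(M_a, M_b)`` is computed from the
valid-region pixels of every ``sample_interval``-th frame (luminance is
excluded — capsule illumination is unstable, chroma is what shifts at an
organ boundary). The dissimilarity of a window pair is the Euclidean distance

    DC_k = sqrt((M_{a,k} - M_{a,k+1})^2 + (M_{b,k} - M_{b,k+1})^2)

and MDC is the running mean of the dissimilarities seen so far (initialized
to DC_1). A pair is *suspicious* when

    DC_k / MDC > 0.2 + 0.3 * t

where the escalation counter ``t`` starts at 0 and increments each time the
Judge inspects a suspicious pair and rejects it. The threshold sequence
0.2, 0.5, 0.8, 1.1, ... therefore quiets the trigger after a few false
alarms on a stationary stream, while a genuine organ transition produces a
ratio far above any escalated threshold. Processing stops at the first
accepted Judge verdict, so frames past the boundary are never touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .csd import SaliencyParams, VROFMask, compute_vrof

__all__ = [
    "MonitorParams",
    "WindowColorStats",
    "MonitorState",
    "MonitorOutcome",
    "frame_mean_color",
    "window_stats",
    "pair_dissimilarity",
    "monitor_step",
    "run_monitor",
]

_CHANNEL_INDEX = {"L": 0, "a": 1, "b": 2}


@dataclass(frozen=True)
class MonitorParams:
    """Windowing geometry and trigger-rule constants."""

    window_size: int = 100
    sample_interval: int = 5
    base_threshold: float = 0.2
    threshold_step: float = 0.3

    def __post_init__(self) -> None:
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        if self.window_size < 2 * self.sample_interval:
            raise ValueError("window_size must be at least 2 * sample_interval")
        if self.base_threshold <= 0 or self.threshold_step < 0:
            raise ValueError("need base_threshold > 0 and threshold_step >= 0")


@dataclass(frozen=True)
class WindowColorStats:
    """Mean valid-region chroma of one window of sampled frames."""

    window_index: int
    mean_a: float
    mean_b: float


@dataclass
class MonitorState:
    """Running trigger statistics across window pairs."""

    dc_history: list[float] = field(default_factory=list)
    mdc: Optional[float] = None
    t: int = 0
    n_triggers: int = 0
    triggered_pair: Optional[int] = None


@dataclass
class MonitorOutcome:
    """Result of a full monitor pass: the accepted estimate (if any) plus
    the final trigger state."""

    estimate: Optional[object]  # BoundaryEstimate from the judge, or None
    state: MonitorState
    n_judge_calls: int


def frame_mean_color(lab: np.ndarray, mask: VROFMask, channel: str) -> float:
    """Mean of one Lab channel over the valid region of a frame."""
    idx = _CHANNEL_INDEX[channel]
    if mask.n_valid == 0:
        raise ValueError("empty VROF mask; the full-frame fallback should apply upstream")
    return float(lab[..., idx][mask.mask].mean())


def sample_offsets(params: MonitorParams) -> np.ndarray:
    """Within-window frame offsets actually analysed (stride sampling)."""
    return np.arange(0, params.window_size, params.sample_interval)


def window_stats(
    frames: Sequence[np.ndarray],
    params: MonitorParams,
    *,
    window_index: int = 0,
    saliency_params: SaliencyParams | None = None,
) -> WindowColorStats:
    """Mean chroma of a window: average of per-frame valid-region means.

    ``frames`` is one window-sized slice of the sequence; every
    ``sample_interval``-th frame is converted to Lab, masked and averaged.
    """
    if len(frames) == 0:
        raise ValueError("empty window")
    means_a, means_b = [], []
    for off in range(0, len(frames), params.sample_interval):
        lab, mask = compute_vrof(frames[off], saliency_params)
        means_a.append(frame_mean_color(lab, mask, "a"))
        means_b.append(frame_mean_color(lab, mask, "b"))
    return WindowColorStats(
        window_index=window_index,
        mean_a=float(np.mean(means_a)),
        mean_b=float(np.mean(means_b)),
    )


def pair_dissimilarity(w1: WindowColorStats, w2: WindowColorStats) -> float:
    """Euclidean chroma distance between two window summaries."""
    return math.hypot(w1.mean_a - w2.mean_a, w1.mean_b - w2.mean_b)


def monitor_step(
    state: MonitorState, dc_k: float, params: MonitorParams
) -> tuple[MonitorState, bool]:
    """Apply the trigger rule to one window-pair dissimilarity.

    On the first call MDC is initialized to the incoming DC, so the first
    pair compares at ratio 1 and always triggers (1 > 0.2): the Judge vets
    the very start of the stream once, and its rejection escalates ``t``.
    MDC is then updated to the mean of every dissimilarity seen so far. A
    zero MDC with a non-zero DC is treated as a trigger — any change from
    perfect constancy is suspicious.
    """
    if state.mdc is None:
        state.mdc = dc_k
    threshold = params.base_threshold + params.threshold_step * state.t
    if state.mdc == 0:
        trigger = True
    else:
        trigger = dc_k / state.mdc > threshold
    state.dc_history.append(dc_k)
    # exact for a constant stream (a plain float mean would drift)
    if min(state.dc_history) == max(state.dc_history):
        state.mdc = state.dc_history[0]
    else:
        state.mdc = math.fsum(state.dc_history) / len(state.dc_history)
    if trigger:
        state.n_triggers += 1
    return state, trigger


def run_monitor(
    frames: Sequence[np.ndarray],
    params: MonitorParams,
    judge_fn: Callable[[int], object],
    *,
    saliency_params: SaliencyParams | None = None,
    stats_fn: Callable[[int], WindowColorStats] | None = None,
) -> MonitorOutcome:
    """Scan window pairs in order, escalating through Judge verdicts.

    ``judge_fn(pair_index)`` inspects the suspicious pair ``(W_k, W_{k+1})``
    (0-based ``pair_index = k``) and returns an estimate with an ``accepted``
    flag. The scan stops at the first accepted verdict; frames beyond the
    accepted pair's span are never accessed, which keeps the cost
    proportional to the frames actually visited (O(m * W * H) per window).

    ``stats_fn(window_index)`` overrides window-statistics computation (used
    by the pipeline to share per-frame work with the Judge).
    """
    n_windows = len(frames) // params.window_size
    if n_windows < 2:
        raise ValueError(
            f"need at least 2 windows of {params.window_size} frames, "
            f"got {len(frames)} frames"
        )

    def default_stats(k: int) -> WindowColorStats:
        start = k * params.window_size
        sl = [frames[i] for i in range(start, start + params.window_size)]
        return window_stats(
            sl, params, window_index=k, saliency_params=saliency_params
        )

    stats_of = stats_fn or default_stats
    state = MonitorState()
    n_judge_calls = 0
    prev = stats_of(0)
    for k in range(n_windows - 1):
        cur = stats_of(k + 1)
        dc_k = pair_dissimilarity(prev, cur)
        state, trigger = monitor_step(state, dc_k, params)
        if trigger:
            n_judge_calls += 1
            estimate = judge_fn(k)
            if getattr(estimate, "accepted", False):
                state.triggered_pair = k
                return MonitorOutcome(estimate=estimate, state=state,
                                      n_judge_calls=n_judge_calls)
            state.t += 1
        prev = cur
    return MonitorOutcome(estimate=None, state=state, n_judge_calls=n_judge_calls)
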