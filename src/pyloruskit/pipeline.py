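"""End-to-end boundary localization: wiring Monitor, Judge and features.

``locate_pylorus`` runs the full method on a frame sequence: per-frame
valid-region masks and chroma means feed the Monitor's window statistics; on
a trigger, the Judge classifies the sampled frames of the three target
windows (the triggered pair plus its predecessor) and either returns an
accepted boundary or escalates the trigger threshold. Per-frame work (Lab
conversion, masks, descriptors) is cached by frame index, so the Judge
reuses the Monitor's masks and repeated triggers never recompute a frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import judge as judge_mod
from .csd import SaliencyParams, VROFMask, compute_vrof
from .features import GLCMParams, PCParams, ctvp
from .judge import BoundaryEstimate, JudgeParams, TrainedModel
from .monitor import (
    MonitorParams,
    MonitorState,
    WindowColorStats,
    frame_mean_color,
    run_monitor,
)
from .synthetic import INTESTINE, STOMACH, SyntheticConfig, generate_frame

__all__ = ["LocateResult", "FrameAnalyzer", "locate_pylorus", "synthetic_training_set"]


@dataclass
class LocateResult:
    """Outcome of a full locate run."""

    boundary_frame: Optional[int]
    accepted: bool
    n_judge_calls: int
    t_final: int
    trigger_history: list[dict]
    estimate: Optional[BoundaryEstimate]
    state: MonitorState


class FrameAnalyzer:
    """Per-frame cache of masks, chroma means and CTVP descriptors."""

    def __init__(
        self,
        frames: Sequence[np.ndarray],
        saliency_params: SaliencyParams | None = None,
        pc_params: PCParams | None = None,
        glcm_params: GLCMParams | None = None,
    ):
        self.frames = frames
        self.saliency_params = saliency_params or SaliencyParams()
        self.pc_params = pc_params or PCParams()
        self.glcm_params = glcm_params or GLCMParams()
        self._masks: dict[int, VROFMask] = {}
        self._chroma: dict[int, tuple[float, float]] = {}
        self._ctvp: dict[int, np.ndarray] = {}

    def mask(self, i: int) -> VROFMask:
        self._analyze(i)
        return self._masks[i]

    def chroma(self, i: int) -> tuple[float, float]:
        """Valid-region mean (a, b) chroma of frame ``i``."""
        self._analyze(i)
        return self._chroma[i]

    def _analyze(self, i: int) -> None:
        if i in self._masks:
            return
        lab, mask = compute_vrof(self.frames[i], self.saliency_params)
        self._masks[i] = mask
        self._chroma[i] = (
            frame_mean_color(lab, mask, "a"),
            frame_mean_color(lab, mask, "b"),
        )

    def descriptor(self, i: int) -> np.ndarray:
        if i not in self._ctvp:
            self._ctvp[i] = ctvp(
                self.frames[i], self.mask(i), self.pc_params, self.glcm_params
            ).values
        return self._ctvp[i]


def _window_sample_indices(window: int, params: MonitorParams) -> np.ndarray:
    start = window * params.window_size
    return start + np.arange(0, params.window_size, params.sample_interval)


def locate_pylorus(
    frames: Sequence[np.ndarray],
    model: TrainedModel,
    monitor_params: MonitorParams | None = None,
    judge_params: JudgeParams | None = None,
    saliency_params: SaliencyParams | None = None,
    pc_params: PCParams | None = None,
    glcm_params: GLCMParams | None = None,
) -> LocateResult:
    """Locate the stomach/intestine boundary in an ordered frame sequence."""
    monitor_params = monitor_params or MonitorParams()
    judge_params = judge_params or JudgeParams()
    analyzer = FrameAnalyzer(frames, saliency_params, pc_params, glcm_params)
    n_windows = len(frames) // monitor_params.window_size
    trigger_history: list[dict] = []

    def stats_fn(window: int) -> WindowColorStats:
        idx = _window_sample_indices(window, monitor_params)
        ab = np.array([analyzer.chroma(int(i)) for i in idx])
        return WindowColorStats(
            window_index=window, mean_a=float(ab[:, 0].mean()), mean_b=float(ab[:, 1].mean())
        )

    def judge_fn(pair_k: int) -> BoundaryEstimate:
        # three target windows: the triggered pair plus the preceding window
        lo = max(pair_k - 1, 0)
        hi = min(pair_k + 1, n_windows - 1)
        idx = np.concatenate(
            [_window_sample_indices(w, monitor_params) for w in range(lo, hi + 1)]
        )
        feats = np.stack([analyzer.descriptor(int(i)) for i in idx])
        labels = model.predict(feats)
        est = judge_mod.estimate_boundary(labels, idx, judge_params)
        trigger_history.append(
            {
                "pair": int(pair_k),
                "accepted": bool(est.accepted),
                "split_cost": int(est.split_cost),
                "boundary_frame": est.boundary_frame,
            }
        )
        return est

    outcome = run_monitor(frames, monitor_params, judge_fn, stats_fn=stats_fn)
    est = outcome.estimate
    return LocateResult(
        boundary_frame=est.boundary_frame if est is not None else None,
        accepted=est is not None and est.accepted,
        n_judge_calls=outcome.n_judge_calls,
        t_final=outcome.state.t,
        trigger_history=trigger_history,
        estimate=est,
        state=outcome.state,
    )


def synthetic_training_set(
    cfg: SyntheticConfig,
    n_per_class: int,
    seed: int,
    *,
    saliency_params: SaliencyParams | None = None,
    pc_params: PCParams | None = None,
    glcm_params: GLCMParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CTVP descriptors for a balanced stomach/intestine training draw.

    Frames are rendered with the generator's appearance settings but an
    independent seed, so a model trained here never sees the evaluation
    sequences themselves.
    """
    pc_params = pc_params or PCParams()
    glcm_params = glcm_params or GLCMParams()
    feats, labels = [], []
    for j in range(n_per_class):
        for label, organ in ((0, STOMACH), (1, INTESTINE)):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), int(label), int(j)))
            )
            frame = generate_frame(organ, cfg, rng)
            _, mask = compute_vrof(frame, saliency_params)
            feats.append(ctvp(frame, mask, pc_params, glcm_params).values)
            labels.append(label)
    return np.stack(feats), np.asarray(labels)
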