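"""Seeded generator of endoscopy-like frame sequences.

Real capsule-endoscopy recordings of the gastro-duodenal transition are not
publicly distributable, so every downstream stage of the pipeline is exercised
on synthetic sequences that reproduce the properties the method relies on:

* reddish, smooth stomach-like tissue versus yellower intestine-like tissue
  carrying a quasi-periodic villi texture,
* an abrupt colour shift at a known boundary frame (the pylorus),
* localized disturbances — overexposed specular blobs, deep shadows, bubble
  rings and low-chroma fluid patches — that the valid-region mask must reject.

Frames are 8-bit RGB arrays. Identical configuration and seed always yield a
bit-identical sequence; each frame draws from its own child random stream so a
sequence can be materialized lazily and out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "STOMACH",
    "INTESTINE",
    "SyntheticConfig",
    "GroundTruth",
    "Disturbance",
    "generate_frame",
    "generate_video",
    "SyntheticVideo",
]

STOMACH = "stomach"
INTESTINE = "intestine"

#: Disturbance kinds, in the (fixed) order they are drawn per frame.
DISTURBANCE_KINDS = ("overexposure", "shadow", "bubble", "fluid")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic frame sequence.

    The defaults emulate the clinical recording format: 256x240-pixel frames,
    a reddish stomach phase and a yellower, villi-textured intestinal phase.
    """

    n_frames: int = 200
    boundary_frame: int = 100
    frame_width: int = 256
    frame_height: int = 240
    stomach_color: tuple[float, float, float] = (165.0, 75.0, 60.0)
    intestine_color: tuple[float, float, float] = (175.0, 140.0, 70.0)
    color_noise_sd: float = 3.0
    villi_amplitude: float = 25.0
    disturbance_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not 0 <= self.boundary_frame < self.n_frames:
            raise ValueError(
                f"boundary_frame {self.boundary_frame} outside [0, {self.n_frames})"
            )
        if self.frame_width < 16 or self.frame_height < 16:
            raise ValueError("frame dimensions must be at least 16 pixels")
        if self.color_noise_sd < 0 or self.villi_amplitude < 0:
            raise ValueError("noise and texture amplitudes must be non-negative")
        if not 0.0 <= self.disturbance_rate <= 1.0:
            raise ValueError("disturbance_rate must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """True boundary position and the implied per-frame organ labels.

    Labels follow the step convention: 0 (stomach) strictly before the
    boundary frame, 1 (intestine) from the boundary frame onward.
    """

    boundary_frame: int
    n_frames: int

    @property
    def per_frame_labels(self) -> np.ndarray:
        labels = np.zeros(self.n_frames, dtype=np.int8)
        labels[self.boundary_frame :] = 1
        return labels


@dataclass(frozen=True)
class Disturbance:
    """A single injected disturbance with its exact pixel footprint."""

    kind: str
    center: tuple[int, int]  # (row, col)
    radius: int
    pixels: np.ndarray = field(repr=False)  # boolean (H, W) footprint


def _frame_rng(cfg: SyntheticConfig, index: int) -> np.random.Generator:
    """Independent, reproducible random stream for one frame."""
    return np.random.default_rng(np.random.SeedSequence((int(cfg.seed), int(index))))


@lru_cache(maxsize=8)
def _villi_texture(shape: tuple[int, int], amplitude: float, seed: int) -> np.ndarray:
    """Quasi-periodic bump lattice: thresholded band-pass noise.

    Band-limited white noise (difference of two Gaussian smoothings) is
    rectified above half a standard deviation, producing bright-edged bumps
    at a villus-like spatial scale without modelling anatomy. The pattern is
    a fixed function of the sequence seed, not of the frame, so noise-free
    intestinal frames are identical (the mucosal pattern persists between
    frames far more than the capsule's photometric noise does).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7111)))
    noise = rng.standard_normal(shape)
    band = ndimage.gaussian_filter(noise, 1.5) - ndimage.gaussian_filter(noise, 4.0)
    sd = band.std()
    if sd == 0:
        return np.zeros(shape)
    bumps = np.clip(band / sd - 0.5, 0.0, None)
    return amplitude * bumps


def _disk(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _annulus(shape, center, r_outer, r_inner) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 <= r_outer**2) & (d2 >= r_inner**2)


def _place(rng: np.random.Generator, shape: tuple[int, int]) -> tuple[tuple[int, int], int]:
    """Seeded placement of a disturbance primitive: center and radius."""
    min_dim = min(shape)
    radius = int(rng.integers(min_dim // 16, min_dim // 8 + 1))
    row = int(rng.integers(radius, shape[0] - radius))
    col = int(rng.integers(radius, shape[1] - radius))
    return (row, col), radius


def _inject_disturbance(img: np.ndarray, kind: str,
                        rng: np.random.Generator) -> Disturbance:
    """Paint one disturbance primitive in place and return its footprint."""
    shape = img.shape[:2]
    center, radius = _place(rng, shape)
    if kind == "overexposure":
        pixels = _disk(shape, center, radius)
        img[pixels] = np.array([252.0, 250.0, 246.0]) + rng.normal(0, 1.0, (int(pixels.sum()), 3))
    elif kind == "shadow":
        pixels = _disk(shape, center, radius)
        img[pixels] = np.array([8.0, 8.0, 9.0]) + rng.normal(0, 1.5, (int(pixels.sum()), 3))
    elif kind == "bubble":
        # thin bright ring with a washed-out, low-chroma interior
        r_inner = max(radius - max(2, radius // 4), 1)
        ring = _annulus(shape, center, radius, r_inner)
        interior = _disk(shape, center, r_inner)
        img[ring] = np.array([205.0, 205.0, 200.0]) + rng.normal(0, 2.0, (int(ring.sum()), 3))
        img[interior] = np.array([140.0, 138.0, 132.0]) + rng.normal(
            0, 2.0, (int(interior.sum()), 3)
        )
        pixels = ring | interior
    elif kind == "fluid":
        pixels = _disk(shape, center, radius)
        img[pixels] = np.array([150.0, 148.0, 135.0]) + rng.normal(0, 2.0, (int(pixels.sum()), 3))
    else:
        raise ValueError(f"unknown disturbance kind {kind!r}")
    return Disturbance(kind=kind, center=center, radius=radius, pixels=pixels)


def generate_frame(
    organ: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    *,
    return_disturbances: bool = False,
):
    """Render one synthetic frame for the given organ phase.

    Stomach frames are a flat reddish field plus pixel noise; intestine frames
    additionally carry the villi bump texture and a yellower base colour.
    Each configured disturbance kind is injected independently with
    probability ``cfg.disturbance_rate``; the draws happen in a fixed order so
    the frame is a pure function of ``(organ, cfg, rng state)``.
    """
    if organ == STOMACH:
        base = np.array(cfg.stomach_color, dtype=float)
        textured = False
    elif organ == INTESTINE:
        base = np.array(cfg.intestine_color, dtype=float)
        textured = True
    else:
        raise ValueError(f"organ must be {STOMACH!r} or {INTESTINE!r}, got {organ!r}")

    shape = (cfg.frame_height, cfg.frame_width)
    img = np.broadcast_to(base, shape + (3,)).astype(float).copy()
    if cfg.color_noise_sd > 0:
        img += rng.normal(0.0, cfg.color_noise_sd, img.shape)
    if textured and cfg.villi_amplitude > 0:
        # villi read as darker pits against the mucosa
        img -= _villi_texture(shape, cfg.villi_amplitude, cfg.seed)[..., None]

    disturbances: list[Disturbance] = []
    for kind in DISTURBANCE_KINDS:
        if rng.random() < cfg.disturbance_rate:
            disturbances.append(_inject_disturbance(img, kind, rng))

    frame = np.clip(img, 0, 255).astype(np.uint8)
    if return_disturbances:
        return frame, disturbances
    return frame


class SyntheticVideo:
    """Lazy, indexable synthetic frame sequence with a known boundary.

    Frames are rendered on first access and cached; ``decode_count`` and
    ``max_decoded_index`` expose how much of the sequence was actually
    materialized, which lets tests verify that the locator stops early.
    """

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        self.ground_truth = GroundTruth(cfg.boundary_frame, cfg.n_frames)
        self._cache: dict[int, np.ndarray] = {}
        self.decode_count = 0
        self.max_decoded_index = -1

    def __len__(self) -> int:
        return self.cfg.n_frames

    def _organ(self, index: int) -> str:
        return INTESTINE if index >= self.cfg.boundary_frame else STOMACH

    def __getitem__(self, index: int) -> np.ndarray:
        if not 0 <= index < len(self):
            raise IndexError(index)
        if index not in self._cache:
            self.decode_count += 1
            self.max_decoded_index = max(self.max_decoded_index, index)
            self._cache[index] = generate_frame(
                self._organ(index), self.cfg, _frame_rng(self.cfg, index)
            )
        return self._cache[index]

    def frame_with_disturbances(self, index: int) -> tuple[np.ndarray, list[Disturbance]]:
        """Re-render frame ``index`` together with its disturbance records."""
        return generate_frame(
            self._organ(index), self.cfg, _frame_rng(self.cfg, index),
            return_disturbances=True,
        )

    def __iter__(self) -> Iterator[np.ndarray]:
        return (self[i] for i in range(len(self)))


def generate_video(cfg: SyntheticConfig) -> tuple[SyntheticVideo, GroundTruth]:
    """Build a lazy frame sequence and its ground truth from a config."""
    video = SyntheticVideo(cfg)
    return video, video.ground_truth
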