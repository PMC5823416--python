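"""Reading and writing frame directories and ground-truth sidecars."""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from .synthetic import GroundTruth, SyntheticVideo

__all__ = ["FrameDirectory", "write_video", "read_ground_truth"]

_FRAME_RE = re.compile(r"(\d+)\.(png|jpg|jpeg)$", re.IGNORECASE)


class FrameDirectory:
    """Lazy frame sequence backed by numbered image files in a directory.

    Files matching ``*<index>.png/jpg`` are ordered by their numeric suffix.
    Decoding is lazy and counted, mirroring :class:`SyntheticVideo`.
    """

    def __init__(self, path):
        self.path = Path(path)
        pairs = []
        for p in sorted(self.path.iterdir()):
            m = _FRAME_RE.search(p.name)
            if m:
                pairs.append((int(m.group(1)), p))
        if not pairs:
            raise FileNotFoundError(f"no numbered frames found in {self.path}")
        pairs.sort()
        self._files = [p for _, p in pairs]
        self._cache: dict[int, np.ndarray] = {}
        self.decode_count = 0

    def __len__(self) -> int:
        return len(self._files)

    def __getitem__(self, index: int) -> np.ndarray:
        if index not in self._cache:
            self.decode_count += 1
            frame = iio.imread(self._files[index])
            if frame.ndim == 3 and frame.shape[2] == 4:
                frame = frame[..., :3]
            self._cache[index] = np.ascontiguousarray(frame)
        return self._cache[index]

    def __iter__(self) -> Iterator[np.ndarray]:
        return (self[i] for i in range(len(self)))


def write_video(video: SyntheticVideo, out_dir) -> Path:
    """Write a synthetic sequence as zero-padded PNGs plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(len(video)):
        iio.imwrite(out / f"frame_{i:06d}.png", video[i])
    gt = video.ground_truth
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "boundary_frame": gt.boundary_frame,
                "labels": gt.per_frame_labels.tolist(),
            }
        )
    )
    return out


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        boundary_frame=int(payload["boundary_frame"]),
        n_frames=len(payload["labels"]),
    )
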