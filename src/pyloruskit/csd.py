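"""Colour-saliency detection (CSD) and the valid-region mask (VROF).

Endoscopy frames are cluttered with disturbances — food debris, shadows,
specular overexposure, air bubbles, fluid — whose colour departs from
digestive-tract tissue. In CIE Lab space, tissue sits high on the a (red)
axis relative to every disturbance, so a saliency score built from the
per-pixel deviation of the a and b channels from their image-wide means
separates tissue from clutter.

The saliency map is

    S(x, y) = (a(x, y) - a_u)^alpha + |b(x, y) - b_u|^beta

computed on Gaussian-blurred a, b channels, where a_u and b_u are the image
means, alpha is an odd integer (default 3) and beta a fractional exponent in
(1, alpha) (default 1.5). The odd signed power makes pixels redder than
average score positive while bright/achromatic disturbances score strongly
negative; the absolute value on the b term keeps the fractional power real.
The valid region of the frame (VROF) is the positive set {S > 0}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab

logger = logging.getLogger(__name__)

__all__ = [
    "SaliencyParams",
    "SaliencyMap",
    "VROFMask",
    "to_lab",
    "blur",
    "saliency",
    "vrof",
    "compute_vrof",
]


@dataclass(frozen=True)
class SaliencyParams:
    """Exponents and blur scales of the colour-saliency score.

    ``sigma2`` is tied to ``sigma1`` in the 1:1.6 ratio of a difference-of-
    Gaussians band-pass; the default pipeline applies only the ``sigma1``
    Gaussian (``use_dog=False``), keeping the DC component that the mean-
    deviation saliency score needs, while ``use_dog=True`` exposes the
    band-pass variant.
    """

    alpha: int = 3
    beta: float = 1.5
    sigma1: float = 1.0
    sigma2: float = 1.6
    use_dog: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 1 or self.alpha % 2 == 0:
            raise ValueError("alpha must be an odd integer greater than 1")
        if not 1.0 < self.beta < self.alpha:
            raise ValueError("beta must satisfy 1 < beta < alpha")
        if self.sigma1 <= 0 or self.sigma2 <= self.sigma1:
            raise ValueError("need 0 < sigma1 < sigma2")


@dataclass
class SaliencyMap:
    values: np.ndarray  # per-pixel S(x, y)
    mean_a: float  # image-wide mean of the (blurred) a channel
    mean_b: float


@dataclass
class VROFMask:
    """Boolean validity map; ``fallback`` marks a degenerate full-frame mask."""

    mask: np.ndarray
    n_valid: int
    fallback: bool = False


def to_lab(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to CIE Lab (sRGB primaries, D65 white).

    Returns a float array with L in [0, 100] and signed a, b channels.
    """
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        raise ValueError(f"expected 8-bit input, got dtype {frame.dtype}")
    return rgb2lab(frame)


def blur(lab: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """Low-pass (or band-pass) filter the a and b channels.

    Reflective boundary handling preserves the channel means, so the
    image-wide averages entering the saliency score are unaffected by the
    smoothing itself.
    """
    out = lab.copy()
    for ch in (1, 2):
        g1 = ndimage.gaussian_filter(lab[..., ch], params.sigma1, mode="reflect")
        if params.use_dog:
            g2 = ndimage.gaussian_filter(lab[..., ch], params.sigma2, mode="reflect")
            out[..., ch] = g1 - g2
        else:
            out[..., ch] = g1
    return out


def saliency(lab_blurred: np.ndarray, params: SaliencyParams) -> SaliencyMap:
    """Per-pixel colour-saliency score from blurred a, b channels."""
    a = lab_blurred[..., 1]
    b = lab_blurred[..., 2]
    a_u = float(a.mean())
    b_u = float(b.mean())
    s = (a - a_u) ** params.alpha + np.abs(b - b_u) ** params.beta
    return SaliencyMap(values=s, mean_a=a_u, mean_b=b_u)


def vrof(sal: SaliencyMap, *, floor_fraction: float = 0.01,
         atol: float = 1e-9) -> VROFMask:
    """Threshold the saliency map at zero to obtain the valid region.

    Positivity is taken up to ``atol``: a nominally constant frame carries
    round-off of order 1e-16 through the colour conversion, and the
    absolute-valued b term would otherwise mark such noise as "valid". If
    fewer than ``floor_fraction`` of pixels are positive (e.g. a constant
    frame gives S == 0 everywhere) the mask degenerates; downstream
    statistics divide by the valid-pixel count, so the whole frame is used
    instead and the result flagged.
    """
    mask = sal.values > atol
    n_valid = int(mask.sum())
    if n_valid < floor_fraction * mask.size:
        logger.warning(
            "VROF degenerate (%d/%d valid pixels); falling back to full frame",
            n_valid, mask.size,
        )
        full = np.ones_like(mask, dtype=bool)
        return VROFMask(mask=full, n_valid=full.size, fallback=True)
    return VROFMask(mask=mask, n_valid=n_valid, fallback=False)


def compute_vrof(
    frame: np.ndarray, params: SaliencyParams | None = None
) -> tuple[np.ndarray, VROFMask]:
    """Full per-frame pipeline: Lab conversion, blur, saliency, mask.

    Returns the (unblurred) Lab image — whose channel values feed the colour
    statistics — together with the valid-region mask.
    """
    params = params or SaliencyParams()
    lab = to_lab(frame)
    sal = saliency(blur(lab, params), params)
    return lab, vrof(sal)
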