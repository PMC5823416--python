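"""The fused colour-texture descriptor (CTVP) and its building blocks.

Texture arm
-----------
Intestinal mucosa is densely textured by villi while the stomach lining is
comparatively smooth. Phase congruency — the degree to which local Fourier
components are in phase — marks this structure independently of image
contrast. Per orientation ``o`` it is the weighted, noise-compensated local
energy over a log-Gabor scale bank divided by the total response amplitude:

    PC_o(x) = W_o(x) * max(E_o(x) - T_o, 0) / (sum_s A_so(x) + eps)

The orientation maps are condensed into the *maximum moment* of their
covariance,

    M = (a + c + sqrt(b^2 + (a - c)^2)) / 2,
    a = sum_o (PC_o cos o)^2,  b = 2 sum_o PC_o^2 sin o cos o,
    c = sum_o (PC_o sin o)^2,

the larger principal value, i.e. structure strength regardless of
orientation. A grey-level co-occurrence matrix (GLCM) of the quantized M map
then yields contrast, correlation, energy and homogeneity, each averaged
over the four standard displacement orientations.

Colour arm
----------
Hue and saturation histograms (16 bins each) in HSI space, computed over the
valid-region mask only; intensity is dropped because capsule illumination is
unstable.

The concatenation — 4 GLCM statistics + 16 hue bins + 16 saturation bins —
is the 36-dimensional CTVP vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.color import rgb2gray

from .csd import VROFMask

__all__ = [
    "PCParams",
    "PCResult",
    "GLCMParams",
    "GLCMFeatures",
    "HSHistogram",
    "CTVPVector",
    "log_gabor_bank",
    "phase_congruency",
    "max_moment",
    "glcm",
    "glcm_features",
    "rgb_to_hsi",
    "hs_histogram",
    "ctvp",
    "CTVP_LAYOUT",
]


# --------------------------------------------------------------------------
# phase congruency
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCParams:
    """Log-Gabor bank geometry and noise compensation for phase congruency.

    ``min_wavelength`` (pixels) and ``mult`` set the scale ladder
    ``min_wavelength * mult**s``; ``sigma_onf`` is the bandwidth ratio of
    each log-Gabor; ``noise_comp_k`` is the number of noise-amplitude
    standard deviations added to the Rayleigh noise-energy estimate T_o;
    ``cutoff``/``gain`` shape the frequency-spread weighting sigmoid.
    """

    n_scales: int = 4
    n_orientations: int = 6
    min_wavelength: float = 3.0
    mult: float = 2.1
    sigma_onf: float = 0.55
    noise_comp_k: float = 2.0
    epsilon: float = 1e-4
    cutoff: float = 0.5
    gain: float = 10.0

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("need at least 2 orientations")
        if self.n_scales < 1:
            raise ValueError("need at least 1 scale")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def orientation_angles(self) -> np.ndarray:
        """Filter orientations, evenly spaced over 180 degrees (radians)."""
        return np.arange(self.n_orientations) * np.pi / self.n_orientations


@dataclass
class PCResult:
    """Per-orientation phase-congruency maps plus covariance moments."""

    pc_maps: np.ndarray  # (n_orientations, H, W), values in [0, 1]
    orientations: np.ndarray  # angles in radians
    moment_a: Optional[np.ndarray] = None
    moment_b: Optional[np.ndarray] = None
    moment_c: Optional[np.ndarray] = None
    max_moment_map: Optional[np.ndarray] = None


def log_gabor_bank(params: PCParams, shape: tuple[int, int]) -> np.ndarray:
    """Frequency-domain bank of oriented log-Gabor filters.

    Returns an array of shape ``(n_scales, n_orientations, H, W)`` in
    unshifted FFT layout. Log-Gabor filters have no DC component by
    construction (the radial term is zeroed at frequency 0), so a constant
    image produces zero response at every scale and orientation.
    """
    rows, cols = shape
    if rows < 2 or cols < 2:
        raise ValueError(f"degenerate shape {shape}")
    fy = np.fft.fftfreq(rows)
    fx = np.fft.fftfreq(cols)
    u2, u1 = np.meshgrid(fy, fx, indexing="ij")
    radius = np.hypot(u1, u2)
    radius[0, 0] = 1.0  # avoid log(0); the DC gain is zeroed explicitly
    theta = np.arctan2(-u2, u1)
    sintheta, costheta = np.sin(theta), np.cos(theta)

    # large-order Butterworth low-pass keeps the widest scales inside Nyquist
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** (2 * 15))

    log_sigma = np.log(params.sigma_onf) ** 2
    bank = np.empty((params.n_scales, params.n_orientations, rows, cols))
    radials = []
    for s in range(params.n_scales):
        f0 = 1.0 / (params.min_wavelength * params.mult**s)
        radial = np.exp(-(np.log(radius / f0) ** 2) / (2 * log_sigma)) * lowpass
        radial[0, 0] = 0.0
        radials.append(radial)
    for o, angl in enumerate(params.orientation_angles):
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.minimum(np.abs(np.arctan2(ds, dc)) * params.n_orientations / 2, np.pi)
        spread = (np.cos(dtheta) + 1) / 2
        for s in range(params.n_scales):
            bank[s, o] = radials[s] * spread
    return bank


def phase_congruency(gray: np.ndarray, params: PCParams | None = None) -> PCResult:
    """Two-dimensional phase congruency of a single-channel image.

    For each orientation, the scale bank's complex responses are summed into
    a local-energy vector; the energy in excess of the Rayleigh-based noise
    threshold T_o, weighted by the frequency-spread sigmoid, is normalized
    by the total amplitude. Values are clipped to [0, 1]. The measure is
    invariant to a global intensity rescaling (both energy and the noise
    estimate scale linearly).
    """
    params = params or PCParams()
    if gray.ndim != 2:
        raise ValueError("phase congruency expects a single-channel image")
    img = np.asarray(gray, dtype=float)
    bank = log_gabor_bank(params, img.shape)
    im_fft = np.fft.fft2(img)

    pc_maps = np.empty((params.n_orientations,) + img.shape)
    for o in range(params.n_orientations):
        e_parts, o_parts = [], []
        sum_an = np.zeros(img.shape)
        max_an = np.zeros(img.shape)
        tau = 0.0
        for s in range(params.n_scales):
            eo = np.fft.ifft2(im_fft * bank[s, o])
            e, od = eo.real, eo.imag
            an = np.abs(eo)
            e_parts.append(e)
            o_parts.append(od)
            sum_an += an
            np.maximum(max_an, an, out=max_an)
            if s == 0:
                # Rayleigh scale of the smallest-wavelength response:
                # its median is tau * sqrt(ln 4)
                tau = float(np.median(an)) / np.sqrt(np.log(4))
        sum_e = np.sum(e_parts, axis=0)
        sum_o = np.sum(o_parts, axis=0)
        x_energy = np.hypot(sum_e, sum_o) + params.epsilon
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        # energy = sum over scales of A_so * cos(phase deviation) - |sin(...)|
        energy = np.zeros(img.shape)
        for e, od in zip(e_parts, o_parts):
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        # total noise amplitude over the geometric scale ladder
        total_tau = tau * (1 - (1 / params.mult) ** params.n_scales) / (1 - 1 / params.mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        t_o = noise_mean + params.noise_comp_k * noise_sigma
        energy = np.maximum(energy - t_o, 0.0)
        # penalize narrow frequency spread
        if params.n_scales > 1:
            width = (sum_an / (max_an + params.epsilon) - 1) / (params.n_scales - 1)
        else:
            width = np.ones(img.shape)
        weight = 1.0 / (1.0 + np.exp(params.gain * (params.cutoff - width)))
        pc_maps[o] = np.clip(weight * energy / (sum_an + params.epsilon), 0.0, 1.0)

    return PCResult(pc_maps=pc_maps, orientations=params.orientation_angles.copy())


def max_moment(pc: PCResult) -> np.ndarray:
    """Maximum moment of the phase-congruency covariance.

    The per-pixel covariance of the orientation responses has principal
    values ``(a + c ± sqrt(b² + (a − c)²)) / 2``; the larger one highlights
    edge/texture strength regardless of orientation. The moment sums are
    cached on the result object.
    """
    angles = pc.orientations
    cos_o = np.cos(angles)[:, None, None]
    sin_o = np.sin(angles)[:, None, None]
    p = pc.pc_maps
    a = ((p * cos_o) ** 2).sum(axis=0)
    b = 2.0 * (p**2 * sin_o * cos_o).sum(axis=0)
    c = ((p * sin_o) ** 2).sum(axis=0)
    m = (a + c + np.sqrt(b**2 + (a - c) ** 2)) / 2.0
    pc.moment_a, pc.moment_b, pc.moment_c = a, b, c
    pc.max_moment_map = m
    return m


# --------------------------------------------------------------------------
# grey-level co-occurrence matrix
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCMParams:
    """Displacement geometry and quantization of the co-occurrence matrix."""

    distance: int = 1
    orientations: tuple[int, ...] = (0, 45, 90, 135)
    levels: int = 16
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        for ang in self.orientations:
            if ang % 45 != 0:
                raise ValueError("orientations must be multiples of 45 degrees")


@dataclass
class GLCMFeatures:
    """Orientation-averaged co-occurrence statistics."""

    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    correlation_defined: bool = True


def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Uniform min–max quantization of a real map into integer grey levels."""
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = ((values - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def _offset(angle_deg: int, d: int) -> tuple[int, int]:
    """Integer (row, col) displacement for a 45-degree-multiple orientation."""
    angle = angle_deg % 180
    return {
        0: (0, d),
        45: (-d, d),
        90: (-d, 0),
        135: (-d, -d),
    }[angle]


def glcm(
    values: np.ndarray,
    params: GLCMParams | None = None,
    *,
    quantized: bool = False,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized co-occurrence matrices, one per displacement orientation.

    ``values`` is either a real map (min–max quantized into ``levels``
    bins) or, with ``quantized=True``, an integer map already in
    ``[0, levels)``. Pair counts at displacement ``(distance, theta)`` are
    accumulated (plus the reverse displacement when ``symmetric``) and
    normalized to sum to 1. ``valid`` optionally restricts counting to
    pairs whose two pixels are both inside a boolean mask.

    Returns an array of shape ``(len(orientations), levels, levels)``.
    """
    params = params or GLCMParams()
    if quantized:
        q = np.asarray(values, dtype=np.intp)
        if q.min() < 0 or q.max() >= params.levels:
            raise ValueError("quantized input outside [0, levels)")
    else:
        q = quantize(values, params.levels)
    rows, cols = q.shape
    out = np.zeros((len(params.orientations), params.levels, params.levels))
    for k, ang in enumerate(params.orientations):
        dr, dc = _offset(ang, params.distance)
        if abs(dr) >= rows or abs(dc) >= cols:
            raise ValueError(
                f"map {q.shape} smaller than displacement {(dr, dc)} at {ang} deg"
            )
        # source/target slices for the (dr, dc) shift
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        src = q[r0:r1, c0:c1]
        dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if valid is not None:
            keep = valid[r0:r1, c0:c1] & valid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            src, dst = src[keep], dst[keep]
        mat = np.zeros((params.levels, params.levels))
        np.add.at(mat, (src.ravel(), dst.ravel()), 1.0)
        if params.symmetric:
            mat = mat + mat.T
        total = mat.sum()
        if total == 0:
            raise ValueError("no co-occurring pairs for this displacement")
        out[k] = mat / total
    return out


def glcm_features(
    matrices: np.ndarray, *, homogeneity_variant: str = "standard"
) -> GLCMFeatures:
    """Contrast, correlation, energy and homogeneity of co-occurrence matrices.

    ``matrices`` is one normalized (G, G) matrix or a stack of them; a stack
    is averaged statistic-by-statistic over orientations. ``homogeneity``
    defaults to the standard inverse-difference form sum C/(1+|i-j|); the
    ``"printed"`` variant additionally inserts mean-centred (i-ux)(j-uy)
    factors (a non-standard formulation retained for comparison — it is not
    bounded by [0, 1]). A matrix with zero marginal variance (constant map)
    has undefined correlation, reported as 0 with ``correlation_defined``
    cleared.
    """
    if homogeneity_variant not in ("standard", "printed"):
        raise ValueError(f"unknown homogeneity variant {homogeneity_variant!r}")
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    g = mats.shape[-1]
    i = np.arange(g)[:, None]
    j = np.arange(g)[None, :]
    contrasts, correlations, energies, homogeneities = [], [], [], []
    corr_defined = True
    for c in mats:
        s = c.sum()
        if not np.isclose(s, 1.0):
            raise ValueError(f"matrix not normalized (sum {s})")
        ux = float((i * c).sum())
        uy = float((j * c).sum())
        sx = float(np.sqrt((((i - ux) ** 2) * c).sum()))
        sy = float(np.sqrt((((j - uy) ** 2) * c).sum()))
        contrasts.append(float((c * (i - j) ** 2).sum()))
        if sx > 0 and sy > 0:
            correlations.append(float(((i - ux) * (j - uy) * c).sum() / (sx * sy)))
        else:
            correlations.append(0.0)
            corr_defined = False
        energies.append(float((c**2).sum()))
        if homogeneity_variant == "standard":
            homogeneities.append(float((c / (1 + np.abs(i - j))).sum()))
        else:
            homogeneities.append(
                float(((i - ux) * (j - uy) * c / (1 + np.abs(i - j))).sum())
            )
    return GLCMFeatures(
        contrast=float(np.mean(contrasts)),
        correlation=float(np.mean(correlations)),
        energy=float(np.mean(energies)),
        homogeneity=float(np.mean(homogeneities)),
        correlation_defined=corr_defined,
    )


# --------------------------------------------------------------------------
# HSI colour histograms
# --------------------------------------------------------------------------

@dataclass
class HSHistogram:
    hist_h: np.ndarray  # 16 normalized hue-bin frequencies
    hist_s: np.ndarray
    n_valid: int


def rgb_to_hsi(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classical HSI decomposition of an 8-bit RGB image.

    I = (R+G+B)/3, S = 1 - 3 min(R,G,B)/(R+G+B), and H from the arccos form,
    all scaled to [0, 1] (hue as angle/360). Achromatic pixels (R=G=B) get
    hue 0 and saturation 0.
    """
    rgb = frame.astype(float) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    i = total / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        theta = np.arccos(np.clip(np.where(den > 0, num / den, 1.0), -1.0, 1.0))
    h = np.where(b <= g, theta, 2 * np.pi - theta) / (2 * np.pi)
    h = np.where(den > 0, h, 0.0)
    return h, np.clip(s, 0.0, 1.0), i


def hs_histogram(
    frame: np.ndarray, mask: VROFMask, *, n_bins: int = 16
) -> HSHistogram:
    """Normalized hue and saturation histograms over the valid region."""
    if mask.n_valid == 0:
        raise ValueError("empty VROF mask")
    h, s, _ = rgb_to_hsi(frame)
    hv = h[mask.mask]
    sv = s[mask.mask]
    h_idx = np.minimum((hv * n_bins).astype(np.intp), n_bins - 1)
    s_idx = np.minimum((sv * n_bins).astype(np.intp), n_bins - 1)
    hist_h = np.bincount(h_idx, minlength=n_bins).astype(float) / mask.n_valid
    hist_s = np.bincount(s_idx, minlength=n_bins).astype(float) / mask.n_valid
    return HSHistogram(hist_h=hist_h, hist_s=hist_s, n_valid=mask.n_valid)


# --------------------------------------------------------------------------
# fused descriptor
# --------------------------------------------------------------------------

CTVP_LAYOUT: tuple[str, ...] = (
    ("glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity")
    + tuple(f"hist_h_{i:02d}" for i in range(16))
    + tuple(f"hist_s_{i:02d}" for i in range(16))
)


@dataclass
class CTVPVector:
    """36-dimensional fused colour-texture descriptor of one frame."""

    values: np.ndarray
    layout: tuple[str, ...] = CTVP_LAYOUT


def ctvp(
    frame: np.ndarray,
    mask: VROFMask,
    pc_params: PCParams | None = None,
    glcm_params: GLCMParams | None = None,
    *,
    texture_on_valid_only: bool = False,
) -> CTVPVector:
    """Compute the fused descriptor of one frame.

    Texture: grayscale → phase congruency → maximum-moment map → GLCM
    statistics, by default over the full frame (co-occurrence needs spatial
    continuity; ``texture_on_valid_only`` restricts pair counting to the
    valid region instead). Colour: valid-region HS histograms.
    """
    pc_params = pc_params or PCParams()
    glcm_params = glcm_params or GLCMParams()
    gray = rgb2gray(frame)
    pc = phase_congruency(gray, pc_params)
    m = max_moment(pc)
    valid = mask.mask if texture_on_valid_only else None
    tex = glcm_features(glcm(m, glcm_params, valid=valid))
    col = hs_histogram(frame, mask)
    values = np.concatenate(
        [
            [tex.contrast, tex.correlation, tex.energy, tex.homogeneity],
            col.hist_h,
            col.hist_s,
        ]
    )
    return CTVPVector(values=values)
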