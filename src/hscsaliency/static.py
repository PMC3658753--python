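"""Static saliency from hypercomplex spectral contrast (HSC).

Pipeline per scale ``l``: resize the RGB input to ``l * base_resolution``,
convert to HSV, encode as a quaternion image, take the hypercomplex Fourier
transform of both the image and its Gaussian-blurred version, form the
per-frequency log-ratio of squared amplitudes carried on the raw image's
unit phase, invert the transform, and square the quaternion modulus.  The
blurred image approximates the scene's average spectral energy, so the log
ratio highlights frequencies whose energy stands out — jointly over hue,
saturation and value rather than per feature channel.

Maps from the scales {1, 0.5, 0.25} are averaged, then optionally divided
by a logarithmic center-distance weight that emulates the human tendency to
attend near the image center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.transform import resize as _sk_resize

from .quaternion import (
    QuaternionSpectrum,
    encode_hsv,
    encode_spatiotemporal,
    hft_forward,
    hft_inverse,
    polar_decompose,
    qnorm,
)

__all__ = [
    "ScaleConfig",
    "gaussian_blur",
    "resize",
    "spectral_contrast",
    "single_scale_saliency",
    "multi_scale_saliency",
    "center_bias",
    "normalize_map",
    "saliency_map",
]

#: amplitudes at or below this contribute zero contrast (0/0 guard)
AMPLITUDE_FLOOR = 1e-12


@dataclass(frozen=True)
class ScaleConfig:
    """Tunable parameters of the spectral-contrast pipeline.

    Attributes
    ----------
    scales
        Pyramid scale factors in (0, 1]; the saliency map is the mean of
        the per-scale maps.
    blur_sigma
        Std-dev (pixels) of the 2-D Gaussian used both to build the
        energy-averaged reference image and to smooth the reconstruction.
    base_resolution
        ``(width, height)`` working resolution; inputs are resized here
        before any spectral computation.
    log_epsilon
        Stabilizer added to both squared amplitudes inside the log ratio.
    polar_axis
        ``"eigen"`` (default) or ``"j"``; see
        :func:`hscsaliency.quaternion.polar_decompose`.
    """

    scales: tuple[float, ...] = (1.0, 0.5, 0.25)
    blur_sigma: float = 3.0
    base_resolution: tuple[int, int] = (320, 240)
    log_epsilon: float = 1e-12
    polar_axis: str = "eigen"

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("scales must be non-empty")
        if any(not (0.0 < s <= 1.0) for s in self.scales):
            raise ValueError(f"all scales must lie in (0, 1], got {self.scales}")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")

    def with_resolution(self, width: int, height: int) -> "ScaleConfig":
        return replace(self, base_resolution=(width, height))


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Channel-wise 2-D Gaussian blur with reflective boundaries.

    Works on 2-D grids and on (M, N, C) stacks (HSV or quaternion images);
    the per-channel mean is preserved up to the discrete kernel's mass.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")
    if image.ndim == 3:
        return ndimage.gaussian_filter(image, sigma=(sigma, sigma, 0), mode="reflect")
    raise ValueError(f"expected a 2-D or 3-D array, got ndim={image.ndim}")


def resize(image: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize used throughout the pipeline (maps and images)."""
    if image.shape[:2] == (height, width):
        return np.asarray(image, dtype=float)
    return _sk_resize(
        image,
        (height, width),
        order=1,
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )


def spectral_contrast(
    Q_raw: QuaternionSpectrum,
    Q_blur: QuaternionSpectrum,
    eps: float = 1e-12,
) -> QuaternionSpectrum:
    """Hypercomplex spectral contrast between a raw and a blurred spectrum.

    ``CQ(u,v) = ln((|Q_raw|^2 + eps) / (|Q_blur|^2 + eps)) * phase_raw(u,v)``

    The amplitude carries the energy contrast (how much a frequency stands
    out against the blurred average) while the raw image's unit phase
    retains the structural information.  Frequencies whose raw amplitude is
    at the floor contribute zero.
    """
    if Q_raw.shape != Q_blur.shape:
        raise ValueError(
            f"spectrum shapes differ: {Q_raw.shape} vs {Q_blur.shape}"
        )
    if Q_raw.amplitude is None or Q_blur.amplitude is None:
        raise ValueError("both spectra must be polar-decomposed first")
    a2 = np.square(Q_raw.amplitude)
    b2 = np.square(Q_blur.amplitude)
    coeff = np.log((a2 + eps) / (b2 + eps))
    coeff = np.where(Q_raw.amplitude <= AMPLITUDE_FLOOR, 0.0, coeff)
    return QuaternionSpectrum(values=coeff[..., None] * Q_raw.unit_phase)


def _contrast_map(q: np.ndarray, config: ScaleConfig) -> np.ndarray:
    """Spectral-contrast saliency of a quaternion image at its own size."""
    Q_raw = polar_decompose(hft_forward(q), axis=config.polar_axis,
                            zero_tol=AMPLITUDE_FLOOR)
    Q_blur = polar_decompose(hft_forward(gaussian_blur(q, config.blur_sigma)),
                             axis=config.polar_axis, zero_tol=AMPLITUDE_FLOOR)
    CQ = spectral_contrast(Q_raw, Q_blur, eps=config.log_epsilon)
    cq = hft_inverse(CQ)
    return gaussian_blur(np.square(qnorm(cq)), config.blur_sigma)


def _scale_shape(config: ScaleConfig, scale: float) -> tuple[int, int]:
    w, h = config.base_resolution
    return max(1, round(h * scale)), max(1, round(w * scale))


def single_scale_saliency(
    rgb_image: np.ndarray,
    config: ScaleConfig = ScaleConfig(),
    scale: float = 1.0,
    motion: np.ndarray | None = None,
) -> np.ndarray:
    """Saliency map at one pyramid scale, returned at base resolution.

    Parameters
    ----------
    rgb_image
        ``(M, N, 3)`` RGB in [0, 1].
    scale
        Scale factor l in (0, 1]; the image is resized to
        ``l * base_resolution`` before the spectral computation.
    motion
        Optional motion field on the same grid as ``rgb_image``; when given
        it is resized alongside the image and encoded on the quaternion's
        scalar part (the spatio-temporal pipeline).

    Returns
    -------
    Non-negative ``(height, width)`` map at ``config.base_resolution``.
    """
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.size == 0:
        raise ValueError("empty image")
    if not (0.0 < scale <= 1.0):
        raise ValueError(f"scale must lie in (0, 1], got {scale}")
    h, w = _scale_shape(config, scale)
    rgb_s = np.clip(resize(rgb, h, w), 0.0, 1.0)
    hsv = rgb2hsv(rgb_s)
    if motion is None:
        q = encode_hsv(hsv)
    else:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != rgb.shape[:2]:
            raise ValueError(
                f"motion shape {motion.shape} does not match image "
                f"shape {rgb.shape[:2]}"
            )
        q = encode_spatiotemporal(resize(motion, h, w), hsv)
    s = _contrast_map(q, config)
    base_w, base_h = config.base_resolution
    return np.maximum(resize(s, base_h, base_w), 0.0)


def multi_scale_saliency(
    rgb_image: np.ndarray,
    config: ScaleConfig = ScaleConfig(),
    motion: np.ndarray | None = None,
) -> np.ndarray:
    """Mean of the single-scale saliency maps over ``config.scales``."""
    maps = [
        single_scale_saliency(rgb_image, config, scale, motion=motion)
        for scale in config.scales
    ]
    return np.mean(maps, axis=0)


def center_bias(saliency: np.ndarray) -> np.ndarray:
    """Divide a map by the logarithmic center-distance weight.

    ``SM(x, y) = S(x, y) / (1 + D_log)`` with
    ``D_log = ln(1 + r / r_half_diag)``, r the Euclidean distance to the
    grid center and r_half_diag half the image diagonal.  The weight is 1 at
    the center and 1 + ln 2 at the corners, emulating the attentional
    preference for central image regions; it never increases a value.
    """
    s = np.asarray(saliency, dtype=float)
    h, w = s.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    # half the corner-to-corner pixel diagonal, so corners sit exactly at
    # r = r_half_diag and their divisor is 1 + ln 2
    r_half_diag = np.hypot(h - 1, w - 1) / 2.0
    if r_half_diag == 0.0:  # 1x1 grid
        return s.copy()
    d_log = np.log1p(r / r_half_diag)
    return s / (1.0 + d_log)


def normalize_map(
    saliency: np.ndarray, smooth_sigma: float | None = None
) -> np.ndarray:
    """Optional Gaussian smoothing, then affine min-max mapping to [0, 255].

    A constant map normalizes to all zeros.
    """
    s = np.asarray(saliency, dtype=float)
    if smooth_sigma is not None:
        s = gaussian_blur(s, smooth_sigma)
    lo, hi = s.min(), s.max()
    if hi <= lo:
        return np.zeros_like(s)
    return (s - lo) * (255.0 / (hi - lo))


def saliency_map(
    rgb_image: np.ndarray,
    config: ScaleConfig = ScaleConfig(),
    apply_center_bias: bool = True,
    resize_to_input: bool = True,
    normalize: bool = True,
    smooth_sigma: float | None = 3.0,
) -> np.ndarray:
    """End-to-end static saliency: multi-scale contrast, bias, normalize.

    Convenience wrapper producing the final map at the input resolution,
    normalized to [0, 255] after a sigma-3 Gaussian (the display/evaluation
    convention); set ``normalize=False`` for the raw non-negative map.
    """
    rgb = np.asarray(rgb_image, dtype=float)
    s = multi_scale_saliency(rgb, config)
    if apply_center_bias:
        s = center_bias(s)
    if resize_to_input:
        s = np.maximum(resize(s, rgb.shape[0], rgb.shape[1]), 0.0)
    if normalize:
        s = normalize_map(s, smooth_sigma=smooth_sigma)
    return s
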