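"""Spatio-temporal saliency: five-frame motion cue folded into the quaternion.

The motion field M_t is a five-tap temporal derivative of the video's
intensity (the V channel of HSV).  Encoding it on the quaternion's scalar
part, q_t = M_t + H_t*i + S_t*j + V_t*k, lets the same spectral-contrast
pipeline score static appearance and motion jointly: the symplectic split
becomes f1 = M + H*i, f2 = S + V*i and everything downstream is unchanged.

Two tap variants are shipped.  ``as_printed`` uses coefficients
(1, -4, -1, 4, -1)/8, whose sum is -1, so a perfectly static scene carries a
constant pseudo-motion of -I/8.  ``zero_sum`` drops the center tap so the
coefficients sum to zero and static content yields exactly zero motion,
making the spatio-temporal map collapse onto the static one.  Both are kept
because neither behavior is strictly better: the first is the published
filter, the second is its DC-free correction.
"""

from __future__ import annotations

import numpy as np

from .static import ScaleConfig, center_bias, multi_scale_saliency, resize

__all__ = ["MOTION_VARIANTS", "frame_intensity", "motion_cue", "video_saliency"]

#: five-tap coefficients for frames t-2 .. t+2, divided by 8
MOTION_VARIANTS: dict[str, tuple[float, ...]] = {
    "as_printed": (1.0, -4.0, -1.0, 4.0, -1.0),
    "zero_sum": (1.0, -4.0, 0.0, 4.0, -1.0),
}


def frame_intensity(frame: np.ndarray) -> np.ndarray:
    """Video intensity feature: the V channel of HSV, i.e. max(R, G, B)."""
    return np.asarray(frame, dtype=float).max(axis=-1)


def _check_sequence(seq: np.ndarray) -> np.ndarray:
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 4 or seq.shape[-1] != 3:
        raise ValueError(f"expected a (T, M, N, 3) frame stack, got {seq.shape}")
    return seq


def motion_cue(seq: np.ndarray, t: int, variant: str = "as_printed") -> np.ndarray:
    """Five-frame motion field at frame ``t``.

    ``M_t = (1/8){I_{t-2} - 4 I_{t-1} - I_t + 4 I_{t+1} - I_{t+2}}``
    (as_printed), with the ``-I_t`` term dropped under ``zero_sum``.
    Frames beyond the sequence ends are edge-replicated.  The filter is
    linear in the intensity, and with V in [0, 1] the as_printed output
    stays within [-3/4, 3/4] (no further normalization is applied).
    """
    seq = _check_sequence(seq)
    T = seq.shape[0]
    if not 0 <= t < T:
        raise IndexError(f"frame index {t} outside [0, {T - 1}]")
    try:
        taps = MOTION_VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown motion variant {variant!r}; choose from "
            f"{sorted(MOTION_VARIANTS)}"
        ) from None
    out = np.zeros(seq.shape[1:3])
    for offset, coef in zip(range(-2, 3), taps):
        if coef == 0.0:
            continue
        idx = min(max(t + offset, 0), T - 1)
        out += coef * frame_intensity(seq[idx])
    return out / 8.0


def video_saliency(
    seq: np.ndarray,
    t: int,
    config: ScaleConfig = ScaleConfig(),
    video_resolution: tuple[int, int] = (128, 128),
    variant: str = "as_printed",
    apply_center_bias: bool = True,
) -> np.ndarray:
    """Spatio-temporal saliency map for frame ``t`` of a sequence.

    The frame window is resized to ``video_resolution`` (width, height),
    the motion cue is computed there, and the multi-scale spectral-contrast
    pipeline runs on the spatio-temporal quaternion q_t.  The map is
    returned at the original frame size, un-normalized.
    """
    seq = _check_sequence(seq)
    if not 0 <= t < seq.shape[0]:
        raise IndexError(f"frame index {t} outside [0, {seq.shape[0] - 1}]")
    vw, vh = video_resolution
    # only the five-frame window around t is resized; clipping the window at
    # the sequence ends reproduces edge replication of the first/last frame
    lo = max(t - 2, 0)
    small = np.stack(
        [
            np.clip(resize(seq[i], vh, vw), 0.0, 1.0)
            for i in range(lo, min(t + 3, seq.shape[0]))
        ]
    )
    t_local = t - lo
    motion = motion_cue(small, t_local, variant=variant)
    cfg = config.with_resolution(vw, vh)
    s = multi_scale_saliency(small[t_local], cfg, motion=motion)
    if apply_center_bias:
        s = center_bias(s)
    return np.maximum(resize(s, seq.shape[1], seq.shape[2]), 0.0)
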