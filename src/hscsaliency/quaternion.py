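"""Quaternion algebra on pixel grids and the hypercomplex Fourier transform.

A quaternion image is stored as a real ``(M, N, 4)`` array whose last axis
holds the components ``[w, x, y, z]`` of ``q = w + x*i + y*j + z*k``.  An
HSV-encoded image is a *pure* quaternion image (``w == 0`` everywhere) with
hue on i, saturation on j and value on k; the spatio-temporal encoding
additionally carries a motion channel on the scalar part.

The hypercomplex Fourier transform (HFT) is computed through the symplectic
decomposition ``q = f1 + f2*j`` with ``f1 = w + x*i`` and ``f2 = y + z*i``:
both symplectic parts live in the complex subfield spanned by {1, i}, so the
left-sided quaternion DFT with transform axis i reduces to two ordinary
complex 2-D FFTs.  The unitary normalization ``1/sqrt(MN)`` is used on both
the forward and inverse transforms, which makes the pair mutually inverse
and preserves energy (Parseval).

A brute-force O((MN)^2) quaternion DFT is provided purely as an independent
test oracle for the FFT route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "qmult",
    "qnorm",
    "qconj",
    "QuaternionSpectrum",
    "encode_hsv",
    "encode_spatiotemporal",
    "symplectic_decompose",
    "symplectic_recompose",
    "hft_forward",
    "hft_inverse",
    "polar_decompose",
    "quaternion_dft_bruteforce",
]

#: identity quaternion, used for zero-amplitude frequencies
_IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def qmult(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product of quaternion arrays (broadcasting over leading axes).

    Components follow i^2 = j^2 = k^2 = -1, ij = k, jk = i, ki = j.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qnorm(q: np.ndarray) -> np.ndarray:
    """Pointwise quaternion modulus |q| = sqrt(w^2 + x^2 + y^2 + z^2)."""
    return np.sqrt(np.sum(np.square(np.asarray(q, dtype=float)), axis=-1))


def qconj(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate w - xi - yj - zk."""
    out = np.array(q, dtype=float, copy=True)
    out[..., 1:] *= -1.0
    return out


@dataclass
class QuaternionSpectrum:
    """A frequency-domain quaternion grid with its polar decomposition.

    Attributes
    ----------
    values
        ``(M, N, 4)`` quaternion coefficients indexed by frequency ``(u, v)``,
        row-major with the DC term at index ``(0, 0)`` (no fftshift).
    amplitude
        ``(M, N)`` moduli ``|Q|``; filled by :func:`polar_decompose`.
    unit_phase
        ``(M, N, 4)`` unit quaternions ``Q/|Q|`` (the ``e^{nu*phi}`` factor);
        the identity quaternion where the amplitude vanishes.
    zero_mask
        ``(M, N)`` boolean flag marking zero-amplitude frequencies.
    """

    values: np.ndarray
    amplitude: np.ndarray | None = field(default=None)
    unit_phase: np.ndarray | None = field(default=None)
    zero_mask: np.ndarray | None = field(default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


def encode_hsv(hsv_image: np.ndarray) -> np.ndarray:
    """Encode an HSV image as a pure quaternion image q = H*i + S*j + V*k.

    Parameters
    ----------
    hsv_image
        ``(M, N, 3)`` array with H, S, V all in [0, 1].

    Returns
    -------
    ``(M, N, 4)`` pure quaternion image (scalar part identically zero).
    """
    hsv = np.asarray(hsv_image, dtype=float)
    if hsv.ndim != 3 or hsv.shape[-1] != 3:
        raise ValueError(f"expected an (M, N, 3) HSV image, got shape {hsv.shape}")
    if hsv.min() < 0.0 or hsv.max() > 1.0:
        raise ValueError(
            f"HSV channels must lie in [0, 1]; got range "
            f"[{hsv.min():.4g}, {hsv.max():.4g}]"
        )
    q = np.zeros(hsv.shape[:2] + (4,), dtype=float)
    q[..., 1:] = hsv
    return q


def encode_spatiotemporal(motion: np.ndarray, hsv_image: np.ndarray) -> np.ndarray:
    """Encode motion + HSV as a full quaternion image q = M + H*i + S*j + V*k.

    The motion channel occupies the scalar part; with ``motion == 0`` this
    reduces exactly to :func:`encode_hsv`.
    """
    motion = np.asarray(motion, dtype=float)
    hsv = np.asarray(hsv_image, dtype=float)
    if motion.shape != hsv.shape[:2]:
        raise ValueError(
            f"motion field shape {motion.shape} does not match image "
            f"shape {hsv.shape[:2]}"
        )
    q = np.empty(hsv.shape[:2] + (4,), dtype=float)
    q[..., 0] = motion
    q[..., 1:] = hsv
    return q


def symplectic_decompose(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a quaternion image into its symplectic pair (f1, f2).

    ``f1 = w + x*i`` and ``f2 = y + z*i`` as complex arrays (the complex
    imaginary unit standing for quaternion i), so that ``q = f1 + f2*j``.
    """
    q = np.asarray(q, dtype=float)
    f1 = q[..., 0] + 1j * q[..., 1]
    f2 = q[..., 2] + 1j * q[..., 3]
    return f1, f2


def symplectic_recompose(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Inverse of :func:`symplectic_decompose`: rebuild q = f1 + f2*j."""
    return np.stack([f1.real, f1.imag, f2.real, f2.imag], axis=-1)


def hft_forward(q: np.ndarray) -> QuaternionSpectrum:
    """Forward hypercomplex Fourier transform of a quaternion image.

    Computed as two unitary complex 2-D FFTs of the symplectic parts,
    ``Q = F1 + F2*j``; equivalent to the left-sided quaternion DFT with
    transform axis i (cross-checked against
    :func:`quaternion_dft_bruteforce`).
    """
    f1, f2 = symplectic_decompose(q)
    F1 = np.fft.fft2(f1, norm="ortho")
    F2 = np.fft.fft2(f2, norm="ortho")
    return QuaternionSpectrum(values=symplectic_recompose(F1, F2))


def hft_inverse(spectrum: QuaternionSpectrum | np.ndarray) -> np.ndarray:
    """Inverse hypercomplex Fourier transform back to a quaternion image.

    The output is a full quaternion image a + b*i + c*j + d*k; even for a
    pure-quaternion input the reconstruction of a *modified* spectrum (e.g.
    after spectral contrast) generally has a nonzero scalar part.
    """
    values = spectrum.values if isinstance(spectrum, QuaternionSpectrum) else spectrum
    F1, F2 = symplectic_decompose(values)
    f1 = np.fft.ifft2(F1, norm="ortho")
    f2 = np.fft.ifft2(F2, norm="ortho")
    return symplectic_recompose(f1, f2)


def polar_decompose(
    spectrum: QuaternionSpectrum,
    axis: str = "eigen",
    zero_tol: float = 0.0,
) -> QuaternionSpectrum:
    """Fill the polar form Q = |Q| * e^{nu*phi} of a quaternion spectrum.

    Parameters
    ----------
    spectrum
        Spectrum whose ``values`` are set.
    axis
        ``"eigen"`` (default): per-frequency unit phase ``Q/|Q|`` — the
        standard quaternion polar form, which reconstructs Q exactly.
        ``"j"``: literal fixed-axis form projecting onto the {1, j}
        subfield, ``e^{j*phi}`` with ``phi = atan2(y, w)``; this discards
        the i/k components and only reconstructs spectra confined to that
        subfield.
    zero_tol
        Amplitudes ``<= zero_tol`` are flagged and given the identity
        quaternion as unit phase (avoids 0/0).

    Returns
    -------
    The same spectrum object with ``amplitude``, ``unit_phase`` and
    ``zero_mask`` populated.
    """
    if axis not in ("eigen", "j"):
        raise ValueError(f"axis must be 'eigen' or 'j', got {axis!r}")
    Q = spectrum.values
    amp = qnorm(Q)
    zero = amp <= zero_tol
    if axis == "eigen":
        safe = np.where(zero, 1.0, amp)
        unit = Q / safe[..., None]
    else:
        phi = np.arctan2(Q[..., 2], Q[..., 0])
        unit = np.zeros_like(Q)
        unit[..., 0] = np.cos(phi)
        unit[..., 2] = np.sin(phi)
    unit = np.where(zero[..., None], _IDENTITY, unit)
    spectrum.amplitude = amp
    spectrum.unit_phase = unit
    spectrum.zero_mask = zero
    return spectrum


def quaternion_dft_bruteforce(q: np.ndarray) -> QuaternionSpectrum:
    """Left-sided axis-i quaternion DFT by direct double summation.

    ``Q[u, v] = (1/sqrt(MN)) * sum_{y,x} e^{-i*2*pi*(y*u/M + x*v/N)} q(y, x)``
    with quaternion left multiplication.  O((M*N)^2) — a test oracle only,
    guarded to small grids.
    """
    q = np.asarray(q, dtype=float)
    M, N = q.shape[:2]
    if M * N > 4096:
        raise ValueError(f"grid {M}x{N} too large for the brute-force oracle")
    ys, xs = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
    out = np.zeros((M, N, 4))
    for u in range(M):
        for v in range(N):
            theta = 2.0 * np.pi * (ys * u / M + xs * v / N)
            # e^{-i*theta} as a quaternion in the {1, i} subfield
            e = np.zeros((M, N, 4))
            e[..., 0] = np.cos(theta)
            e[..., 1] = -np.sin(theta)
            out[u, v] = qmult(e, q).sum(axis=(0, 1))
    out /= np.sqrt(M * N)
    return QuaternionSpectrum(values=out)
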