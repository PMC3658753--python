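"""Deterministic generators of psychophysical stimuli and synthetic videos.

Pop-out patterns follow the classic visual-search conventions: a regular
grid of identical distractor items (oriented bars, dots, curves or crosses)
with a single deviant item differing in one attribute — color or
orientation — whose tight bounding box is returned as ground truth.  The
background defaults to neutral mid-gray: an achromatic background has an
arbitrary hue coordinate in HSV, and a red target's hue (0) would coincide
with a white background's, masking the very attribute under test.  A
pre-attentive saliency model should place its strongest response on the
deviant.  Rendering is aliased on purpose (hard edges, no smoothing) so the
recorded boxes are pixel-exact.

Synthetic videos place a colored square translating at constant velocity
over either a fixed random texture or a drifting sum of two sinusoidal
gratings; the latter provides enough temporal non-stationarity to defeat
naive frame differencing.  Per-frame ground-truth boxes track the square
exactly.

All generators are pure functions of (spec, seed): the same spec yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as _disk, polygon as _polygon

__all__ = [
    "PatternSpec",
    "VideoSpec",
    "make_popout_pattern",
    "make_synthetic_video",
    "boxes_to_mask",
]

Box = tuple[int, int, int, int]  # (x, y, w, h), half-open, origin top-left


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of a pop-out search array.

    ``deviant`` selects the odd item's differing attribute: ``"color"``,
    ``"orientation"``, or ``"both"`` (mixed stimulus with two odd items,
    one per attribute).
    """

    rows: int = 5
    cols: int = 7
    kind: str = "bar"  # bar | dot | curve | cross
    deviant: str = "color"
    odd_slot: tuple[int, int] | None = None  # (row, col); random if None
    image_size: tuple[int, int] = (320, 240)  # (width, height)
    bar_length: int = 26
    bar_width: int = 7
    distractor_color: tuple[float, float, float] = (0.10, 0.70, 0.15)
    odd_color: tuple[float, float, float] = (0.90, 0.08, 0.08)
    distractor_angle: float = 90.0  # degrees, 90 = vertical
    odd_angle: float = 0.0
    background: tuple[float, float, float] = (0.5, 0.5, 0.5)
    jitter: int = 3  # max positional jitter (pixels) per item
    seed: int = 0


@dataclass(frozen=True)
class VideoSpec:
    """Parameters of a moving-square synthetic video."""

    size: tuple[int, int] = (128, 128)  # (width, height)
    n_frames: int = 30
    background: str = "static_texture"  # static_texture | dynamic_waves
    object_size: int = 16
    object_color: tuple[float, float, float] | None = (0.90, 0.15, 0.10)
    start: tuple[int, int] = (20, 56)  # (x, y) of the square's top-left
    velocity: tuple[float, float] = (2.0, 0.0)  # pixels/frame (vx, vy)
    wave_amplitude: float = 0.18
    wave_speed: float = 0.6  # radians/frame phase drift
    seed: int = 0


def _rotated_bar(cy: float, cx: float, length: int, width: int,
                 angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a filled rotated rectangle (no anti-aliasing)."""
    a = np.deg2rad(angle_deg)
    ux, uy = np.cos(a), -np.sin(a)  # along-bar direction (image y grows down)
    vx, vy = -uy, ux
    hl, hw = length / 2.0, width / 2.0
    corners_y = [cy + uy * s * hl + vy * r * hw for s, r in
                 ((1, 1), (1, -1), (-1, -1), (-1, 1))]
    corners_x = [cx + ux * s * hl + vx * r * hw for s, r in
                 ((1, 1), (1, -1), (-1, -1), (-1, 1))]
    return _polygon(corners_y, corners_x)


def _item_pixels(kind: str, cy: float, cx: float, spec: PatternSpec,
                 angle: float) -> tuple[np.ndarray, np.ndarray]:
    if kind == "bar":
        return _rotated_bar(cy, cx, spec.bar_length, spec.bar_width, angle)
    if kind == "dot":
        return _disk((cy, cx), spec.bar_length / 2.5)
    if kind == "cross":
        r1, c1 = _rotated_bar(cy, cx, spec.bar_length, spec.bar_width, angle)
        r2, c2 = _rotated_bar(cy, cx, spec.bar_length, spec.bar_width,
                              angle + 90.0)
        return np.concatenate([r1, r2]), np.concatenate([c1, c2])
    if kind == "curve":
        # half-annulus arc: ring pixels above the item center, rotated
        rad = spec.bar_length / 2.0
        yy, xx = np.mgrid[-rad - 2:rad + 3, -rad - 2:rad + 3]
        rr = np.hypot(yy, xx)
        ring = (rr <= rad) & (rr >= rad - spec.bar_width)
        theta = np.arctan2(yy, xx) - np.deg2rad(angle)
        ring &= np.sin(theta) <= 0
        ys, xs = np.nonzero(ring)
        return (ys + int(round(cy)) - int(rad) - 2,
                xs + int(round(cx)) - int(rad) - 2)
    raise ValueError(f"unknown item kind {kind!r}")


def _paint(img: np.ndarray, ys: np.ndarray, xs: np.ndarray,
           color: tuple[float, float, float]) -> Box:
    """Paint item pixels (clipped to the canvas) and return the tight box."""
    h, w = img.shape[:2]
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    ys, xs = ys[keep], xs[keep]
    img[ys, xs] = color
    x0, y0 = int(xs.min()), int(ys.min())
    return (x0, y0, int(xs.max()) - x0 + 1, int(ys.max()) - y0 + 1)


def make_popout_pattern(spec: PatternSpec = PatternSpec()) -> tuple[np.ndarray, list[Box]]:
    """Render a pop-out search array.

    Returns
    -------
    image
        ``(height, width, 3)`` RGB float array in [0, 1].
    odd_boxes
        Tight bounding boxes of the deviant item(s): one box for a single
        deviant, two for the mixed ``deviant="both"`` stimulus.
    """
    if spec.deviant not in ("color", "orientation", "both"):
        raise ValueError(f"unknown deviant attribute {spec.deviant!r}")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    img = np.empty((h, w, 3))
    img[:] = spec.background

    cell_w, cell_h = w / spec.cols, h / spec.rows
    slots = [(r, c) for r in range(spec.rows) for c in range(spec.cols)]
    if spec.odd_slot is None:
        odd = [tuple(slots[rng.integers(len(slots))])]
    else:
        r, c = spec.odd_slot
        if not (0 <= r < spec.rows and 0 <= c < spec.cols):
            raise ValueError(f"odd_slot {spec.odd_slot} outside the "
                             f"{spec.rows}x{spec.cols} grid")
        odd = [(r, c)]
    if spec.deviant == "both":
        others = [s for s in slots if s != odd[0]]
        odd.append(tuple(others[rng.integers(len(others))]))

    odd_boxes: list[Box] = []
    for r, c in slots:
        cy = (r + 0.5) * cell_h + rng.integers(-spec.jitter, spec.jitter + 1)
        cx = (c + 0.5) * cell_w + rng.integers(-spec.jitter, spec.jitter + 1)
        color, angle = spec.distractor_color, spec.distractor_angle
        is_odd = (r, c) in odd
        if is_odd:
            which = spec.deviant
            if which == "both":
                which = "color" if (r, c) == odd[0] else "orientation"
            if which == "color":
                color = spec.odd_color
            else:
                angle = spec.odd_angle
        ys, xs = _item_pixels(spec.kind, cy, cx, spec, angle)
        box = _paint(img, ys, xs, color)
        if is_odd:
            odd_boxes.append(box)
    return img, odd_boxes


def _texture(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Fixed smooth random texture: blurred uniform noise, mid-gray range."""
    noise = rng.uniform(0.0, 1.0, size=(h, w))
    tex = ndimage.gaussian_filter(noise, sigma=2.0, mode="wrap")
    tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)
    return 0.25 + 0.5 * tex


def _wave_background(h: int, w: int, phase: float, amplitude: float) -> np.ndarray:
    """Drifting sum of two sinusoidal gratings (dynamic water-like surface)."""
    yy, xx = np.mgrid[0:h, 0:w]
    g1 = np.sin(2 * np.pi * (0.055 * xx + 0.02 * yy) + phase)
    g2 = np.sin(2 * np.pi * (0.018 * xx - 0.045 * yy) - 1.7 * phase)
    return 0.5 + amplitude * (g1 + g2) / 2.0


def make_synthetic_video(spec: VideoSpec = VideoSpec()) -> tuple[np.ndarray, list[list[Box]]]:
    """Render a moving-square video with exact per-frame ground truth.

    Returns
    -------
    frames
        ``(T, height, width, 3)`` RGB float stack in [0, 1].
    boxes
        Per-frame list of ground-truth boxes (one box per frame, or empty
        lists when ``object_color`` is None).
    """
    if spec.background not in ("static_texture", "dynamic_waves"):
        raise ValueError(f"unknown background {spec.background!r}")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.size
    tex = _texture(rng, h, w)

    frames = np.empty((spec.n_frames, h, w, 3))
    boxes: list[list[Box]] = []
    for t in range(spec.n_frames):
        if spec.background == "static_texture":
            base = tex
        else:
            base = _wave_background(h, w, spec.wave_speed * t,
                                    spec.wave_amplitude)
        frame = np.clip(base, 0.0, 1.0)[..., None] * np.array([0.55, 0.65, 0.80])
        frame = np.ascontiguousarray(frame)
        frame_boxes: list[Box] = []
        if spec.object_color is not None:
            x = int(round(spec.start[0] + spec.velocity[0] * t))
            y = int(round(spec.start[1] + spec.velocity[1] * t))
            s = spec.object_size
            if x < 0 or y < 0 or x + s > w or y + s > h:
                raise ValueError(
                    f"object leaves the frame at frame {t}: box "
                    f"({x}, {y}, {s}, {s}) outside {w}x{h}"
                )
            frame[y:y + s, x:x + s] = spec.object_color
            frame_boxes.append((x, y, s, s))
        frames[t] = frame
        boxes.append(frame_boxes)
    return frames, boxes


def boxes_to_mask(boxes: list[Box], height: int, width: int) -> np.ndarray:
    """Rasterize half-open boxes to a boolean mask."""
    mask = np.zeros((height, width), dtype=bool)
    for x, y, bw, bh in boxes:
        mask[y:y + bh, x:x + bw] = True
    return mask
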