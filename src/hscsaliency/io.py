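"""Image, sequence, box-file and config I/O.

Conventions: RGB images are float arrays in [0, 1]; saliency maps are
written as 8-bit grayscale PNGs after normalization; frame sequences are
directories of same-size images read in lexicographic order; box files are
plain text with one line per frame, ``frame_index x y w h`` (0-based,
origin top-left, half-open boxes); config files are flat ``key = value``
text.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_map",
    "read_sequence",
    "read_boxes",
    "write_boxes",
    "RunConfig",
    "load_config",
]

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".ppm", ".pgm", ".bmp", ".tif", ".tiff")


def read_image(path) -> np.ndarray:
    """Read an image as an (M, N, 3) RGB float array in [0, 1].

    Grayscale inputs are broadcast to three channels; alpha is dropped;
    8- and 16-bit integer data are scaled by their full range (no clipping).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return np.clip(arr, 0.0, 1.0)


def write_map(saliency: np.ndarray, path) -> None:
    """Write a [0, 255] map as an 8-bit grayscale PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.asarray(saliency, dtype=float), 0.0, 255.0)
    iio.imwrite(path, np.round(data).astype(np.uint8))


def write_image(rgb: np.ndarray, path) -> None:
    """Write an RGB float image in [0, 1] as an 8-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(data * 255.0).astype(np.uint8))


def read_sequence(directory) -> np.ndarray:
    """Read a directory of frames as a (T, M, N, 3) float stack.

    Frames are ordered lexicographically by filename; a frame whose size
    differs from the first is rejected by name.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not paths:
        raise ValueError(f"no image frames found in {directory}")
    frames = []
    shape = None
    for p in paths:
        frame = read_image(p)
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise ValueError(
                f"frame {p.name} has size {frame.shape[:2]}, expected "
                f"{shape[:2]}"
            )
        frames.append(frame)
    return np.stack(frames)


def read_boxes(path) -> dict[int, list[tuple[int, int, int, int]]]:
    """Read a per-frame box file: lines of ``frame_index x y w h``."""
    path = Path(path)
    out: dict[int, list[tuple[int, int, int, int]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 'frame x y w h'")
        t, x, y, w, h = (int(p) for p in parts)
        out.setdefault(t, []).append((x, y, w, h))
    return out


def write_boxes(boxes_per_frame, path) -> None:
    """Write per-frame boxes; empty frames are listed with no lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for t, frame_boxes in enumerate(boxes_per_frame):
        for x, y, w, h in frame_boxes:
            lines.append(f"{t} {x} {y} {w} {h}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class RunConfig:
    """Flat run configuration shared by the CLI subcommands."""

    mode: str = "static"  # static | video | extract | eval | fixtures
    scales: tuple[float, ...] = (1.0, 0.5, 0.25)
    blur_sigma: float = 3.0
    base_width: int = 320
    base_height: int = 240
    video_width: int = 128
    video_height: int = 128
    log_epsilon: float = 1e-12
    motion_variant: str = "as_printed"
    center_bias: bool = True
    threshold: int = 128
    morph_radius: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def scale_config(self):
        from .static import ScaleConfig

        return ScaleConfig(
            scales=self.scales,
            blur_sigma=self.blur_sigma,
            base_resolution=(self.base_width, self.base_height),
            log_epsilon=self.log_epsilon,
        )


def _coerce(value: str, target):
    if isinstance(target, bool):
        low = value.strip().lower()
        if low in ("1", "true", "yes", "on"):
            return True
        if low in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {value!r}")
    if isinstance(target, tuple):
        return tuple(float(v) for v in value.replace(",", " ").split())
    return type(target)(value)


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    path = Path(path)
    known = {f.name: f for f in fields(RunConfig)}
    cfg = RunConfig()
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        setattr(cfg, key, _coerce(value.strip(), getattr(cfg, key)))
    return cfg
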