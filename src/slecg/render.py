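"""Rasterize a normalized segment into a small grayscale image.

Each 10 s segment becomes a 96x96 binary intensity grid — the input
representation of the 2-D classifier.  Time maps to columns (each column
owns a contiguous block of samples), amplitude maps linearly to rows
with +1 at the top, and each column is drawn as the filled min–max
envelope of its samples.  The drawing is pure integer bookkeeping: no
plotting backend, no anti-aliasing, byte-for-byte deterministic, and
negating the input mirrors the image vertically, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

DEFAULT_SIZE = 96


@dataclass
class ImagePatch:
    pixels: np.ndarray  # (height, width), values in [0, 1]; trace=1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def rasterize_segment(samples: np.ndarray, width: int = DEFAULT_SIZE,
                      height: int = DEFAULT_SIZE, meta: dict | None = None) -> ImagePatch:
    """Draw the min–max envelope trace of a [-1, 1] segment.

    Column ``c`` covers samples ``[c*L/W, (c+1)*L/W)`` (integer edges, so
    every sample lands in exactly one column).  Amplitude ``a`` occupies
    the continuous vertical position ``(1-a)/2*H``; a column is filled
    over every pixel row whose closed unit interval meets the column's
    amplitude span — a rule symmetric under negation, so the zero line
    (a pixel-grid boundary for even heights) lights both middle rows.
    """
    x = np.asarray(samples, dtype=float)
    if width < 8 or height < 8:
        raise ValueError("width and height must be >= 8")
    if x.ndim != 1 or x.size < width:
        raise ValueError(f"need at least {width} samples, got {x.size}")
    if np.max(np.abs(x)) > 1.0 + 1e-9:
        raise ValueError("samples outside [-1, 1]; normalize amplitude first")
    x = np.clip(x, -1.0, 1.0)

    # Signed vertical offsets from the image centerline: amplitude a sits at
    # t = a*height/2, and the bottom-most pixel row its span touches is
    # f(t) = floor(height/2 - t).  The top-most row is expressed through the
    # same helper as height-1-f(-t), which makes rasterize(-x) the exact
    # vertical mirror of rasterize(x) by construction, independent of any
    # floating-point rounding at pixel boundaries.
    h2 = height / 2.0

    def _f(t: float) -> int:
        return int(np.floor(h2 - t))

    edges = (np.arange(width + 1) * x.size) // width
    grid = np.zeros((height, width), dtype=float)
    for c in range(width):
        col = x[edges[c]:edges[c + 1]]
        t_min = col.min() * h2
        t_max = col.max() * h2
        r_top = height - 1 - _f(-t_max)
        r_bot = _f(t_min)
        grid[max(r_top, 0):min(r_bot, height - 1) + 1, c] = 1.0
    return ImagePatch(grid, meta=dict(meta or {}))


def save_png(patch: ImagePatch, path: str | Path) -> None:
    """Write as 8-bit grayscale PNG (trace renders black on white)."""
    img = Image.fromarray(
        np.round((1.0 - patch.pixels) * 255).astype(np.uint8), mode="L")
    img.save(Path(path), format="PNG")


def load_png(path: str | Path) -> ImagePatch:
    arr = np.asarray(Image.open(Path(path)).convert("L"), dtype=float)
    return ImagePatch(1.0 - arr / 255.0, meta={"path": str(path)})
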