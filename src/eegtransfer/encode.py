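"""Trace-to-image encodings of 1-second EEG windows.

Two encodings feed the convolutional classifier:

* **merged chart** — the three channel traces over-drawn in one grayscale
  plane (trace intensity 0 on a 255 background); keeping everything
  black-and-white prevents the model from learning spurious colour cues;
* **RGB synthesis** — each channel rendered into its own binary plane and
  the planes stacked as the R, G, B components of a single colour image,
  so channel identity is carried by colour instead of position.

Rasterization is a deterministic integer-only Bresenham polyline with
1-pixel line width, so with antialiasing off every emitted plane is exactly
two-valued and byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InvalidArgumentError

Encoding = Literal["merged_chart", "rgb_synthesis"]

#: Default channel → colour-plane assignment (plane order R, G, B).
DEFAULT_CHANNEL_MAP: tuple[str, str, str] = ("Fp1", "Fpz", "Fp2")
CHANNEL_NAMES = ("Fp1", "Fpz", "Fp2")


@dataclass(frozen=True)
class RasterSpec:
    """Canvas geometry and intensity conventions for trace rendering.

    The 224×224 default matches the convolutional backbone's expected
    input; trace pixels get ``line_value`` (default 0, black) on a
    ``background_value`` (default 255, white) canvas.  Swapping the two
    values yields the black-background display convention.
    """

    width: int = 224
    height: int = 224
    line_value: int = 0
    background_value: int = 255
    draw_axes: bool = False
    antialias: bool = False

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise InvalidArgumentError("canvas must be at least 2×2")
        if not (0 <= self.line_value <= 255 and 0 <= self.background_value <= 255):
            raise InvalidArgumentError("intensities must lie in [0, 255]")
        if self.line_value == self.background_value:
            raise InvalidArgumentError("line and background intensities must differ")
        if self.antialias:
            raise InvalidArgumentError(
                "antialiased rendering is not supported: planes must stay two-valued")

    def require_canvas(self) -> None:
        if self.width < 32 or self.height < 32:
            raise InvalidArgumentError("encoded images require a canvas of at least 32×32")


@dataclass
class EncodedImage:
    """A rasterized window plus its provenance.

    ``pixels`` is height×width (merged chart) or height×width×3 (RGB
    synthesis), dtype uint8.
    """

    pixels: np.ndarray
    encoding: Encoding
    subject_id: str = ""
    label: str = ""
    window_index: int = 0
    channel_map: tuple[str, str, str] = DEFAULT_CHANNEL_MAP

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.encoding == "merged_chart" and self.pixels.ndim != 2:
            raise InvalidArgumentError("merged_chart must have a single plane")
        if self.encoding == "rgb_synthesis" and (
                self.pixels.ndim != 3 or self.pixels.shape[2] != 3):
            raise InvalidArgumentError("rgb_synthesis must have exactly 3 planes")


def _bresenham(x0: int, y0: int, x1: int, y1: int) -> list[tuple[int, int]]:
    """Integer line rasterization; returns (x, y) pixels including endpoints."""
    dx = abs(x1 - x0)
    dy = -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    pts = []
    x, y = x0, y0
    while True:
        pts.append((x, y))
        if x == x1 and y == y1:
            break
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x += sx
        if e2 <= dx:
            err += dx
            y += sy
    return pts


def render_trace_bitmap(trace: np.ndarray, spec: RasterSpec) -> np.ndarray:
    """Rasterize a [0, 1]-valued trace as a binary polyline bitmap.

    Sample index maps linearly onto columns [0, width−1]; value 1 maps to
    the top row and 0 to the bottom row.  Returns a height×width uint8
    plane containing only ``line_value`` and ``background_value``.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size < 2:
        raise InvalidArgumentError("trace must have at least 2 samples")
    if not np.all(np.isfinite(trace)):
        raise InvalidArgumentError("trace contains NaN or infinite values")
    w, h = spec.width, spec.height
    xs = np.round(np.arange(trace.size) * (w - 1) / (trace.size - 1)).astype(int)
    ys = np.round((1.0 - np.clip(trace, 0.0, 1.0)) * (h - 1)).astype(int)
    plane = np.full((h, w), spec.background_value, dtype=np.uint8)
    for i in range(trace.size - 1):
        for x, y in _bresenham(xs[i], ys[i], xs[i + 1], ys[i + 1]):
            plane[y, x] = spec.line_value
    return plane


def _draw_axes(plane: np.ndarray, spec: RasterSpec) -> None:
    plane[-1, :] = spec.line_value   # x axis along the bottom row
    plane[:, 0] = spec.line_value    # y axis along the left column


def encode_merged_chart(window: np.ndarray, spec: RasterSpec | None = None,
                        subject_id: str = "", label: str = "",
                        window_index: int = 0) -> EncodedImage:
    """Over-draw the three channel traces in one grayscale plane.

    All traces are drawn at ``line_value`` — per-channel colours would let
    the model key on colour rather than waveform shape.  Overdraw is
    idempotent: identical traces produce the single-trace image.
    """
    spec = spec or RasterSpec()
    spec.require_canvas()
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] != 3:
        raise InvalidArgumentError("window must be a 3×L matrix")
    plane = np.full((spec.height, spec.width), spec.background_value, dtype=np.uint8)
    for trace in window:
        mask = render_trace_bitmap(trace, spec) == spec.line_value
        plane[mask] = spec.line_value
    if spec.draw_axes:
        _draw_axes(plane, spec)
    return EncodedImage(plane, "merged_chart", subject_id, label, window_index)


def encode_rgb(window: np.ndarray, spec: RasterSpec | None = None,
               channel_map: Sequence[str] = DEFAULT_CHANNEL_MAP,
               subject_id: str = "", label: str = "",
               window_index: int = 0) -> EncodedImage:
    """Stack per-channel binary trace planes as the R, G, B components.

    ``channel_map`` assigns electrodes to colour planes in R, G, B order
    (default Fp1→R, Fpz→G, Fp2→B).  A pixel crossed by no trace is white
    (255, 255, 255); a pixel crossed only by the R-assigned trace is
    (0, 255, 255), and so on.  Axes are never drawn in this encoding — the
    coordinate frame would contaminate the colour synthesis.
    """
    spec = spec or RasterSpec()
    spec.require_canvas()
    if spec.draw_axes:
        raise InvalidArgumentError("rgb synthesis forbids axes (draw_axes must be False)")
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] != 3:
        raise InvalidArgumentError("window must be a 3×L matrix")
    channel_map = tuple(channel_map)
    if sorted(channel_map) != sorted(CHANNEL_NAMES):
        raise InvalidArgumentError(
            f"channel_map must be a permutation of {CHANNEL_NAMES}")
    by_name = dict(zip(CHANNEL_NAMES, window))
    planes = [render_trace_bitmap(by_name[name], spec) for name in channel_map]
    pixels = np.stack(planes, axis=-1)
    return EncodedImage(pixels, "rgb_synthesis", subject_id, label,
                        window_index, channel_map=channel_map)


def decode_rgb(image: EncodedImage) -> list[np.ndarray]:
    """Recover the three per-channel trace masks from an RGB synthesis.

    Inverse of the plane stacking: ``decode_rgb(encode_rgb(w))`` returns the
    three ``render_trace_bitmap`` planes bit-exactly (as boolean masks,
    True on the trace).
    """
    if image.encoding != "rgb_synthesis":
        raise InvalidArgumentError("decode_rgb requires an rgb_synthesis image")
    px = image.pixels
    values = np.unique(px)
    allowed = {0, 255}
    if not set(values.tolist()) <= allowed:
        raise InvalidArgumentError(
            f"non-binary plane values {sorted(set(values.tolist()) - allowed)}")
    return [px[:, :, c] == 0 for c in range(3)]


def encode_windowset(windows, encoding: Encoding = "rgb_synthesis",
                     spec: RasterSpec | None = None,
                     channel_map: Sequence[str] = DEFAULT_CHANNEL_MAP
                     ) -> list[EncodedImage]:
    """Encode every window of a WindowSet with shared provenance."""
    images = []
    for idx, w in enumerate(windows.windows):
        if encoding == "merged_chart":
            img = encode_merged_chart(w, spec, windows.subject_id,
                                      windows.label, idx)
        elif encoding == "rgb_synthesis":
            img = encode_rgb(w, spec, channel_map, windows.subject_id,
                             windows.label, idx)
        else:
            raise InvalidArgumentError(f"unknown encoding {encoding!r}")
        images.append(img)
    return images


# ---------------------------------------------------------------------------
# Lossless PNG I/O plus a dataset manifest.
# ---------------------------------------------------------------------------

def write_image(image: EncodedImage, path: str | Path) -> None:
    """Write an encoded image as lossless 8-bit PNG (grayscale or RGB)."""
    mode = "L" if image.encoding == "merged_chart" else "RGB"
    Image.fromarray(image.pixels, mode=mode).save(Path(path), format="PNG")


def read_image(path: str | Path, encoding: Encoding,
               subject_id: str = "", label: str = "",
               window_index: int = 0) -> EncodedImage:
    arr = np.asarray(Image.open(Path(path)))
    return EncodedImage(arr, encoding, subject_id, label, window_index)


def write_image_dataset(images: Sequence[EncodedImage], outdir: str | Path,
                        manifest_name: str = "images.csv") -> Path:
    """Write PNGs plus a manifest CSV (path, subject_id, label, window, encoding)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        fname = f"{img.subject_id}_{img.window_index:04d}.png"
        write_image(img, outdir / fname)
        rows.append({"path": fname, "subject_id": img.subject_id,
                     "label": img.label, "window_index": img.window_index,
                     "encoding": img.encoding})
    manifest = outdir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_image_dataset(manifest_path: str | Path) -> list[EncodedImage]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    return [read_image(base / row.path, row.encoding, row.subject_id,
                       row.label, row.window_index)
            for row in df.itertuples()]
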