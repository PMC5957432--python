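"""Image-stack input/output.

Stacks are read from PNG/TIFF/JPEG files (8- or 16-bit) into floating-point
arrays in [0, 255]; frame order is the lexicographic filename order unless
an explicit list of paths is given.  Fused images are written as 8-bit
PNG/TIFF with rounding and clamping applied only at export.
"""

from __future__ import annotations

import glob
import os
import warnings

import imageio.v3 as iio
import numpy as np
from PIL import Image

__all__ = ["load_image", "load_stack", "save_image", "save_mask"]

_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


def load_image(path) -> np.ndarray:
    """Read one image as float64 in [0, 255]; 16-bit data are rescaled."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - report the offending path
        raise ValueError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]  # drop alpha
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        return arr.astype(float) * (255.0 / 65535.0)
    return arr.astype(float)


def _resolve_paths(source) -> list[str]:
    if isinstance(source, (str, os.PathLike)):
        source = os.fspath(source)
        if os.path.isdir(source):
            paths = [
                os.path.join(source, f)
                for f in sorted(os.listdir(source))
                if f.lower().endswith(_EXTENSIONS)
            ]
        else:
            paths = sorted(glob.glob(source))
    else:
        paths = [os.fspath(p) for p in source]
    if not paths:
        raise ValueError(f"no readable image files found for {source!r}")
    return paths


def load_stack(source) -> np.ndarray:
    """Load a focus stack from a directory, glob pattern, or list of paths.

    Returns (N, H, W) for grayscale input or (N, H, W, 3) for color.  All
    frames must share one shape; mixed sizes raise an error naming the
    offending files.
    """
    paths = _resolve_paths(source)
    frames = [load_image(p) for p in paths]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        detail = ", ".join(f"{p}: {f.shape}" for p, f in zip(paths, frames))
        raise ValueError(f"frames have mixed shapes: {detail}")
    if len(frames) == 1:
        warnings.warn("stack contains a single frame", stacklevel=2)
    return np.stack(frames)


def save_image(path, image) -> None:
    """Write an image as 8-bit, rounding and clamping to [0, 255]."""
    arr = np.asarray(image, dtype=float)
    out = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)


def save_mask(path, mask) -> None:
    """Write a label mask as an indexed 8-bit PNG (label n -> palette n)."""
    arr = np.asarray(mask)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("mask labels must fit in 8 bits")
    img = Image.fromarray(arr.astype(np.uint8), mode="P")
    # distinct palette entries so regions are visually separable
    rng = np.random.default_rng(0)
    palette = rng.integers(40, 256, size=(256, 3))
    palette[0] = 0
    img.putpalette(palette.astype(np.uint8).ravel().tolist())
    img.save(path)
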