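"""Synthetic multi-focus microscope stacks with known ground truth.

Real focus stacks of this kind (a bullet top, an insect body under a
desktop microscope at ~720x480) have two defining features: a textured
scene whose depth varies smoothly or in contiguous pieces, and frames in
which exactly the pixels whose depth matches the frame's focal plane are
sharp while everything else is defocus-blurred, more strongly the further
its depth lies from the plane.  The generator reproduces exactly that
geometry so every pipeline stage can be validated against a known
all-in-focus image:

* a textured ground-truth image (band-limited noise, a concentric-ring
  pattern, or blob-like patches — all carrying fine texture so the focus
  measure has signal everywhere),
* a depth map in [0, 1] with contiguous level sets (a vertical ramp
  constant per row, a radial bowl, or smooth blobs),
* N frames with focal planes d_n = (n-1)/(N-1); pixel (x, y) of frame n is
  the ground truth blurred with a Gaussian of
  sigma(x, y) = sigma_max * |depth(x, y) - d_n|, realized by blending a
  small bank of uniformly blurred depth-band images, plus optional
  additive zero-mean Gaussian noise,
* the true per-pixel sharpest frame, argmin_n |depth - d_n|.

Everything is driven by one integer seed; regeneration is bit-identical.

What this does not emulate: optics-accurate defocus (disk PSFs,
diffraction), frame misregistration, and non-Gaussian camera noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticStackTruth",
    "make_ground_truth",
    "make_depth_map",
    "render_stack",
    "simulate",
]

GROUND_TRUTH_KINDS = ("texture", "rings", "natural-like")
DEPTH_KINDS = ("horizontal-stripes", "radial", "blobs")


@dataclass
class SyntheticStackTruth:
    """A rendered stack together with everything needed to score a fusion."""

    ground_truth: np.ndarray
    depth_map: np.ndarray
    frames: np.ndarray
    true_masks: np.ndarray
    seed: int


def _check_shape(shape):
    h, w = int(shape[0]), int(shape[1])
    if h < 8 or w < 8:
        raise ValueError(f"shape {shape!r} is degenerate; need at least 8x8")
    return h, w


def _rescale(img, lo=20.0, hi=235.0):
    mn, mx = img.min(), img.max()
    if mx - mn < 1e-12:
        return np.full_like(img, (lo + hi) / 2.0)
    return lo + (hi - lo) * (img - mn) / (mx - mn)


def make_ground_truth(shape, kind: str = "texture", seed: int = 0, rgb: bool = False):
    """Textured all-in-focus image in [20, 235] (headroom for noise).

    kind="texture": band-limited noise (fine plus coarse scales).
    kind="rings": concentric rings over fine texture (machined-surface
    look).  kind="natural-like": smooth blob patches over fine texture.
    """
    h, w = _check_shape(shape)
    if kind not in GROUND_TRUTH_KINDS:
        raise ValueError(f"unknown ground-truth kind {kind!r}")
    rng = np.random.default_rng(seed)
    fine = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.0)
    fine = fine / max(fine.std(), 1e-12)  # unit variance: fine detail must carry
    # a realistic share of the contrast, as in micrographs, or the focus
    # measure has nothing to discriminate with
    if kind == "texture":
        coarse = ndimage.gaussian_filter(rng.standard_normal((h, w)), 8.0)
        img = fine + 1.5 * coarse / max(coarse.std(), 1e-12)
    elif kind == "rings":
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
        rings = np.sin(2.0 * np.pi * r / 12.0)
        img = 3.0 * rings + fine
    else:  # natural-like
        blobs = ndimage.gaussian_filter(rng.standard_normal((h, w)), 12.0)
        patches = np.digitize(blobs, np.quantile(blobs, [0.25, 0.5, 0.75]))
        img = patches.astype(float) + 0.6 * fine
    img = _rescale(img)
    if rgb:
        tint = 1.0 + 0.12 * ndimage.gaussian_filter(rng.standard_normal((h, w, 3)), (16, 16, 0))
        img = np.clip(img[..., None] * tint, 0.0, 255.0)
    return img


def make_depth_map(shape, kind: str = "horizontal-stripes", seed: int = 0):
    """Depth in [0, 1] with contiguous level sets.

    kind="horizontal-stripes": depth = row/(H-1), constant per row.
    kind="radial": depth grows with distance from the image centre.
    kind="blobs": smoothed random field normalized to [0, 1].
    """
    h, w = _check_shape(shape)
    if kind not in DEPTH_KINDS:
        raise ValueError(f"unknown depth kind {kind!r}")
    if kind == "horizontal-stripes":
        rows = np.arange(h, dtype=float) / (h - 1)
        return np.repeat(rows[:, None], w, axis=1)
    if kind == "radial":
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
        return r / r.max()
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 8.0)
    return (field - field.min()) / max(field.max() - field.min(), 1e-12)


def _blur(img: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return img.copy()
    spatial = (sigma, sigma) + (0,) * (img.ndim - 2)
    return ndimage.gaussian_filter(img, spatial, mode="nearest")


def render_stack(
    ground_truth,
    depth_map,
    n_frames: int,
    sigma_max: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_bands: int = 16,
) -> SyntheticStackTruth:
    """Render N defocused frames of a scene with known depth.

    Frame n focuses the depth plane d_n = (n-1)/(N-1); its blur at a pixel
    is sigma_max * |depth - d_n|.  The spatially varying blur is realized by
    blurring the ground truth once per depth band (band centres uniform in
    [0, 1]) and linearly blending the two bands bracketing each pixel's
    depth — exact per-pixel kernels at a fraction of the cost.
    """
    truth = np.asarray(ground_truth, dtype=float)
    depth = np.asarray(depth_map, dtype=float)
    if truth.shape[:2] != depth.shape:
        raise ValueError("ground truth and depth map shapes differ")
    if n_frames < 2:
        raise ValueError(f"need at least 2 frames, got {n_frames!r}")
    if sigma_max <= 0:
        raise ValueError(f"sigma_max must be positive, got {sigma_max!r}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd!r}")
    if depth.min() < 0 or depth.max() > 1:
        raise ValueError("depth map values must lie in [0, 1]")
    n_bands = max(2, int(n_bands))
    rng = np.random.default_rng(seed)

    centers = np.linspace(0.0, 1.0, n_bands)
    pos = depth * (n_bands - 1)
    lo = np.minimum(pos.astype(int), n_bands - 2)
    t = pos - lo
    if truth.ndim == 3:
        t = t[..., None]

    planes = np.arange(n_frames, dtype=float) / (n_frames - 1)
    frames = np.empty((n_frames,) + truth.shape)
    for n, d_n in enumerate(planes):
        bank = [_blur(truth, sigma_max * abs(c - d_n)) for c in centers]
        bank = np.stack(bank)
        low = bank[lo, np.arange(depth.shape[0])[:, None], np.arange(depth.shape[1])]
        high = bank[lo + 1, np.arange(depth.shape[0])[:, None], np.arange(depth.shape[1])]
        frame = (1.0 - t) * low + t * high
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[n] = np.clip(frame, 0.0, 255.0)

    true_masks = np.argmin(np.abs(depth[None] - planes[:, None, None]), axis=0) + 1
    return SyntheticStackTruth(truth, depth, frames, true_masks.astype(int), int(seed))


def simulate(
    shape=(256, 256),
    n_frames: int = 8,
    texture: str = "texture",
    depth: str = "horizontal-stripes",
    sigma_max: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    rgb: bool = False,
) -> SyntheticStackTruth:
    """One-call generator: ground truth + depth map + rendered stack."""
    truth = make_ground_truth(shape, kind=texture, seed=seed, rgb=rgb)
    depth_map = make_depth_map(shape, kind=depth, seed=seed + 1)
    return render_stack(
        truth, depth_map, n_frames, sigma_max=sigma_max, noise_sd=noise_sd, seed=seed + 2
    )
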