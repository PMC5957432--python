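"""Region mosaicking on Laplacian pyramids (RMLP).

The pixel-level pyramid fusion baseline picks each band-pass coefficient
independently, so the coefficients that reconstruct one output pixel usually
come from several different source frames, mixing in defocused content and
producing distortion.  RMLP instead segments the stack into contiguous
focus regions once (DBRG mask), decomposes that categorical mask into a
mask pyramid matched to the Laplacian pyramid geometry, and *selects* whole
regions: every band-pass cell is copied verbatim from the single source the
mask names at that cell,

    F_k(i, j) = LP_{k, M_k(i, j)}(i, j),

and the top (low-pass) level is selected the same way from the Gaussian
bases.  Because each mask level is a down-sampled copy of the one below,
the regions are geometrically consistent across scales and almost every
output pixel is reconstructed entirely from one source frame.

Mask levels are down-sampled by 2x2 majority vote (labels are categorical,
so the Gaussian filter used for intensity levels does not apply); ties go
to the smallest label.

Color stacks are fused per channel by default; a shared-mask mode computes
one mask from the ITU-R BT.601 luminance and applies it to all channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import dbrg, pyramids
from .focus_measure import sml

__all__ = [
    "FusionResult",
    "build_mask_pyramid",
    "mosaic_fuse",
    "fuse_top_layer",
    "rmlp_fuse_gray",
    "rmlp_fuse_color",
    "rmlp_fuse",
    "lp_fuse_gray",
    "lp_fuse_color",
    "lp_fuse",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FusionResult:
    """Fused image plus the mask and parameters that produced it."""

    fused: np.ndarray
    mask: np.ndarray | None
    params: dict = field(default_factory=dict)


def _as_stack(stack) -> np.ndarray:
    arr = np.asarray(stack, dtype=float)
    if arr.ndim not in (3, 4) or arr.shape[0] < 1:
        raise ValueError(
            "stack must be (N, H, W) grayscale or (N, H, W, 3) color, "
            f"got shape {np.shape(stack)}"
        )
    if arr.ndim == 4 and arr.shape[-1] != 3:
        raise ValueError(f"color stack must have 3 channels, got {arr.shape[-1]}")
    return arr


def _halve(shape):
    return ((shape[0] + 1) // 2, (shape[1] + 1) // 2)


def build_mask_pyramid(mask, n_levels: int, n_sources=None) -> list[np.ndarray]:
    """Down-sample a label mask level by level with 2x2 majority voting.

    Level 0 is the mask itself; each coarser cell takes the most frequent
    label among its (at most four) children inside the image, ties to the
    smallest label.  Level shapes follow the same ceil-halving chain as the
    intensity pyramids.
    """
    arr = np.asarray(mask).astype(int, copy=False)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    n = int(arr.max()) if n_sources is None else int(n_sources)
    if arr.min() < 1 or arr.max() > n:
        raise ValueError(f"mask labels must lie in [1, {n}]")
    if n_levels > pyramids.max_levels(arr.shape):
        raise ValueError(
            f"{n_levels} levels infeasible for mask shape {arr.shape}; "
            f"maximum is {pyramids.max_levels(arr.shape)}"
        )
    levels = [arr]
    for _ in range(n_levels - 1):
        cur = levels[-1]
        ho, wo = _halve(cur.shape)
        padded = np.zeros((2 * ho, 2 * wo), dtype=int)  # label 0 = outside, never counted
        padded[: cur.shape[0], : cur.shape[1]] = cur
        counts = np.empty((n, ho, wo), dtype=int)
        for label in range(1, n + 1):
            b = (padded == label).astype(int)
            counts[label - 1] = (
                b[0::2, 0::2] + b[0::2, 1::2] + b[1::2, 0::2] + b[1::2, 1::2]
            )
        levels.append(counts.argmax(axis=0) + 1)
    return levels


def _select(arrays, labels: np.ndarray) -> np.ndarray:
    stack = np.stack([np.asarray(a, dtype=float) for a in arrays])
    return np.take_along_axis(stack, (labels - 1)[None], axis=0)[0]


def fuse_top_layer(gaussian_bases, top_mask) -> np.ndarray:
    """Select the low-pass base value of the source named by the top mask."""
    mask = np.asarray(top_mask).astype(int, copy=False)
    bases = [np.asarray(b, dtype=float) for b in gaussian_bases]
    if any(b.shape != mask.shape for b in bases):
        raise ValueError(
            f"base shapes {[b.shape for b in bases]} do not match mask {mask.shape}"
        )
    if mask.min() < 1 or mask.max() > len(bases):
        raise ValueError(f"mask labels must lie in [1, {len(bases)}]")
    return _select(bases, mask)


def mosaic_fuse(lps, mask_pyramid) -> list[np.ndarray]:
    """Mosaic source Laplacian pyramids under a mask pyramid.

    Pure selection at every level: band-pass cells are copied from the
    source the mask level names, and the top level (the Gaussian base held
    by each Laplacian pyramid) is selected under the top mask level.
    """
    n = len(lps)
    if n < 1:
        raise ValueError("need at least one source pyramid")
    depth = len(mask_pyramid)
    if any(len(p) != depth for p in lps):
        raise ValueError("source pyramids and mask pyramid differ in depth")
    fused = []
    for k in range(depth):
        mask_k = np.asarray(mask_pyramid[k]).astype(int, copy=False)
        level = [p[k] for p in lps]
        if any(np.shape(lv) != mask_k.shape for lv in level):
            raise ValueError(f"level {k} shapes do not match the mask level")
        if mask_k.min() < 1 or mask_k.max() > n:
            raise ValueError(f"mask level {k} labels exceed [1, {n}]")
        fused.append(_select(level, mask_k))
    return fused


def _auto_levels(shape, n_levels):
    if n_levels is not None:
        return int(n_levels)
    return min(6, pyramids.max_levels(shape))


def rmlp_fuse_gray(
    stack,
    w: int = 1,
    threshold: float = 0.0,
    radius: int | None = None,
    n_levels: int | None = None,
    top_mask_mode: str = "pyramid",
    mask: np.ndarray | None = None,
) -> FusionResult:
    """Fuse a grayscale focus stack into one all-in-focus image.

    Pipeline: SML focus maps -> winner-take-all mask -> DBRG segmentation ->
    per-source Laplacian pyramids -> mask pyramid -> region mosaicking ->
    reconstruction.  Deterministic for fixed inputs and parameters.

    Parameters
    ----------
    stack : array_like
        (N, H, W) aligned grayscale frames, nominal range [0, 255].
    w, threshold
        SML window half-width and discrimination threshold.
    radius : int, optional
        DBRG disk radius; defaults to 8 scaled by ``min(H, W)/480``.
    n_levels : int, optional
        Pyramid depth K; defaults to 6, capped by image size.
    top_mask_mode : {"pyramid", "sml"}
        "pyramid" (default) selects the low-pass base under the down-sampled
        mask-pyramid top, keeping regions consistent across scales; "sml"
        recomputes the top mask as the SML argmax of the Gaussian bases.
    mask : ndarray, optional
        Precomputed segmentation mask (skips SML + DBRG); used for
        shared-mask color fusion.
    """
    arr = _as_stack(stack)
    if arr.ndim != 3:
        raise ValueError("rmlp_fuse_gray expects a grayscale (N, H, W) stack")
    n, h, w_img = arr.shape
    if n == 1:
        warnings.warn("single-frame stack: returning a copy", stacklevel=2)
        return FusionResult(arr[0].copy(), np.ones((h, w_img), dtype=int), {})
    if top_mask_mode not in ("pyramid", "sml"):
        raise ValueError(f"unknown top_mask_mode {top_mask_mode!r}")
    radius = dbrg.default_radius((h, w_img)) if radius is None else int(radius)
    n_levels = _auto_levels((h, w_img), n_levels)

    if mask is None:
        focus_maps = [sml(frame, w=w, threshold=threshold) for frame in arr]
        mask = dbrg.segment(dbrg.initial_mask(focus_maps), radius=radius, n_sources=n)
    else:
        mask = np.asarray(mask).astype(int, copy=False)
        if mask.shape != (h, w_img):
            raise ValueError("precomputed mask shape does not match the stack")

    lps = [pyramids.build_laplacian_pyramid(frame, n_levels) for frame in arr]
    mask_pyr = build_mask_pyramid(mask, n_levels, n_sources=n)
    fused_pyr = mosaic_fuse(lps, mask_pyr)
    if top_mask_mode == "sml":
        bases = [p[-1] for p in lps]
        top = dbrg.initial_mask([sml(b, w=w, threshold=threshold) for b in bases])
        fused_pyr[-1] = fuse_top_layer(bases, top)
    fused = pyramids.reconstruct(fused_pyr)
    params = {"w": w, "T": threshold, "R": radius, "K": n_levels,
              "top_mask_mode": top_mask_mode}
    return FusionResult(fused, mask, params)


def rmlp_fuse_color(
    stack,
    w: int = 1,
    threshold: float = 0.0,
    radius: int | None = None,
    n_levels: int | None = None,
    color_mode: str = "per-channel",
    top_mask_mode: str = "pyramid",
) -> FusionResult:
    """Fuse an RGB focus stack.

    ``color_mode="per-channel"`` (default) runs the grayscale pipeline
    independently on R, G and B and stacks the results;
    ``color_mode="shared-mask"`` computes one DBRG mask from the BT.601
    luminance and applies it to all three channels.
    """
    arr = _as_stack(stack)
    if arr.ndim != 4:
        raise ValueError("rmlp_fuse_color expects a color (N, H, W, 3) stack")
    kwargs = dict(w=w, threshold=threshold, radius=radius, n_levels=n_levels,
                  top_mask_mode=top_mask_mode)
    if color_mode == "per-channel":
        results = [rmlp_fuse_gray(arr[..., c], **kwargs) for c in range(3)]
        fused = np.stack([r.fused for r in results], axis=-1)
        params = dict(results[0].params, color_mode=color_mode)
        return FusionResult(fused, results[0].mask, params)
    if color_mode == "shared-mask":
        luma = rmlp_fuse_gray(arr @ _LUMA, **kwargs)
        channels = [
            rmlp_fuse_gray(arr[..., c], mask=luma.mask, **kwargs).fused
            for c in range(3)
        ]
        params = dict(luma.params, color_mode=color_mode)
        return FusionResult(np.stack(channels, axis=-1), luma.mask, params)
    raise ValueError(f"unknown color_mode {color_mode!r}")


def rmlp_fuse(stack, **kwargs) -> FusionResult:
    """Dispatch to the grayscale or color pipeline on stack dimensionality."""
    arr = _as_stack(stack)
    if arr.ndim == 3:
        kwargs.pop("color_mode", None)
        return rmlp_fuse_gray(arr, **kwargs)
    return rmlp_fuse_color(arr, **kwargs)


def lp_fuse_gray(stack, n_levels: int | None = None) -> FusionResult:
    """Pixel-level Laplacian-pyramid fusion baseline on a grayscale stack."""
    arr = _as_stack(stack)
    if arr.ndim != 3:
        raise ValueError("lp_fuse_gray expects a grayscale (N, H, W) stack")
    n_levels = _auto_levels(arr.shape[1:], n_levels)
    lps = [pyramids.build_laplacian_pyramid(frame, n_levels) for frame in arr]
    fused = pyramids.reconstruct(pyramids.lp_fuse_pixel(lps))
    return FusionResult(fused, None, {"K": n_levels})


def lp_fuse_color(stack, n_levels: int | None = None) -> FusionResult:
    """Per-channel pixel-level baseline on an RGB stack."""
    arr = _as_stack(stack)
    if arr.ndim != 4:
        raise ValueError("lp_fuse_color expects a color (N, H, W, 3) stack")
    fused = np.stack(
        [lp_fuse_gray(arr[..., c], n_levels).fused for c in range(3)], axis=-1
    )
    return FusionResult(fused, None, {"K": _auto_levels(arr.shape[1:3], n_levels)})


def lp_fuse(stack, n_levels: int | None = None) -> FusionResult:
    """Dispatch the pixel-level baseline on stack dimensionality."""
    arr = _as_stack(stack)
    return lp_fuse_gray(arr, n_levels) if arr.ndim == 3 else lp_fuse_color(arr, n_levels)
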