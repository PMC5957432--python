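"""Gaussian and Laplacian pyramids and the pixel-level fusion baseline.

A Gaussian pyramid low-pass filters and decimates an image level by level::

    G_k(i, j) = sum_{m,n=-2..2} w(m, n) G_{k-1}(2i + m, 2j + n)

with the separable 5x5 Burt-Adelson binomial kernel
``(1, 4, 6, 4, 1)/16`` in each direction (the a = 0.375 generating kernel).
The Laplacian pyramid stores the band-pass residuals
``LP_k = G_k - expand(G_{k+1})`` for k < K-1 and keeps the low-pass Gaussian
base as its top level, which makes the decomposition exactly invertible:
reconstruction adds back the very expansions that were subtracted.

Level sizes follow the ceil-halving chain ``ceil(H/2), ceil(W/2)``; borders
are mirrored (reflection without repeating the edge pixel) so constants pass
through reduce, expand, decompose and reconstruct unchanged.

The classical pixel-level Laplacian-pyramid fusion rule is included as the
baseline: at each band-pass cell the source with the largest absolute
coefficient wins; base levels are averaged.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "gaussian_reduce",
    "expand",
    "build_gaussian_pyramid",
    "build_laplacian_pyramid",
    "reconstruct",
    "lp_fuse_pixel",
    "max_levels",
]

_K1D = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
KERNEL_2D = np.outer(_K1D, _K1D)


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    return arr


def _half(n: int) -> int:
    return (n + 1) // 2


def max_levels(shape) -> int:
    """Deepest pyramid for ``shape``: every level keeps min dimension >= 2."""
    h, w = int(shape[0]), int(shape[1])
    k = 1
    while min(_half(h), _half(w)) >= 2:
        h, w = _half(h), _half(w)
        k += 1
    return k


def gaussian_reduce(image) -> np.ndarray:
    """Filter with the 5x5 binomial kernel and decimate by 2 (ceil sizes)."""
    arr = _as_image(image)
    if min(arr.shape) < 2:
        raise ValueError(f"image must be at least 2x2, got {arr.shape}")
    filtered = ndimage.correlate(arr, KERNEL_2D, mode="mirror")
    return filtered[::2, ::2]


def expand(image, target_shape) -> np.ndarray:
    """Upsample a level back to ``target_shape``.

    Zero-interleave onto the target grid, then convolve with 4x the 5x5
    kernel; the factor 4 restores unit DC gain over the interleaved zeros,
    so constants expand to the same constant.
    """
    arr = _as_image(image)
    th, tw = int(target_shape[0]), int(target_shape[1])
    if (_half(th), _half(tw)) != arr.shape:
        raise ValueError(
            f"target shape {(th, tw)} does not ceil-halve to source shape {arr.shape}"
        )
    up = np.zeros((th, tw))
    up[::2, ::2] = arr
    return ndimage.correlate(up, 4.0 * KERNEL_2D, mode="mirror")


def _check_levels(image_shape, n_levels: int) -> None:
    if not isinstance(n_levels, (int, np.integer)) or n_levels < 2:
        raise ValueError(f"pyramid needs at least 2 levels, got {n_levels!r}")
    feasible = max_levels(image_shape)
    if n_levels > feasible:
        raise ValueError(
            f"{n_levels} levels infeasible for shape {tuple(image_shape)}; "
            f"maximum is {feasible}"
        )


def build_gaussian_pyramid(image, n_levels: int) -> list[np.ndarray]:
    """List of ``n_levels`` images; level 0 is the source itself."""
    arr = _as_image(image)
    _check_levels(arr.shape, n_levels)
    levels = [arr]
    for _ in range(n_levels - 1):
        levels.append(gaussian_reduce(levels[-1]))
    return levels


def build_laplacian_pyramid(image, n_levels: int) -> list[np.ndarray]:
    """Band-pass residual levels plus the Gaussian base as the top level."""
    gauss = build_gaussian_pyramid(image, n_levels)
    levels = [
        gauss[k] - expand(gauss[k + 1], gauss[k].shape) for k in range(n_levels - 1)
    ]
    levels.append(gauss[-1])
    return levels


def _check_pyramid(levels) -> list[np.ndarray]:
    if len(levels) < 2:
        raise ValueError("pyramid needs at least 2 levels")
    arrs = [np.asarray(lv, dtype=float) for lv in levels]
    for k in range(len(arrs) - 1):
        want = (_half(arrs[k].shape[0]), _half(arrs[k].shape[1]))
        if arrs[k + 1].shape != want:
            raise ValueError(
                f"level {k + 1} shape {arrs[k + 1].shape} does not ceil-halve "
                f"level {k} shape {arrs[k].shape}"
            )
    return arrs


def reconstruct(levels) -> np.ndarray:
    """Invert a Laplacian pyramid: expand-and-add from the base downward."""
    arrs = _check_pyramid(levels)
    image = arrs[-1]
    for k in range(len(arrs) - 2, -1, -1):
        image = arrs[k] + expand(image, arrs[k].shape)
    return image


def lp_fuse_pixel(pyramids) -> list[np.ndarray]:
    """Classical pixel-level Laplacian-pyramid fusion (the baseline rule).

    Band-pass levels take, cell by cell, the coefficient of the source with
    the largest absolute value (ties to the smallest source index); the
    low-pass base level is the mean of the sources' bases.
    """
    if len(pyramids) < 2:
        raise ValueError("need at least two pyramids to fuse")
    pyrs = [_check_pyramid(p) for p in pyramids]
    depth = len(pyrs[0])
    for p in pyrs[1:]:
        if len(p) != depth or any(a.shape != b.shape for a, b in zip(p, pyrs[0])):
            raise ValueError("pyramids differ in geometry")
    fused = []
    for k in range(depth - 1):
        stack = np.stack([p[k] for p in pyrs])
        winner = np.argmax(np.abs(stack), axis=0)
        fused.append(np.take_along_axis(stack, winner[None], axis=0)[0])
    fused.append(np.mean([p[-1] for p in pyrs], axis=0))
    return fused
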