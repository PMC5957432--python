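"""Density-based region growing (DBRG) segmentation of the focus mask.

The per-pixel winner-take-all mask ``argmax_n SML_n`` is noisy: in smooth or
defocused areas the focus measure is weak and single pixels flip to the
wrong source frame.  Because the in-focus part of each frame of a microscope
stack is a *contiguous* region, the mask can be cleaned by a density
argument: a pixel is reliable (a *seed*) when one label occupies more than
half of the Euclidean disk of radius ``R`` around it.  Clusters grow out of
seed pixels through density-connectivity, and the leftover pixels (isolated
noise, smooth regions) are assigned to the nearest labeled pixel under the
checker-board (Chebyshev) distance.

Densities are normalized by the number of disk cells actually inside the
image (not the continuous disk area), so a uniform neighbourhood scores
exactly 1.0 even at image corners and the 0.5 seed threshold keeps its
majority meaning everywhere.

All tie-breaks (label argmax, equal-distance fills) go to the smallest
source index, which makes the whole segmentation deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

__all__ = [
    "initial_mask",
    "neighborhood_density",
    "find_seeds",
    "seed_map",
    "segment",
    "default_radius",
    "disk_offsets",
]

_UNLABELED = 0


def default_radius(shape, base: int = 8, reference: int = 480, floor: int = 4) -> int:
    """Disk radius scaled to image size.

    ``R = 8`` suits ~720x480 frames; the radius scales proportionally with
    the smaller image dimension and never drops below ``floor``.
    """
    h, w = int(shape[0]), int(shape[1])
    return max(floor, round(base * min(h, w) / reference))


def disk_offsets(radius: int) -> np.ndarray:
    """(di, dj) offsets of the discrete disk {di^2 + dj^2 <= R^2}."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius!r}")
    r = int(radius)
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    keep = di * di + dj * dj <= r * r
    return np.stack([di[keep], dj[keep]], axis=1)


def _disk_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    return (di * di + dj * dj <= r * r).astype(float)


def _as_mask(mask, n_sources=None) -> tuple[np.ndarray, int]:
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("label mask must be a non-empty 2-D integer array")
    arr = arr.astype(int, copy=False)
    n = int(arr.max()) if n_sources is None else int(n_sources)
    if arr.min() < 1 or arr.max() > n:
        raise ValueError(f"mask labels must lie in [1, {n}]")
    return arr, n


def initial_mask(focus_maps) -> np.ndarray:
    """Winner-take-all label mask from per-source focus maps.

    ``labels[i, j] = argmax_n SML_n(i, j) + 1`` (labels are 1-based source
    indices); ties go to the smallest source index.
    """
    maps = [np.asarray(m, dtype=float) for m in focus_maps]
    if len(maps) < 1:
        raise ValueError("need at least one focus map")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps) or len(shape) != 2:
        raise ValueError(
            f"focus maps must share one 2-D shape, got {[m.shape for m in maps]}"
        )
    return np.argmax(np.stack(maps), axis=0).astype(int) + 1


def _label_counts(mask: np.ndarray, n_sources: int, radius: int):
    """Per-label disk counts and in-image disk sizes, exact integers.

    FFT convolution with the disk indicator gives the counts; results are
    rounded back to integers so the 0.5 threshold can be tested exactly as
    ``2 * count > size``.
    """
    kernel = _disk_kernel(radius)
    size = np.rint(fftconvolve(np.ones(mask.shape), kernel, mode="same")).astype(int)
    counts = np.empty((n_sources,) + mask.shape, dtype=int)
    for n in range(1, n_sources + 1):
        counts[n - 1] = np.rint(
            fftconvolve((mask == n).astype(float), kernel, mode="same")
        ).astype(int)
    return counts, size


def neighborhood_density(mask, center, radius: int, n_sources=None) -> np.ndarray:
    """Per-label density in the disk of ``radius`` around ``center``.

    Returns a length-N vector whose entry ``n-1`` is the fraction of disk
    cells (clipped to the image) carrying label ``n``; entries sum to 1.
    """
    arr, n = _as_mask(mask, n_sources)
    i, j = int(center[0]), int(center[1])
    h, w = arr.shape
    if not (0 <= i < h and 0 <= j < w):
        raise ValueError(f"center {center!r} outside image of shape {arr.shape}")
    offs = disk_offsets(radius)
    ii = offs[:, 0] + i
    jj = offs[:, 1] + j
    inside = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
    labels = arr[ii[inside], jj[inside]]
    dens = np.bincount(labels, minlength=n + 1)[1:].astype(float)
    return dens / labels.size


def seed_map(mask, radius: int, n_sources=None):
    """Vectorized seed detection over the whole mask.

    Returns ``(is_seed, majority)``: a boolean map of pixels whose maximum
    per-label disk density strictly exceeds 0.5, and the majority label at
    every pixel (ties to the smallest label).
    """
    arr, n = _as_mask(mask, n_sources)
    counts, size = _label_counts(arr, n, radius)
    majority = counts.argmax(axis=0).astype(int) + 1
    is_seed = 2 * counts.max(axis=0) > size
    return is_seed, majority


def find_seeds(mask, radius: int, n_sources=None) -> set:
    """Set of ``((i, j), majority_label)`` for every seed pixel."""
    is_seed, majority = seed_map(mask, radius, n_sources)
    ii, jj = np.nonzero(is_seed)
    return {((int(i), int(j)), int(majority[i, j])) for i, j in zip(ii, jj)}


def _fill_nearest_chebyshev(labels: np.ndarray) -> np.ndarray:
    """Assign unlabeled cells the label of the nearest labeled pixel.

    Simultaneous multi-source expansion over the 8-connected neighbourhood
    (checker-board distance); a cell reached at equal distance from several
    labels takes the smallest.  Implemented as iterated grey-scale erosion
    with unlabeled cells held at a +inf sentinel: the min over a 3x3 window
    is exactly "closest first, then smallest label".
    """
    big = 2**31  # sentinel far above any label; headroom against overflow
    work = np.where(labels == _UNLABELED, big, labels).astype(np.int64)
    footprint = np.ones((3, 3), dtype=bool)
    while True:
        holes = work == big
        if not holes.any():
            break
        eroded = ndimage.grey_erosion(work, footprint=footprint, mode="constant", cval=big)
        work[holes] = eroded[holes]
    return work.astype(int)


def segment(initial, radius: int = 8, n_sources=None) -> np.ndarray:
    """Refine a winner-take-all mask into contiguous focus regions.

    Every seed pixel is labeled with its disk-majority label; each label's
    cluster then grows one disk step, absorbing unlabeled pixels whose
    initial label matches (non-seed border pixels are absorbed but never
    extend growth, and every possible extender — a seed — is already
    labeled, so a single dilation realizes the transitive growth).  The
    remaining pixels are noise or smooth-region pixels and take the label of
    the nearest labeled pixel under Chebyshev distance.

    If the mask has no seed at all (pathological inputs such as a fine
    checkerboard) the initial mask is returned unchanged.

    Parameters
    ----------
    initial : array_like
        2-D winner-take-all label mask, labels in ``[1, N]``.
    radius : int
        Disk radius ``R``; 8 suits ~480-pixel frames and should scale with
        image size (see :func:`default_radius`).

    Returns
    -------
    ndarray
        Total label mask (no unlabeled cells), labels a subset of the
        input's labels.
    """
    arr, n = _as_mask(initial, n_sources)
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius!r}")
    is_seed, majority = seed_map(arr, radius, n)
    if not is_seed.any():
        return arr.copy()
    out = np.where(is_seed, majority, _UNLABELED)

    kernel = _disk_kernel(radius)
    for label in range(1, n + 1):
        core = out == label
        if not core.any():
            continue
        reach = np.rint(fftconvolve(core.astype(float), kernel, mode="same")) >= 1
        out[(out == _UNLABELED) & reach & (arr == label)] = label

    return _fill_nearest_chebyshev(out)
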