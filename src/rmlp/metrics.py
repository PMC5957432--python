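"""Reference-based fusion quality metrics: RMSE and mean SSIM.

RMSE is the root mean squared pixel error against the ground-truth
all-in-focus image.  SSIM is the structural similarity index of Wang et
al.: within each sliding window,

    SSIM = (2 mu_f mu_g + C1)(2 sigma_fg + C2)
           / ((mu_f^2 + mu_g^2 + C1)(sigma_f^2 + sigma_g^2 + C2)),

with C1 = (K1 L)^2 and C2 = (K2 L)^2 stabilizing the ratios (K1 = 0.01,
K2 = 0.03, L = 255 by default), averaged over all window positions.  The
window is the conventional 11x11 Gaussian-weighted window with sigma = 1.5.
Color images are scored per channel and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MetricConfig", "rmse", "ssim"]


@dataclass
class MetricConfig:
    """SSIM constants and window specification.

    k1, k2 : stabilizing constants; C1 = (k1*L)^2, C2 = (k2*L)^2.
    dynamic_range : L, the pixel dynamic range (255 for 8-bit data).
    window_size, sigma : Gaussian sliding-window size and width.
    """

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 255.0
    window_size: int = 11
    sigma: float = 1.5

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("K1 and K2 must be positive")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic range must be positive")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window size must be an odd integer >= 3")


def _pair(fused, reference):
    a = np.asarray(fused, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.ndim not in (2, 3):
        raise ValueError("images must be 2-D grayscale or (H, W, C) color")
    return a, b


def rmse(fused, reference) -> float:
    """Root mean squared error over all pixels (and channels)."""
    a, b = _pair(fused, reference)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _ssim_2d(a: np.ndarray, b: np.ndarray, cfg: MetricConfig) -> float:
    pad = (cfg.window_size - 1) // 2
    truncate = pad / cfg.sigma

    def filt(x):
        return ndimage.gaussian_filter(x, cfg.sigma, truncate=truncate)

    mu_a = filt(a)
    mu_b = filt(b)
    # window moments without bias correction (Gaussian-weighted statistics)
    var_a = filt(a * a) - mu_a * mu_a
    var_b = filt(b * b) - mu_b * mu_b
    cov = filt(a * b) - mu_a * mu_b

    c1 = (cfg.k1 * cfg.dynamic_range) ** 2
    c2 = (cfg.k2 * cfg.dynamic_range) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    ssim_map = num / den
    # drop the border where the window overhangs the image
    interior = ssim_map[pad:-pad, pad:-pad] if min(a.shape) > 2 * pad else ssim_map
    return float(interior.mean())


def ssim(fused, reference, config: MetricConfig | None = None) -> float:
    """Mean structural similarity between two images.

    Returns a value in [-1, 1]; 1 exactly iff the images are identical.
    Color images are scored channel by channel and the scores averaged.
    """
    a, b = _pair(fused, reference)
    cfg = config or MetricConfig()
    if a.ndim == 3:
        return float(
            np.mean([_ssim_2d(a[..., c], b[..., c], cfg) for c in range(a.shape[-1])])
        )
    return _ssim_2d(a, b, cfg)
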