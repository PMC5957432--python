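import numpy as np
import pytest

import rmlp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """128x128 4-frame noise-free stripe stack shared by unit tests."""
    return rmlp.simulate(shape=(128, 128), n_frames=4, sigma_max=4.0,
                         noise_sd=0.0, seed=7)


# ---------------------------------------------------------------- oracles

def ml_oracle(img):
    """Nested-loop modified Laplacian with edge replication."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            up = img[max(i - 1, 0), j]
            down = img[min(i + 1, h - 1), j]
            left = img[i, max(j - 1, 0)]
            right = img[i, min(j + 1, w - 1)]
            out[i, j] = abs(2 * img[i, j] - up - down) + abs(
                2 * img[i, j] - left - right
            )
    return out


def sml_oracle(img, w, threshold):
    """Nested-loop windowed sum of thresholded ML values."""
    ml = ml_oracle(img)
    h, wid = ml.shape
    out = np.zeros((h, wid))
    for i in range(h):
        for j in range(wid):
            acc = 0.0
            for di in range(-w, w + 1):
                for dj in range(-w, w + 1):
                    x, y = i + di, j + dj
                    if 0 <= x < h and 0 <= y < wid and ml[x, y] >= threshold:
                        acc += ml[x, y]
            out[i, j] = acc
    return out


def density_oracle(mask, center, radius):
    """Per-label disk-count density at one pixel, by direct loops."""
    mask = np.asarray(mask)
    h, w = mask.shape
    n = int(mask.max())
    counts = np.zeros(n)
    total = 0
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di * di + dj * dj > radius * radius:
                continue
            x, y = center[0] + di, center[1] + dj
            if 0 <= x < h and 0 <= y < w:
                counts[mask[x, y] - 1] += 1
                total += 1
    return counts / total


def majority_downsample_oracle(mask, n_labels):
    """2x2 block majority vote with smallest-label ties, by direct loops."""
    mask = np.asarray(mask)
    h, w = mask.shape
    ho, wo = (h + 1) // 2, (w + 1) // 2
    out = np.zeros((ho, wo), dtype=int)
    for i in range(ho):
        for j in range(wo):
            votes = np.zeros(n_labels + 1, dtype=int)
            for di in range(2):
                for dj in range(2):
                    x, y = 2 * i + di, 2 * j + dj
                    if x < h and y < w:
                        votes[mask[x, y]] += 1
            out[i, j] = np.argmax(votes[1:]) + 1
    return out
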