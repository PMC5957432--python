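# rmlp — all-in-focus fusion of microscope focus stacks

High-magnification optics have a shallow depth of field: a microscope frame
of a 3-D object (a bullet top, an insect body) is sharp only where the
object's depth matches the focal plane. The remedy is *multi-focus image
fusion*: capture a stack of aligned frames at different focal planes and
compose the sharp part of each into a single all-in-focus image. This
package implements **Region Mosaicking on Laplacian Pyramids (RMLP)** for
such stacks, together with the classical pixel-level Laplacian-pyramid
fusion baseline, reference quality metrics (RMSE, SSIM), and a synthetic
stack generator with known ground truth.

## Method

Given N aligned frames I₁ … I_N:

1. **Focus measure.** Per-pixel sharpness of each frame is the
   Sum-Modified-Laplacian:
   ML(x,y) = |2I(x,y) − I(x−1,y) − I(x+1,y)| + |2I(x,y) − I(x,y−1) − I(x,y+1)|,
   summed over a (2w+1)×(2w+1) window (default 3×3) with an optional
   discrimination threshold T.
2. **Region segmentation (DBRG).** The winner-take-all mask
   M₀(i,j) = argmaxₙ SMLₙ(i,j) is cleaned by density-based region growing:
   a pixel is a *seed* when one label fills more than half of the radius-R
   disk around it; clusters grow from seeds, and leftover pixels take the
   label of the nearest labeled pixel under checker-board (Chebyshev)
   distance. Focus regions of a microscope stack are contiguous, so this
   removes isolated mislabels without disturbing region boundaries.
3. **Region mosaicking.** Each frame is decomposed into a K-level Laplacian
   pyramid LP_{k,n}; the mask is decomposed into a matching mask pyramid M_k
   by 2×2 majority voting. Fusion is pure selection,
   F_k(i,j) = LP_{k, M_k(i,j)}(i,j), with the low-pass top level selected
   from the Gaussian bases the same way, and the fused pyramid is collapsed
   back to the all-in-focus image. Because every level of the mask pyramid
   is a down-sampled copy of the same region map, almost every output pixel
   is reconstructed entirely from one source frame — unlike the pixel-level
   baseline F_k = LP_{k,n̂} with n̂ = argmaxₙ|LP_{k,n}|, which mixes sources
   across levels and introduces distortion.

RGB stacks are fused per channel by default (a shared luminance-derived
mask is available as an option). Quality against a ground-truth reference
is scored with RMSE and mean SSIM (11×11 Gaussian window, σ = 1.5,
C₁ = (0.01·255)², C₂ = (0.03·255)²).

## Worked example

```python
import rmlp

# study stack: 8 frames of a textured scene, focal planes sweeping a
# depth ramp, defocus blur up to sigma = 4 px
bundle = rmlp.simulate(shape=(256, 256), n_frames=8, sigma_max=4.0,
                       noise_sd=0.0, seed=1)

result = rmlp.rmlp_fuse(bundle.frames, radius=8)
baseline = rmlp.lp_fuse(bundle.frames)

for name, image in [("RMLP", result.fused),
                    ("pixel-level LP", baseline.fused),
                    ("best single frame", min(bundle.frames,
                     key=lambda f: rmlp.rmse(f, bundle.ground_truth)))]:
    print(f"{name:>18}:  RMSE {rmlp.rmse(image, bundle.ground_truth):6.3f}"
          f"   SSIM {rmlp.ssim(image, bundle.ground_truth):.4f}")
```

prints

```
              RMLP:  RMSE  0.111   SSIM 1.0000
    pixel-level LP:  RMSE  1.352   SSIM 0.9972
 best single frame:  RMSE  6.601   SSIM 0.8517
```

The best single frame is sharp only in its own depth band (RMSE 6.6 against
the all-in-focus truth). Pixel-level pyramid fusion recovers most of the
scene but mixes coefficients from defocused frames (RMSE 1.35); region
mosaicking selects whole regions from single frames and is an order of
magnitude closer to the truth. `result.mask` holds the segmented region
map and `result.params` the fully resolved parameters.

## Command line

```sh
rmlp simulate --shape 256x256 --frames 8 --sigma-max 4 --seed 1 --out bundle/
rmlp fuse --input bundle/frame_*.png --output fused.png --save-mask
rmlp evaluate --test fused.png --ref bundle/truth.png
```

`fuse` writes a JSON sidecar with every resolved parameter; identical
inputs and configuration give byte-identical outputs.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `w`  | 1       | SML window half-width (3×3 window) |
| `threshold` (T) | 0 | SML discrimination threshold |
| `radius` (R) | 8 scaled by min(H,W)/480 | DBRG disk radius |
| `n_levels` (K) | 6, capped by image size | pyramid depth |

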