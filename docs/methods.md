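# Methods

## Imaging model and assumptions

A multi-focus microscope stack is modelled as N aligned frames of one
static scene whose depth varies contiguously. Frame n focuses one depth
plane; a pixel's defocus blur grows with the distance between its depth
and that plane. Two assumptions carry the whole method: frames are
pixel-aligned (a stable capture platform; no registration is attempted),
and the in-focus pixels of each frame form contiguous regions rather than
scattered points. All arithmetic is floating point on intensities in
[0, 255]; quantization to 8 bits happens only on image export.

## Focus measure

Sharpness is the Sum-Modified-Laplacian: the absolute values of the
horizontal and vertical second differences are summed per pixel (so
opposite-sign curvature cannot cancel) and then summed over a
(2w+1)×(2w+1) window. The pixel step of the second difference is fixed at
one pixel. Defaults: w = 1 (a 3×3 window — larger windows blur the focus
boundary), threshold T = 0, which makes the measure a plain windowed sum;
T is exposed because discarding window cells with ML < T can suppress the
noise floor in very smooth scenes. The threshold is applied per window
cell, not to the whole window sum. Borders use edge replication so that a
constant image scores exactly zero everywhere; window cells outside the
image contribute nothing.

## Density-based region growing

The winner-take-all mask argmaxₙ SMLₙ is correct in textured, well-focused
areas and noisy in smooth or strongly defocused ones. DBRG repairs it
using spatial label density: for the disk of radius R around a pixel
(Euclidean disk, R in pixels), the density of label n is the fraction of
disk cells carrying n. Densities are normalized by the number of disk
cells *inside the image*, not by the continuous area πR²: with the
continuous normalization a perfectly uniform neighbourhood at an image
corner would score ≈ 0.25 and could never seed, which breaks the majority
semantics of the 0.5 threshold.

A pixel whose maximum density strictly exceeds 0.5 is a seed. Every seed
is labeled with its disk-majority label; each label's cluster then grows
one disk step, absorbing unlabeled pixels whose initial label matches.
Growth transitivity only ever passes through seed pixels, and all seeds
are labeled up front, so a single dilation per label realizes the full
transitive closure; this also removes any dependence on cluster
iteration order — the output is the same whatever order seeds are
visited in. Remaining pixels (noise, smooth regions) take the label of
the nearest labeled pixel under Chebyshev ("checker-board") distance,
computed by iterated 3×3 minimum filtering with unlabeled cells held at a
sentinel; a pixel at equal distance from several labels deterministically
takes the smallest. All argmax ties likewise resolve to the smallest
source index.

Degenerate input: a mask with no seed at all (e.g. three labels
interleaved at unit period) is returned unchanged — there is no density
evidence to grow from. Note that a two-label checkerboard is *not*
seedless under the discrete normalization: an interior R = 8 disk has 197
cells split 101/96 by parity, a bare strict majority for the centre's own
label, so such a mask is its own fixed point through the seed path.

Default R = 8, scaled as max(4, round(8·min(H,W)/480)) — the radius must
grow with frame size to keep the same physical neighbourhood, and R = 8
suits the ~480-pixel frames this was tuned for. The radius should stay
well below the expected focus-region width: once the disk outgrows the
regions (R = 64 on 256-pixel frames with eight depth bands), no label can
reach majority anywhere, segmentation falls back to the raw mask, and
fusion quality collapses — the practical failure mode of over-smoothing.

## Pyramids and fusion

Gaussian reduction filters with the separable 5×5 binomial kernel
(1, 4, 6, 4, 1)/16 per axis (the Burt–Adelson a = 0.375 kernel) and
decimates by two; levels ceil-halve, and every level must keep both
dimensions ≥ 2. Borders are mirrored without repeating the edge pixel,
which preserves constants exactly through reduce, expand, decompose and
reconstruct. Expansion zero-interleaves onto the target grid and filters
with 4× the kernel (unit DC gain over the interleaved zeros). The
Laplacian pyramid stores band-pass residuals G_k − expand(G_{k+1}) and
keeps the Gaussian base as its top level; reconstruction is exact by
construction (round-trip error is float rounding, < 1e−6 on 8-bit-range
images, and the tests assert that bound).

The mask is down-sampled by 2×2 majority vote per level (labels are
categorical; averaging is meaningless), ties to the smallest label, block
cells outside the image abstaining. Fusion is selection at every level:
band-pass cells and the low-pass top are copied from the source named by
the mask level. By default the top level is selected under the
down-sampled mask-pyramid top, which keeps regions consistent across
scales; a variant that recomputes the top mask from the SML of the
Gaussian bases is available (`top_mask_mode="sml"`) but is noisier at
coarse resolution and not the default. Default K = 6, capped by image
size: depth barely changes results when the mask is accurate (selection
plus exact reconstruction is depth-invariant inside regions), but deeper
pyramids feather the cost of mask errors and boundary transitions across
scales, which measurably helps on noisy stacks; beyond K ≈ 7 the base is
too small to matter. No explicit feathering is applied at region
boundaries — selection is hard at every level and smoothing arises only
from reconstruction.

The pixel-level baseline fuses band-pass cells by largest absolute
coefficient (ties to the smallest source) and averages the bases. Its
characteristic failure is reconstructing one output pixel from several
frames; its clean-stack RMSE against truth is dominated by exactly this
band-pass mixing (replacing its band-pass levels with the truth's removes
almost all the error, replacing the base does not).

Color stacks are fused per channel (R, G, B independently); the
shared-mask mode computes one DBRG mask from BT.601 luminance and applies
it to all channels, trading a little per-channel optimality for a single
consistent region map.

## Synthetic stacks

The generator reproduces the stack geometry described above at desk
scale. Ground-truth textures: band-limited noise ("texture"), concentric
rings over fine texture ("rings", a machined-surface look), and smoothed
blob patches ("natural-like"). The fine-scale component is variance
normalized to carry a realistic share of the contrast (≈ 10 intensity
units RMS, fine:coarse variance 1:1.5 for "texture"): micrograph texture
has strong local contrast, and a focus measure built on second
differences needs fine-scale signal to discriminate — with fine detail at
the ~1-unit level the winner-take-all mask is near-random even at modest
noise. Depth maps: a per-row ramp ("horizontal-stripes", so frame n's
focus band is a horizontal stripe), a radial bowl, or a smooth random
field — all with contiguous level sets, matching the imaging model.

Frame n (focal plane d_n = (n−1)/(N−1)) blurs the truth with
σ(x,y) = σ_max·|depth − d_n|, realized by blurring once per depth band
(16 bands, centres uniform in [0, 1]) and linearly blending the two bands
bracketing each pixel — exact spatially varying kernels cost far more and
change nothing at these sizes. Optional zero-mean Gaussian noise is added
per frame and the result clipped to [0, 255]. The true sharpest-frame
mask is argminₙ|depth − d_n|, ties to the smallest frame. One integer
seed drives everything; regeneration is bit-identical.

Default study geometry, used throughout the tests and the reproduction
script: 256×256, N = 8, stripe depth, σ_max = 4, noise sd ∈ {0, 2} —
large enough for six pyramid levels and eight distinct focus bands,
small enough that the whole suite runs in seconds. What the generator
does *not* emulate: optics-accurate defocus PSFs (disks, diffraction),
misregistration, chromatic effects, non-Gaussian sensor noise. Passing
on these stacks therefore validates the algorithmic contracts (mask
recovery, region-consistent selection, exact reconstruction, metric
behaviour), not robustness to registration error or real sensor
statistics.

## Metrics

RMSE is the root mean squared intensity error. SSIM follows the standard
structural-similarity definition with C₁ = (K₁L)², C₂ = (K₂L)²
(K₁ = 0.01, K₂ = 0.03, L = 255) — the stabilizers must be squared to be
dimensionally consistent with the variance terms — computed over an
11×11 Gaussian-weighted sliding window with σ = 1.5, window moments
without bias correction, border windows dropped from the mean. The
implementation agrees with scikit-image's `structural_similarity` in the
equivalent configuration to ~1e−6 and that agreement is pinned by a test.
Color metrics average the per-channel scores.

## Noise behaviour

Region mosaicking is pure selection, so injected sensor noise passes into
the fused image at unit gain: on the study stack with noise sd 2 its RMSE
rises from ≈ 0.11 to ≈ 2.01 — essentially the noise floor, with the DBRG
mask staying > 92% correct. The pixel-level baseline amplifies noise
(choose-max favours extreme coefficients; its noise-induced error
component is ≈ 2.8 for the same stacks, noisy RMSE ≈ 3.1). Note a
quadrature subtlety when comparing *increments*: a method with a large
clean-stack error shows a smaller RMSE increment for the same added
noise, because independent error components add in quadrature — so the
baseline's increment (≈ 1.79) can undercut the selection method's
(≈ 1.90) even though both its absolute noisy error and its noise-induced
component are much larger. Robustness comparisons should therefore be
read on absolute error or on noise-induced components, not on increments.

## Known limitations

- No registration: misaligned stacks produce ghosting; alignment is the
  caller's responsibility.
- Hard selection: no feathering at region boundaries beyond what pyramid
  reconstruction provides; scenes violating the contiguous-focus
  assumption (moving objects, interleaved depths) will show seams.
- No denoising: frame noise is passed through; denoise frames first if
  noise is the limiting factor.
- The seed threshold's strict-majority semantics interacts with disk
  parity (see the checkerboard note); patterns at the pixel period are
  pathological inputs, outside the imaging model.
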