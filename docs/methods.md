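# Methods

This note records the model, the numerical choices, and what the synthetic
phantoms do and do not establish.

## Model and assumptions

The pipeline assumes (i) the target structure's pose relative to each atlas
is approximately a 2-D similarity transform (scale K, rotation θ,
translation), with residual, non-affine anatomical differences that are
small compared to the structure; (ii) intensities within a modality are
linearly related between subjects up to smooth bias — hence NCC as the
similarity measure; (iii) intensities *on* the structure contour follow an
approximately normal, unimodal distribution that is consistent between the
atlas population and the target — this is what makes the histogram prior
informative; and (iv) the structure boundary is smooth at the scale of a
few pixels, so a snake with elastic and bending regularization can
represent it. Processing is slice-wise 2-D; volumes are treated as
independent axial slices and overlap metrics pooled across them.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ncc_threshold` | 0.87 | atlas selection cut on post-registration NCC; if none pass, the top `fallback_k`=3 are used, flagged |
| `patch_size` | 3 px | local window for voting weights |
| `half_width` | 8 px | initial search-window half-width per contour pixel |
| `w_p`, `w_g` | 0.7/0.3 (`ibsr`), 0.6/0.4 (`mrbrains`) | intensity-prior vs gradient weight in the decision score Y |
| `y_threshold` | 0.6 | acceptance cut on Y |
| `n_bins` | 20 | uniform intensity bins of the contour prior on [0,1] |
| `sigma` | 0.5 px | Gaussian smoothing before scoring and for the snake potential |
| `alpha, beta, gamma` | 30/70/70 (`ibsr`), 60/100/100 (`mrbrains`) | snake elasticity, bending, external weights |
| `step_size` | 0.01 | semi-implicit time step, halved automatically on energy increase |
| `tol` | 0.05 px | mean displacement under which (for 10 iterations) evolution stops |
| `binarization_threshold` | 0.5 | fused-probability cut for the initial template (ties → foreground) |

The two profiles bundle the settings appropriate for white-matter
segmentation in low-resolution T1 volumes (`ibsr`) and thalamus
segmentation (`mrbrains`).

## Numerical choices

**Registration.** The optimizer is a 3-level Gaussian pyramid;
phase-correlation initializes translation at the coarsest level, then
Nelder–Mead refines (K, θ, dx, dy) from five rotation starts, and the best
candidate is refined through the finer levels. Rotation/scaling center is
the image center (any fixed center is absorbed by translation). Warping is
inverse-mapped (output-driven) sampling; labels always nearest-neighbor;
out-of-frame samples are background. NCC over a zero-variance image is
defined as 0 so blank slices cannot abort a run. NCC is evaluated over the
target's tissue bounding box (Otsu threshold) so background does not
dominate. The search is fully deterministic.

**Fusion.** Patch NCCs use exact clipped windows at the border (integral
images). Negative patch NCCs are clamped to zero — a negative correlation
is not evidence for a vote. Pixels where every raw weight vanishes fall
back to uniform weights. An exact binarization tie (0.5) is assigned
foreground, erring toward recall, which template optimization can trim.

**Intensity prior.** Contour intensities are sampled bilinearly at subpixel
points on the 0.5 iso-contour of each atlas's class mask — the intensity
*on* the contour — after the same Gaussian smoothing the target receives.
The sampled 20-bin histogram gets one pass of [1, 2, 1]/4 kernel smoothing
(a density estimate; one accidentally empty bin should not zero its
weight). The per-bin relative frequencies and their min–max rescaling
follow the definitions exactly; an all-equal histogram yields an
uninformative prior (all weights 1, deferring to the gradient). For the
snake potential the weights are additionally interpolated linearly between
bin centers, because the binned lookup has zero spatial gradient almost
everywhere and would give the snake no force.

**Scoring.** The Roberts magnitude is `sqrt(Gx² + Gy²)` over the two 2×2
kernels. The gradient is min–max normalized *per search window* (largest
value kept where windows overlap): a weak edge of a small structure is
then scored against its local contrast instead of the strongest edge in
the slice. Acceptance is inclusive (`Y ≥ threshold`). The search-window
value 8 is read as a half-width (17×17 window), configurable.

**Chaining.** Accepted points are rastered, closed with a 3×3 structuring
element (1-px gaps), and hole-filled. An annular accepted band is traced at
its skeleton centerline — the unbiased medial line; tracing the filled
region's outer margin would bias the contour outward by about a pixel.
Solid (satellite-scale) blobs are eroded once before tracing unless erosion
collapses them. Tracing is Moore-neighbor boundary following with
state-recurrence termination. Loops with fewer than 4 points or enclosing
less than 6 px² are discarded; survivors are resampled to uniform arc
length (spacing ≈1.5 px, at least 16 points) and lightly smoothed with a
3-point circular moving average to remove the ±0.5 px quantization of
integer boundary walks.

**Snake.** The external energy enters as −γ·E_img: the potential is large
at edges and modal-intensity pixels, and the curve is *attracted* to high
E_img (minimizing +E_img would repel the contour from the edges it is
meant to find). The bending integrand is read as |v″|². Time stepping is
the standard semi-implicit scheme — internal terms through a cyclic
pentadiagonal system factorized once, external force explicit with
bilinear sampling. A step that would raise the total discrete energy
triggers step halving, so the energy is non-increasing between arc-length
resampling events (every 25 iterations). Loops enclosing less than 20 px²
are passed through unevolved: below the discretization scale the elastic
term would simply collapse them (the same small/thin-structure limitation
the underlying model is known for). Out-of-frame points are clamped and
flagged.

**Rasterization.** A final mask pixel is one whose center is inside a loop
by the even–odd rule or exactly on a loop edge; loops of sub-pixel area
contribute nothing (flagged).

**Metrics.** The Hausdorff distance defaults to boundary pixel sets (the
surface-distance reading consistent with small grid-distance values such
as √2 and 2√2); the full-pixel-set variant is behind a flag. Distances are
in pixels unless a physical spacing is supplied. For volumes, overlap
metrics pool all slices; HD is reported per slice and as the max.

## The phantom generator

Each suite is a bright inner structure with a wavy boundary (six radial
sine bumps, amplitude 5 % of the inner radius) inside a darker elliptical
surround on a dark background, plus two satellite structures of the target
class (radius 2 px) placed 7.5 px outside the wavy boundary — within the
default search half-width. Intensities add a smooth per-subject texture
field (sd 0.05, correlation length 2 px) and are blurred with σ = 1.4 px,
emulating the partial-volume edge width of low-resolution MR; each atlas
further gets a smooth multiplicative bias (±10 %) and additive Gaussian
noise (sd 0.02), and the target independent noise.

Atlases differ from the target by a stored random similarity transform
(|θ| ≤ 15°, K ∈ [0.9, 1.1], shift ≤ 10 px) *and* by small anatomical
variation: decorrelated wave phases, ±40 % wave amplitude, ±2 % axis
lengths, and 2.5 px satellite jitter. The anatomical variation is
essential: it is what makes the fused consensus imperfect — subject-
specific boundary detail and sub-consensus satellites are exactly what
template optimization exists to recover. Two auxiliary configurations turn
parts of this off: `affine_only_config` (no anatomy jitter; each atlas is
an affine-exact warp of the target geometry, so the stored transform is
the true NCC optimum — the right conditions for parameter-recovery
experiments; with anatomy jitter on, the NCC optimum genuinely sits a few
degrees away from the stored transform and sub-degree recovery is not
defined) and `degenerate_config` (additionally no geometric perturbation
and no noise; texture and bias are kept because they are intensity
properties whose spread the histogram prior needs — on a piecewise-
constant image the 20-bin prior collapses to one or two bins and the
accepted contour band fragments, a real property of the method).

What the phantoms do *not* emulate: Rician noise statistics, partial-volume
mixtures of more than two tissues, cortical folding or any thin-sheet
geometry, lesions, and 3-D continuity between slices. Passing tests on
phantoms therefore demonstrates the mechanics and internal consistency of
every stage under the method's stated assumptions — not clinical-grade
accuracy on real MR data.

## Problem sizes used in tests

Phantom suites are 128×128 with 10 atlases (4 for the fast pipeline
tests); the test suite and the acceptance script use 10 suites for
registration recovery, 20 for the template-optimization improvement rate,
and single suites for the end-to-end checks — sizes chosen so the full
validation runs in a few minutes on one CPU while keeping every rate
estimate meaningful.

## Known limitations

- Structures thinner than ~3 px are below the snake's discretization scale
  and are carried by the chained contour alone.
- The decision score is only as good as the contour-intensity prior; if
  the target's intensity distribution shifts relative to the atlas
  population (different scanner normalization), P(x) degrades and the
  gradient term alone must carry the boundary.
- A template that misses a structure entirely by more than the search
  half-width cannot be recovered.
- Registration is 2-D similarity only; strong through-plane rotation or
  shear is outside the model.
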