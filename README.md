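# maacs — multi-atlas active-contour segmentation

`maacs` segments a structure in a 2-D grayscale MR slice using an *atlas
set*: pairs of intensity images and expert-drawn label images from other
subjects. It is written for researchers who want a transparent,
classically-grounded alternative to learning-based segmentation for brain
structures such as white matter or the thalamus, together with a synthetic
phantom generator so every stage can be validated without clinical data.

## Method

Four stages, each available as a standalone module and composed by a
scikit-learn style estimator:

1. **Affine registration** (`maacs.registration`). Each atlas is aligned to
   the target with a similarity transform `p' = K·R(θ)·(p−c) + c + t`,
   maximizing the normalized correlation coefficient

   `NCC(T,F) = Σ(T−T̄)(F−F̄) / sqrt(Σ(T−T̄)² Σ(F−F̄)²)`

   over the tissue bounding box, via a 3-level Gaussian pyramid with
   phase-correlation initialization and Nelder–Mead refinement. Atlases
   with NCC above 0.87 are kept; labels are warped nearest-neighbor.

2. **Local weighted-voting fusion** (`maacs.fusion`). Each pixel's label is
   `S(x) = argmax_c Σᵢ wᵢ(x)·[Mᵢ(x)=c]`, where `wᵢ(x)` is the NCC of the
   3×3 patches of target and warped atlas at `x` (clamped at 0, normalized
   across atlases). Thresholding the foreground probability at 0.5 gives
   the *initial template*.

3. **Template optimization** (`maacs.template`). Around every template
   contour pixel a search window (half-width 8, clipped at neighboring
   contour lines) is scanned; each pixel is scored
   `Y = w_p·P(x) + w_g·grad_norm(x)`, where `P` is a 20-bin histogram prior
   over contour intensities learned from the atlas labels and `grad_norm`
   the locally normalized Roberts gradient. Pixels with `Y ≥ 0.6` are
   chained (Moore-neighbor tracing) into the closed *initial active
   contour* (IAC).

4. **Snake evolution** (`maacs.snake`). The IAC minimizes
   `E = ∮ α/2|v′|² + β/2|v″|² − γ·E_img(v) ds` with the hybrid potential
   `E_img = |∇(G_σ∗I)² + P(x)|`, stepped semi-implicitly with a cyclic
   pentadiagonal solver. The filled final contour is the segmentation.

Evaluation (`maacs.metrics`) provides Dice, Recall, Precision and the
boundary Hausdorff distance; `maacs.phantom` generates brain-like phantom
suites with known ground truth and stored atlas transforms.

## Worked example

```python
from maacs.phantom import PhantomConfig, generate
from maacs.pipeline import MultiAtlasSegmenter

suite = generate(PhantomConfig(seed=0))          # 10 atlases, 128x128
est = MultiAtlasSegmenter(profile="ibsr", target_class=2)
est.fit([a.intensity for a in suite.atlases], [a.label for a in suite.atlases])
res = est.segment(suite.target, reference=suite.truth)
print(f"dice={res.metrics.dice:.4f}  hausdorff={res.metrics.hausdorff:.2f} px")
print(f"atlases kept: {len(res.registrations)}   loops: {len(res.iac.loops)}")
```

prints

```
dice=0.9881  hausdorff=1.00 px
atlases kept: 10   loops: 3
```

i.e. the pipeline recovers 98.8 % (Dice) of the ground-truth structure with
a worst boundary error of one pixel; all 10 atlases passed the NCC cut, and
the final contour has three closed loops — the main wavy structure plus the
two small satellite structures that the fused template alone loses.

The same pipeline runs from the shell:

```bash
maacs simulate --seed 0 --out suite/
maacs segment --target suite/target.txt --atlas-dir suite/atlases \
      --ref suite/truth.txt --class 2 --out run/
maacs evaluate --seg run/slice_000/final_mask.txt --ref suite/truth.txt --class 2
```

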