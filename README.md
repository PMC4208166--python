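# leukoseg

White-blood-cell (leukocyte) segmentation in stained blood-smear microscopy
images, built around k-means pixel clustering in purpose-chosen color
spaces, cluster-wise Reinhard color transfer for stain normalization, and
mathematical morphology — together with the matching evaluation statistics
and a seeded synthetic smear generator so the whole pipeline is testable
without any image database.

## The problem

Differential blood counts need each leukocyte (WBC) separated into its
**nucleus** and **cytoplasm** before classification. In a
Romanowsky-stained smear the nucleus is a dark purple blob and is easy to
find; the cytoplasm is the hard part — its color sits between the pale
background and the pink red cells (RBCs). On top of that, slides imaged in
different sessions carry different color casts, which breaks any method
with fixed color assumptions.

## The method

1. **Color adjustment** (optional, needs a template image). A global
   Reinhard moment transfer in CIELAB removes the bulk cast:
   per channel, `x ↦ (σ_t/σ_s)(x − μ_s) + μ_t`. Then both images are
   3-way k-means partitioned on RGB triples into background / RBC /
   nucleus parts (semantics assigned by centroid luminance), and each
   input part is shifted onto the matching template part's Lab location,
   estimated over the part *core* to resist cross-class contamination.
2. **Nucleus**: 3-way k-means on `[r g b]` rows; the darkest cluster is
   the nucleus mask.
3. **RBC + nucleus**: 2-way k-means on `[b y]` rows (RGB blue channel and
   CMYK yellow-ink channel, in both of which stained cells contrast
   strongly with background while cytoplasm does not); the high-Y cluster
   is foreground. Subtracting the nucleus and dilating slightly yields the
   RBC mask: `I_RBC = I_RBC∪Nucleus − I_Nucleus`.
4. **Whole WBC**: each channel is enhanced as
   `I_enh = I + bothat(I) − tophat(I)` with a disk sized between the RBC
   and WBC radii — this flattens every red cell into the background while
   whole leukocytes survive, isolating the faint cytoplasm. A 3-way
   k-means on the enhanced image separates background from cells; RBCs
   are subtracted and the mask is denoised (opening → component-size
   filter → hole filling → closing).
5. **Cytoplasm**: `wbc − nucleus`.

Evaluation reproduces the statistics used in this literature: detection
precision/recall `A1 = n_correct/n_detected`, `A2 = n_detected/n_truth`
(with `E1 = 1 − A1`, `E2 = 1 − A2`), the boundary Hausdorff distance `D`,
over/under-segmentation rates `OR = |P∖T|/|T|`, `UR = |T∖P|/|T|`,
`ER = OR + UR`, and the relative distance error
`RDE = ½(mean_i d_{e_i}² + mean_j d_{t_j}²)` over boundary pixels.

The k-means engine is written from first principles (it *is* the
segmentation method): greedy D²-seeding, Lloyd iterations with
deterministic tie-breaks, empty-cluster re-seeding, a Hartigan
single-point escape step at convergence, and seeded restarts.

## Worked example

```python
import numpy as np
from leukoseg import SceneSpec, PipelineConfig, generate, run, evaluate_masks, dice

# a synthetic stained smear with a color cast, plus a cast-free template
img, truth = generate(SceneSpec(seed=42, global_cast=(0.06, -0.04, 0.03)))
template, _ = generate(SceneSpec(seed=7))

result = run(img, template, PipelineConfig(seed=0))

print(f"nucleus Dice:   {dice(result.nucleus, truth.nucleus):.3f}")
print(f"WBC Dice:       {dice(result.wbc, truth.wbc):.3f}")
print(f"cytoplasm Dice: {dice(result.cytoplasm, truth.cytoplasm):.3f}")
rep = evaluate_masks(result.wbc, truth.wbc)
print(f"detection: {rep.n_correct}/{rep.n_truth} WBCs (A1={rep.A1:.2f}, A2={rep.A2:.2f})")
print(f"boundary:  Hausdorff D={rep.D:.2f} px, RDE={rep.RDE:.2f}")
print(f"pixels:    OR={rep.OR:.4f}, UR={rep.UR:.4f}, ER={rep.ER:.4f}")
```

prints

```
nucleus Dice:   1.000
WBC Dice:       0.996
cytoplasm Dice: 0.994
detection: 1/1 WBCs (A1=1.00, A2=1.00)
boundary:  Hausdorff D=1.00 px, RDE=0.07
pixels:    OR=0.0000, UR=0.0083, ER=0.0083
```

The nucleus is recovered exactly; the WBC outline misses an 8-px rim
(under-segmentation 0.83% of the cell area), and the worst boundary
disagreement is a single pixel.

A command-line interface mirrors the library:

```bash
leukoseg synth -n 5 --seed 1 --out scenes/          # images + truth masks
leukoseg segment scenes/scene_*.png --template scenes/scene_000.png --out masks/
leukoseg eval masks/ scenes/ --out report.json      # A1 A2 D / OR UR ER RDE
```

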