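# Methods

This note records the model behind `leukoseg`, the parameters that matter,
what the synthetic data does and does not emulate, and the design choices
made where the design was genuinely open.

## Segmentation model and assumptions

The pipeline treats a stained blood-smear image as a mixture of four color
populations — pale background, pink red cells, faint bluish cytoplasm and
dark purple nuclei — and recovers them with per-image k-means clustering
rather than fixed thresholds, so it adapts to the staining of each slide.
Its assumptions:

* every image contains at least one leukocyte, and no artifact larger than
  a leukocyte (violations degrade through the component-size filter, not
  through errors);
* nuclei are the darkest population and background the brightest, by
  luminance (Rec. 601 weights) — true of Romanowsky-type stains;
* red cells are smaller than leukocytes, and both are roughly disk-shaped
  at the scale set by the structuring elements;
* overlapping leukocytes are not separated (out of scope).

The cytoplasm is never clustered directly — its color is too close to
background and red cells. Instead the whole-WBC region is isolated by the
hat-transform enhancement `I + bothat − tophat`: with a disk radius between
the red-cell and leukocyte radii, grayscale closing lifts every dark
structure smaller than the disk (red cells, and the nucleus *within* its
cytoplasm, which closing raises exactly to the surrounding cytoplasm
level) while larger dark structures survive. The enhanced image therefore
contains background plus whole leukocytes only, which a 3-way clustering
separates. The same sign convention means small *bright* structures are
darkened; the classic opposite-sign sharpening is available as
`hat_sign="sharpen"` but is not the default, because the default is what
makes red cells vanish — the property the WBC stage depends on.

### Background identification under k-means

Clusterings of the enhanced image are labelled semantically: background is
bright, cells are dark. When the enhanced image has fewer intrinsic modes
than k, k-means splits the large uniform background along pixel noise; a
rule that takes only the single brightest centroid as background would
then count half the background as cell. The rule used instead is: every
cluster whose centroid luminance is within `bg_luma_margin` of the
brightest centroid is background. The margin (default 0.03) must exceed
the luma gap of a noise-driven background split (≈ 0.016 at the default
noise level, scaling with sensor noise) and stay below the weakest genuine
stained-structure contrast (≈ 0.05 after color adjustment of a strongly
cast image). With three well-separated modes the rule reduces to
"brightest centroid is background".

## Color adjustment

Stain normalization is a two-stage Reinhard-style transfer in CIELAB
(the decorrelated log-LMS lαβ space is selectable):

1. **Global pass** — whole-image population moments of the input are
   mapped onto the template's (`x ↦ (σ_t/σ_s)(x − μ_s) + μ_t` per
   channel). This removes the session-level cast. It also serves a
   structural role: the 3-way partitions that drive the cluster-wise pass
   are computed on normalized colors, so cytoplasm pixels — which sit
   between the background and red-cell populations — contaminate the same
   part in both images, instead of flipping sides under a strong cast.
2. **Cluster-wise pass** — input and template are 3-way partitioned,
   parts are paired semantically (brightest = background, darkest =
   nucleus, remainder = red cells; luminance ties broken by lower blue),
   and each input part is shifted per channel onto the matching template
   part's Lab location. Two estimation choices make this stable:
   * **Part cores.** A part is a k-means cluster and in practice carries a
     few percent of another class. Whole-part moments are mixture moments:
     3% contamination at a 10σ offset doubles the part's σ, and a
     contamination *fraction* that differs between input and template
     shifts the two part means apart — both effects land exactly on the
     faint cytoplasm contrast the downstream stages need. Statistics are
     therefore computed over the part core, the pixels whose distance to
     their own centroid is less than half their distance to the nearest
     other centroid; straddling pixels are excluded symmetrically in both
     images.
   * **Shift-only maps.** Per-part spread ratios are not identifiable:
     even over cores they are dominated by sensor noise and by channels
     squashed against the gamut boundary by a clipped cast (a collapsed
     σ in the denominator can double or halve the offsets of the admixed
     pixels a part carries). Spread matching is left to the global pass,
     where the two images' compositions correspond; the cluster-wise pass
     corrects locations only.

   Consequently the published per-part moment-matching identity holds for
   part-core locations, not for whole-part moments; `transfer` itself (the
   module-level operation) matches moments exactly.

Reunion is hard (each pixel written by the map of its own part, no
feathering) and RGB clipping happens once, after reunion.

**Measured neutrality.** On the synthetic suite the casts are global and
additive, and every segmentation stage is per-image k-means — invariant to
additive color shifts — so the unadjusted pipeline is already cast-proof
there and adjustment has no error-rate benefit to deliver; its hard part
boundaries bisect the straddling cytoplasm cloud and cost a small
under-segmentation on occasional scenes. Across suite seeds the mean
WBC error-rate difference (with − without adjustment) is ±0.003,
statistically a tie with the sign decided by noise, while detection
(A1, A2) ties at 1.0. Real stain variation is class-dependent rather than
a uniform offset, which is where the cluster-wise pass has something real
to correct; the synthetic suite cannot show that benefit.

## k-means

Written from first principles, since the clustering rule is the method:

* greedy D² (k-means++-style) seeding — each new centroid is the best of
  `2 + ln(k+1)` distance-weighted candidates; plain random-row seeding is
  retained as `init="random_points"`;
* Lloyd iterations; assignment ties break to the lowest centroid index;
* an empty cluster is re-seeded at the point farthest from its centroid;
* convergence when the inertia improvement is ≤ `tol` (default 1e-6) or
  at `max_iter` (default 100);
* at each Lloyd fixed point, a Hartigan single-point escape: the exact
  SSE change of moving x from cluster j to l is
  `n_l/(n_l+1)·d(x,μ_l)² − n_j/(n_j−1)·d(x,μ_j)²`, which can be negative
  even when x is nearest μ_j; the best strictly improving move is applied
  and Lloyd resumes (bounded number of escapes). This closes the gap to
  the global optimum on small instances where restarts alone are
  unreliable;
* `n_init` seeded restarts (default 4), best inertia kept; everything is
  a pure function of the seed.

## Structuring elements and size thresholds

All structuring elements are disks; radii are in pixels at a scale where a
red cell spans 12–18 px and a leukocyte 32–45 px (a cropped 100×-objective
field):

| parameter | default | role |
|---|---|---|
| `se_hat_radius` | 12 | hat-transform disk; must lie strictly between red-cell and leukocyte radii (midpoint of the valid window at this scale) |
| `se_open_radius` | 3 | opening that removes speckle before component filtering |
| `se_close_radius` | 5 | closing that bridges narrow gaps after hole filling |
| `se_dilate_radius` | 2 | dilation compensating the clustering's under-sized red cells |
| `min_component_frac` | 0.005 | component-size threshold as a fraction of image area |
| `bg_luma_margin` | 0.03 | background-cluster luminance margin (see above) |
| `k_rgb`, `k_by`, `k_enh` | 3, 2, 3 | cluster counts for the RGB, [B,Y] and enhanced-image clusterings |

Denoising order is opening → 8-connected component-size filter → hole
filling → closing; the size filter is idempotent, and hole filling is what
repairs nucleus-sized holes that the enhancement's closing can punch into
the cell mask when the nucleus sits nearer the cell rim than one disk
radius.

## Synthetic scenes

The generator emulates a well-spread monolayer region of a stained thin
film on a 192×192 canvas: pale lavender background, ~10 pink red-cell
disks (radius 6–9 px), one or two leukocytes drawn as a 1–3-lobed dark
purple nucleus (extent 9–12 px) inside a lighter cytoplasm halo (+7–10 px,
so leukocyte radii are 16–22 px), per-object color jitter (σ = 0.02),
global additive casts (suite scenes draw each channel offset uniformly
from ±0.12; the template is cast-free), and i.i.d. Gaussian pixel noise
(σ = 0.015), clipped to gamut. Cells are placed with a 24-px minimum
edge-to-edge gap — the spacing at which the background between two cells
always admits the hat-transform disk, as in a well-spread smear where
cells are resolvable; leukocytes are drawn on top, so red cells never
occlude a nucleus. Truth masks record the pre-noise geometry.

Deliberately not modelled: optics (blur/PSF — edges are hard), red-cell
central pallor and texture, within-cell color gradients, the five WBC
classes' chromatic differences, touching or overlapping leukocytes, and
class-dependent stain variation. Passing tests therefore show that the
pipeline recovers geometry under color casts, jitter and pixel noise at
realistic scales and class contrasts — not that it handles defocus,
textured cells, or cell overlap.

## Evaluation conventions

* Detection matching is greedy one-to-one on component IoU (default
  threshold 0.5); degenerate ratios are defined (A1 = 1 when nothing was
  detected and nothing existed, 0 when detections were expected; A2
  symmetric).
* `D` is the classical (max–min) Hausdorff distance between 8-connected
  outer boundaries, averaged over a dataset by the aggregator; a
  mean-boundary-distance per image would be the other defensible reading.
* OR/UR/ER use the transparent `|·∖·|/|truth|` family.
* RDE squares the nearest-boundary distances, exactly as the formula
  prints; `squared=False` gives the unsquared variant found elsewhere in
  the literature.
* Aggregation pools detection counts (then recomputes ratios) and
  averages distance/pixel metrics; boundary metrics of empty masks are
  NaN and excluded from means.

## Numerical conventions

8-bit images are normalized by exact division by 255 and written back as
`round(255·x)`. CIELAB uses D65/sRGB; lαβ clamps LMS at 1e-6 before the
log so black pixels stay finite. HSI takes H = 0 on achromatic pixels.
CMYK takes C = M = Y = 0 at K = 1. Transfer with a zero-spread source
channel maps to the constant template mean. Statistics are population
moments (divide by n). All randomness flows from explicit integer seeds;
two runs with the same inputs and seeds are bit-identical.

## Problem sizes

The standard suite is 20 scenes of 192×192 px plus one template; the full
pipeline (with and without adjustment) over the suite completes in about
two minutes on one CPU, and the complete test suite in about the same
again. Small-instance oracles (exhaustive k-means enumeration, O(n²)
boundary-metric checks) run on ≤ 8 points / ≤ 30×30 masks.
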