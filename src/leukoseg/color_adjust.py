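"""Cluster-wise color adjustment.

A global moment transfer over-corrects stained smears because background,
red cells and nuclei occupy very different color regions. The adjustment
therefore clusters both the template and the input into three parts by
k-means on RGB triples, pairs the parts semantically (background = brightest
centroid, nucleus = darkest, red cells = the remaining one), runs the Lab
moment transfer part against part, and reassembles the input from the three
transferred parts. Each pixel is written by exactly one part; RGB clipping
happens once, after reunion.
"""

from __future__ import annotations

import numpy as np

from .clustering import ClusterResult, build_features, kmeans_fit, unflatten
from .color_spaces import lab_to_rgb, rgb_to_lab, validate_rgb
from .color_transfer import LabStats, lab_stats, transfer

__all__ = ["partition3", "label_parts", "adjust", "PART_NAMES"]

PART_NAMES = ("background", "rbc", "nucleus")

# Rec. 601 luma weights, used only to order centroids by brightness.
_LUMA = np.array([0.299, 0.587, 0.114])


def partition3(img: np.ndarray, seed: int = 0) -> tuple[ClusterResult, list[np.ndarray]]:
    """Cluster every pixel into three partitions by k-means on [r g b] rows.

    Returns the fit and three boolean masks that are pairwise disjoint and
    cover the image. Requires at least three distinct pixel colors.
    """
    arr = validate_rgb(img)
    feats = build_features(
        [arr[..., 0], arr[..., 1], arr[..., 2]], channel_names=("R", "G", "B")
    )
    n_distinct = np.unique(feats.rows, axis=0).shape[0]
    if n_distinct < 3:
        raise ValueError(
            f"3-way partition needs ≥ 3 distinct pixel colors, found {n_distinct}"
        )
    cr = kmeans_fit(feats, k=3, seed=seed)
    label_img = unflatten(cr.labels, feats.shape)
    masks = [label_img == j for j in range(3)]
    return cr, masks


def label_parts(cr: ClusterResult) -> dict[str, int]:
    """Assign semantics to the three RGB clusters by centroid brightness.

    Background is the brightest centroid, the nucleus the darkest and the
    red-cell part the remaining one — the usual ordering in a stained smear
    where nuclei take up the most dye. Luminance ties are broken by the
    lower blue-channel value so the mapping is always deterministic.
    """
    if cr.centroids.shape != (3, 3):
        raise ValueError("label_parts expects exactly 3 centroids in RGB")
    luma = cr.centroids @ _LUMA
    order = np.lexsort((cr.centroids[:, 2], luma))  # ascending luma, then blue
    return {"nucleus": int(order[0]), "rbc": int(order[1]), "background": int(order[2])}


def adjust(
    input_img: np.ndarray,
    template_img: np.ndarray,
    seed: int = 0,
    variant: str = "cielab_d65",
) -> np.ndarray:
    """Cluster-wise color transfer of *input_img* toward *template_img*.

    Coarse-to-fine: a global whole-image moment transfer first removes the
    bulk color cast, then both images are 3-way partitioned, parts are
    paired by semantic label, and each input part receives the moment
    transfer computed from its own pixels toward the matching template
    part's Lab statistics.

    The global pre-pass matters for robustness: partitions are computed on
    color-normalized pixels, so the input's parts are contaminated (e.g. by
    cytoplasm pixels, which sit between background and red-cell colors) in
    the same way as the template's. Without it, a strong cast can push the
    contaminating pixels into a *different* part than in the template, and
    the part-wise σ ratios then destroy exactly the faint cytoplasm
    contrast the downstream segmentation needs. When the input already
    matches the template the pre-pass is the identity.
    """
    inp = validate_rgb(input_img)
    tmpl = validate_rgb(template_img)

    lab_raw = rgb_to_lab(inp, variant=variant)
    lab_tm_full = rgb_to_lab(tmpl, variant=variant)
    inp = lab_to_rgb(
        transfer(lab_raw, lab_stats(lab_raw), lab_stats(lab_tm_full)), variant=variant
    )

    cr_in, masks_in = partition3(inp, seed=seed)
    cr_tm, masks_tm = partition3(tmpl, seed=seed)
    sem_in = label_parts(cr_in)
    sem_tm = label_parts(cr_tm)

    lab_in = rgb_to_lab(inp, variant=variant)
    lab_tm = rgb_to_lab(tmpl, variant=variant)

    core_in = _part_cores(inp, cr_in)
    core_tm = _part_cores(tmpl, cr_tm)

    out_lab = np.empty_like(lab_in)
    for name in PART_NAMES:
        j_in = sem_in[name]
        j_tm = sem_tm[name]
        m_in = masks_in[j_in]
        # Statistics come from the part *cores* — pixels much closer to
        # their own centroid than to any other. A part is a k-means
        # cluster and usually carries an admixture of another class
        # (typically cytoplasm, whose color sits between background and
        # red cells); the admixture fraction differs between input and
        # template, so moments over whole parts would mis-shift exactly
        # the faint-contrast pixels the downstream segmentation needs.
        # Straddling pixels are near-equidistant between centroids and are
        # excluded from the cores by construction, in both images alike.
        stats_in = lab_stats(lab_in, core_in[j_in])
        stats_tm = lab_stats(lab_tm, core_tm[j_tm])
        # The part-wise pass aligns locations only (pure per-channel
        # shift); spread matching already happened in the global pre-pass,
        # where the two images' compositions correspond. Part-core spread
        # ratios are dominated by sensor noise and gamut clipping rather
        # than stain spread, and rescaling by them can blow up the offsets
        # of the admixed pixels each part carries.
        stats_tm = LabStats(mean=stats_tm.mean, std=stats_in.std, n=stats_tm.n)
        transferred = transfer(lab_in, stats_in, stats_tm)
        out_lab[m_in] = transferred[m_in]
    return lab_to_rgb(out_lab, variant=variant)


def _part_cores(img: np.ndarray, cr: ClusterResult, ratio: float = 0.5) -> list[np.ndarray]:
    """Core mask per cluster: pixels with d_own < ratio · d_nearest_other.

    Falls back to the full cluster if a core comes out empty (degenerate
    geometry, e.g. two nearly coincident centroids).
    """
    h, w, _ = img.shape
    flat = img.reshape(-1, 3)
    d2 = ((flat[:, None, :] - cr.centroids[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1)
    d_own = np.sqrt(d2[np.arange(flat.shape[0]), order[:, 0]])
    d_second = np.sqrt(d2[np.arange(flat.shape[0]), order[:, 1]])
    core = (d_own < ratio * d_second).reshape(h, w)
    label_img = cr.labels.reshape(h, w)
    cores = []
    for j in range(cr.k):
        m = (label_img == j) & core
        cores.append(m if m.any() else label_img == j)
    return cores
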