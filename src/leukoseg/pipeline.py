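"""The segmentation core: nucleus, red-cell, whole-WBC and cytoplasm masks.

Stages, in running order:

1. optional cluster-wise color adjustment toward a template image;
2. nucleus mask from a 3-way RGB k-means (darkest cluster);
3. joint red-cell + nucleus mask from a 2-way k-means on the [B, Y] pair
   (blue channel and CMYK yellow-ink channel), where stained cells absorb
   blue light and therefore carry a high yellow-ink value;
4. red-cell mask by set difference with the nucleus, then a small dilation
   to compensate for the clustering's tendency to under-size cells;
5. contrast manipulation I + bothat(I) − tophat(I) per channel with a disk
   larger than any red cell: cells smaller than the disk are flattened into
   the background while whole leukocytes survive, isolating the cytoplasm;
6. 3-way k-means on the enhanced image; the non-background clusters form
   the cell mask, red cells are subtracted, and the result is denoised
   (opening → component-size filter → hole filling → closing);
7. cytoplasm = WBC − nucleus.

Every free parameter lives in :class:`PipelineConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as gray_closing, disk, opening as gray_opening

from . import color_adjust
from .clustering import build_features, kmeans_fit, unflatten
from .color_spaces import rgb_to_cmyk, validate_rgb

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "PipelineStageError",
    "segment_nucleus",
    "segment_rbc_nucleus",
    "extract_rbc",
    "enhance",
    "segment_wbc",
    "denoise",
    "extract_cytoplasm",
    "run",
    "composite_labels",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PipelineConfig:
    """All tunable parameters of the segmentation pipeline.

    Structuring elements are disks with radii in pixels, sized for a
    100×-objective scale at which a red cell spans roughly 12–18 px and a
    whole leukocyte 32–45 px. ``se_hat_radius`` must sit strictly between
    the red-cell radius and the leukocyte radius, so that the hat
    transforms in the enhancement step erase red cells but keep whole
    WBCs; the default 12 is the midpoint of that window at this scale
    (a red cell smaller than the disk is flattened into the background,
    a leukocyte larger than it survives).
    """

    seed: int = 0
    k_rgb: int = 3
    k_by: int = 2
    k_enh: int = 3
    se_open_radius: int = 3
    se_close_radius: int = 5
    se_dilate_radius: int = 2
    se_hat_radius: int = 12
    min_component_frac: float = 0.005
    bg_luma_margin: float = 0.03
    apply_color_adjust: bool = True
    lab_variant: str = "cielab_d65"
    hat_sign: str = "smooth"  # "smooth": I + bothat − tophat; "sharpen": opposite
    iou_min: float = 0.5

    def __post_init__(self):
        for name in ("se_open_radius", "se_close_radius", "se_dilate_radius", "se_hat_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if not (0.0 < self.min_component_frac < 1.0):
            raise ValueError("min_component_frac must lie strictly between 0 and 1")
        if self.hat_sign not in ("smooth", "sharpen"):
            raise ValueError("hat_sign must be 'smooth' or 'sharpen'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SegmentationResult:
    """Final masks of one run plus the intermediates that produced them.

    Invariants (checked by :func:`run`): nucleus ⊆ wbc, cytoplasm =
    wbc − nucleus, cytoplasm ∩ nucleus = ∅.
    """

    nucleus: np.ndarray
    wbc: np.ndarray
    cytoplasm: np.ndarray
    rbc: np.ndarray
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _check_same_shape(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: mask shapes differ ({a.shape} vs {b.shape})")


def segment_nucleus(img: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Nucleus mask: darkest of the three RGB k-means clusters."""
    cr, masks = color_adjust.partition3(validate_rgb(img), seed=cfg.seed)
    sem = color_adjust.label_parts(cr)
    return masks[sem["nucleus"]]


def segment_rbc_nucleus(img: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Joint red-cell + nucleus mask from 2-way k-means on [B, Y] features.

    B is the RGB blue channel and Y the CMYK yellow-ink channel; both give
    strong contrast between stained cells and the pale background whereas
    the cytoplasm stays close to background. The foreground is the cluster
    whose centroid has the larger Y component.
    """
    arr = validate_rgb(img)
    y = rgb_to_cmyk(arr)[..., 2]
    feats = build_features([arr[..., 2], y], channel_names=("B", "Y"))
    cr = kmeans_fit(feats, k=cfg.k_by, seed=cfg.seed)
    fg = int(np.argmax(cr.centroids[:, 1]))
    return unflatten(cr.labels, feats.shape) == fg


def extract_rbc(rbc_nucleus: np.ndarray, nucleus: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Red-cell mask: (rbc∪nucleus) − nucleus, then dilation by a small disk."""
    rn = np.asarray(rbc_nucleus, dtype=bool)
    nu = np.asarray(nucleus, dtype=bool)
    _check_same_shape(rn, nu, "extract_rbc")
    diff = rn & ~nu
    if not diff.any():
        return diff
    return ndimage.binary_dilation(diff, structure=disk(cfg.se_dilate_radius))


def enhance(img: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Contrast manipulation I + bothat(I) − tophat(I), per channel, clipped.

    bothat = closing − I responds to dark structures smaller than the disk,
    tophat = I − opening to small bright ones. With a disk radius between
    the red-cell and leukocyte radii this flattens red cells into the
    background while leaving whole leukocytes (including the cytoplasm,
    whose contrast against background is otherwise too weak to cluster)
    intact. ``hat_sign="sharpen"`` selects the opposite sign convention, the
    traditional extreme-sharpening form I + tophat − bothat.
    """
    arr = validate_rgb(img)
    se = disk(cfg.se_hat_radius)
    out = np.empty_like(arr)
    for c in range(3):
        chan = arr[..., c]
        tophat = chan - gray_opening(chan, se)
        bothat = gray_closing(chan, se) - chan
        if cfg.hat_sign == "smooth":
            out[..., c] = chan + bothat - tophat
        else:
            out[..., c] = chan + tophat - bothat
    return np.clip(out, 0.0, 1.0)


def denoise(mask: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Clean a binary mask: opening, size filter, hole filling, closing.

    The component-size threshold is ``min_component_frac`` of the image
    area; 8-connected components below it are dropped.
    """
    m = np.asarray(mask, dtype=bool)
    m = gray_opening(m, disk(cfg.se_open_radius))
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n:
        threshold = cfg.min_component_frac * m.shape[0] * m.shape[1]
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= threshold) + 1
        m = np.isin(labels, keep)
    m = ndimage.binary_fill_holes(m)
    m = gray_closing(m, disk(cfg.se_close_radius))
    return m


def segment_wbc(
    img: np.ndarray, nucleus: np.ndarray, rbc: np.ndarray, cfg: PipelineConfig
) -> np.ndarray:
    """Whole-WBC mask from clustering the enhanced image.

    The enhanced image is clustered with k = ``k_enh``; every cluster whose
    centroid luminance comes within ``bg_luma_margin`` of the brightest
    centroid counts as background, and the cell mask is the complement.
    Folding near-brightest clusters into the background makes the rule
    robust to k-means splitting a large uniform background by noise alone,
    while genuinely stained structures sit far darker than the margin. Red
    cells are subtracted, the mask is denoised, and the nucleus is united
    back in so the containment invariant nucleus ⊆ wbc always holds.
    """
    arr = validate_rgb(img)
    nu = np.asarray(nucleus, dtype=bool)
    rb = np.asarray(rbc, dtype=bool)
    _check_same_shape(nu, arr[..., 0], "segment_wbc: nucleus vs image")
    _check_same_shape(rb, arr[..., 0], "segment_wbc: rbc vs image")

    enhanced = enhance(arr, cfg)
    feats = build_features(
        [enhanced[..., 0], enhanced[..., 1], enhanced[..., 2]],
        channel_names=("R", "G", "B"),
    )
    cr = kmeans_fit(feats, k=cfg.k_enh, seed=cfg.seed)
    luma = cr.centroids @ _LUMA
    is_bg = luma >= luma.max() - cfg.bg_luma_margin
    cells = ~is_bg[unflatten(cr.labels, feats.shape)]
    wbc_raw = cells & ~rb
    wbc = denoise(wbc_raw, cfg)
    return wbc | nu


def extract_cytoplasm(wbc: np.ndarray, nucleus: np.ndarray) -> np.ndarray:
    """Cytoplasm mask: wbc − nucleus."""
    w = np.asarray(wbc, dtype=bool)
    n = np.asarray(nucleus, dtype=bool)
    _check_same_shape(w, n, "extract_cytoplasm")
    return w & ~n


def run(
    img: np.ndarray,
    template: np.ndarray | None = None,
    cfg: PipelineConfig | None = None,
) -> SegmentationResult:
    """Run the full pipeline on one image.

    With ``template=None`` color adjustment is skipped regardless of
    ``cfg.apply_color_adjust``. Intermediate masks are recorded under the
    stage names for debugging; any stage failure is re-raised tagged with
    the stage in which it occurred.
    """
    cfg = cfg or PipelineConfig()
    arr = validate_rgb(img)
    intermediates: dict[str, np.ndarray] = {}

    work = arr
    if cfg.apply_color_adjust and template is not None:
        try:
            work = color_adjust.adjust(
                arr, validate_rgb(template), seed=cfg.seed, variant=cfg.lab_variant
            )
        except Exception as exc:  # noqa: BLE001 - tag with stage and re-raise
            raise PipelineStageError("color_adjust", exc) from exc
        intermediates["adjusted"] = work

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(name, exc) from exc

    nucleus = _stage("segment_nucleus", segment_nucleus, work, cfg)
    intermediates["nucleus_raw"] = nucleus
    rbc_nucleus = _stage("segment_rbc_nucleus", segment_rbc_nucleus, work, cfg)
    intermediates["rbc_nucleus"] = rbc_nucleus
    rbc = _stage("extract_rbc", extract_rbc, rbc_nucleus, nucleus, cfg)
    intermediates["rbc"] = rbc
    wbc = _stage("segment_wbc", segment_wbc, work, nucleus, rbc, cfg)
    cytoplasm = _stage("extract_cytoplasm", extract_cytoplasm, wbc, nucleus)

    result = SegmentationResult(
        nucleus=nucleus, wbc=wbc, cytoplasm=cytoplasm, rbc=rbc, intermediates=intermediates
    )
    assert not (result.nucleus & ~result.wbc).any()
    assert not (result.cytoplasm & result.nucleus).any()
    return result


def composite_labels(result: SegmentationResult) -> np.ndarray:
    """4-level visualization raster: background/rbc/cytoplasm/nucleus = 0/85/170/255."""
    out = np.zeros(result.nucleus.shape, dtype=np.uint8)
    out[result.rbc] = 85
    out[result.cytoplasm] = 170
    out[result.nucleus] = 255
    return out
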