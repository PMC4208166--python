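"""Evaluation statistics for mask-versus-ground-truth comparison.

Object-level detection: predicted and true masks are decomposed into
8-connected components; a predicted component counts as a correct detection
when its best intersection-over-union with a still-unmatched true component
reaches a threshold (default 0.5). From the counts,

* A1 = correctly detected / total detected (precision),
* A2 = total detected / total true cells (recall),
* E1 = 1 − A1 (false-detection ratio), E2 = 1 − A2 (leak-detection ratio).

Boundary-level: the classical Hausdorff distance D between the outer
boundaries, and the relative distance error RDE — the symmetric mean of
squared nearest-neighbour distances between the two boundary point sets.

Pixel-level: over-segmentation rate OR = |pred∖truth|/|truth|,
under-segmentation rate UR = |truth∖pred|/|truth|, ER = OR + UR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "EvalReport",
    "boundary_points",
    "match_detections",
    "detection_ratios",
    "hausdorff",
    "pixel_rates",
    "rde",
    "dice",
    "evaluate_masks",
    "aggregate",
]

_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class EvalReport:
    """Detection, boundary and pixel statistics for one image (or a pool)."""

    A1: float
    A2: float
    E1: float
    E2: float
    D: float
    OR: float
    UR: float
    ER: float
    RDE: float
    n_detected: int
    n_correct: int
    n_truth: int

    def to_dict(self) -> dict:
        return {
            "A1": self.A1, "A2": self.A2, "E1": self.E1, "E2": self.E2,
            "D": self.D, "OR": self.OR, "UR": self.UR, "ER": self.ER,
            "RDE": self.RDE, "n_detected": self.n_detected,
            "n_correct": self.n_correct, "n_truth": self.n_truth,
        }


def _as_mask(m: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(m)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D mask")
    return arr.astype(bool)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of the mask's 8-connected outer boundary.

    A boundary pixel is a foreground pixel with at least one background
    pixel among its 8 neighbours (image borders count as background).
    """
    m = _as_mask(mask, "mask")
    if not m.any():
        raise ValueError("boundary of an empty mask is undefined")
    interior = ndimage.binary_erosion(m, structure=_STRUCT8, border_value=0)
    return np.argwhere(m & ~interior)


def match_detections(
    pred: np.ndarray, truth: np.ndarray, iou_min: float = 0.5
) -> tuple[int, int, int]:
    """Count (n_detected, n_correct, n_truth) components under greedy IoU matching.

    Components are 8-connected. Pairs are matched one-to-one in descending
    IoU; a predicted component is correct when its matched IoU ≥ *iou_min*.
    """
    p = _as_mask(pred, "pred")
    t = _as_mask(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    lab_p, n_p = ndimage.label(p, structure=_STRUCT8)
    lab_t, n_t = ndimage.label(t, structure=_STRUCT8)
    if n_p == 0 or n_t == 0:
        return n_p, 0, n_t

    pairs = []
    for i in range(1, n_p + 1):
        comp_p = lab_p == i
        area_p = int(comp_p.sum())
        overlapping = np.unique(lab_t[comp_p])
        for j in overlapping:
            if j == 0:
                continue
            comp_t = lab_t == j
            inter = int((comp_p & comp_t).sum())
            union = area_p + int(comp_t.sum()) - inter
            pairs.append((inter / union, i, int(j)))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))

    used_p: set[int] = set()
    used_t: set[int] = set()
    n_correct = 0
    for iou, i, j in pairs:
        if iou < iou_min:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        n_correct += 1
    return n_p, n_correct, n_t


def detection_ratios(
    n_detected: int, n_correct: int, n_truth: int
) -> tuple[float, float, float, float]:
    """(A1, A2, E1, E2) from detection counts, with degenerate cases defined.

    A1 = n_correct/n_detected; when nothing was detected, A1 is 1 if there
    was also nothing to detect and 0 otherwise. A2 = n_detected/n_truth,
    defined 1 when both counts are zero.
    """
    if min(n_detected, n_correct, n_truth) < 0:
        raise ValueError("counts must be non-negative")
    if n_detected > 0:
        a1 = n_correct / n_detected
    else:
        a1 = 1.0 if n_truth == 0 else 0.0
    if n_truth > 0:
        a2 = n_detected / n_truth
    else:
        a2 = 1.0 if n_detected == 0 else 0.0
    return a1, a2, 1.0 - a1, 1.0 - a2


def hausdorff(pred: np.ndarray, truth: np.ndarray) -> float:
    """Classical Hausdorff distance (pixels) between the two outer boundaries.

    max over both directions of the farthest nearest-neighbour Euclidean
    distance. Both masks must be non-empty.
    """
    bp = boundary_points(pred).astype(float)
    bt = boundary_points(truth).astype(float)
    d_pt = cKDTree(bt).query(bp)[0].max()
    d_tp = cKDTree(bp).query(bt)[0].max()
    return float(max(d_pt, d_tp))


def pixel_rates(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(OR, UR, ER): over-/under-segmentation and total pixel error rates."""
    p = _as_mask(pred, "pred")
    t = _as_mask(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    n_truth = int(t.sum())
    if n_truth == 0:
        raise ValueError("pixel rates are undefined for an empty ground truth")
    over = int((p & ~t).sum()) / n_truth
    under = int((t & ~p).sum()) / n_truth
    return over, under, over + under


def rde(pred: np.ndarray, truth: np.ndarray, squared: bool = True) -> float:
    """Relative distance error between the two outer boundaries.

    ½·[ mean over predicted-boundary pixels of d² + mean over true-boundary
    pixels of d² ], d being the nearest-neighbour Euclidean distance to the
    other boundary. ``squared=False`` uses plain distances instead.
    """
    bp = boundary_points(pred).astype(float)
    bt = boundary_points(truth).astype(float)
    d_e = cKDTree(bt).query(bp)[0]
    d_t = cKDTree(bp).query(bt)[0]
    if squared:
        d_e, d_t = d_e**2, d_t**2
    return float(0.5 * (d_e.mean() + d_t.mean()))


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); defined 1.0 when both masks are empty."""
    p = _as_mask(pred, "pred")
    t = _as_mask(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    total = int(p.sum()) + int(t.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / total


def evaluate_masks(pred: np.ndarray, truth: np.ndarray, iou_min: float = 0.5) -> EvalReport:
    """Full per-image report comparing a predicted mask with the ground truth.

    Boundary metrics (D, RDE) are reported as NaN when either mask is
    empty, since boundaries are undefined there.
    """
    n_det, n_cor, n_tru = match_detections(pred, truth, iou_min=iou_min)
    a1, a2, e1, e2 = detection_ratios(n_det, n_cor, n_tru)
    over, under, err = pixel_rates(pred, truth)
    p_any = bool(np.asarray(pred).any())
    t_any = bool(np.asarray(truth).any())
    if p_any and t_any:
        d = hausdorff(pred, truth)
        r = rde(pred, truth)
    else:
        d = float("nan")
        r = float("nan")
    return EvalReport(
        A1=a1, A2=a2, E1=e1, E2=e2, D=d, OR=over, UR=under, ER=err, RDE=r,
        n_detected=n_det, n_correct=n_cor, n_truth=n_tru,
    )


def aggregate(reports: list[EvalReport]) -> EvalReport:
    """Pool a list of per-image reports into one dataset-level report.

    Detection counts are summed and the ratios recomputed from the pooled
    counts; distance and pixel-rate metrics are arithmetic means (NaN
    boundary metrics are excluded from their means).
    """
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    n_det = sum(r.n_detected for r in reports)
    n_cor = sum(r.n_correct for r in reports)
    n_tru = sum(r.n_truth for r in reports)
    a1, a2, e1, e2 = detection_ratios(n_det, n_cor, n_tru)

    def _nanmean(values):
        vals = [v for v in values if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return EvalReport(
        A1=a1, A2=a2, E1=e1, E2=e2,
        D=_nanmean(r.D for r in reports),
        OR=float(np.mean([r.OR for r in reports])),
        UR=float(np.mean([r.UR for r in reports])),
        ER=float(np.mean([r.ER for r in reports])),
        RDE=_nanmean(r.RDE for r in reports),
        n_detected=n_det, n_correct=n_cor, n_truth=n_tru,
    )
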