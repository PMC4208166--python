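"""Reinhard-style color transfer by moment matching in Lab space.

Stain normalization step: the per-channel mean is subtracted from the input,
each channel is scaled by the ratio of the template's standard deviation to
the input's, and the template mean is added back. After the transfer the
input's per-channel Lab statistics equal the template's, which removes
global color casts between acquisition sessions.

Statistics are population moments (divide by n); at image scale the
distinction from sample moments is immaterial but fixing it keeps tests
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LabStats", "lab_stats", "transfer"]


@dataclass(frozen=True)
class LabStats:
    """Per-channel mean and population standard deviation over n pixels."""

    mean: np.ndarray
    std: np.ndarray
    n: int

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=np.float64))
        if self.mean.shape != (3,) or self.std.shape != (3,):
            raise ValueError("mean and std must be 3-vectors")
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")
        if self.n < 1:
            raise ValueError("statistics need at least one pixel")


def lab_stats(
    img: np.ndarray, mask: np.ndarray | None = None, robust: bool = False
) -> LabStats:
    """Per-channel mean and spread of a Lab image, optionally masked.

    With ``robust=False`` (default): mean and population standard
    deviation. With ``robust=True``: per channel, the spread is the
    normal-consistent median absolute deviation (MAD × 1.4826) and the
    location is the mean of the samples within 2.5 MAD of the median.
    Both ignore a contaminating subpopulation of up to ~half the pixels —
    useful when the pixels come from a k-means part that carries an
    admixture of another class (a few percent of such outliers can double
    the plain σ, and an admixture whose fraction differs between two
    images shifts their plain means apart). For a clean unimodal part the
    robust and plain estimates agree closely. Channels whose MAD is zero
    (e.g. clipped against the gamut boundary) fall back to the plain
    mean and σ.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) Lab image, got shape {arr.shape}")
    if mask is None:
        pixels = arr.reshape(-1, 3)
    else:
        m = np.asarray(mask, dtype=bool)
        if m.shape != arr.shape[:2]:
            raise ValueError(
                f"mask shape {m.shape} does not match image shape {arr.shape[:2]}"
            )
        if not m.any():
            raise ValueError("mask selects no pixels")
        pixels = arr[m]
    if robust:
        med = np.median(pixels, axis=0)
        dev = np.abs(pixels - med)
        mad = np.median(dev, axis=0)
        std = 1.4826 * mad
        loc = np.empty(3)
        for c in range(3):
            if mad[c] == 0.0:
                std[c] = pixels[:, c].std()
                loc[c] = pixels[:, c].mean()
            else:
                keep = dev[:, c] <= 2.5 * mad[c]
                loc[c] = pixels[keep, c].mean()
    else:
        loc = pixels.mean(axis=0)
        std = pixels.std(axis=0)
    return LabStats(mean=loc, std=std, n=pixels.shape[0])


def transfer(input_lab: np.ndarray, src: LabStats, tmpl: LabStats) -> np.ndarray:
    """Map each channel x → (σ_t/σ_s)·(x − mean_s) + mean_t.

    When a source channel is constant (σ_s = 0) the scale is undefined; the
    limit convention maps the whole channel to the template mean.
    """
    arr = np.asarray(input_lab, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) Lab image, got shape {arr.shape}")
    scale = np.where(src.std > 0.0, tmpl.std / np.where(src.std > 0.0, src.std, 1.0), 0.0)
    return (arr - src.mean) * scale + tmpl.mean
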