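"""Color-space conversions used by the segmentation pipeline.

Images are plain ``numpy`` arrays. An RGB image is an ``(H, W, 3)`` float
array with every channel in ``[0, 1]`` (8-bit files are divided by 255 on
load). Converters are per-pixel pure functions; none of them mutates its
input.

Four representations are supported:

* **CIELAB** (D65 white point, sRGB primaries) — the space in which the
  Reinhard-style moment matching of :mod:`leukoseg.color_transfer` runs by
  default. The decorrelated log-LMS *lαβ* space of the original color-transfer
  literature is available as an alternative variant.
* **CMYK** — subtractive printing inks; the yellow-ink channel Y gives strong
  contrast between stained cells (which absorb blue light) and the pale
  background, and feeds the red-cell/nucleus clustering step.
* **HSI** — hue/saturation/intensity under the classical arccos hue formula.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.color import lab2rgb, rgb2lab

__all__ = [
    "validate_rgb",
    "rgb_to_lab",
    "lab_to_rgb",
    "rgb_to_cmyk",
    "rgb_to_hsi",
    "read_rgb",
    "write_rgb",
    "write_mask",
    "LAB_VARIANTS",
]

LAB_VARIANTS = ("cielab_d65", "reinhard_lalphabeta")

# Ruderman RGB->LMS matrix and the lαβ decorrelation transform used by the
# classical color-transfer algorithm. Log is taken base 10 on LMS clamped
# away from zero so that black pixels stay finite.
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LMS2LAB = (
    np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)])
    @ np.array([[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float)
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)
_LMS_FLOOR = 1e-6


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that *img* is an (H, W, 3) float image in [0, 1]; return float64 view."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("RGB values must lie in [0, 1]; normalize 8-bit data by 255")
    return arr


def rgb_to_lab(img: np.ndarray, variant: str = "cielab_d65") -> np.ndarray:
    """Convert an RGB image to a lightness/opponent-chroma space.

    Parameters
    ----------
    img:
        (H, W, 3) RGB array in [0, 1].
    variant:
        ``"cielab_d65"`` for CIELAB under D65 (default), or
        ``"reinhard_lalphabeta"`` for the decorrelated log-LMS lαβ space.
    """
    arr = validate_rgb(img)
    if variant == "cielab_d65":
        return rgb2lab(arr)
    if variant == "reinhard_lalphabeta":
        lms = arr @ _RGB2LMS.T
        log_lms = np.log10(np.maximum(lms, _LMS_FLOOR))
        return log_lms @ _LMS2LAB.T
    raise ValueError(f"unknown Lab variant {variant!r}; choose from {LAB_VARIANTS}")


def lab_to_rgb(img: np.ndarray, variant: str = "cielab_d65") -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`; out-of-gamut results are clipped to [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) Lab image, got shape {arr.shape}")
    if variant == "cielab_d65":
        with warnings.catch_warnings():
            # lab2rgb warns on out-of-gamut triples; the contract is to clip.
            warnings.simplefilter("ignore")
            rgb = lab2rgb(arr)
        return np.clip(rgb, 0.0, 1.0)
    if variant == "reinhard_lalphabeta":
        lms = np.power(10.0, arr @ _LAB2LMS.T)
        return np.clip(lms @ _LMS2RGB.T, 0.0, 1.0)
    raise ValueError(f"unknown Lab variant {variant!r}; choose from {LAB_VARIANTS}")


def rgb_to_cmyk(img: np.ndarray) -> np.ndarray:
    """Convert RGB to CMYK.

    K = 1 − max(R, G, B); C = (1 − R − K)/(1 − K) and likewise M, Y.
    Pure black (K = 1) uses the convention C = M = Y = 0.
    """
    arr = validate_rgb(img)
    k = 1.0 - arr.max(axis=2)
    denom = 1.0 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        cmy = (1.0 - arr - k[..., None]) / denom[..., None]
    cmy[denom == 0.0] = 0.0
    out = np.concatenate([cmy, k[..., None]], axis=2)
    return np.clip(out, 0.0, 1.0)


def rgb_to_hsi(img: np.ndarray) -> np.ndarray:
    """Convert RGB to HSI: H in degrees [0, 360), S and I in [0, 1].

    I = (R+G+B)/3, S = 1 − min(R,G,B)/I, and H from the arccos formulation.
    Achromatic pixels (S = 0, including I = 0) take H = 0 by convention.
    """
    arr = validate_rgb(img)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    intensity = arr.mean(axis=2)
    minimum = arr.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = 1.0 - minimum / intensity
    sat[intensity == 0.0] = 0.0
    sat = np.clip(sat, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(num / den, -1.0, 1.0)))
    hue = np.where(b <= g, theta, 360.0 - theta)
    hue = np.where(sat == 0.0, 0.0, hue)
    hue = np.where(hue == 360.0, 0.0, hue)
    return np.stack([hue, sat, intensity], axis=2)


# ---------------------------------------------------------------------------
# File I/O: 8-bit PNG/TIFF/JPEG readers and writers.
# ---------------------------------------------------------------------------

def read_rgb(path) -> np.ndarray:
    """Read an 8-bit RGB image file and normalize to [0, 1] floats.

    Grayscale files are rejected: the pipeline is color-based and a silent
    channel replication would hide an input mistake. An alpha channel, if
    present, is dropped.
    """
    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 2:
        raise ValueError(
            f"{path}: grayscale image; the pipeline needs 3-channel RGB input"
        )
    if raw.ndim != 3 or raw.shape[2] not in (3, 4):
        raise ValueError(f"{path}: unsupported image shape {raw.shape}")
    rgb = raw[..., :3]
    if rgb.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit data, got dtype {rgb.dtype}")
    return rgb.astype(np.float64) / 255.0


def write_rgb(path, img: np.ndarray) -> None:
    """Write a [0, 1] float RGB image as an 8-bit file (round(255·x))."""
    import imageio.v3 as iio

    arr = validate_rgb(img)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    arr = np.asarray(mask, dtype=bool)
    iio.imwrite(path, (arr.astype(np.uint8) * 255))
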