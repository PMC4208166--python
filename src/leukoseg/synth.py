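"""Seeded synthetic blood-smear generator with perfect ground truth.

No public dataset accompanies the method, so every pipeline stage and every
metric is exercised on generated scenes: a pale near-uniform background,
pink red-cell disks, and one or more leukocytes drawn as a dark purple
nucleus (one to three overlapping lobes, emulating neutrophil morphology)
inside a lighter cytoplasm halo whose color sits close to the background —
the property that makes cytoplasm segmentation hard in real smears. Global
color casts emulate session-to-session illumination drift; per-object color
jitter and i.i.d. Gaussian pixel noise emulate staining variability and
sensor noise. Optics (blur, point-spread) are deliberately not modelled.

Scales are chosen for a 100×-objective crop: red cells span 12–18 px,
whole leukocytes 32–44 px, on a 192×192 canvas. Cells are placed with a
generous mutual gap, as in a well-spread monolayer region of a thin film,
so that scenes contain well-separated cells (the method itself ignores
overlapping leukocytes).

Ground-truth masks record the pre-noise geometry and satisfy the
segmentation-result invariants by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import SegmentationResult

__all__ = ["SceneSpec", "generate", "default_suite", "DEFAULT_COLORS"]

# Romanowsky-type staining palette: pale lavender background, pink RBCs,
# pale blue-lilac cytoplasm (close to background by design), dark purple
# chromatin.
DEFAULT_COLORS: dict[str, tuple[float, float, float]] = {
    "background": (0.93, 0.91, 0.95),
    "rbc": (0.90, 0.70, 0.72),
    "cytoplasm": (0.80, 0.77, 0.90),
    "nucleus": (0.36, 0.25, 0.52),
}

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; ``seed`` makes it fully reproducible."""

    height: int = 192
    width: int = 192
    n_rbc: int = 10
    rbc_radius_range: tuple[int, int] = (6, 9)
    n_wbc: int = 1
    nucleus_radius_range: tuple[int, int] = (9, 12)
    cytoplasm_halo_range: tuple[int, int] = (7, 10)
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    color_jitter_std: float = 0.02
    noise_std: float = 0.015
    global_cast: tuple[float, float, float] = (0.0, 0.0, 0.0)
    min_gap: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("scene must be at least 32×32 pixels")
        for name in ("rbc_radius_range", "nucleus_radius_range", "cytoplasm_halo_range"):
            lo, hi = getattr(self, name)
            if lo < 2 or hi < lo:
                raise ValueError(f"{name} must satisfy 2 ≤ lo ≤ hi")
        if self.cytoplasm_halo_range[0] <= 0:
            raise ValueError("cytoplasm halo must be positive so cytoplasm is non-empty")
        if self.n_wbc < 0 or self.n_rbc < 0:
            raise ValueError("object counts must be non-negative")
        required = {"background", "rbc", "cytoplasm", "nucleus"}
        if set(self.colors) != required:
            raise ValueError(f"colors must define exactly {sorted(required)}")
        cols = {k: np.asarray(v, dtype=float) for k, v in self.colors.items()}
        triples = [tuple(v) for v in cols.values()]
        if len(set(triples)) != 4:
            raise ValueError("the four class colors must be pairwise distinct")
        luma = {k: float(v @ _LUMA) for k, v in cols.items()}
        if luma["nucleus"] >= min(luma[k] for k in ("background", "rbc", "cytoplasm")):
            raise ValueError("nucleus must be the darkest class by luminance")
        if luma["background"] <= max(luma[k] for k in ("rbc", "cytoplasm", "nucleus")):
            raise ValueError("background must be the brightest class by luminance")


def _disk_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _place(
    rng: np.random.Generator,
    placed: list[tuple[float, float, float]],
    radius: float,
    h: int,
    w: int,
    min_gap: float,
    attempts: int = 2000,
):
    """Rejection-sample a center keeping the disk inside the frame and away
    from every previously placed disk by at least ``min_gap`` edge-to-edge."""
    margin = radius + 2.0
    if 2 * margin >= min(h, w):
        raise ValueError("object too large for the scene")
    for _ in range(attempts):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ok = all(
            np.hypot(cy - py, cx - px) >= radius + pr + min_gap
            for py, px, pr in placed
        )
        if ok:
            placed.append((cy, cx, radius))
            return cy, cx
    raise RuntimeError(
        "could not place all objects; reduce counts, radii or min_gap"
    )


def generate(spec: SceneSpec) -> tuple[np.ndarray, SegmentationResult]:
    """Render one scene; returns the noisy RGB image and its ground truth.

    Leukocytes are placed first, then red cells; leukocytes are drawn on
    top, so red cells never occlude a nucleus. Object placement is retried
    from scratch a bounded number of times before raising.
    """
    h, w = spec.height, spec.width
    for restart in range(20):
        rng = np.random.default_rng((spec.seed, restart))
        try:
            return _render(spec, rng, h, w)
        except RuntimeError:
            continue
    raise RuntimeError(
        f"infeasible scene spec: could not place {spec.n_wbc} WBCs and "
        f"{spec.n_rbc} RBCs with min_gap={spec.min_gap} on {h}×{w}"
    )


def _render(spec: SceneSpec, rng: np.random.Generator, h: int, w: int):
    colors = {k: np.asarray(v, dtype=float) for k, v in spec.colors.items()}
    img = np.ones((h, w, 3)) * colors["background"]
    nucleus_mask = np.zeros((h, w), dtype=bool)
    wbc_mask = np.zeros((h, w), dtype=bool)
    rbc_mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []

    def jitter(base: np.ndarray) -> np.ndarray:
        return np.clip(base + rng.normal(0.0, spec.color_jitter_std, size=3), 0.0, 1.0)

    wbcs = []
    for _ in range(spec.n_wbc):
        extent = rng.uniform(*spec.nucleus_radius_range)
        halo = rng.uniform(*spec.cytoplasm_halo_range)
        r_cyt = extent + halo
        cy, cx = _place(rng, placed, r_cyt, h, w, spec.min_gap)
        n_lobes = int(rng.integers(1, 4))
        lobes = []
        if n_lobes == 1:
            lobes.append((cy, cx, extent))
        else:
            lobes.append((cy, cx, 0.8 * extent))
            for _ in range(n_lobes - 1):
                r_l = rng.uniform(0.5, 0.65) * extent
                ang = rng.uniform(0.0, 2 * np.pi)
                off = extent - r_l  # lobe stays inside the nuclear extent
                lobes.append((cy + off * np.sin(ang), cx + off * np.cos(ang), r_l))
        wbcs.append((cy, cx, r_cyt, lobes))

    rbcs = []
    for _ in range(spec.n_rbc):
        r = rng.uniform(*spec.rbc_radius_range)
        cy, cx = _place(rng, placed, r, h, w, spec.min_gap)
        rbcs.append((cy, cx, r))

    # Paint order: RBCs first, WBCs on top.
    for cy, cx, r in rbcs:
        m = _disk_mask(h, w, cy, cx, r)
        img[m] = jitter(colors["rbc"])
        rbc_mask |= m
    for cy, cx, r_cyt, lobes in wbcs:
        cyt = _disk_mask(h, w, cy, cx, r_cyt)
        img[cyt] = jitter(colors["cytoplasm"])
        nuc = np.zeros((h, w), dtype=bool)
        for ly, lx, lr in lobes:
            nuc |= _disk_mask(h, w, ly, lx, lr)
        img[nuc] = jitter(colors["nucleus"])
        wbc_mask |= cyt
        nucleus_mask |= nuc
    rbc_mask &= ~wbc_mask  # leukocytes are drawn on top

    img = img + np.asarray(spec.global_cast, dtype=float)
    img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = SegmentationResult(
        nucleus=nucleus_mask,
        wbc=wbc_mask,
        cytoplasm=wbc_mask & ~nucleus_mask,
        rbc=rbc_mask,
    )
    return img, truth


def default_suite(
    n_scenes: int, seed: int = 0
) -> list[tuple[np.ndarray, SegmentationResult, np.ndarray]]:
    """Generate the standard evaluation suite.

    ``n_scenes`` scenes with per-scene random global casts (uniform in
    ±0.12 per channel), varied seeds, and occasionally two leukocytes; one
    cast-free template image is shared by all scenes and returned alongside
    each of them. The whole suite is a pure function of ``seed``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be ≥ 1")
    rng = np.random.default_rng(seed)
    template_spec = SceneSpec(seed=int(rng.integers(2**31)))
    template_img, _ = generate(template_spec)
    suite = []
    for _ in range(n_scenes):
        cast = tuple(rng.uniform(-0.12, 0.12, size=3))
        n_wbc = 2 if rng.random() < 0.25 else 1
        spec = SceneSpec(
            seed=int(rng.integers(2**31)),
            global_cast=cast,
            n_wbc=n_wbc,
        )
        img, truth = generate(spec)
        suite.append((img, truth, template_img))
    return suite
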