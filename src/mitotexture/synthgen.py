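"""Synthetic mitochondrial-morphology ROI generator.

Emulates the three morphology classes seen in confocal ROIs of stained
mitochondria: *puncta* (small disconnected, roughly circular spots),
*fibers* (interconnected branching tubular networks) and *rods* (short
straight unbranched segments). Fibers and rods share tubule width and
intensity so the two classes overlap in texture space, which is the hard
case for any classifier; puncta are designed to be distinct. A "treated"
condition is modelled as a fragmentation-shifted morphology mixture.

Noise model: Poisson shot noise on the signal plus additive Gaussian read
noise — the standard confocal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import Image2D

CLASSES = ("fiber", "puncta", "rod")

# morphology mixture weights for the two-condition mode; "treated" shifts
# mass from networks toward fragmented puncta
CONDITION_WEIGHTS = {
    "untreated": {"fiber": 0.45, "rod": 0.30, "puncta": 0.25},
    "treated": {"fiber": 0.20, "rod": 0.30, "puncta": 0.50},
}


@dataclass
class SynthConfig:
    """Generator settings.

    ``noise_sd`` is the Gaussian read-noise standard deviation as a fraction
    of the dynamic range; ``photon_budget`` scales Poisson shot noise (counts
    at full signal). Defaults give moderate, realistic noise for 8-bit
    confocal-like ROIs.
    """

    image_size: int = 69
    noise_sd: float = 0.05
    background_level: float = 0.12
    photon_budget: float = 150.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SynthROI:
    """One generated ROI: the noisy 8/16-bit image, the clean signal in
    [0, 1], and the number of drawn objects."""

    image: Image2D
    clean: np.ndarray
    n_objects: int
    class_label: str


def _finish(clean: np.ndarray, cfg: SynthConfig, rng: np.random.Generator,
            n_objects: int, label: str) -> SynthROI:
    clean = np.clip(clean, 0.0, 1.0)
    noisy = clean
    if cfg.noise_sd > 0 or cfg.photon_budget > 0:
        shot = rng.poisson(clean * cfg.photon_budget) / cfg.photon_budget
        noisy = shot + rng.normal(0.0, cfg.noise_sd, clean.shape)
    full = 2**cfg.bit_depth - 1
    pixels = np.clip(np.rint(noisy * full), 0, full).astype(
        np.uint8 if cfg.bit_depth == 8 else np.uint16)
    return SynthROI(Image2D(pixels, bit_depth=cfg.bit_depth, pixel_size_um=0.035),
                    clean, n_objects, label)


def make_puncta(cfg: SynthConfig | None = None,
                rng: np.random.Generator | None = None) -> SynthROI:
    """Disconnected, approximately circular Gaussian spots on low background."""
    cfg = cfg or SynthConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    s = cfg.image_size
    clean = np.full((s, s), cfg.background_level)
    n_spots = int(rng.integers(8, 21))
    centers: list[tuple[float, float]] = []
    yy, xx = np.mgrid[0:s, 0:s]
    attempts = 0
    while len(centers) < n_spots and attempts < 500:
        attempts += 1
        cy, cx = rng.uniform(5, s - 5, size=2)
        if all((cy - oy) ** 2 + (cx - ox) ** 2 >= 8.0**2 for oy, ox in centers):
            sigma = rng.uniform(1.2, 2.2)
            amp = rng.uniform(0.6, 1.0)
            clean += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            centers.append((cy, cx))
    return _finish(clean, cfg, rng, len(centers), "puncta")


def _random_walk_skeleton(canvas: np.ndarray, rng: np.random.Generator,
                          n_seeds: int, branch_prob: float,
                          target_px: float, max_walkers: int = 40) -> None:
    """Draw branching random-walk skeletons onto a boolean canvas in place.

    Walkers step until they exit the border or the skeleton reaches
    ``target_px`` pixels; dead walker populations are re-seeded so sparse
    draws still reach a comparable skeleton budget.
    """
    s = canvas.shape[0]

    def spawn():
        pos = rng.uniform(5, s - 5, size=2)
        return [pos[0], pos[1], rng.uniform(0, 2 * np.pi)]

    walkers = [spawn() for _ in range(n_seeds)]
    n_spawned = len(walkers)
    steps = 0
    while canvas.sum() < target_px and steps < 2000:
        steps += 1
        if not walkers:
            walkers.append(spawn())
            n_spawned += 1
        nxt = []
        for y, x, ang in walkers:
            ang += rng.normal(0.0, 0.25)
            y += np.sin(ang)
            x += np.cos(ang)
            if not (0 <= y < s and 0 <= x < s):
                continue
            canvas[int(y), int(x)] = True
            if n_spawned < max_walkers and rng.random() < branch_prob:
                nxt.append([y, x, ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.2)])
                n_spawned += 1
            nxt.append([y, x, ang])
        walkers = nxt


def make_fibers(cfg: SynthConfig | None = None,
                rng: np.random.Generator | None = None) -> SynthROI:
    """Interconnected branching tubular network (~3 px tubule width).

    The skeleton pixel budget is drawn from the same range a rod ROI's
    total segment length spans, so fibers and rods overlap in coverage and
    differ chiefly in connectivity — the hard case for classification.
    """
    cfg = cfg or SynthConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    s = cfg.image_size
    skel = np.zeros((s, s), dtype=bool)
    n_seeds = int(rng.integers(2, 6))
    target_px = rng.uniform(120, 360) * (s / 69.0) ** 2
    _random_walk_skeleton(skel, rng, n_seeds, branch_prob=0.05, target_px=target_px)
    tube = ndimage.binary_dilation(skel, ndimage.generate_binary_structure(2, 2))
    amp = rng.uniform(0.7, 1.0)
    signal = ndimage.gaussian_filter(tube.astype(np.float64) * amp, sigma=0.8)
    clean = cfg.background_level + signal
    return _finish(clean, cfg, rng, n_seeds, "fiber")


def make_rods(cfg: SynthConfig | None = None,
              rng: np.random.Generator | None = None) -> SynthROI:
    """Short straight unbranched segments (length 10-25 px, ~3 px wide),
    mutually disjoint."""
    cfg = cfg or SynthConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    s = cfg.image_size
    occupied = np.zeros((s, s), dtype=bool)
    signal = np.zeros((s, s), dtype=np.float64)
    struct = ndimage.generate_binary_structure(2, 2)
    n_target = int(rng.integers(5, 13))
    n_drawn = 0
    attempts = 0
    while n_drawn < n_target and attempts < 300:
        attempts += 1
        length = rng.uniform(10, 25)
        ang = rng.uniform(0, np.pi)
        cy, cx = rng.uniform(6, s - 6, size=2)
        y0, x0 = cy - length / 2 * np.sin(ang), cx - length / 2 * np.cos(ang)
        y1, x1 = cy + length / 2 * np.sin(ang), cx + length / 2 * np.cos(ang)
        if not (0 <= y0 < s and 0 <= x0 < s and 0 <= y1 < s and 0 <= x1 < s):
            continue
        t = np.linspace(0.0, 1.0, int(2 * length))
        ry = np.clip((y0 + t * (y1 - y0)).astype(int), 0, s - 1)
        rx = np.clip((x0 + t * (x1 - x0)).astype(int), 0, s - 1)
        stroke = np.zeros((s, s), dtype=bool)
        stroke[ry, rx] = True
        tube = ndimage.binary_dilation(stroke, struct)
        # require separation so rods stay disjoint components
        halo = ndimage.binary_dilation(tube, struct, iterations=2)
        if (halo & occupied).any():
            continue
        occupied |= tube
        amp = rng.uniform(0.7, 1.0)
        signal = np.maximum(signal, tube.astype(np.float64) * amp)
        n_drawn += 1
    clean = cfg.background_level + ndimage.gaussian_filter(signal, sigma=0.8)
    return _finish(clean, cfg, rng, n_drawn, "rod")


_MAKERS = {"fiber": make_fibers, "puncta": make_puncta, "rod": make_rods}


def make_roi(class_label: str, cfg: SynthConfig | None = None,
             rng: np.random.Generator | None = None) -> SynthROI:
    try:
        return _MAKERS[class_label](cfg, rng)
    except KeyError:
        raise ValueError(f"unknown class {class_label!r}; use one of {CLASSES}")


def make_dataset(n_per_class: dict[str, int] | int, cfg: SynthConfig | None = None,
                 seed: int = 0) -> tuple[list[SynthROI], pd.DataFrame]:
    """Generate a labeled ROI set plus its manifest.

    ``n_per_class`` is either a per-class count mapping or a single count
    used for all three classes. Fully deterministic under ``seed``.
    """
    cfg = cfg or SynthConfig()
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in CLASSES}
    unknown = set(n_per_class) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    if len(n_per_class) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    rois, records = [], []
    for label in CLASSES:
        for i in range(n_per_class.get(label, 0)):
            roi = make_roi(label, cfg, rng)
            roi_id = f"{label}_{i:03d}"
            rois.append(roi)
            records.append({"roi_id": roi_id, "class_label": label,
                            "n_objects": roi.n_objects, "seed": seed,
                            "image_size": cfg.image_size, "noise_sd": cfg.noise_sd})
    return rois, pd.DataFrame(records)


def make_condition_dataset(n_images: int, condition: str, cfg: SynthConfig | None = None,
                           seed: int = 0) -> tuple[list[SynthROI], pd.DataFrame]:
    """ROIs drawn from a condition-specific morphology mixture; the treated
    condition shifts weight from fibers toward puncta (fragmentation)."""
    if condition not in CONDITION_WEIGHTS:
        raise ValueError(f"unknown condition {condition!r}")
    cfg = cfg or SynthConfig()
    weights = CONDITION_WEIGHTS[condition]
    rng = np.random.default_rng(seed)
    labels = rng.choice(list(weights), size=n_images, p=list(weights.values()))
    rois, records = [], []
    for i, label in enumerate(labels):
        roi = make_roi(str(label), cfg, rng)
        rois.append(roi)
        records.append({"roi_id": f"{condition}_{i:03d}", "class_label": str(label),
                        "condition": condition, "n_objects": roi.n_objects,
                        "seed": seed})
    return rois, pd.DataFrame(records)
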