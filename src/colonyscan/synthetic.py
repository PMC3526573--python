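"""Synthetic phase-contrast-like images with ground-truth colony masks.

Real micrographs of stem-cell colonies on a fibroblast feeder layer show
two texturally distinct populations on a noisy, unevenly illuminated
background: colonies are carpets of small, tightly packed cells (fine
isotropic granularity) surrounded by a bright halo, while the feeder layer
is sparse, elongated cells (anisotropic strokes).  This module renders that
structure procedurally — stamped primitives on a smooth background, no
external data — so the whole detection pipeline can be trained and
evaluated against exact ground truth.

Colony outlines are discs whose radius is perturbed by a smooth random
periodic function of angle, so border pixels are genuinely ambiguous, as in
real images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .bif import compute_features
from .classifier import FeatureConfig, TrainingSet
from .io import GrayImage

__all__ = ["GeneratorConfig", "generate", "make_training_set"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the two-texture colony/feeder image generator.

    Intensities are on an arbitrary luminance scale with background level
    0.5; contrasts are additive amplitudes on that scale.  Defaults render
    a 500x500 field of view with 1-6 irregular colonies of 40-150 px radius.
    """

    shape: tuple[int, int] = (500, 500)
    n_colonies: tuple[int, int] = (1, 6)  # inclusive range
    radius: tuple[float, float] = (40.0, 150.0)
    boundary_wobble: float = 0.12  # relative radial perturbation amplitude
    boundary_harmonics: tuple[int, int] = (2, 6)
    # colony texture: dense isotropic granularity
    blob_density: float = 0.07  # stamps per colony pixel
    blob_radius: tuple[float, float] = (2.0, 5.0)
    blob_contrast: float = 0.12
    # background texture: sparse elongated fibroblast-like strokes
    stroke_density: float = 2.4e-4  # strokes per image pixel
    stroke_length: tuple[float, float] = (30.0, 80.0)
    stroke_width: tuple[float, float] = (3.0, 6.0)
    stroke_contrast: float = 0.10
    # field-level nuisances
    illumination_amplitude: float = 0.08
    noise_sd: float = 0.02
    halo_strength: float = 0.15
    background_level: float = 0.5
    area_per_pixel_um2: float = 2.86
    seed: int | None = None
    #: explicit (row, col, radius) triples overriding random placement
    colonies: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 1 or w < 1:
            raise ValueError("image shape must be positive")
        for name in ("blob_density", "stroke_density", "noise_sd",
                     "halo_strength", "illumination_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_colonies[0] < 0 or self.n_colonies[1] < self.n_colonies[0]:
            raise ValueError("n_colonies must be a non-negative inclusive range")
        max_r = self.radius[1] if self.colonies is None else max(
            (c[2] for c in self.colonies), default=0.0
        )
        if max_r * 2 > min(self.shape):
            raise ValueError(
                f"colony radius {max_r} does not fit in image of shape {self.shape}"
            )


def _radial_profile(rng: np.random.Generator, cfg: GeneratorConfig):
    """Random smooth periodic radius modulation w(theta), roughly unit SD."""
    k_lo, k_hi = cfg.boundary_harmonics
    ks = np.arange(k_lo, k_hi + 1)
    amp_a = rng.normal(size=len(ks))
    amp_b = rng.normal(size=len(ks))
    norm = math.sqrt(len(ks))

    def w(theta: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(theta)
        for k, a, b in zip(ks, amp_a, amp_b):
            acc += a * np.cos(k * theta) + b * np.sin(k * theta)
        return acc / norm

    return w


def _rasterise_colony(
    shape: tuple[int, int],
    row: float,
    col: float,
    r0: float,
    wobble: float,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
) -> tuple[slice, slice, np.ndarray]:
    """Binary patch for one colony, returned with its bounding-box slices."""
    pad = int(math.ceil(r0 * (1.0 + 3.0 * wobble))) + 2
    r_lo, r_hi = max(int(row) - pad, 0), min(int(row) + pad + 1, shape[0])
    c_lo, c_hi = max(int(col) - pad, 0), min(int(col) + pad + 1, shape[1])
    dy = np.arange(r_lo, r_hi)[:, None] - row
    dx = np.arange(c_lo, c_hi)[None, :] - col
    dist = np.hypot(dy, dx)
    if wobble > 0:
        w = _radial_profile(rng, cfg)
        theta = np.arctan2(dy, dx)
        radius = r0 * np.clip(1.0 + wobble * w(theta), 0.3, 1.9)
    else:
        radius = np.full_like(dist, r0)
    return slice(r_lo, r_hi), slice(c_lo, c_hi), dist <= radius


def _stamp_strokes(
    layer: np.ndarray, rng: np.random.Generator, cfg: GeneratorConfig
) -> None:
    """Add randomly oriented elongated strokes (fibroblast bodies)."""
    from skimage.draw import polygon

    h, w = layer.shape
    n = rng.poisson(cfg.stroke_density * h * w)
    for _ in range(n):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        angle = rng.uniform(0, math.pi)
        length = rng.uniform(*cfg.stroke_length)
        width = rng.uniform(*cfg.stroke_width)
        amp = cfg.stroke_contrast * rng.uniform(0.5, 1.0) * rng.choice((-1.0, 1.0))
        ca, sa = math.cos(angle), math.sin(angle)
        # rotated rectangle corners
        half_l, half_w = length / 2.0, width / 2.0
        corners = np.array(
            [
                (cy + sa * half_l + ca * half_w, cx + ca * half_l - sa * half_w),
                (cy + sa * half_l - ca * half_w, cx + ca * half_l + sa * half_w),
                (cy - sa * half_l - ca * half_w, cx - ca * half_l + sa * half_w),
                (cy - sa * half_l + ca * half_w, cx - ca * half_l - sa * half_w),
            ]
        )
        rr, cc = polygon(corners[:, 0], corners[:, 1], shape=layer.shape)
        layer[rr, cc] += amp


def _stamp_blobs(
    layer: np.ndarray,
    region_rows: np.ndarray,
    region_cols: np.ndarray,
    n_blobs: int,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
) -> None:
    """Add small Gaussian bumps at random positions inside one colony."""
    h, w = layer.shape
    if n_blobs == 0 or len(region_rows) == 0:
        return
    picks = rng.integers(0, len(region_rows), size=n_blobs)
    radii = rng.uniform(*cfg.blob_radius, size=n_blobs)
    amps = cfg.blob_contrast * rng.uniform(0.5, 1.0, size=n_blobs)
    amps *= rng.choice((-1.0, 1.0), size=n_blobs)
    for i in range(n_blobs):
        cy, cx = int(region_rows[picks[i]]), int(region_cols[picks[i]])
        rb = radii[i]
        ext = int(math.ceil(rb * 1.5))
        r_lo, r_hi = max(cy - ext, 0), min(cy + ext + 1, h)
        c_lo, c_hi = max(cx - ext, 0), min(cx + ext + 1, w)
        dy = np.arange(r_lo, r_hi)[:, None] - cy
        dx = np.arange(c_lo, c_hi)[None, :] - cx
        sig = rb / 2.0
        layer[r_lo:r_hi, c_lo:c_hi] += amps[i] * np.exp(
            -(dy**2 + dx**2) / (2.0 * sig**2)
        )


def generate(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[GrayImage, np.ndarray, pd.DataFrame]:
    """Render one synthetic image with its ground-truth mask.

    Returns ``(image, mask, colony_table)`` where ``mask`` is a uint8 H x W
    ground-truth colony map and ``colony_table`` lists, per colony, its
    centre, nominal radius and true rasterised pixel area.  The same seed
    (``seed`` argument, falling back to ``config.seed``) reproduces the
    output bit-for-bit.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    h, w = config.shape
    mask = np.zeros((h, w), dtype=bool)

    # --- colony geometry --------------------------------------------------
    if config.colonies is not None:
        placements = [tuple(map(float, c)) for c in config.colonies]
    else:
        n = int(rng.integers(config.n_colonies[0], config.n_colonies[1] + 1))
        placements = []
        for _ in range(n):
            r0 = rng.uniform(*config.radius)
            margin = min(r0 * (1.0 + 2.0 * config.boundary_wobble), min(h, w) / 2.0)
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            placements.append((cy, cx, r0))

    records = []
    colony_patches = []
    for i, (cy, cx, r0) in enumerate(placements, start=1):
        rs, cs, patch = _rasterise_colony(
            (h, w), cy, cx, r0, config.boundary_wobble, rng, config
        )
        mask[rs, cs] |= patch
        colony_patches.append((rs, cs, patch))
        records.append(
            {
                "colony_id": i,
                "row": cy,
                "col": cx,
                "radius_px": r0,
                "area_px": int(patch.sum()),
            }
        )
    table = pd.DataFrame(
        records, columns=["colony_id", "row", "col", "radius_px", "area_px"]
    )

    # --- rendering --------------------------------------------------------
    img = np.full((h, w), config.background_level, dtype=np.float64)
    if config.illumination_amplitude > 0:
        phi = rng.uniform(0, 2 * math.pi)
        yy = np.arange(h)[:, None]
        xx = np.arange(w)[None, :]
        ramp = yy * math.sin(phi) + xx * math.cos(phi)
        span = ramp.max() - ramp.min()
        if span > 0:
            img += config.illumination_amplitude * (
                (ramp - ramp.min()) / span - 0.5
            )

    strokes = np.zeros((h, w), dtype=np.float64)
    _stamp_strokes(strokes, rng, config)
    strokes = ndimage.gaussian_filter(strokes, 0.8, mode="reflect")
    img += strokes * ~mask

    blobs = np.zeros((h, w), dtype=np.float64)
    for rs, cs, patch in colony_patches:
        rows, cols = np.nonzero(patch)
        n_blobs = int(round(config.blob_density * len(rows)))
        _stamp_blobs(
            blobs, rows + rs.start, cols + cs.start, n_blobs, rng, config
        )
    img += blobs * mask

    if config.halo_strength > 0 and mask.any():
        rim = ndimage.binary_dilation(mask, iterations=2) & ~mask
        img += config.halo_strength * ndimage.gaussian_filter(
            rim.astype(np.float64), 1.5, mode="reflect"
        )

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=(h, w))

    np.clip(img, 0.0, None, out=img)
    gray = GrayImage(img, area_per_pixel_um2=config.area_per_pixel_um2)
    return gray, mask.astype(np.uint8), table


def make_training_set(
    configs,
    pixels_per_image: int = 20_000,
    feature_config: FeatureConfig | None = None,
    seed: int | None = 0,
) -> TrainingSet:
    """Sample balanced labelled pixels from generated images.

    ``configs`` is an iterable of :class:`GeneratorConfig` (each typically
    carrying its own seed).  Per image, ``pixels_per_image // 2`` colony and
    as many background pixels are drawn without replacement and featurised
    with :func:`colonyscan.bif.compute_features`; a provenance table
    records image index, row and column per sampled pixel.

    Raises
    ------
    ValueError
        If an image lacks enough pixels of either class.
    """
    fc = feature_config or FeatureConfig()
    configs = list(configs)
    if not configs:
        raise ValueError("at least one generator config is required")
    rng = np.random.default_rng(seed)
    per_class = pixels_per_image // 2
    feats, labels, prov = [], [], []
    for idx, cfg in enumerate(configs):
        gray, mask, _ = generate(cfg)
        fs = compute_features(gray.pixels, fc.scales, fc.epsilon, fc.window)
        flat_feats = fs.as_table()
        flat_mask = mask.ravel().astype(bool)
        for label, pool in ((1, np.flatnonzero(flat_mask)),
                            (0, np.flatnonzero(~flat_mask))):
            if len(pool) < per_class:
                raise ValueError(
                    f"image {idx}: only {len(pool)} pixels of class {label}, "
                    f"need {per_class}"
                )
            chosen = rng.choice(pool, size=per_class, replace=False)
            feats.append(flat_feats[chosen])
            labels.append(np.full(per_class, label, dtype=np.int8))
            prov.append(
                pd.DataFrame(
                    {
                        "image": idx,
                        "row": chosen // mask.shape[1],
                        "col": chosen % mask.shape[1],
                        "label": label,
                    }
                )
            )
    return TrainingSet(
        features=np.concatenate(feats),
        labels=np.concatenate(labels),
        feature_config=fc,
        provenance=pd.concat(prov, ignore_index=True),
    )


def growth_series(
    base: GeneratorConfig, radii_scale: list[float], seed: int = 0
) -> list[GeneratorConfig]:
    """Configs emulating one field imaged on successive days.

    Colony positions are held fixed while radii grow by the given factors,
    mimicking day-to-day colony expansion.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(base.n_colonies[0], base.n_colonies[1] + 1))
    h, w = base.shape
    max_scale = max(radii_scale)
    centres = []
    for _ in range(n):
        r0 = rng.uniform(base.radius[0], base.radius[1] / max_scale)
        margin = min(r0 * max_scale * 1.3, min(h, w) / 2.0)
        centres.append((rng.uniform(margin, h - margin),
                        rng.uniform(margin, w - margin), r0))
    out = []
    for day, s in enumerate(radii_scale):
        out.append(
            replace(
                base,
                colonies=tuple((cy, cx, r0 * s) for cy, cx, r0 in centres),
                seed=(seed + 1000 * day) % (2**31),
            )
        )
    return out
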