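"""Synthetic scenes, ratings and analytic fixtures.

Three families of generators:

* analytic fixtures with known fractal/spectral ground truth — the Sierpinski
  carpet (dimension log 8 / log 3), fractional-Brownian-motion surfaces
  (surface dimension 3 − H) and planted-exponent spectral noise — used to
  validate the estimators;
* office-like scenes: a non-green background (flat, gradient or spectrally
  textured) with "furniture" rectangles for color complexity and elliptical
  plant blobs whose pixels sit strictly inside the vegetation HSV criterion,
  calibrated to a target green-area percentage;
* study-shaped ratings: 60 photos in 12 groups of 5, each group rated by its
  own raters on the 11 IRCS items, with a latent photo mean that is linear in
  √greenery and the color fractal plus participant and residual Gaussian
  noise, discretised by round-then-clamp onto the 1–5 scale.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import color as skcolor

from restoview.exceptions import ValidationError
from restoview.images import ChannelField, HSVCriteria, RasterImage, greenery_percentage
from restoview.psychometrics import ScaleDefinition, default_scale

__all__ = [
    "SyntheticSceneSpec",
    "RatingSimSpec",
    "gen_sierpinski",
    "gen_fbm_surface",
    "gen_spectral_image",
    "gen_office_scene",
    "make_scene_specs",
    "gen_photo_set",
    "gen_ratings",
]

# Plant-pixel HSV band, strictly inside the detection criterion
# (hue 50-170 deg, sat 20-100 %, val 10-100 %) so 8-bit rounding cannot
# push a plant pixel across the threshold.
_PLANT_HUE = (75.0, 145.0)
_PLANT_SAT = (0.35, 0.85)
_PLANT_VAL = (0.25, 0.85)

# Background hues avoid the detection band with a wide margin.
_BG_HUES = tuple(np.r_[np.arange(190, 350, 20), np.arange(0, 40, 10)])


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one generated office-like scene."""

    greenery_target: float = 0.0
    width: int = 640
    height: int = 320
    n_plant_blobs: int = 6
    background: str = "texture"  # flat | gradient | texture
    texture_exponent: float = 1.0
    n_furniture: int = 5
    palette_seed: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.greenery_target <= 100.0:
            raise ValidationError("greenery_target must lie in [0, 100]")
        if self.width < 64 or self.height < 64:
            raise ValidationError("scene must be at least 64 x 64")
        if self.background not in ("flat", "gradient", "texture"):
            raise ValidationError(f"unknown background {self.background!r}")


@dataclass(frozen=True)
class RatingSimSpec:
    """Parameters of the grouped-rating simulation."""

    n_photos: int = 60
    n_groups: int = 12
    photos_per_group: int = 5
    raters_per_group: int = 100
    intercept: float = 2.8
    slope_greenery: float = 0.12  # per unit sqrt-percent
    slope_color_fractal: float = -0.10
    sigma: float = 0.6  # residual SD per item response
    participant_sd: float | None = None  # default sigma / 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_photos != self.n_groups * self.photos_per_group:
            raise ValidationError("n_photos must equal n_groups * photos_per_group")
        if self.raters_per_group < 1:
            raise ValidationError("raters_per_group must be >= 1")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")

    @property
    def offset_sd(self) -> float:
        return self.sigma / 2.0 if self.participant_sd is None else self.participant_sd


# ---------------------------------------------------------------------------
# analytic fixtures


def gen_sierpinski(level: int) -> np.ndarray:
    """Sierpinski-carpet mask of size 3^level; occupied fraction (8/9)^level."""
    if not 1 <= level <= 6:
        raise ValidationError("level must be in [1, 6]")
    cell = np.ones((3, 3), dtype=bool)
    cell[1, 1] = False
    mask = cell
    for _ in range(level - 1):
        mask = np.kron(mask, cell)
    return mask


def _spectral_noise(amp_exponent: float, size: int, seed: int) -> np.ndarray:
    """Gaussian field with radial amplitude spectrum proportional to f^-amp_exponent."""
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.sqrt(fx * fx + fy * fy)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-amp_exponent)
    w = rng.normal(size=(size, size)) + 1j * rng.normal(size=(size, size))
    fld = np.fft.ifft2(w * amp).real
    lo, hi = fld.min(), fld.max()
    if hi == lo:
        return np.full_like(fld, 0.5)
    return (fld - lo) / (hi - lo)


def gen_fbm_surface(H: float, size: int, seed: int) -> ChannelField:
    """Fractional-Brownian-motion surface with Hurst exponent H.

    Spectral synthesis with amplitude proportional to f^-(H+1); the surface's
    differential box-counting dimension is 3 - H.
    """
    if not 0.0 < H < 1.0:
        raise ValidationError("Hurst exponent must lie in (0, 1)")
    if size < 64 or size & (size - 1):
        raise ValidationError("size must be a power of 2, at least 64")
    return ChannelField(_spectral_noise(H + 1.0, size, seed), "brightness")


def gen_spectral_image(beta: float, size: int, seed: int) -> ChannelField:
    """Noise field with planted amplitude-spectrum exponent beta (0 = white)."""
    if not 0.0 <= beta <= 3.0:
        raise ValidationError("beta must lie in [0, 3]")
    return ChannelField(_spectral_noise(beta, size, seed), "brightness")


# ---------------------------------------------------------------------------
# office scenes


def _palette(rng: np.random.Generator, n: int = 5) -> np.ndarray:
    """n non-green HSV colors (hue away from the vegetation band)."""
    hues = rng.choice(_BG_HUES, size=n, replace=True) + rng.uniform(-5, 5, n)
    hues = np.mod(hues, 360.0)
    sats = rng.uniform(0.25, 0.75, n)
    vals = rng.uniform(0.3, 0.9, n)
    return np.stack([hues / 360.0, sats, vals], axis=1)


def _hsv_to_rgb01(hsv: np.ndarray) -> np.ndarray:
    return skcolor.hsv2rgb(hsv)


def gen_office_scene(spec: SyntheticSceneSpec) -> RasterImage:
    """Render one office-like scene calibrated to its greenery target.

    Plant pixels are selected exactly — the first ``round(target% · area)``
    pixels in blob paint order — so the measured green share matches the
    target to within pixel rounding; a target of 0 yields no green pixel.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    pal_rng = rng if spec.palette_seed is None else np.random.default_rng(spec.palette_seed)
    # per-scene palette size: a room decorated in 2 hues vs 10 spans the
    # color-variety axis without touching texture roughness
    pal = _palette(pal_rng, n=int(pal_rng.integers(2, 11)))

    hsv = np.empty((h, w, 3), dtype=float)
    if spec.background == "flat":
        hsv[:] = pal[0]
    elif spec.background == "gradient":
        # fixed non-green hue; blend saturation/value so the hue path can
        # never cross the vegetation band
        t = np.linspace(0.0, 1.0, w)[None, :]
        hsv[..., 0] = pal[0, 0]
        hsv[..., 1] = pal[0, 1] * (1 - t) + pal[1, 1] * t
        hsv[..., 2] = pal[0, 2] * (1 - t) + pal[1, 2] * t
    else:  # texture
        hsv[:] = pal[0]
        size = 1 << int(np.ceil(np.log2(max(h, w))))
        tex = _spectral_noise(spec.texture_exponent, size, int(rng.integers(2**31)))[:h, :w]
        amp = rng.uniform(0.05, 0.8)
        hsv[..., 2] = np.clip(pal[0, 2] + amp * (tex - 0.5), 0.15, 0.98)

    # coarse wall panels: large uniform recolorings (hue/sat only, brightness
    # kept) that move the joint color distribution without adding texture
    # roughness — the roughness-free component of color complexity
    panel_p = rng.uniform(0.0, 1.0) if spec.n_furniture > 0 else 0.0
    panel = int(rng.choice([max(h // 5, 64), max(h // 4, 64), max(h // 2, 64)]))
    for py in range(0, h, panel):
        for px_ in range(0, w, panel):
            if rng.uniform() < panel_p:
                color = pal[int(rng.integers(len(pal)))]
                hsv[py : py + panel, px_ : px_ + panel, 0] = color[0]
                hsv[py : py + panel, px_ : px_ + panel, 1] = color[1]

    # furniture and clutter rectangles recolor hue/saturation but keep the
    # brightness field, so color transitions do not leak into the luminance
    # roughness (which is governed by the background texture alone)
    for _ in range(spec.n_furniture):
        cw = int(rng.integers(w // 16, w // 3))
        ch = int(rng.integers(h // 16, h // 3))
        x0 = int(rng.integers(0, max(1, w - cw)))
        y0 = int(rng.integers(0, max(1, h - ch)))
        hsv[y0 : y0 + ch, x0 : x0 + cw, :2] = pal[int(rng.integers(len(pal))), :2]
    for _ in range(2 * spec.n_furniture):
        cw = int(rng.integers(max(2, w // 40), w // 10))
        ch = int(rng.integers(max(2, h // 40), h // 10))
        x0 = int(rng.integers(0, max(1, w - cw)))
        y0 = int(rng.integers(0, max(1, h - ch)))
        hsv[y0 : y0 + ch, x0 : x0 + cw, :2] = pal[int(rng.integers(len(pal))), :2]
    # busy regions (shelves, pinboards): per-pixel jitter sets the luminance
    # roughness; an independent per-scene chroma-variety knob decides whether
    # that roughness is monochrome (books in one color) or multi-hued
    # (colorful spines) — this decouples color complexity from the
    # brightness-texture fractals
    chroma_variety = rng.uniform(0.0, 1.0)
    n_busy = int(rng.integers(0, min(spec.n_furniture, 10) + 1)) if spec.n_furniture else 0
    for _ in range(n_busy):
        cw = int(rng.integers(w // 8, w // 3))
        ch = int(rng.integers(h // 8, h // 3))
        x0 = int(rng.integers(0, max(1, w - cw)))
        y0 = int(rng.integers(0, max(1, h - ch)))
        region_color = pal[int(rng.integers(len(pal)))]
        idx = rng.integers(0, len(pal), size=(ch, cw))
        multi = rng.uniform(size=(ch, cw)) < chroma_variety
        # hue varies per pixel; saturation is the region's, brightness is kept
        sl = hsv[y0 : y0 + ch, x0 : x0 + cw]
        sl[..., 0] = np.where(multi, pal[idx][..., 0], region_color[0])
        sl[..., 1] = region_color[1]

    # independent micro-roughness in hue and saturation: gives the per-channel
    # texture fractals variance of their own (the shifts are small relative to
    # the coarse color boxes, so the color fractal barely responds)
    hue_jit = rng.uniform(0.0, 3.0) / 360.0
    sat_jit = rng.uniform(0.0, 0.08)
    hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-hue_jit, hue_jit, (h, w)), 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] + rng.uniform(-sat_jit, sat_jit, (h, w)), 0.12, 0.98)

    # plant blobs: paint ellipses until enough pixels, keep exactly n_target.
    # Each blob is a near-uniform green (small per-pixel jitter): foliage has
    # low color variety, so greenery smooths the color field rather than
    # adding clutter.
    n_target = int(round(spec.greenery_target / 100.0 * h * w))
    if n_target > 0:
        mask = np.zeros((h, w), dtype=bool)
        pixel_chunks: list = []
        blob_of_chunk: list = []
        yy, xx = np.mgrid[0:h, 0:w]
        attempts = 0
        while mask.sum() < n_target:
            attempts += 1
            if attempts > 500:
                raise ValidationError(
                    f"greenery target {spec.greenery_target}% unreachable at {w}x{h}"
                )
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            ry = rng.uniform(0.04, 0.18) * h
            rx = rng.uniform(0.04, 0.18) * w
            blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            new = blob & ~mask
            if new.any():
                pixel_chunks.append(np.flatnonzero(new.ravel()))
                blob_of_chunk.append(attempts)
                mask |= blob
        keep = np.concatenate(pixel_chunks)[:n_target]
        blob_ids = np.repeat(blob_of_chunk, [len(c) for c in pixel_chunks])[:n_target]
        gy, gx = np.unravel_index(keep, (h, w))
        # one base green per scene; blobs deviate slightly from it
        scene_hue = rng.uniform(_PLANT_HUE[0] + 10, _PLANT_HUE[1] - 10)
        scene_sat = rng.uniform(_PLANT_SAT[0] + 0.10, _PLANT_SAT[1] - 0.10)
        scene_val = rng.uniform(_PLANT_VAL[0] + 0.10, _PLANT_VAL[1] - 0.10)
        base_hue = {b: scene_hue + rng.uniform(-4, 4) for b in set(blob_ids)}
        base_sat = {b: scene_sat + rng.uniform(-0.03, 0.03) for b in set(blob_ids)}
        base_val = {b: scene_val + rng.uniform(-0.03, 0.03) for b in set(blob_ids)}
        n_green = len(keep)
        ghsv = np.stack(
            [
                (np.vectorize(base_hue.get)(blob_ids) + rng.uniform(-2, 2, n_green)) / 360.0,
                np.vectorize(base_sat.get)(blob_ids) + rng.uniform(-0.02, 0.02, n_green),
                np.vectorize(base_val.get)(blob_ids) + rng.uniform(-0.03, 0.03, n_green),
            ],
            axis=1,
        )
        hsv[gy, gx] = ghsv

    rgb = np.clip(np.round(_hsv_to_rgb01(hsv) * 255.0), 0, 255).astype(np.uint8)
    img = RasterImage(rgb, source_id=f"scene-{spec.seed}")
    measured = greenery_percentage(img, HSVCriteria())
    if abs(measured - spec.greenery_target) > 2.0:
        raise ValidationError(
            f"rendered greenery {measured:.2f}% misses target {spec.greenery_target}% by > 2 points"
        )
    return img


def make_scene_specs(
    n: int = 60,
    max_green: float = 60.0,
    seed: int = 0,
    width: int = 640,
    height: int = 320,
) -> list:
    """n varied scene specs with greenery targets spanning [0, max_green]."""
    rng = np.random.default_rng(seed)
    targets = np.linspace(0.0, max_green, n)
    backgrounds = rng.choice(["texture", "gradient", "flat"], size=n, p=[0.6, 0.2, 0.2])
    specs = []
    for i in range(n):
        specs.append(
            SyntheticSceneSpec(
                greenery_target=float(targets[i]),
                width=width,
                height=height,
                n_plant_blobs=int(rng.integers(3, 10)),
                background=str(backgrounds[i]),
                texture_exponent=float(rng.uniform(0.6, 1.6)),
                n_furniture=int(rng.integers(0, 25)),
                seed=int(rng.integers(2**31)),
            )
        )
    return specs


def gen_photo_set(specs: Sequence[SyntheticSceneSpec], n_groups: int = 12):
    """Render a photo set and deal it into greenery-balanced groups.

    Photos are sorted by greenery target and dealt serpentine-style, so every group
    spans low-to-high greenery and group means stay close to the grand mean.
    Returns ``(images, manifest)``; the manifest records photo_id, group,
    target and measured greenery, and the scene seed.
    """
    if len(specs) % n_groups:
        raise ValidationError("number of specs must be divisible by n_groups")
    images = []
    rows = []
    for i, spec in enumerate(specs):
        img = gen_office_scene(spec)
        img.source_id = f"photo{i:02d}"
        images.append(img)
        rows.append(
            {
                "photo_id": img.source_id,
                "greenery_target": spec.greenery_target,
                "greenery_measured": greenery_percentage(img),
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    order = manifest["greenery_target"].to_numpy().argsort(kind="stable")
    groups = np.empty(len(specs), dtype=int)
    groups[order] = _serpentine(len(specs), n_groups)
    manifest["group"] = groups
    return images, manifest[["photo_id", "group", "greenery_target", "greenery_measured", "seed"]]


# ---------------------------------------------------------------------------
# ratings


def _serpentine(n: int, n_groups: int) -> np.ndarray:
    """Boustrophedon dealing order: 0..k-1, k-1..0, ... balances block pairs."""
    pattern = []
    forward = list(range(n_groups))
    for block in range(-(-n // n_groups)):
        pattern.extend(forward if block % 2 == 0 else forward[::-1])
    return np.array(pattern[:n])


def assign_groups(features: pd.DataFrame, spec: RatingSimSpec) -> pd.Series:
    """Greenery-balanced grouping: sort by sqrt_greenery, deal serpentine."""
    order = features["sqrt_greenery"].to_numpy().argsort(kind="stable")
    groups = np.empty(len(features), dtype=int)
    groups[order] = _serpentine(len(features), spec.n_groups)
    return pd.Series(groups, index=features.index, name="group")


def gen_ratings(
    features: pd.DataFrame,
    spec: RatingSimSpec,
    groups: pd.Series | None = None,
    scale: ScaleDefinition | None = None,
) -> pd.DataFrame:
    """Simulate long-format IRCS ratings with planted effect structure.

    The latent photo mean is ``a + b·√g + c·color_fractal``; each response is
    ``clamp(round(latent + participant offset + eps), 1, 5)`` with
    ``eps ~ N(0, sigma)`` per item.  Reverse-keyed items are stored inverted
    (``6 - x``) so that scoring recovers the latent scale.  Raters belong to
    one group and rate its five photos on all 11 items.
    """
    for col in ("sqrt_greenery", "color_fractal"):
        if col not in features.columns:
            raise ValidationError(f"features must contain {col!r}")
    if len(features) != spec.n_photos:
        raise ValidationError(
            f"features has {len(features)} photos, spec expects {spec.n_photos}"
        )
    if scale is None:
        scale = default_scale()
    if groups is None:
        groups = assign_groups(features, spec)
    rng = np.random.default_rng(spec.seed)
    mu = (
        spec.intercept
        + spec.slope_greenery * features["sqrt_greenery"]
        + spec.slope_color_fractal * features["color_fractal"]
    )
    reverse = np.array([it.reverse for it in scale.items])
    item_ids = np.array(scale.item_ids)
    frames = []
    for g in range(spec.n_groups):
        photo_ids = groups.index[groups.to_numpy() == g]
        mu_g = mu.loc[photo_ids].to_numpy()  # (P,)
        n_r = spec.raters_per_group
        offsets = rng.normal(0.0, spec.offset_sd, size=n_r)
        eps = rng.normal(0.0, spec.sigma, size=(n_r, len(photo_ids), len(item_ids)))
        latent = mu_g[None, :, None] + offsets[:, None, None] + eps
        raw = np.clip(np.round(latent), 1, 5).astype(int)
        resp = np.where(reverse[None, None, :], 6 - raw, raw)
        r_idx, p_idx, i_idx = np.indices(resp.shape)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.char.add(
                        f"g{g:02d}r", r_idx.ravel().astype(str)
                    ),
                    "photo_id": np.asarray(photo_ids)[p_idx.ravel()],
                    "item_id": item_ids[i_idx.ravel()],
                    "response": resp.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
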