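"""Visual-property indicators for indoor-scene photographs.

Every estimator consumes an 8-bit RGB :class:`RasterImage` (or a real-valued
channel field derived from it) and produces one scalar indicator.  The full
catalogue, assembled by :func:`extract_features`, comprises 19 indicators:

* ``sqrt_greenery`` — square root of the green-area percentage, the share of
  pixels whose HSV values fall inside a vegetation criterion.
* ``mean_brightness``, ``mean_saturation`` — channel means on [0, 1].
* ``shape_fractal`` — box-counting dimension of the brightness edge map.
* ``geom_fractal_brightness_{small,large,overall}`` — box-counting dimension
  of the median-binarized brightness field at three scale windows.
* ``stat_fractal_{brightness,saturation,hue}_{small,large,overall}`` —
  differential box-counting (DBC) dimension of the intensity surface,
  contract range [2, 3] (rougher texture → higher).
* ``color_fractal`` — box counting in the joint (x, y, R, G, B) space,
  contract range [2, 5] (more abrupt/varied color transitions → higher).
* ``one_over_f_{brightness,saturation}`` — amplitude-spectrum exponent from
  the radially averaged power spectrum; pink (1/f) structure gives 1.

Scale conventions: box grids are anchored at the top-left corner and partial
boxes at the right/bottom edges are counted; the default box-size ladder is
powers of two from 2 up to min(H, W)/4, split into "small" (lower half) and
"large" (upper half) windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from skimage import color as skcolor
from skimage.filters import apply_hysteresis_threshold, gaussian, sobel
from skimage.morphology import skeletonize

from restoview.exceptions import (
    DegenerateInputError,
    DegenerateInputWarning,
    DimensionError,
    ValidationError,
)

__all__ = [
    "RasterImage",
    "HSVCriteria",
    "ChannelField",
    "ScaleWindow",
    "VisualFeatureVector",
    "ExtractionConfig",
    "FEATURE_NAMES",
    "preprocess",
    "to_hsv",
    "greenery_percentage",
    "sqrt_transform",
    "mean_channel",
    "box_count_dimension",
    "shape_fractal",
    "geometric_fractal",
    "statistical_fractal",
    "color_fractal",
    "one_over_f_fluctuation",
    "default_scale_windows",
    "extract_features",
]

# Working resolution of the survey display images.
WORK_WIDTH = 640
WORK_HEIGHT = 320
CROP_WIDTH = 4096
CROP_HEIGHT = 2048


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RasterImage:
    """8-bit RGB pixel grid with provenance metadata."""

    pixels: np.ndarray  # H x W x 3, uint8
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"expected H x W x 3 pixel array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have at least one pixel")
        if px.dtype != np.uint8:
            if np.any(px < 0) or np.any(px > 255):
                raise ValidationError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_file(cls, path, source_id: str | None = None) -> "RasterImage":
        """Load a PNG/JPEG file; an alpha channel is dropped with a warning."""
        with Image.open(path) as im:
            if im.mode in ("RGBA", "LA", "PA"):
                warnings.warn(f"{path}: alpha channel dropped", UserWarning, stacklevel=2)
            rgb = im.convert("RGB")
            px = np.asarray(rgb, dtype=np.uint8)
        return cls(px, source_id=source_id if source_id is not None else str(path))

    def to_file(self, path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)


@dataclass(frozen=True)
class HSVCriteria:
    """Inclusive HSV band defining a "green" pixel.

    ``degrees_percent`` interprets the bounds as hue degrees in [0, 360) and
    saturation/value percent in [0, 100]; ``native_8bit`` interprets them on
    the 8-bit OpenCV scale (hue 0–179 = degrees/2, S and V 0–255).
    """

    hue_min: float = 50.0
    hue_max: float = 170.0
    sat_min: float = 20.0
    sat_max: float = 100.0
    val_min: float = 10.0
    val_max: float = 100.0
    convention: Literal["degrees_percent", "native_8bit"] = "degrees_percent"

    def __post_init__(self) -> None:
        if not (self.hue_min < self.hue_max):
            raise ValidationError("hue_min must be < hue_max")
        if self.sat_min > self.sat_max or self.val_min > self.val_max:
            raise ValidationError("saturation/value bounds out of order")
        if self.convention not in ("degrees_percent", "native_8bit"):
            raise ValidationError(f"unknown HSV convention {self.convention!r}")


@dataclass
class ChannelField:
    """Real-valued H x W field on [0, 1] derived from one HSV channel."""

    values: np.ndarray
    channel_name: Literal["brightness", "saturation", "hue"] = "brightness"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValidationError("channel field must be a nonempty 2-D array")
        if np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9:
            raise ValidationError("channel values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass(frozen=True)
class ScaleWindow:
    """Ordered set of box edge lengths over which a log-log slope is fitted."""

    box_sizes: tuple
    label: Literal["small", "large", "overall"] = "overall"

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.box_sizes)
        if len(sizes) < 3:
            raise ValidationError("a log-log regression needs at least 3 box sizes")
        if any(s < 1 for s in sizes) or any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError("box sizes must be strictly increasing and >= 1")
        object.__setattr__(self, "box_sizes", sizes)

    def validate_for(self, shape: tuple) -> None:
        if self.box_sizes[-1] > min(shape[:2]):
            raise ValidationError(
                f"largest box size {self.box_sizes[-1]} exceeds min image side {min(shape[:2])}"
            )


def default_scale_windows(shape: tuple) -> dict:
    """Power-of-two ladder from 2 to min(H, W)/4, split into small/large halves.

    For short ladders (fewer than 6 rungs) the two halves overlap so that each
    window keeps the 3 points a regression needs.
    """
    side = min(shape[:2])
    top = side // 4
    sizes = []
    s = 2
    while s <= top:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        raise DimensionError(f"image side {side} too small for a 3-point box-size ladder")
    n = len(sizes)
    if n >= 6:
        small = sizes[: n // 2]
        large = sizes[n // 2 :]
    else:
        small = sizes[:3]
        large = sizes[-3:]
    return {
        "small": ScaleWindow(tuple(small), "small"),
        "large": ScaleWindow(tuple(large), "large"),
        "overall": ScaleWindow(tuple(sizes), "overall"),
    }


FEATURE_NAMES = (
    "sqrt_greenery",
    "mean_brightness",
    "mean_saturation",
    "shape_fractal",
    "geom_fractal_brightness_small",
    "geom_fractal_brightness_large",
    "geom_fractal_brightness_overall",
    "stat_fractal_brightness_small",
    "stat_fractal_brightness_large",
    "stat_fractal_brightness_overall",
    "stat_fractal_saturation_small",
    "stat_fractal_saturation_large",
    "stat_fractal_saturation_overall",
    "stat_fractal_hue_small",
    "stat_fractal_hue_large",
    "stat_fractal_hue_overall",
    "color_fractal",
    "one_over_f_brightness",
    "one_over_f_saturation",
)


@dataclass
class VisualFeatureVector:
    """The 19 modeling indicators for one photograph, plus the raw greenery percent."""

    source_id: str
    greenery_pct: float
    sqrt_greenery: float
    mean_brightness: float
    mean_saturation: float
    shape_fractal: float
    geom_fractal_brightness_small: float
    geom_fractal_brightness_large: float
    geom_fractal_brightness_overall: float
    stat_fractal_brightness_small: float
    stat_fractal_brightness_large: float
    stat_fractal_brightness_overall: float
    stat_fractal_saturation_small: float
    stat_fractal_saturation_large: float
    stat_fractal_saturation_overall: float
    stat_fractal_hue_small: float
    stat_fractal_hue_large: float
    stat_fractal_hue_overall: float
    color_fractal: float
    one_over_f_brightness: float
    one_over_f_saturation: float
    flags: tuple = ()

    def __post_init__(self) -> None:
        if abs(self.sqrt_greenery - math.sqrt(self.greenery_pct)) > 1e-12:
            raise ValidationError("sqrt_greenery must equal sqrt(greenery_pct)")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass(frozen=True)
class ExtractionConfig:
    """Everything that parameterises feature extraction; serialises to JSON."""

    criteria: HSVCriteria = field(default_factory=HSVCriteria)
    preprocess: bool = True
    crop: bool = True
    edge_percentile: float = 90.0
    edge_sigma: float = 1.0
    fft_n_bins: int = 16

    def to_dict(self) -> dict:
        c = self.criteria
        return {
            "criteria": {
                "hue_min": c.hue_min,
                "hue_max": c.hue_max,
                "sat_min": c.sat_min,
                "sat_max": c.sat_max,
                "val_min": c.val_min,
                "val_max": c.val_max,
                "convention": c.convention,
            },
            "preprocess": self.preprocess,
            "crop": self.crop,
            "edge_percentile": self.edge_percentile,
            "edge_sigma": self.edge_sigma,
            "fft_n_bins": self.fft_n_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfig":
        crit = HSVCriteria(**d["criteria"]) if "criteria" in d else HSVCriteria()
        kwargs = {k: v for k, v in d.items() if k != "criteria"}
        return cls(criteria=crit, **kwargs)


# ---------------------------------------------------------------------------
# preprocessing and channels


def preprocess(img: RasterImage, crop: bool = True) -> RasterImage:
    """Center-crop to 4096 x 2048, then area-average down to 640 x 320.

    Images already at the working size pass through unchanged.  With ``crop``
    disabled the crop step is skipped and the image is resized directly.
    """
    if img.width == WORK_WIDTH and img.height == WORK_HEIGHT:
        return img
    px = img.pixels
    if crop:
        if img.width < CROP_WIDTH or img.height < CROP_HEIGHT:
            raise DimensionError(
                f"image {img.width}x{img.height} smaller than crop window "
                f"{CROP_WIDTH}x{CROP_HEIGHT}"
            )
        x0 = (img.width - CROP_WIDTH) // 2
        y0 = (img.height - CROP_HEIGHT) // 2
        px = px[y0 : y0 + CROP_HEIGHT, x0 : x0 + CROP_WIDTH]
    resized = Image.fromarray(px, mode="RGB").resize(
        (WORK_WIDTH, WORK_HEIGHT), resample=Image.BOX
    )
    return RasterImage(np.asarray(resized, dtype=np.uint8), source_id=img.source_id)


def to_hsv(img: RasterImage):
    """RGB -> (hue degrees [0, 360), saturation percent, value percent).

    Achromatic pixels get hue 0.
    """
    hsv = skcolor.rgb2hsv(img.pixels)
    hue = hsv[..., 0] * 360.0
    hue = np.where(hue >= 360.0, 0.0, hue)
    return hue, hsv[..., 1] * 100.0, hsv[..., 2] * 100.0


def channel_fields(img: RasterImage) -> dict:
    """Brightness/saturation/hue fields on [0, 1] for the fractal estimators.

    Hue is treated as a linear (non-circular) field — a documented
    approximation; it only feeds texture-roughness estimates.
    """
    hsv = skcolor.rgb2hsv(img.pixels)
    return {
        "brightness": ChannelField(hsv[..., 2], "brightness"),
        "saturation": ChannelField(hsv[..., 1], "saturation"),
        "hue": ChannelField(hsv[..., 0], "hue"),
    }


def greenery_percentage(img: RasterImage, crit: HSVCriteria | None = None) -> float:
    """Percentage of pixels whose H, S and V all fall inclusively in ``crit``.

    The inclusive comparisons carry a 1e-9 guard band: HSV values of 8-bit
    pixels are rationals spaced at least ~1e-5 apart, so the guard only
    absorbs float rounding and a pixel sitting exactly on a threshold counts
    as inside, as the inclusive contract requires.
    """
    if crit is None:
        crit = HSVCriteria()
    hue, sat, val = to_hsv(img)
    if crit.convention == "native_8bit":
        hue = hue / 2.0  # OpenCV 8-bit hue scale (0-179)
        sat = sat * 255.0 / 100.0
        val = val * 255.0 / 100.0
    eps = 1e-9
    green = (
        (hue >= crit.hue_min - eps)
        & (hue <= crit.hue_max + eps)
        & (sat >= crit.sat_min - eps)
        & (sat <= crit.sat_max + eps)
        & (val >= crit.val_min - eps)
        & (val <= crit.val_max + eps)
    )
    return 100.0 * float(np.count_nonzero(green)) / green.size


def sqrt_transform(pct: float) -> float:
    """Square root of a percentage; the perceptual scale used for greenery."""
    if pct < 0:
        raise ValidationError(f"percentage must be nonnegative, got {pct}")
    return math.sqrt(pct)


def _values(field_or_array) -> np.ndarray:
    if isinstance(field_or_array, ChannelField):
        return field_or_array.values
    return np.asarray(field_or_array, dtype=float)


def mean_channel(field) -> float:
    v = _values(field)
    if v.size == 0:
        raise ValidationError("empty channel field")
    return float(v.mean())


# ---------------------------------------------------------------------------
# box counting


def _block_reduce(arr: np.ndarray, size: int, how: str) -> np.ndarray:
    """Reduce over size x size blocks anchored top-left; partial edge blocks kept."""
    h, w = arr.shape
    ph = (-h) % size
    pw = (-w) % size
    if ph or pw:
        if how == "any":
            arr = np.pad(arr, ((0, ph), (0, pw)), constant_values=False)
        elif how == "max":
            arr = np.pad(arr, ((0, ph), (0, pw)), constant_values=-np.inf)
        else:
            arr = np.pad(arr, ((0, ph), (0, pw)), constant_values=np.inf)
    blocks = arr.reshape(arr.shape[0] // size, size, arr.shape[1] // size, size)
    if how == "any":
        return blocks.any(axis=(1, 3))
    if how == "max":
        return blocks.max(axis=(1, 3))
    return blocks.min(axis=(1, 3))


def _loglog_slope(sizes: Sequence[int], counts: Sequence[float]) -> float:
    """OLS slope of log N versus log(1/eps)."""
    x = -np.log(np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def box_count_dimension(mask: np.ndarray, window: ScaleWindow) -> float:
    """Box-counting dimension of a binary set.

    N(eps) counts eps-boxes containing at least one occupied cell; the
    dimension is the OLS slope of log N versus log(1/eps) over the window.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if not mask.any():
        raise DegenerateInputError("all-empty mask has no box-counting dimension")
    window.validate_for(mask.shape)
    counts = [int(_block_reduce(mask, s, "any").sum()) for s in window.box_sizes]
    return _loglog_slope(window.box_sizes, counts)


def shape_fractal(img: RasterImage, config: ExtractionConfig | None = None) -> float:
    """Box-counting dimension of the brightness edge map, in [0, 2].

    Edges come from a Gaussian-smoothed Sobel gradient with hysteresis
    thresholds set from the gradient distribution (high = the configured
    percentile, low = half of high).  A perfectly uniform image has no edges
    and yields 0 with a warning.
    """
    if config is None:
        config = ExtractionConfig()
    bright = skcolor.rgb2hsv(img.pixels)[..., 2]
    smoothed = gaussian(bright, sigma=config.edge_sigma)
    grad = sobel(smoothed)
    positive = grad[grad > 1e-12]  # flat regions carry no edge information
    if positive.size == 0:
        warnings.warn("uniform image: empty edge map, shape fractal set to 0",
                      DegenerateInputWarning, stacklevel=2)
        return 0.0
    high = float(np.percentile(positive, config.edge_percentile))
    # hysteresis compares strictly; keep pixels sitting exactly at the threshold
    edges = apply_hysteresis_threshold(grad, np.nextafter(high / 2.0, 0.0),
                                       np.nextafter(high, 0.0))
    # thin to one pixel so the box count measures the curve, not its thickness
    edges = skeletonize(edges)
    if not edges.any():
        warnings.warn("empty edge map, shape fractal set to 0",
                      DegenerateInputWarning, stacklevel=2)
        return 0.0
    window = default_scale_windows(edges.shape)["overall"]
    return box_count_dimension(edges, window)


def geometric_fractal(field, window: ScaleWindow) -> float:
    """Box-counting dimension of the field's above-median set.

    A constant field has no median split; it is reported as the plane-filling
    value 2.0 with a warning.
    """
    v = _values(field)
    med = float(np.median(v))
    if v.max() == v.min():
        warnings.warn("constant field: geometric fractal set to 2.0",
                      DegenerateInputWarning, stacklevel=2)
        return 2.0
    occ = v > med
    if not occ.any():
        occ = v >= med
    return box_count_dimension(occ, window)


def statistical_fractal(field, window: ScaleWindow) -> float:
    """Differential box-counting dimension of the intensity surface, in [2, 3].

    For box size eps, each eps x eps spatial cell contributes
    ceil((max - min) / h) + 1 intensity boxes, with box height
    h = eps * range / min(H, W) so the unit intensity range spans the same
    number of boxes as the shorter spatial side.
    """
    v = _values(field)
    h_img, w_img = v.shape
    side = min(h_img, w_img)
    if window.box_sizes[0] > side:
        raise DimensionError("field smaller than the smallest box size")
    window.validate_for(v.shape)
    counts = []
    for s in window.box_sizes:
        h_box = s / side  # intensity range is the unit interval
        mx = _block_reduce(v, s, "max")
        mn = _block_reduce(v, s, "min")
        n_cell = np.ceil((mx - mn) / h_box) + 1.0
        counts.append(float(n_cell.sum()))
    return _loglog_slope(window.box_sizes, counts)


def color_fractal(img: RasterImage, window: ScaleWindow | None = None) -> float:
    """Box-counting dimension in the joint (x, y, R, G, B) space, in [2, 5].

    Spatial boxes of edge eps pair with color boxes of edge 256 * eps/min(H, W),
    so both axes shrink at the same relative rate; N(eps) is the number of
    occupied 5-D boxes.

    The default ladder uses coarse relative sizes (1/8, 1/4, 1/2 of the short
    side): the 5-D box population grows as (S/eps)^5, so finer boxes would
    outnumber the pixels and the count would saturate at the sample size
    instead of tracking the color-space geometry.
    """
    px = img.pixels
    h_img, w_img = px.shape[:2]
    side = min(h_img, w_img)
    if window is None:
        window = ScaleWindow((side // 8, side // 4, side // 2), "overall")
    window.validate_for(px.shape)
    ys, xs = np.mgrid[0:h_img, 0:w_img]
    rgb = px.reshape(-1, 3).astype(np.int64)
    ys = ys.ravel()
    xs = xs.ravel()
    counts = []
    for s in window.box_sizes:
        c_edge = 256.0 * s / side
        yb = ys // s
        xb = xs // s
        cb = np.floor(rgb / c_edge).astype(np.int64)
        n_spatial_x = w_img // s + (1 if w_img % s else 0)
        n_color = int(255 // c_edge) + 1
        key = yb * n_spatial_x + xb
        for ch in range(3):
            key = key * n_color + cb[:, ch]
        counts.append(len(np.unique(key)))
    return _loglog_slope(window.box_sizes, counts)


# ---------------------------------------------------------------------------
# spectral fluctuation


def _radial_spectrum(v: np.ndarray, n_bins: int):
    """Radially averaged power spectrum over log-spaced frequency bins.

    The fit band runs from the second radial bin (2 / min(H, W) cycles/pixel)
    to half the Nyquist frequency (0.25), avoiding DC leakage and the
    pixel-grid aliased octave.
    """
    h_img, w_img = v.shape
    spec = np.abs(np.fft.fft2(v - v.mean())) ** 2
    fy = np.fft.fftfreq(h_img)[:, None]
    fx = np.fft.fftfreq(w_img)[None, :]
    f = np.sqrt(fx * fx + fy * fy)
    f_lo = 2.0 / min(h_img, w_img)
    f_hi = 0.25
    edges = np.geomspace(f_lo, f_hi, n_bins + 1)
    fr = f.ravel()
    pr = spec.ravel()
    sel = (fr >= edges[0]) & (fr <= edges[-1])
    idx = np.clip(np.searchsorted(edges, fr[sel], side="right") - 1, 0, n_bins - 1)
    power_sum = np.bincount(idx, weights=pr[sel], minlength=n_bins)
    n = np.bincount(idx, minlength=n_bins)
    keep = n > 0
    centers = np.sqrt(edges[:-1] * edges[1:])
    return centers[keep], power_sum[keep] / n[keep]


def one_over_f_fluctuation(field, n_bins: int = 16) -> float:
    """Amplitude-spectrum exponent from the radially averaged power spectrum.

    The power-spectrum slope beta is halved so that pink (1/f amplitude)
    structure maps to 1; white noise maps to 0.
    """
    v = _values(field)
    if v.shape[0] < 32 or v.shape[1] < 32:
        raise DimensionError("field must be at least 32 x 32 for a spectral fit")
    if v.max() == v.min():
        raise DegenerateInputError("constant field has an undefined spectrum")
    freqs, power = _radial_spectrum(v, n_bins)
    if len(freqs) < 3 or np.any(power <= 0):
        raise DegenerateInputError("spectrum too sparse for a log-log fit")
    x = np.log(freqs)
    y = np.log(power)
    xc = x - x.mean()
    slope = float((xc @ (y - y.mean())) / (xc @ xc))
    return -slope / 2.0


# ---------------------------------------------------------------------------
# full catalogue


def extract_features(img: RasterImage, config: ExtractionConfig | None = None) -> VisualFeatureVector:
    """Run the full 19-indicator catalogue on one photograph.

    Deterministic given image and config.  Degenerate-input warnings from the
    individual estimators are collected into ``flags`` rather than raised.
    """
    if config is None:
        config = ExtractionConfig()
    if config.preprocess:
        img = preprocess(img, crop=config.crop)
    flags: list = []

    def run(name, fn, *args, **kwargs):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DegenerateInputWarning)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # re-raise with the feature name attached
                raise type(exc)(f"{name}: {exc}") from exc
        flags.extend(f"{name}: {w.message}" for w in caught
                     if issubclass(w.category, DegenerateInputWarning))
        return out

    pct = greenery_percentage(img, config.criteria)
    fields = channel_fields(img)
    windows = default_scale_windows(img.pixels.shape)

    values = {
        "greenery_pct": pct,
        "sqrt_greenery": sqrt_transform(pct),
        "mean_brightness": mean_channel(fields["brightness"]),
        "mean_saturation": mean_channel(fields["saturation"]),
        "shape_fractal": run("shape_fractal", shape_fractal, img, config),
        "color_fractal": run("color_fractal", color_fractal, img),
    }
    for label in ("small", "large", "overall"):
        values[f"geom_fractal_brightness_{label}"] = run(
            f"geom_fractal_brightness_{label}",
            geometric_fractal, fields["brightness"], windows[label])
    for chan in ("brightness", "saturation", "hue"):
        for label in ("small", "large", "overall"):
            values[f"stat_fractal_{chan}_{label}"] = run(
                f"stat_fractal_{chan}_{label}",
                statistical_fractal, fields[chan], windows[label])
    for chan in ("brightness", "saturation"):
        name = f"one_over_f_{chan}"
        try:
            values[name] = run(name, one_over_f_fluctuation, fields[chan], config.fft_n_bins)
        except DegenerateInputError as exc:
            flags.append(f"{name}: {exc}")
            values[name] = 0.0
    return VisualFeatureVector(source_id=img.source_id, flags=tuple(flags), **values)


def feature_frame(vectors: Sequence[VisualFeatureVector]):
    """Stack feature vectors into a DataFrame indexed by source_id."""
    import pandas as pd

    rows = []
    for vec in vectors:
        row = {"source_id": vec.source_id, **vec.as_dict(), "greenery_pct": vec.greenery_pct}
        rows.append(row)
    return pd.DataFrame(rows).set_index("source_id")
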