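"""The six haze-related image features and the Beer-Lambert distance fit.

A hazy photograph follows the atmospheric scattering model

    I(x) = t(x) J(x) + (1 - t(x)) A

where J is the clean scene radiance, A the airlight color and
t = exp(-beta d) the transmission over the camera-to-object distance d
(Beer-Lambert, extinction coefficient beta).  The dark-channel prior —
outdoor haze-free patches contain some pixel with near-zero intensity in at
least one channel — lets t be estimated from a single image:

    t~(x) = 1 - min_{y in Omega(x)} min_c I_c(y) / A_c

The scalar features fed to the regressor are the mean of t~ over non-sky
pixels, the RMS contrast of the most distant ROI, whole-image RMS contrast,
image entropy, the mean gradient amplitude of the sky (smoothness) and the
mean blue value of the sky, plus the solar zenith angle and relative
humidity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from hazepm.io_dataset import ROIBox, SampleRecord, load_image
from hazepm.preprocess import SkyMask, quantize, segment_sky, strip_watermark, to_gray
from hazepm.solar_position import solar_geometry

#: Table-style feature names, in canonical order.
FEATURE_NAMES = (
    "Transmission",
    "ROI contrast",
    "Image entropy",
    "Image contrast",
    "Sky smoothness",
    "Sky color",
    "Solar zenith angle",
    "humidity",
)


@dataclass(frozen=True)
class Airlight:
    """Per-channel airlight intensity, each in (0, 1]."""

    a_r: float
    a_g: float
    a_b: float

    def __post_init__(self) -> None:
        for c in (self.a_r, self.a_g, self.a_b):
            if not 0.0 < c <= 1.0:
                raise ValueError(f"airlight component {c} outside (0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_r, self.a_g, self.a_b])


@dataclass
class TransmissionMap:
    """Estimated transmission t~ per pixel, clipped to [0, 1]."""

    values: np.ndarray
    patch_size: int


@dataclass(frozen=True)
class ExtinctionFit:
    """Semilog least-squares fit of ROI transmission against distance."""

    beta: float              # extinction coefficient, 1/m (= -slope)
    intercept: float         # ln t at d = 0
    r2_loglinear: float      # R^2 of the ln(t)-vs-d regression


@dataclass
class FeatureVector:
    """The covariate row for one sample; missing entries are NaN."""

    transmission: float
    roi_contrast: float
    image_entropy: float
    image_contrast: float
    sky_smoothness: float
    sky_color: float
    solar_zenith: float
    humidity: float = math.nan

    def as_array(self, include_humidity: bool = True) -> np.ndarray:
        vals = [
            self.transmission,
            self.roi_contrast,
            self.image_entropy,
            self.image_contrast,
            self.sky_smoothness,
            self.sky_color,
            self.solar_zenith,
        ]
        if include_humidity:
            vals.append(self.humidity)
        return np.array(vals)


@dataclass
class FeatureConfig:
    """Tunable constants of the feature-extraction stage."""

    patch_size: int = 15                 # dark-channel window Omega
    entropy_bins: int = 256
    airlight_quantile: float = 0.001     # brightest fraction of dark-channel pixels
    sky_coverage_min: float = 0.02       # below this, airlight falls back to whole image
    airlight_floor: float = 0.05         # per-channel lower bound
    watermark_top: int = 0
    watermark_bottom: int = 0
    watermark_auto: bool = False
    min_nonsky_fraction: float = 0.01    # below this, transmission averages all pixels


def dark_channel(img: np.ndarray, patch_size: int = 15) -> np.ndarray:
    """Dark channel: min over channels, then min over the patch window.

    The window is ``patch_size`` x ``patch_size``, centered, edge-clamped.
    """
    if patch_size < 1 or patch_size % 2 == 0:
        raise ValueError(f"patch_size must be odd and >= 1, got {patch_size}")
    min_channel = img.min(axis=-1)
    return ndimage.minimum_filter(min_channel, size=patch_size, mode="nearest")


def estimate_airlight(
    img: np.ndarray,
    dark: np.ndarray,
    sky: SkyMask | None = None,
    *,
    quantile: float = 0.001,
    sky_coverage_min: float = 0.02,
    floor: float = 0.05,
) -> Airlight:
    """Airlight from the brightest dark-channel pixels.

    Pixels are ranked by dark-channel value; the brightest ``quantile``
    fraction (at least one pixel) is selected, restricted to the sky mask
    when it covers at least ``sky_coverage_min`` of the image, otherwise
    over the whole image.  The airlight is the per-channel mean of the
    selection, floored at ``floor`` per channel.
    """
    if img.max() <= 0:
        raise ValueError("all-zero image: airlight undefined")
    flat_img = img.reshape(-1, 3)
    flat_dark = dark.ravel()
    if sky is not None and sky.coverage >= sky_coverage_min:
        idx = np.flatnonzero(sky.values.ravel())
    else:
        idx = np.arange(flat_dark.size)
    k = max(1, int(round(quantile * idx.size)))
    order = np.argsort(flat_dark[idx], kind="stable")
    chosen = idx[order[-k:]]
    a = flat_img[chosen].mean(axis=0)
    a = np.maximum(a, floor)
    return Airlight(*np.minimum(a, 1.0))


def transmission_map(img: np.ndarray, airlight: Airlight, patch_size: int = 15) -> TransmissionMap:
    """Transmission estimate t~ = 1 - dark_channel(I / A), clipped to [0, 1]."""
    a = airlight.as_array()
    normalized = img / a
    t = 1.0 - dark_channel(normalized, patch_size)
    return TransmissionMap(np.clip(t, 0.0, 1.0), patch_size)


def roi_transmissions(tmap: TransmissionMap, rois: Sequence[ROIBox]) -> list[float]:
    """Mean transmission inside each ROI box, in list order."""
    h, w = tmap.values.shape
    out = []
    for box in rois:
        box.check_within(h, w)
        region = tmap.values[box.slice()]
        if region.size == 0:
            raise ValueError(f"empty ROI box {box}")
        out.append(float(region.mean()))
    return out


def fit_extinction(
    transmissions: Sequence[float], distances: Sequence[float]
) -> ExtinctionFit:
    """Least-squares fit of ln(t) on distance; beta = -slope.

    Non-positive transmissions are excluded (they have no logarithm); at
    least two usable (t, d) points with distinct distances are required.
    """
    t = np.asarray(transmissions, dtype=float)
    d = np.asarray(distances, dtype=float)
    if t.shape != d.shape:
        raise ValueError("transmissions and distances must have equal length")
    usable = t > 0
    t, d = t[usable], d[usable]
    if t.size < 2 or np.unique(d).size < 2:
        raise ValueError("need >= 2 positive transmissions at distinct distances")
    logt = np.log(t)
    slope, intercept = np.polyfit(d, logt, 1)
    fitted = slope * d + intercept
    ss_res = float(np.sum((logt - fitted) ** 2))
    ss_tot = float(np.sum((logt - logt.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ExtinctionFit(beta=-float(slope), intercept=float(intercept), r2_loglinear=r2)


def rms_contrast(gray: np.ndarray) -> float:
    """RMS contrast: population standard deviation of the intensities."""
    if gray.size == 0:
        raise ValueError("empty image")
    return float(gray.std())


def image_entropy(gray: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the quantized intensity histogram."""
    if gray.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(quantize(gray, bins).ravel(), minlength=bins)
    p = counts[counts > 0] / gray.size
    return float(-np.sum(p * np.log2(p)))


def sky_color(img: np.ndarray, sky: SkyMask) -> float:
    """Mean blue-channel value over sky pixels; NaN for an empty mask."""
    if not sky.values.any():
        return math.nan
    return float(img[..., 2][sky.values].mean())


def sky_smoothness(gray: np.ndarray, sky: SkyMask) -> float:
    """Mean gradient amplitude over sky pixels with a fully-sky stencil.

    Gradients are central differences (one-sided at image borders), so a
    pixel counts only when every neighbor its difference stencil touches is
    also sky.  Returns NaN when no such pixel exists.
    """
    if not sky.values.any():
        return math.nan
    gy, gx = np.gradient(gray)
    amplitude = np.sqrt(gx**2 + gy**2)
    valid = _stencil_inside(sky.values)
    if not valid.any():
        return math.nan
    return float(amplitude[valid].mean())


def _stencil_inside(mask: np.ndarray) -> np.ndarray:
    """Pixels whose np.gradient stencil (row and column neighbors) is in-mask."""
    h, w = mask.shape
    valid = mask.copy()
    up = np.roll(mask, 1, axis=0)
    up[0] = True                      # top row uses a one-sided stencil downward
    down = np.roll(mask, -1, axis=0)
    down[-1] = True
    left = np.roll(mask, 1, axis=1)
    left[:, 0] = True
    right = np.roll(mask, -1, axis=1)
    right[:, -1] = True
    return valid & up & down & left & right


def extract_features(
    sample: SampleRecord,
    rois: Sequence[ROIBox],
    config: FeatureConfig | None = None,
    *,
    image: np.ndarray | None = None,
    sky_mask: SkyMask | None = None,
) -> FeatureVector:
    """Run the full feature pipeline for one sample.

    ``image`` may be supplied to skip disk I/O; ``sky_mask`` overrides
    per-image segmentation with a fixed scene-level mask (useful for fixed
    cameras, where the skyline does not move between frames).
    """
    cfg = config or FeatureConfig()
    img = image if image is not None else load_image(sample.image_path)
    try:
        if cfg.watermark_auto or cfg.watermark_top or cfg.watermark_bottom:
            img = strip_watermark(
                img, cfg.watermark_top, cfg.watermark_bottom, auto=cfg.watermark_auto
            )
        sky = sky_mask if sky_mask is not None else segment_sky(img)
        gray = to_gray(img)
        dark = dark_channel(img, cfg.patch_size)
        airlight = estimate_airlight(
            img,
            dark,
            sky,
            quantile=cfg.airlight_quantile,
            sky_coverage_min=cfg.sky_coverage_min,
            floor=cfg.airlight_floor,
        )
        tmap = transmission_map(img, airlight, cfg.patch_size)

        non_sky = ~sky.values
        if non_sky.mean() < cfg.min_nonsky_fraction:
            transmission = float(tmap.values.mean())
        else:
            transmission = float(tmap.values[non_sky].mean())

        if rois:
            far = max(
                rois,
                key=lambda b: b.distance if not math.isnan(b.distance) else -math.inf,
            )
            far.check_within(*gray.shape)
            roi_c = rms_contrast(gray[far.slice()])
        else:
            roi_c = math.nan

        return FeatureVector(
            transmission=transmission,
            roi_contrast=roi_c,
            image_entropy=image_entropy(gray, cfg.entropy_bins),
            image_contrast=rms_contrast(gray),
            sky_smoothness=sky_smoothness(gray, sky),
            sky_color=sky_color(img, sky),
            solar_zenith=solar_geometry(
                sample.timestamp_utc, sample.longitude, sample.latitude
            ).zenith,
            humidity=sample.humidity,
        )
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed for {sample.image_path}: {exc}") from exc


def feature_table(
    samples: Sequence[SampleRecord],
    rois: Sequence[ROIBox],
    config: FeatureConfig | None = None,
):
    """Extract features for many samples into a pandas DataFrame.

    Columns follow :data:`FEATURE_NAMES` plus ``pm25``.
    """
    import pandas as pd

    rows = []
    for s in samples:
        fv = extract_features(s, rois, config)
        rows.append(list(fv.as_array()) + [s.pm25])
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["pm25"])
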