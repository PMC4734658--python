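"""Synthetic hazy-scene rendering with known ground truth.

Images are rendered from the same forward model the estimator inverts:
I = t J + (1 - t) A with t = exp(-beta d).  The scene is a fixed skyline:
a sky band (depth -> infinity, so sky renders exactly as the airlight) over
a row of textured building blocks at strictly increasing distances.  With
``dark_anchor`` enabled, every building pixel has zero reflectance in its
minimum channel (buildings with no blue reflectance), so the dark-channel
prior holds exactly in every window and transmission recovery is well-posed;
disabling it gives strictly positive reflectance floors for robustness
experiments.

The generator draws PM values, maps them to extinction via
beta = beta_per_pm * PM (optionally inflated by relative humidity, mimicking
hygroscopic particle growth), renders each image, and emits a manifest in
the same dialect the I/O module reads, so the whole pipeline runs without
any real photo archive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from hazepm.io_dataset import (
    DatasetManifest,
    ROIBox,
    SampleRecord,
    save_image,
    save_manifest,
    save_roi_config,
)
from hazepm.preprocess import SkyMask

#: City-like presets for synthetic manifests: (longitude, latitude, altitude,
#: capture hour in UTC).  The capture hour approximates a fixed local
#: morning shot.
CITY_PRESETS = {
    "beijing": (116.46, 39.92, 50.0, 1),
    "shanghai": (121.48, 31.24, 5.0, 2),
    "phoenix": (-112.07, 33.45, 340.0, 17),
}


@dataclass
class SceneSpec:
    """Geometry and radiometry of the fixed synthetic scene."""

    width: int = 240
    height: int = 160
    sky_fraction: float = 0.45
    block_distances: tuple[float, ...] = (500.0, 1500.0, 2800.0, 4000.0)
    airlight: tuple[float, float, float] = (0.78, 0.84, 0.92)
    dark_anchor: bool = True
    #: Per-block reflectance (lo, hi); brighter with distance so the blocks'
    #: intensity ranges stay disjoint under any amount of haze (the farther
    #: block contracts toward the airlight faster, so a range that starts
    #: above a nearer one never crosses it).
    block_reflectance: tuple[tuple[float, float], ...] = (
        (0.03, 0.14),
        (0.17, 0.28),
        (0.31, 0.42),
        (0.45, 0.56),
    )
    cloud_amplitude: float = 0.0
    sky_gradient: float = 0.0       # blue-channel drop from zenith row to horizon
    noise_sd: float = 0.0
    texture_seed: int = 12345

    def __post_init__(self) -> None:
        if not 0.2 <= self.sky_fraction <= 0.8:
            raise ValueError("sky_fraction must lie in [0.2, 0.8]")
        d = self.block_distances
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("block_distances must be strictly increasing")
        if not all(0.0 < a <= 1.0 for a in self.airlight):
            raise ValueError("airlight components must lie in (0, 1]")
        if len(self.block_reflectance) != len(d):
            raise ValueError("block_reflectance must have one (lo, hi) pair per block")
        if not all(0.0 <= lo < hi <= 1.0 for lo, hi in self.block_reflectance):
            raise ValueError("block reflectance pairs must satisfy 0 <= lo < hi <= 1")

    @property
    def sky_rows(self) -> int:
        return int(round(self.sky_fraction * self.height))

    @property
    def n_blocks(self) -> int:
        return len(self.block_distances)

    def block_columns(self) -> list[tuple[int, int]]:
        """Half-open column spans of the building blocks (left to right)."""
        edges = np.linspace(0, self.width, self.n_blocks + 1).astype(int)
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def depth_map(self) -> np.ndarray:
        """Per-pixel distance in meters; sky rows are infinite."""
        depth = np.full((self.height, self.width), np.inf)
        for (c0, c1), dist in zip(self.block_columns(), self.block_distances):
            depth[self.sky_rows :, c0:c1] = dist
        return depth

    def clean_radiance(self) -> np.ndarray:
        """Deterministic textured scene radiance J (sky rows hold airlight)."""
        rng = np.random.default_rng(self.texture_seed)
        j = np.empty((self.height, self.width, 3))
        j[: self.sky_rows] = np.asarray(self.airlight)
        ground_rows = self.height - self.sky_rows
        for (c0, c1), (lo, hi) in zip(self.block_columns(), self.block_reflectance):
            block = rng.uniform(lo, hi, size=(ground_rows, c1 - c0, 3))
            if self.dark_anchor:
                # Buildings with zero blue reflectance: every pixel's minimum
                # channel is 0, so every dark-channel window sees a zero and
                # the prior is exact (and the block luma range, 0.886*[lo,hi],
                # keeps the blocks' disjoint-brightness ordering).
                block[..., 2] = 0.0
            j[self.sky_rows :, c0:c1] = block
        return j

    def true_sky_mask(self) -> SkyMask:
        mask = np.zeros((self.height, self.width), dtype=bool)
        mask[: self.sky_rows] = True
        return SkyMask(mask)

    def roi_boxes(self, inset: int = 8, top_margin: int = 8, bottom_margin: int = 8) -> list[ROIBox]:
        """One ROI per building block, inset so dark-channel windows stay inside."""
        top = self.sky_rows + top_margin
        bottom = self.height - bottom_margin
        boxes = []
        for (c0, c1), dist in zip(self.block_columns(), self.block_distances):
            boxes.append(ROIBox(top, c0 + inset, bottom, c1 - inset, dist))
        return boxes


@dataclass
class SynthDatasetSpec:
    """Study conditions for a generated dataset."""

    n_images: int = 200
    pm_range: tuple[float, float] = (0.0, 300.0)
    beta_per_pm: float = 2.5e-6     # extinction (1/m) per PM index unit
    seed: int = 0
    humidity_effect: float | None = None
    humidity_range: tuple[float, float] = (0.3, 0.9)
    city: str = "beijing"
    start_date: tuple[int, int, int] = (2014, 1, 1)

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.beta_per_pm <= 0:
            raise ValueError("beta_per_pm must be > 0")
        if self.city not in CITY_PRESETS:
            raise ValueError(f"unknown city preset {self.city!r}")

    def beta_for(self, pm: float, humidity: float) -> float:
        beta = self.beta_per_pm * pm
        if self.humidity_effect is not None:
            beta *= 1.0 + self.humidity_effect * humidity
        return beta


def render(
    spec: SceneSpec, beta: float, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render one hazy image; returns (image, true transmission map).

    Transmission is t = exp(-beta * depth) per pixel (0 for sky).  The sky
    is airlight plus the optional vertical blue gradient and band-limited
    cloud texture; Gaussian pixel noise of sd ``noise_sd`` is added last and
    the image clipped to [0, 1].
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    depth = spec.depth_map()
    # Sky depth is infinite, so sky transmission is 0 for every beta
    # (including beta = 0, where 0 * inf would otherwise be NaN).
    t = np.zeros_like(depth)
    finite = np.isfinite(depth)
    t[finite] = np.exp(-beta * depth[finite])
    j = spec.clean_radiance()
    a = np.asarray(spec.airlight)
    img = t[..., None] * j + (1.0 - t[..., None]) * a

    sky_rows = spec.sky_rows
    if spec.sky_gradient > 0 and sky_rows > 1:
        ramp = np.linspace(0.0, spec.sky_gradient, sky_rows)
        img[:sky_rows, :, 2] -= ramp[:, None]
    if spec.cloud_amplitude > 0 and sky_rows > 0:
        crng = np.random.default_rng(spec.texture_seed + 1)
        field_ = ndimage.gaussian_filter(
            crng.standard_normal((sky_rows, spec.width)), sigma=4.0
        )
        field_ /= max(np.abs(field_).max(), 1e-12)
        img[:sky_rows] += (spec.cloud_amplitude * field_)[..., None]
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), t


def render_dataset(
    dspec: SynthDatasetSpec, scene: SceneSpec
) -> tuple[list[SampleRecord], list[np.ndarray], list[ROIBox]]:
    """Draw PM/humidity values and render the whole dataset in memory.

    Returns (records, images, rois); ``image_path`` fields are synthetic
    names (``img_00000.png`` ...) that :func:`generate_dataset` materializes.
    """
    rng = np.random.default_rng(dspec.seed)
    lon, lat, alt, hour_utc = CITY_PRESETS[dspec.city]
    start = datetime(*dspec.start_date, hour_utc, tzinfo=timezone.utc)
    pms = rng.uniform(*dspec.pm_range, size=dspec.n_images)
    hums = rng.uniform(*dspec.humidity_range, size=dspec.n_images)
    jitter = rng.integers(0, 30, size=dspec.n_images)  # minutes
    records: list[SampleRecord] = []
    images: list[np.ndarray] = []
    for i in range(dspec.n_images):
        beta = dspec.beta_for(pms[i], hums[i])
        img, _ = render(scene, beta, rng=np.random.default_rng([dspec.seed, i]))
        ts = start + timedelta(days=int(i), minutes=int(jitter[i]))
        records.append(
            SampleRecord(
                image_path=f"img_{i:05d}.png",
                timestamp_utc=ts,
                longitude=lon,
                latitude=lat,
                altitude=alt,
                pm25=float(pms[i]),
                weather_class="cloudy" if hums[i] > 0.6 else "clear",
                humidity=float(hums[i]),
            )
        )
        images.append(img)
    return records, images, scene.roi_boxes()


def generate_dataset(
    dspec: SynthDatasetSpec, scene: SceneSpec, out_dir: str | Path
) -> DatasetManifest:
    """Render the dataset to ``out_dir``: PNG images, manifest.csv, rois.cfg."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, images, rois = render_dataset(dspec, scene)
    resolved = []
    for rec, img in zip(records, images):
        path = out / rec.image_path
        save_image(img, path)
        resolved.append(
            SampleRecord(
                image_path=str(path),
                timestamp_utc=rec.timestamp_utc,
                longitude=rec.longitude,
                latitude=rec.latitude,
                altitude=rec.altitude,
                pm25=rec.pm25,
                weather_class=rec.weather_class,
                humidity=rec.humidity,
            )
        )
    manifest = DatasetManifest(records=resolved, rois=rois, scene_id=f"synthetic-{dspec.city}")
    save_manifest(manifest, out / "manifest.csv")
    save_roi_config(rois, out / "rois.cfg", scene_id=manifest.scene_id)
    return manifest
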