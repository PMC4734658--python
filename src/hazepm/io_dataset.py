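"""Dataset I/O: sample manifests, ROI configuration and image loading.

A dataset is a fixed outdoor scene photographed repeatedly.  Each sample is
one photograph plus the metadata the regression needs: capture time (UTC),
camera position, the reported PM2.5 index, a coarse weather class and
relative humidity.  ROI boxes are drawn once for the scene and shared by
every sample; each box may carry the distance from the camera to the
building it frames, which the Beer-Lambert fit uses.
"""

from __future__ import annotations

import configparser
import csv
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

WEATHER_CLASSES = ("clear", "cloudy", "other", "unknown")

MANIFEST_COLUMNS = (
    "image_path",
    "timestamp_utc",
    "longitude",
    "latitude",
    "altitude",
    "pm25",
    "weather_class",
    "humidity",
)


class ManifestFormatError(ValueError):
    """The manifest file as a whole is malformed (missing columns, empty)."""


class ManifestRowError(ValueError):
    """A single manifest row failed validation; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"manifest line {line}: {message}")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one photograph of the scene.

    ``pm25`` may be NaN for prediction-only samples; ``humidity`` is a
    relative-humidity fraction in [0, 1] and may be NaN when unrecorded.
    """

    image_path: str
    timestamp_utc: datetime
    longitude: float
    latitude: float
    altitude: float
    pm25: float = math.nan
    weather_class: str = "unknown"
    humidity: float = math.nan

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.timestamp_utc.tzinfo is None:
            raise ValueError("timestamp_utc must be timezone-aware")
        if not math.isnan(self.pm25) and self.pm25 < 0:
            raise ValueError(f"pm25 {self.pm25} must be >= 0")
        if not math.isnan(self.humidity) and not 0.0 <= self.humidity <= 1.0:
            raise ValueError(f"humidity {self.humidity} outside [0, 1]")
        if self.weather_class not in WEATHER_CLASSES:
            raise ValueError(f"weather_class {self.weather_class!r} not one of {WEATHER_CLASSES}")


@dataclass(frozen=True)
class ROIBox:
    """Rectangular region of interest, 0-based, half-open [top,bottom) x [left,right).

    ``distance`` is the camera-to-building distance in meters (NaN if unknown).
    """

    top: int
    left: int
    bottom: int
    right: int
    distance: float = math.nan

    def __post_init__(self) -> None:
        if self.bottom <= self.top or self.right <= self.left:
            raise ValueError("ROI box must satisfy bottom > top and right > left")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI box indices must be non-negative")
        if not math.isnan(self.distance) and self.distance <= 0:
            raise ValueError("ROI distance must be > 0 when given")

    def slice(self) -> tuple[slice, slice]:
        return slice(self.top, self.bottom), slice(self.left, self.right)

    def check_within(self, height: int, width: int) -> None:
        if self.bottom > height or self.right > width:
            raise ValueError(
                f"ROI box {self} exceeds image bounds {height}x{width}"
            )


@dataclass
class DatasetManifest:
    """Ordered samples of one fixed scene plus the shared ROI boxes."""

    records: list[SampleRecord]
    rois: list[ROIBox] = field(default_factory=list)
    scene_id: str = "scene"

    def __post_init__(self) -> None:
        dists = [b.distance for b in self.rois if not math.isnan(b.distance)]
        if any(d2 <= d1 for d1, d2 in zip(dists, dists[1:])):
            raise ValueError("ROI distances must be strictly increasing in list order")

    def __len__(self) -> int:
        return len(self.records)


def _parse_timestamp(text: str) -> datetime:
    ts = datetime.fromisoformat(text.strip().replace("Z", "+00:00"))
    if ts.tzinfo is None:
        raise ValueError(f"timestamp {text!r} has no UTC offset")
    return ts.astimezone(timezone.utc)


def _parse_float(text: str, default: float = math.nan) -> float:
    text = text.strip()
    if text == "" or text.lower() in ("nan", "na", "none"):
        return default
    return float(text)


def load_manifest(path: str | Path, rois: Sequence[ROIBox] = (), scene_id: str = "scene") -> DatasetManifest:
    """Read a CSV manifest into a validated :class:`DatasetManifest`.

    The CSV must have a header naming the :data:`MANIFEST_COLUMNS`;
    ``pm25``/``humidity`` cells may be empty.  Malformed rows raise
    :class:`ManifestRowError` with their line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ManifestFormatError(f"{path}: empty manifest")
        missing = set(MANIFEST_COLUMNS[:5]) - set(reader.fieldnames)
        if missing:
            raise ManifestFormatError(f"{path}: missing required columns {sorted(missing)}")
        records: list[SampleRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    SampleRecord(
                        image_path=row["image_path"].strip(),
                        timestamp_utc=_parse_timestamp(row["timestamp_utc"]),
                        longitude=float(row["longitude"]),
                        latitude=float(row["latitude"]),
                        altitude=float(row["altitude"]),
                        pm25=_parse_float(row.get("pm25", "")),
                        weather_class=(row.get("weather_class") or "unknown").strip() or "unknown",
                        humidity=_parse_float(row.get("humidity", "")),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ManifestRowError(lineno, str(exc)) from exc
    if not records:
        raise ManifestFormatError(f"{path}: manifest contains no rows")
    return DatasetManifest(records=records, rois=list(rois), scene_id=scene_id)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write the manifest back to CSV (ISO-8601 UTC timestamps, repr floats)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in manifest.records:
            writer.writerow(
                [
                    rec.image_path,
                    rec.timestamp_utc.astimezone(timezone.utc).isoformat(),
                    repr(rec.longitude),
                    repr(rec.latitude),
                    repr(rec.altitude),
                    "" if math.isnan(rec.pm25) else repr(rec.pm25),
                    rec.weather_class,
                    "" if math.isnan(rec.humidity) else repr(rec.humidity),
                ]
            )


def load_roi_config(path: str | Path) -> tuple[list[ROIBox], str]:
    """Read ROI boxes from a key-value config file.

    Format::

        [scene]
        scene_id = beijing_tower

        [rois]
        roi1 = top,left,bottom,right,distance
        roi2 = ...

    ``distance`` may be omitted or empty.  Returns (boxes, scene_id).
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    scene_id = parser.get("scene", "scene_id", fallback="scene")
    boxes: list[ROIBox] = []
    if parser.has_section("rois"):
        for _, value in parser.items("rois"):
            parts = [p.strip() for p in value.split(",")]
            if len(parts) not in (4, 5):
                raise ValueError(f"ROI entry {value!r}: expected top,left,bottom,right[,distance]")
            top, left, bottom, right = (int(p) for p in parts[:4])
            distance = _parse_float(parts[4]) if len(parts) == 5 else math.nan
            boxes.append(ROIBox(top, left, bottom, right, distance))
    return boxes, scene_id


def save_roi_config(boxes: Sequence[ROIBox], path: str | Path, scene_id: str = "scene") -> None:
    parser = configparser.ConfigParser()
    parser["scene"] = {"scene_id": scene_id}
    parser["rois"] = {
        f"roi{i + 1}": f"{b.top},{b.left},{b.bottom},{b.right},"
        + ("" if math.isnan(b.distance) else repr(b.distance))
        for i, b in enumerate(boxes)
    }
    with open(path, "w") as fh:
        parser.write(fh)


def load_image(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG as an H x W x 3 float array in [0, 1].

    8-bit values are divided by 255; grayscale images are replicated to
    three channels.
    """
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return arr


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a float [0,1] RGB array as an 8-bit PNG (round-to-nearest)."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    data = np.rint(arr * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="RGB").save(path)
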