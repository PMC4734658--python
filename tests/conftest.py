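"""Shared fixtures: a default synthetic scene and cached feature tables.

Feature extraction over a rendered dataset is the expensive step, so the
tables used by the regression-level tests are computed once per session.
"""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from hazepm.haze_features import FEATURE_NAMES, extract_features
from hazepm.io_dataset import SampleRecord
from hazepm.synth_scene import SceneSpec, SynthDatasetSpec, render_dataset


def extract_table(dspec: SynthDatasetSpec, scene: SceneSpec) -> pd.DataFrame:
    """Render a dataset in memory and extract the full feature table."""
    records, images, rois = render_dataset(dspec, scene)
    rows = []
    for rec, img in zip(records, images):
        fv = extract_features(rec, rois, image=img)
        rows.append(list(fv.as_array()) + [rec.pm25])
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["pm25"])


@pytest.fixture(scope="session")
def default_scene() -> SceneSpec:
    return SceneSpec()


@pytest.fixture(scope="session")
def sample_record() -> SampleRecord:
    return SampleRecord(
        image_path="synthetic.png",
        timestamp_utc=datetime(2014, 6, 1, 1, 0, tzinfo=timezone.utc),
        longitude=116.46,
        latitude=39.92,
        altitude=50.0,
        pm25=80.0,
        weather_class="clear",
        humidity=0.5,
    )


@pytest.fixture(scope="session")
def synth_features() -> pd.DataFrame:
    """Feature table of the standard 200-image noisy synthetic dataset."""
    return extract_table(
        SynthDatasetSpec(n_images=200, seed=1),
        SceneSpec(noise_sd=0.01),
    )


@pytest.fixture(scope="session")
def humid_features() -> pd.DataFrame:
    """Feature table of a dataset whose extinction is inflated by humidity."""
    return extract_table(
        SynthDatasetSpec(n_images=150, seed=2, humidity_effect=1.0),
        SceneSpec(noise_sd=0.01),
    )


def feature_matrix(df: pd.DataFrame, with_humidity: bool = False):
    cols = list(FEATURE_NAMES) if with_humidity else list(FEATURE_NAMES[:-1])
    return df[cols].to_numpy(dtype=float), df["pm25"].to_numpy(dtype=float), cols
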