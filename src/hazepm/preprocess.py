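"""Preprocessing: watermark removal, grayscale conversion and sky segmentation.

Webcam frames usually carry a timestamp watermark rendered in white in the
first or last few rows; those rows are cropped before any feature is
computed.  The sky mask is produced by Otsu thresholding of the grayscale
image (sky is the bright class in these scenes), cleaned with a
morphological opening and hole filling, and restricted to connected
components that touch the top image row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

#: Luma weights (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateInputError(ValueError):
    pass


@dataclass
class SkyMask:
    """Boolean sky mask (True = sky) plus bookkeeping.

    ``empty_warning`` is set when no component touched the top row, in which
    case the mask is all False rather than an exception: downstream sky
    features return missing values.
    """

    values: np.ndarray
    empty_warning: bool = False

    @property
    def coverage(self) -> float:
        return float(self.values.mean())


def strip_watermark(
    img: np.ndarray,
    top_rows: int | None = 0,
    bottom_rows: int | None = 0,
    *,
    auto: bool = False,
    white_level: float = 0.92,
    row_fraction: float = 0.5,
    min_rows: int = 8,
) -> np.ndarray:
    """Crop watermark rows from the top/bottom of an RGB image.

    With ``auto=True`` the leading and trailing runs of rows whose fraction
    of near-white pixels (all channels > ``white_level``) exceeds
    ``row_fraction`` are removed instead of the explicit counts.
    """
    h = img.shape[0]
    if auto:
        near_white = np.all(img > white_level, axis=-1).mean(axis=1) > row_fraction
        top_rows = 0
        while top_rows < h and near_white[top_rows]:
            top_rows += 1
        bottom_rows = 0
        while bottom_rows < h - top_rows and near_white[h - 1 - bottom_rows]:
            bottom_rows += 1
    top_rows = int(top_rows or 0)
    bottom_rows = int(bottom_rows or 0)
    if top_rows < 0 or bottom_rows < 0:
        raise ValueError("row counts must be non-negative")
    if h - top_rows - bottom_rows < min_rows:
        raise DegenerateInputError(
            f"stripping {top_rows}+{bottom_rows} rows from a {h}-row image "
            f"leaves fewer than {min_rows} rows"
        )
    return img[top_rows : h - bottom_rows]


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma grayscale: 0.299 R + 0.587 G + 0.114 B, clipped to [0, 1]."""
    return np.clip(img @ _LUMA, 0.0, 1.0)


def quantize(gray: np.ndarray, bins: int = 256) -> np.ndarray:
    """Quantize [0,1] intensities to integer levels 0..bins-1 (1.0 -> bins-1)."""
    return np.minimum((np.clip(gray, 0.0, 1.0) * bins).astype(np.int64), bins - 1)


def otsu_threshold(gray: np.ndarray, bins: int = 256) -> float:
    """Bin-edge threshold maximizing between-class variance.

    The histogram covers [0, 1] with ``bins`` equal levels.  Candidate
    thresholds are the interior bin edges k/bins, k = 1..bins-1; the lower
    class is {levels < k}.  Ties go to the smallest qualifying edge.
    Raises :class:`DegenerateInputError` on a (quantized) constant image.
    """
    levels = quantize(gray, bins)
    counts = np.bincount(levels.ravel(), minlength=bins).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    n = counts.sum()
    p = counts / n
    centers = np.arange(bins, dtype=np.float64)
    omega = np.cumsum(p)                 # weight of class {levels < k} at edge k
    mu = np.cumsum(p * centers)          # first moment of the lower class
    mu_total = mu[-1]
    w0 = omega[:-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = np.where(
            (w0 > 0) & (w1 > 0),
            (mu_total * w0 - mu[:-1]) ** 2 / (w0 * w1),
            -np.inf,
        )
    k = int(np.argmax(between)) + 1      # argmax returns the first maximizer
    return k / bins


def segment_sky(
    img: np.ndarray,
    *,
    bins: int = 256,
    opening_radius: int = 2,
    selem: np.ndarray | None = None,
) -> SkyMask:
    """Segment the sky region of a (watermark-stripped) RGB image.

    Pipeline: grayscale -> Otsu threshold -> bright class -> morphological
    opening (disk of ``opening_radius``) -> fill holes (4-connected false
    regions not touching the border) -> keep 8-connected components that
    touch the top image row.
    """
    gray = to_gray(img)
    try:
        thr = otsu_threshold(gray, bins=bins)
    except DegenerateInputError:
        return SkyMask(np.zeros(gray.shape, dtype=bool), empty_warning=True)
    binary = gray > thr
    if selem is None:
        selem = morphology.disk(opening_radius)
    opened = morphology.opening(binary, selem)
    filled = ndimage.binary_fill_holes(opened)  # default structure = 4-connectivity
    labels = measure.label(filled, connectivity=2)
    top_labels = np.unique(labels[0])
    top_labels = top_labels[top_labels != 0]
    mask = np.isin(labels, top_labels)
    return SkyMask(mask, empty_warning=not mask.any())
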