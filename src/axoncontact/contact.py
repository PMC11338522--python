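"""ER-ribosome contact estimation from two-channel super-resolution images.

The estimator thresholds the ER channel into a mask, measures the proportion
of ribosome-channel intensity falling inside the mask and inside a slightly
enlarged mask, and calibrates chance overlap by re-measuring after mirroring
the ribosome channel about the image's vertical midline (the "flip null") —
in a straightened axon segment that flip preserves the axon's intensity
envelope while destroying any true co-alignment with the ER.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .core import BinaryMask, PixelImage
from .errors import DegenerateInputError, ParameterError, UndefinedFractionError

__all__ = [
    "ContactConfig", "ContactResult", "segment_er_mask", "dilate_mask",
    "contact_fraction", "flip_null", "render_localizations", "analyze_segment",
]


@dataclass(frozen=True)
class ContactConfig:
    """Parameters of the contact estimator."""

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    dilate_nm: float = 5.0


@dataclass(frozen=True)
class ContactResult:
    """Overlap fractions for one axon segment."""

    fraction_in_mask: float
    fraction_in_enlarged: float
    fraction_flipped: float
    mask_area_fraction: float
    threshold_used: float

    def __post_init__(self) -> None:
        if self.fraction_in_enlarged < self.fraction_in_mask - 1e-12:
            raise ValueError("enlarged-mask fraction cannot shrink")


def segment_er_mask(
    er_image: PixelImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> BinaryMask:
    """Threshold the ER channel into a binary mask (pixels strictly above
    the threshold).

    ``method='otsu'`` picks the threshold automatically; a constant image
    has no bimodality and raises :class:`DegenerateInputError`.
    ``method='fixed'`` uses ``fixed_threshold`` verbatim.
    """
    arr = er_image.intensities
    if arr.size == 0:
        raise ParameterError("empty image")
    if method == "otsu":
        if np.ptp(arr) == 0:
            raise DegenerateInputError(
                "constant image: automatic thresholding is undefined"
            )
        thr = float(threshold_otsu(arr))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ParameterError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    return BinaryMask(arr > thr, er_image.pixel_size_nm, threshold_used=thr)


def dilate_mask(mask: BinaryMask, distance_nm: float) -> BinaryMask:
    """Morphological dilation by a disk of radius ``ceil(distance / pixel)``
    pixels; a positive sub-pixel distance still dilates by one pixel, and
    distance 0 is the identity."""
    if distance_nm < 0:
        raise ParameterError("distance_nm must be >= 0")
    if distance_nm == 0:
        return BinaryMask(mask.mask.copy(), mask.pixel_size_nm,
                          threshold_used=mask.threshold_used)
    r = max(int(math.ceil(distance_nm / mask.pixel_size_nm)), 1)
    dilated = binary_dilation(mask.mask, structure=disk(r))
    return BinaryMask(dilated, mask.pixel_size_nm,
                      threshold_used=mask.threshold_used)


def contact_fraction(ribo_image: PixelImage, mask: BinaryMask) -> float:
    """Proportion of total ribosome-channel intensity inside the mask."""
    if ribo_image.shape != mask.shape:
        raise ParameterError("image and mask shapes differ")
    total = float(ribo_image.intensities.sum())
    if total <= 0:
        raise UndefinedFractionError("total ribosome intensity is zero")
    return float(ribo_image.intensities[mask.mask].sum()) / total


def flip_null(ribo_image: PixelImage, mask: BinaryMask) -> float:
    """Chance-overlap control: contact fraction after mirroring the
    ribosome channel left-right about the vertical midline (the ER mask is
    left untouched)."""
    flipped = PixelImage(
        np.fliplr(ribo_image.intensities),
        ribo_image.pixel_size_nm,
        ribo_image.channel_label,
    )
    return contact_fraction(flipped, mask)


def render_localizations(
    table, pixel_size_nm: float, blur_sd_nm: float = 0.0
) -> dict[str, PixelImage]:
    """Reconstruct localization tables into per-channel 2D histograms.

    Bins are half-open, ``pixel_size_nm`` wide, anchored at the origin; the
    grid spans all channels jointly so the outputs are congruent.  An
    optional Gaussian blur of sd ``blur_sd_nm`` smooths the reconstruction;
    total intensity stays equal to the localization count up to kernel
    truncation at the borders.
    """
    from scipy.ndimage import gaussian_filter

    if pixel_size_nm <= 0:
        raise ParameterError("pixel_size_nm must be positive")
    if blur_sd_nm < 0:
        raise ParameterError("blur_sd_nm must be >= 0")
    if len(table) == 0:
        raise DegenerateInputError("empty localization table")
    x = np.asarray(table["x_nm"], dtype=float)
    y = np.asarray(table["y_nm"], dtype=float)
    nx = int(np.floor(x.max() / pixel_size_nm)) + 1
    ny = int(np.floor(y.max() / pixel_size_nm)) + 1
    out: dict[str, PixelImage] = {}
    for channel in sorted(set(table["channel"])):
        sel = np.asarray(table["channel"] == channel)
        cols = np.floor(x[sel] / pixel_size_nm).astype(int)
        rows = np.floor(y[sel] / pixel_size_nm).astype(int)
        ok = (rows >= 0) & (cols >= 0)
        grid = np.zeros((ny, nx))
        np.add.at(grid, (rows[ok], cols[ok]), 1.0)
        if blur_sd_nm > 0:
            grid = gaussian_filter(
                grid, blur_sd_nm / pixel_size_nm, mode="constant", truncate=4.0
            )
        out[channel] = PixelImage(grid, pixel_size_nm, channel_label=channel)
    return out


def analyze_segment(
    er_image: PixelImage,
    ribo_image: PixelImage,
    config: ContactConfig = ContactConfig(),
) -> ContactResult:
    """Full contact workflow for one straightened segment: threshold the ER
    channel, dilate, measure both overlap fractions and the flip null."""
    if er_image.shape != ribo_image.shape:
        raise ParameterError("channel shapes differ")
    if er_image.pixel_size_nm != ribo_image.pixel_size_nm:
        raise ParameterError("channel pixel sizes differ")
    mask = segment_er_mask(
        er_image, method=config.threshold_method,
        fixed_threshold=config.fixed_threshold,
    )
    enlarged = dilate_mask(mask, config.dilate_nm)
    return ContactResult(
        fraction_in_mask=contact_fraction(ribo_image, mask),
        fraction_in_enlarged=contact_fraction(ribo_image, enlarged),
        fraction_flipped=flip_null(ribo_image, mask),
        mask_area_fraction=mask.area_fraction,
        threshold_used=float(mask.threshold_used),
    )
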