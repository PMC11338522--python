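"""Segmented-line intensity quantification and derived effect sizes.

Covers the measurements made on straightened or traced axon segments:
background-corrected mean intensity under a polyline band, percent change
between conditions, the axon/dendrite polarity index, per-batch
normalization of proximity-labeling (split-APEX) intensities, and
branch-point versus shaft enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AxonTrace, PixelImage, Rect, sample_band
from .errors import NormalizationError, ParameterError, UndefinedFractionError

__all__ = [
    "LineProfileMeasurement", "PolarityResult", "profile_mean",
    "percent_change", "polarity_index", "normalize_apex", "branch_enrichment",
]


@dataclass(frozen=True)
class LineProfileMeasurement:
    """Mean intensity under a polyline band, minus a background-ROI mean.

    ``corrected_mean`` may be negative (dim signal under a bright
    background estimate); it is retained but flagged rather than truncated,
    since truncation would bias downstream percent-change estimates.
    """

    raw_mean: float
    background: float
    corrected_mean: float
    profile_length_um: float
    line_width_px: int

    @property
    def negative_flagged(self) -> bool:
        return self.corrected_mean < 0


@dataclass(frozen=True)
class PolarityResult:
    """Axon/dendrite polarity index PI = (Id - Ia) / (Id + Ia), where Id is
    the mean of three dendritic intensities and Ia the axonal intensity.
    PI < 0 means axon-enriched, PI > 0 dendrite-enriched, 0 unpolarized."""

    pi: float
    i_d: float
    i_a: float


def profile_mean(
    image: PixelImage,
    polyline: AxonTrace,
    width_px: int,
    background_roi: Rect | tuple[int, int, int, int],
    s_window_nm: tuple[float, float] | None = None,
) -> LineProfileMeasurement:
    """Background-corrected mean intensity along a segmented line.

    The image is resampled bilinearly at ~1-pixel steps along the polyline
    with ``width_px`` perpendicular samples, optionally restricted to the
    arc-length window ``s_window_nm``; the mean of the background ROI is
    subtracted from the band mean.
    """
    if not isinstance(background_roi, Rect):
        background_roi = Rect(*background_roi)
    s0, s1 = s_window_nm if s_window_nm is not None else (None, None)
    band = sample_band(image, polyline, width_px, s0, s1)
    raw = float(band.mean())
    bg = float(background_roi.slice_from(image.intensities).mean())
    length_nm = (
        polyline.length_nm if s_window_nm is None else (s1 - s0)
    )
    return LineProfileMeasurement(
        raw_mean=raw, background=bg, corrected_mean=raw - bg,
        profile_length_um=length_nm / 1000.0, line_width_px=int(width_px),
    )


def percent_change(
    control_values: Sequence[float], test_values: Sequence[float]
) -> float:
    """Percent change of group means relative to control; positive values
    are reductions: ``100 * (mean(control) - mean(test)) / mean(control)``."""
    control = np.asarray(control_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    if control.size == 0 or test.size == 0:
        raise ParameterError("both groups must be non-empty")
    mc = control.mean()
    if mc <= 0:
        raise UndefinedFractionError("control mean must be positive")
    return float(100.0 * (mc - test.mean()) / mc)


def polarity_index(
    axon_intensity: float, dendrite_intensities: Sequence[float]
) -> PolarityResult:
    """Polarity index from one axonal and exactly three dendritic
    background-corrected mean intensities."""
    dend = np.asarray(dendrite_intensities, dtype=float)
    if dend.shape != (3,):
        raise ParameterError("exactly three dendrite intensities are required")
    i_a = float(axon_intensity)
    if i_a < 0 or np.any(dend < 0):
        raise ParameterError("intensities must be non-negative")
    i_d = float(dend.mean())
    if i_d + i_a == 0:
        raise UndefinedFractionError("all intensities are zero; PI undefined")
    return PolarityResult(pi=(i_d - i_a) / (i_d + i_a), i_d=i_d, i_a=i_a)


def normalize_apex(
    measurements: pd.DataFrame,
    control_condition: str,
    correct_expression: bool = False,
) -> pd.DataFrame:
    """Normalize split-APEX streptavidin intensities per batch.

    Expects columns ``strep, v5, ha, condition, batch_id``.  If
    ``correct_expression``, strep is first divided per cell by ``v5 * ha``
    (cells with a non-positive expression signal are flagged ``excluded``
    and ignored); then, within each batch, values are divided by the batch's
    control-condition mean, so the control-batch mean is 1 by construction.
    """
    required = {"strep", "v5", "ha", "condition", "batch_id"}
    missing = required - set(measurements.columns)
    if missing:
        raise ParameterError(f"measurements missing columns: {sorted(missing)}")
    df = measurements.copy()
    df["excluded"] = False
    work = df["strep"].astype(float)
    if correct_expression:
        denom = df["v5"].astype(float) * df["ha"].astype(float)
        bad = denom <= 0
        df.loc[bad, "excluded"] = True
        work = work.where(~bad) / denom.where(~bad)
    df["expression_corrected"] = work if correct_expression else np.nan
    df["strep_raw"] = df["strep"].astype(float)
    norm = pd.Series(np.nan, index=df.index)
    for batch, grp in df.groupby("batch_id"):
        ctrl = grp[(grp["condition"] == control_condition) & ~grp["excluded"]]
        if ctrl.empty:
            raise NormalizationError(
                f"batch {batch!r} has no usable {control_condition!r} rows"
            )
        ctrl_mean = work.loc[ctrl.index].mean()
        if not ctrl_mean > 0:
            raise NormalizationError(
                f"batch {batch!r} control mean is non-positive"
            )
        norm.loc[grp.index] = work.loc[grp.index] / ctrl_mean
    df["strep_normalized"] = norm
    return df


def branch_enrichment(
    branch_values: Sequence[float], shaft_values: Sequence[float]
) -> float:
    """Fold change of branch-point over shaft signal:
    ``mean(branch) / mean(shaft)``."""
    branch = np.asarray(branch_values, dtype=float)
    shaft = np.asarray(shaft_values, dtype=float)
    if branch.size == 0 or shaft.size == 0:
        raise ParameterError("both value lists must be non-empty")
    ms = shaft.mean()
    if ms <= 0:
        raise UndefinedFractionError("shaft mean must be positive")
    return float(branch.mean() / ms)
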