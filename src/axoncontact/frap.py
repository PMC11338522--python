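"""Normalization and averaging of fluorescence-recovery (FRAP) traces.

A raw trace is background-corrected, divided by an unbleached reference
trace (rescaled to its own prebleach mean) to undo acquisition bleaching,
then affinely mapped so that the mean of the three frames before the bleach
is exactly 100% and the first post-bleach frame is exactly 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateInputError,
    ParameterError,
    RangeError,
)

__all__ = [
    "FrapSeries", "NormalizedFrapCurve", "MeanRecoveryCurve", "RecoveryPoint",
    "normalize_frap", "average_recovery", "recovery_at",
]

_N_ANCHOR_FRAMES = 3  # prebleach frames averaged into the 100% anchor


@dataclass(frozen=True)
class FrapSeries:
    """Raw photobleaching-recovery trace.

    ``background`` may be a scalar or a per-frame array; ``reference`` is an
    optional trace from an unbleached region of the same cell, used to
    correct for bleaching caused by image acquisition itself.
    ``bleach_index`` is the index of the first post-bleach frame.
    """

    times_s: np.ndarray
    raw: np.ndarray
    background: float | np.ndarray = 0.0
    reference: np.ndarray | None = None
    bleach_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        raw = np.asarray(self.raw, dtype=float)
        if t.ndim != 1 or raw.shape != t.shape:
            raise ParameterError("times_s and raw must be 1D and congruent")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("times_s must be strictly increasing")
        if not 0 < self.bleach_index < len(t):
            raise ParameterError("bleach_index must be inside the trace")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "raw", raw)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != t.shape:
                raise ParameterError("reference must match the trace length")
            object.__setattr__(self, "reference", ref)
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim not in (0, 1) or (bg.ndim == 1 and bg.shape != t.shape):
            raise ParameterError("background must be scalar or per-frame")
        object.__setattr__(self, "background", bg)


@dataclass(frozen=True)
class NormalizedFrapCurve:
    """Recovery curve in percent, anchored at 100 (prebleach mean of three
    frames) and 0 (first post-bleach frame)."""

    times_s: np.ndarray
    percent: np.ndarray
    bleach_index: int


@dataclass(frozen=True)
class MeanRecoveryCurve:
    """Per-timepoint mean, standard error and count over normalized curves."""

    times_s: np.ndarray
    mean_percent: np.ndarray
    sem_percent: np.ndarray
    n: int
    bleach_index: int


@dataclass(frozen=True)
class RecoveryPoint:
    t_requested_s: float
    t_used_s: float
    percent: float


def normalize_frap(
    series: FrapSeries, correct_acquisition_bleach: bool = True
) -> NormalizedFrapCurve:
    """Background-correct, reference-correct and anchor a FRAP trace.

    Steps: (1) subtract background per frame; (2) if enabled, divide by the
    reference trace rescaled to its own prebleach mean; (3) map affinely so
    the mean of the three frames preceding the bleach is 100 and the value
    at the bleach frame is 0.  The output is invariant under any positive
    affine rescaling of the raw data with matching background.
    """
    bi = series.bleach_index
    if bi < _N_ANCHOR_FRAMES:
        raise ParameterError(
            f"need at least {_N_ANCHOR_FRAMES} prebleach frames"
        )
    sig = series.raw - series.background
    if correct_acquisition_bleach:
        if series.reference is None:
            raise ParameterError(
                "acquisition-bleach correction requires a reference trace "
                "(or pass correct_acquisition_bleach=False)"
            )
        ref = series.reference - series.background
        ref_pre = float(np.mean(ref[bi - _N_ANCHOR_FRAMES : bi]))
        if ref_pre <= 0 or np.any(ref == 0):
            raise DegenerateInputError("reference trace is degenerate")
        sig = sig / (ref / ref_pre)
    pre = float(np.mean(sig[bi - _N_ANCHOR_FRAMES : bi]))
    b0 = float(sig[bi])
    if pre == b0:
        raise DegenerateInputError(
            "prebleach mean equals the bleach-frame value; nothing was bleached"
        )
    percent = 100.0 * (sig - b0) / (pre - b0)
    return NormalizedFrapCurve(
        times_s=series.times_s.copy(), percent=percent, bleach_index=bi
    )


def average_recovery(curves: list[NormalizedFrapCurve]) -> MeanRecoveryCurve:
    """Per-timepoint mean and standard error over curves sharing one time
    grid.  No resampling is performed; mismatched grids are an error."""
    if not curves:
        raise ParameterError("no curves to average")
    t0 = curves[0].times_s
    bi = curves[0].bleach_index
    for c in curves[1:]:
        if c.times_s.shape != t0.shape or not np.allclose(
            c.times_s, t0, rtol=0.0, atol=1e-9
        ) or c.bleach_index != bi:
            raise AlignmentError("curves do not share a common time grid")
    stack = np.stack([c.percent for c in curves])
    mean = stack.mean(axis=0)
    n = len(curves)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return MeanRecoveryCurve(
        times_s=t0.copy(), mean_percent=mean, sem_percent=sem, n=n,
        bleach_index=bi,
    )


def recovery_at(
    curve: MeanRecoveryCurve | NormalizedFrapCurve, t_s: float
) -> RecoveryPoint:
    """Recovery percentage at the sampled timepoint nearest ``t_s``
    (no interpolation)."""
    t = np.asarray(curve.times_s)
    if not t[0] <= t_s <= t[-1]:
        raise RangeError(f"t={t_s}s outside the sampled span [{t[0]}, {t[-1]}]")
    idx = int(np.argmin(np.abs(t - t_s)))
    values = (
        curve.mean_percent
        if isinstance(curve, MeanRecoveryCurve)
        else curve.percent
    )
    return RecoveryPoint(
        t_requested_s=float(t_s), t_used_s=float(t[idx]),
        percent=float(values[idx]),
    )
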