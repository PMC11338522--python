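"""Core carriers shared by every quantifier.

Conventions used repo-wide:

* images are 2D numpy arrays indexed ``[row, col]``; physical coordinates are
  ``(x_nm, y_nm)`` with x along columns and y along rows;
* pixel *centers* sit at ``(i + 0.5) * pixel_size_nm``, so the physical point
  ``p_nm`` maps to the fractional array coordinate ``p_nm / pixel_size_nm - 0.5``;
* localization binning is half-open: position ``x`` falls into bin
  ``floor(x / pixel_size_nm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = ["PixelImage", "BinaryMask", "AxonTrace", "sample_band", "Rect"]


@dataclass(frozen=True)
class PixelImage:
    """Single-channel 2D intensity grid with a physical pixel size.

    Parameters
    ----------
    intensities
        Non-negative 2D array (any float/integer dtype).
    pixel_size_nm
        Physical edge length of a pixel in nanometers.
    channel_label
        Free-text channel name (``"er"``, ``"ribo"``, ``"fill"``, ...).
    """

    intensities: np.ndarray
    pixel_size_nm: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ParameterError("intensities must be a 2D array")
        if not np.all(arr >= 0):
            raise ParameterError("intensities must be non-negative")
        if not self.pixel_size_nm > 0:
            raise ParameterError("pixel_size_nm must be positive")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean grid congruent with the image it was derived from."""

    mask: np.ndarray
    pixel_size_nm: float
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ParameterError("mask must be a 2D array")
        if not self.pixel_size_nm > 0:
            raise ParameterError("pixel_size_nm must be positive")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class AxonTrace:
    """Polyline along an axon segment, in physical units.

    ``vertices`` is an ``(n, 2)`` array of ``(x_nm, y_nm)`` points, n >= 2,
    with consecutive vertices distinct.  ``branch_points_nm`` holds arc-length
    positions of collateral branch points, each within ``[0, length_nm]``.
    """

    vertices: np.ndarray
    width_nm: float
    branch_points_nm: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ParameterError("vertices must be an (n>=2, 2) array")
        seg = np.diff(v, axis=0)
        if np.any(np.all(seg == 0, axis=1)):
            raise ParameterError("consecutive vertices must be distinct")
        if not self.width_nm > 0:
            raise ParameterError("width_nm must be positive")
        object.__setattr__(self, "vertices", v)
        bp = tuple(float(b) for b in self.branch_points_nm)
        total = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
        for b in bp:
            if not 0 <= b <= total + 1e-9:
                raise ParameterError(
                    f"branch point at {b} nm outside [0, {total}] nm"
                )
        object.__setattr__(self, "branch_points_nm", bp)

    @property
    def length_nm(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))

    def point_at(self, s_nm: np.ndarray) -> np.ndarray:
        """Interpolate ``(x, y)`` at arc-length positions ``s_nm``."""
        s_nm = np.atleast_1d(np.asarray(s_nm, dtype=float))
        seg = np.diff(self.vertices, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = np.clip(s_nm, 0.0, cum[-1])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        frac = (s - cum[idx]) / seg_len[idx]
        return self.vertices[idx] + frac[:, None] * seg[idx]

    def tangent_at(self, s_nm: np.ndarray) -> np.ndarray:
        """Unit tangent vectors at arc-length positions ``s_nm``."""
        s_nm = np.atleast_1d(np.asarray(s_nm, dtype=float))
        seg = np.diff(self.vertices, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = np.clip(s_nm, 0.0, cum[-1])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        return seg[idx] / seg_len[idx, None]

    def reversed(self) -> "AxonTrace":
        total = self.length_nm
        return AxonTrace(
            vertices=self.vertices[::-1].copy(),
            width_nm=self.width_nm,
            branch_points_nm=tuple(total - b for b in self.branch_points_nm),
        )


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle, ImageJ-style ``(x, y, w, h)``:
    ``x``/``y`` are the top-left column/row, ``w``/``h`` the extent."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ParameterError("Rect width and height must be positive")

    def slice_from(self, arr: np.ndarray) -> np.ndarray:
        if (
            self.y < 0
            or self.x < 0
            or self.y + self.h > arr.shape[0]
            or self.x + self.w > arr.shape[1]
        ):
            raise GeometryError("background ROI exceeds image bounds")
        return arr[self.y : self.y + self.h, self.x : self.x + self.w]


def sample_band(
    image: PixelImage,
    trace: AxonTrace,
    width_px: int,
    s_start_nm: float | None = None,
    s_stop_nm: float | None = None,
) -> np.ndarray:
    """Resample an image along a polyline band by bilinear interpolation.

    Positions are spaced evenly at ~1 pixel steps along the arc between
    ``s_start_nm`` and ``s_stop_nm`` (defaults: whole trace), and ``width_px``
    perpendicular offsets at 1-pixel spacing are taken symmetrically around
    the line.  Returns an array of shape ``(n_positions, width_px)``.

    Raises
    ------
    GeometryError
        If any sample coordinate falls outside the pixel-center grid.
    """
    from scipy.ndimage import map_coordinates

    if width_px < 1:
        raise ParameterError("width_px must be >= 1")
    px = image.pixel_size_nm
    s0 = 0.0 if s_start_nm is None else float(s_start_nm)
    s1 = trace.length_nm if s_stop_nm is None else float(s_stop_nm)
    if not 0 <= s0 < s1 <= trace.length_nm + 1e-6:
        raise ParameterError("invalid arc-length window")
    n_pos = max(int(round((s1 - s0) / px)), 1) + 1
    s = np.linspace(s0, s1, n_pos)
    pts = trace.point_at(s)          # (n, 2) in nm
    tan = trace.tangent_at(s)        # (n, 2) unit
    normal = np.stack([-tan[:, 1], tan[:, 0]], axis=1)
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * px
    # (n, w, 2) physical sample points
    samples = pts[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    cols = samples[..., 0] / px - 0.5
    rows = samples[..., 1] / px - 0.5
    nr, nc = image.shape
    if (
        rows.min() < -0.5 - 1e-6
        or cols.min() < -0.5 - 1e-6
        or rows.max() > nr - 0.5 + 1e-6
        or cols.max() > nc - 0.5 + 1e-6
    ):
        raise GeometryError("sampling band exits the image bounds")
    vals = map_coordinates(
        image.intensities, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    )
    return vals.reshape(rows.shape)
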