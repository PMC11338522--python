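"""Reading and writing of the on-disk formats the pipeline exchanges.

Images travel as TIFF with a YAML sidecar (``<image>.yaml``) holding the
physical pixel size and channel label; localization tables as CSV with the
header ``x_nm,y_nm,precision_nm,frame,channel``; FRAP traces as CSV; scenes
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import PixelImage
from .errors import ConfigError, ParameterError
from .frap import FrapSeries
from .synth import GroundTruthScene

LOC_COLUMNS = ["x_nm", "y_nm", "precision_nm", "frame", "channel"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_image(path: str | Path, image: PixelImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.intensities.astype(np.float32))
    meta = {
        "pixel_size_nm": float(image.pixel_size_nm),
        "channel_label": image.channel_label,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> PixelImage:
    """Load a TIFF; pixel size comes from the YAML sidecar unless given
    explicitly."""
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    label = ""
    if pixel_size_nm is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise ConfigError(
                f"no pixel size: pass pixel_size_nm or provide {sidecar.name}"
            )
        meta = yaml.safe_load(sidecar.read_text())
        pixel_size_nm = float(meta["pixel_size_nm"])
        label = meta.get("channel_label", "")
    return PixelImage(np.clip(arr, 0, None), pixel_size_nm, channel_label=label)


def write_localizations(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=LOC_COLUMNS)


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LOC_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"localization CSV missing columns: {sorted(missing)}")
    if not (df["precision_nm"] > 0).all():
        raise ParameterError("precision_nm must be positive")
    if not (df["frame"] >= 0).all():
        raise ParameterError("frame must be >= 0")
    return df


def write_scene(path: str | Path, scene: GroundTruthScene) -> None:
    payload = {
        "trace_vertices_nm": scene.trace.vertices.tolist(),
        "width_nm": scene.trace.width_nm,
        "branch_points_nm": list(scene.trace.branch_points_nm),
        "er_tubule_radius_nm": scene.er_tubule_radius_nm,
        "positions_nm": scene.positions_nm.tolist(),
        "amplitudes": scene.amplitudes.tolist(),
        "bound": scene.bound.astype(int).tolist(),
        "bound_fraction": scene.bound_fraction,
        "bind_distance_nm": scene.bind_distance_nm,
        "seed": scene.seed,
        "tubule_coeffs": scene.tubule_coeffs.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_scene(path: str | Path) -> GroundTruthScene:
    from .core import AxonTrace

    d = json.loads(Path(path).read_text())
    trace = AxonTrace(
        vertices=np.asarray(d["trace_vertices_nm"]),
        width_nm=d["width_nm"],
        branch_points_nm=tuple(d["branch_points_nm"]),
    )
    return GroundTruthScene(
        trace=trace,
        er_tubule_radius_nm=d["er_tubule_radius_nm"],
        positions_nm=np.asarray(d["positions_nm"], dtype=float).reshape(-1, 3),
        amplitudes=np.asarray(d["amplitudes"], dtype=float),
        bound=np.asarray(d["bound"], dtype=bool),
        bound_fraction=d["bound_fraction"],
        bind_distance_nm=d["bind_distance_nm"],
        seed=d["seed"],
        tubule_coeffs=np.asarray(d["tubule_coeffs"], dtype=float),
    )


def read_frap_csv(path: str | Path, bleach_index: int | None = None) -> FrapSeries:
    """Load a FRAP trace CSV with columns ``time_s, raw, background``,
    optional ``reference`` and optional ``is_prebleach`` (used to locate the
    bleach frame when ``bleach_index`` is not given)."""
    df = pd.read_csv(path)
    for col in ("time_s", "raw"):
        if col not in df.columns:
            raise ParameterError(f"FRAP CSV missing column {col!r}")
    if bleach_index is None:
        if "is_prebleach" not in df.columns:
            raise ParameterError(
                "either bleach_index or an is_prebleach column is required"
            )
        bleach_index = int(np.argmin(df["is_prebleach"].astype(bool).to_numpy()))
    background = (
        df["background"].to_numpy(dtype=float)
        if "background" in df.columns
        else 0.0
    )
    reference = (
        df["reference"].to_numpy(dtype=float)
        if "reference" in df.columns
        else None
    )
    return FrapSeries(
        times_s=df["time_s"].to_numpy(dtype=float),
        raw=df["raw"].to_numpy(dtype=float),
        background=background,
        reference=reference,
        bleach_index=bleach_index,
    )
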