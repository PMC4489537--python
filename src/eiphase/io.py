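"""Image, curve and config I/O: 32-bit float TIFF, two-column CSV, YAML sidecars.

Every image travels with a JSON sidecar (``<path>.json``) holding the grid
spacing and provenance metadata, so a write/read round trip is lossless both
in pixel values and in geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .illumination import TabulatedCurve

__all__ = [
    "read_image",
    "write_image",
    "read_curve_csv",
    "write_curve_csv",
    "write_profile_csv",
    "write_config",
]


def write_image(values: np.ndarray, path, step_y_um: float, step_x_um: float, meta: dict | None = None) -> None:
    """Write a single-channel 32-bit float TIFF plus a JSON sidecar."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2:
        raise ValueError("only single-channel 2D images are written")
    tifffile.imwrite(
        path,
        values,
        resolution=(1e4 / step_x_um, 1e4 / step_y_um),  # pixels per cm
        resolutionunit="CENTIMETER",
    )
    sidecar = {"step_y_um": step_y_um, "step_x_um": step_x_um, "meta": _jsonable(meta or {})}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path):
    """Read a 32-bit float single-channel TIFF written by :func:`write_image`.

    Returns ``(values, step_y_um, step_x_um, meta)``. Integer or
    multi-channel TIFFs are rejected with a conversion hint.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    values = tifffile.imread(path)
    if values.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2D image, got shape {values.shape} "
            "(convert with e.g. tifffile to a single float32 plane)"
        )
    if not np.issubdtype(values.dtype, np.floating):
        raise ValueError(
            f"{path}: expected float pixel data, got {values.dtype} "
            "(convert to 32-bit float TIFF first)"
        )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    step_y_um = step_x_um = None
    meta: dict = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        step_y_um = sidecar.get("step_y_um")
        step_x_um = sidecar.get("step_x_um")
        meta = sidecar.get("meta", {})
    else:
        with tifffile.TiffFile(path) as tif:
            tags = tif.pages[0].tags
            if "XResolution" in tags and "YResolution" in tags:
                xr = tags["XResolution"].value
                yr = tags["YResolution"].value
                step_x_um = 1e4 * xr[1] / xr[0]
                step_y_um = 1e4 * yr[1] / yr[0]
    return values.astype(np.float64), step_y_um, step_x_um, meta


def write_curve_csv(y_e_um: np.ndarray, c: np.ndarray, path) -> None:
    """Write an illumination curve as two-column CSV with a one-line header."""
    pd.DataFrame({"y_e_um": np.asarray(y_e_um), "C": np.asarray(c)}).to_csv(path, index=False)


def read_curve_csv(path) -> TabulatedCurve:
    """Read a tabulated illumination curve from a two-column CSV.

    The abscissa must be strictly increasing and all cells numeric; violations
    are rejected with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such curve file: {path}")
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (y_e_um, C)")
    if table.empty:
        raise ValueError(f"{path}: curve file has a header but no data rows")
    y = table.iloc[:, 0].to_numpy(dtype=float)
    c = table.iloc[:, 1].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(y) | ~np.isfinite(c))[0]
    if bad.size:
        raise ValueError(f"{path}: non-numeric/NaN cell at data row {bad[0] + 1}")
    non_mono = np.where(np.diff(y) <= 0)[0]
    if non_mono.size:
        raise ValueError(
            f"{path}: abscissa not strictly increasing at data row {non_mono[0] + 2}"
        )
    return TabulatedCurve(y, c)


def write_profile_csv(series: dict[str, np.ndarray], path) -> None:
    """Write named 1D profiles as CSV columns."""
    pd.DataFrame({k: np.asarray(v) for k, v in series.items()}).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_config(config: dict, path) -> None:
    """Echo the fully resolved run configuration next to the outputs."""
    Path(path).write_text(yaml.safe_dump(_jsonable(config), sort_keys=True))
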