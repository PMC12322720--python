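"""Image and table I/O: TIFF frames, detection CSVs, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_image", "write_image", "write_detections", "read_detections"]


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a single- or multi-page TIFF.

    Returns ``(array, metadata)``: a 2-D array for a single frame or a 3-D
    (frames, rows, cols) stack for a time series.  Metadata carries the
    pixel size (µm) when the file declares a resolution.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            meta: dict = {"n_pages": len(tif.pages)}
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None:
                num, den = res.value
                if num:
                    per_unit = num / den
                    # convert pixels-per-unit to µm per pixel
                    unit_um = {2: 25400.0, 3: 10000.0}.get(
                        getattr(unit, "value", None) and unit.value, None
                    )
                    if unit_um:
                        meta["pixel_size_um"] = unit_um / per_unit
    except tifffile.TiffFileError as err:
        raise ValueError(f"cannot read {path} as TIFF: {err}") from err
    return arr, meta


def write_image(path: str | Path, image: np.ndarray, pixel_size_um: float | None = None) -> None:
    """Write a frame (or stack) as 16-bit TIFF."""
    img = np.asarray(image)
    if img.dtype != np.uint16:
        img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    # grayscale, one page per frame (a 3-D stack would otherwise be
    # auto-interpreted as separated RGB planes)
    kw: dict = {"photometric": "minisblack"}
    if pixel_size_um:
        ppcm = 10000.0 / pixel_size_um
        kw["resolution"] = (ppcm, ppcm)
        kw["resolutionunit"] = "CENTIMETER"
    tifffile.imwrite(path, img, **kw)


_DETECTION_HEADER = (
    "# detections: one row per localized emitter; positions in pixel-index "
    "(x_px, y_px) and object-space micrometres (x_um, y_um); photons and "
    "background in photon units; sigma in px\n"
)


def write_detections(path: str | Path, detections: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_DETECTION_HEADER)
        detections.to_csv(fh, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
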