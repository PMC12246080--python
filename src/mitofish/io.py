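"""File I/O: TIFF rasters with pitch metadata, localization/bead CSVs,
masks, summaries.

Conventions: coordinates in files are always nanometers (floating point);
pixel indices are never serialized.  Images are single-channel 32-bit TIFF
with the pixel pitch stored in the image description (JSON) and echoed in a
YAML sidecar next to the file; on reading, the TIFF tag wins, the sidecar
covers TIFFs without a tag, and an explicit ``pitch`` argument is the last
resort.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import BEAD_COLUMNS, RAW_COLUMNS
from .types import MitoMask, PixelImage


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_image(image: PixelImage, path: str | Path) -> None:
    """Write a 32-bit single-channel TIFF plus a YAML sidecar."""
    path = Path(path)
    meta = {"pitch_nm": float(image.pitch), "channel": image.channel,
            "origin_nm": list(image.origin_nm)}
    tifffile.imwrite(path, image.grid.astype(np.float32),
                     description=json.dumps(meta))
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_image(path: str | Path, pitch: float | None = None,
               channel: str | None = None) -> PixelImage:
    """Read a TIFF raster; pitch from tag, else sidecar, else argument."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    meta: dict = {}
    with tifffile.TiffFile(path) as tif:
        grid = tif.asarray().astype(float)
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                parsed = json.loads(desc.value)
                if isinstance(parsed, dict):
                    meta = parsed
            except (json.JSONDecodeError, TypeError):
                pass
    if "pitch_nm" not in meta:
        sc = _sidecar(path)
        if sc.exists():
            with open(sc) as fh:
                side = yaml.safe_load(fh) or {}
            if isinstance(side, dict):
                meta = {**side, **meta}
    px = meta.get("pitch_nm", pitch)
    if px is None:
        raise ValueError(
            f"no pixel pitch in TIFF metadata or sidecar for {path}; "
            "supply pitch explicitly")
    return PixelImage(grid=grid, pitch=float(px),
                      channel=channel or meta.get("channel"),
                      origin_nm=tuple(meta.get("origin_nm", (0.0, 0.0))))


def write_mask(mask: MitoMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit 0/255 TIFF with pitch metadata."""
    path = Path(path)
    meta = {"pitch_nm": float(mask.pitch), "mask": True}
    tifffile.imwrite(path, (mask.grid.astype(np.uint8) * 255),
                     description=json.dumps(meta))
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_mask(path: str | Path, pitch: float | None = None) -> MitoMask:
    img = read_image(path, pitch=pitch)
    return MitoMask(grid=img.grid > 0, pitch=img.pitch)


def _read_table(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{what} file {path} is missing required "
                             f"column {col!r}")
    for col in required:
        if col in ("dataset_id", "bead_id", "trace_id"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"{what} file {path}: malformed value {df.loc[bad.idxmax(), col]!r} "
                f"in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a raw-localization CSV; unknown columns pass through."""
    return _read_table(path, RAW_COLUMNS, "localization")


def read_beads(path: str | Path) -> pd.DataFrame:
    """Read a fiducial-bead CSV."""
    return _read_table(path, BEAD_COLUMNS, "bead")


def write_localizations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_summary(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_summary(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
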