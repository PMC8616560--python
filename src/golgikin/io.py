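"""Reading and writing the pipeline's on-disk formats.

Movies and snapshots are multi-page TIFF with dimension order (T, C, Y, X),
16-bit unsigned, with frame interval and channel names stored as JSON in the
file description. Tables are CSV with a comment header carrying provenance
(seed, config hash); summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import InvalidParameterError
from .synthetic import GroundTruth, MovieStack

__all__ = [
    "save_movie",
    "load_movie",
    "save_image",
    "load_image",
    "save_table",
    "load_table",
    "save_ground_truth",
    "load_ground_truth",
    "save_yaml",
    "load_yaml",
]


def _to_uint16(data: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(data), 0, 65535).astype(np.uint16)


def save_movie(path, movie: MovieStack) -> None:
    """Write a movie as (T, C, Y, X) uint16 TIFF with JSON metadata."""
    meta = {
        "axes": "TCYX",
        "frame_interval_s": movie.frame_interval,
        "channel_names": list(movie.channel_names),
    }
    tifffile.imwrite(
        str(path),
        _to_uint16(movie.data),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def load_movie(path, frame_interval: float | None = None) -> MovieStack:
    """Read a (T, C, Y, X) TIFF movie; metadata fallback to ``frame_interval``.

    A dimension-order mismatch (anything but a 4-D stack) is an error, not a
    silent transpose.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    if data.ndim == 3:  # single-channel movie or single multi-channel frame: ambiguous
        raise InvalidParameterError(
            f"{path}: expected a 4-D (T, C, Y, X) stack, got shape {data.shape}"
        )
    if data.ndim != 4:
        raise InvalidParameterError(
            f"{path}: expected a 4-D (T, C, Y, X) stack, got shape {data.shape}"
        )
    interval = meta.get("frame_interval_s", frame_interval)
    if interval is None:
        raise InvalidParameterError(f"{path}: no frame interval in metadata; pass frame_interval")
    return MovieStack(
        data.astype(float), float(interval), list(meta.get("channel_names", []))
    )


def save_image(path, image: np.ndarray, as_labels: bool = False) -> None:
    """Write a (C, Y, X) or (Y, X) image as uint16 TIFF (labels kept integral)."""
    arr = np.asarray(image)
    out = arr.astype(np.uint16) if as_labels else _to_uint16(arr)
    tifffile.imwrite(str(path), out, photometric="minisblack")


def load_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def save_table(path, df: pd.DataFrame, header_lines: list[str] | None = None) -> None:
    """CSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_ground_truth(outdir, gt: GroundTruth) -> None:
    """Write the simulator's truth record as one CSV per table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("puncta", "coloc_pairs", "cell_records", "hot_pixels"):
        getattr(gt, name).to_csv(outdir / f"{name}.csv", index=False)


def load_ground_truth(outdir) -> GroundTruth:
    outdir = Path(outdir)
    kwargs = {}
    for name in ("puncta", "coloc_pairs", "cell_records", "hot_pixels"):
        f = outdir / f"{name}.csv"
        if f.exists():
            kwargs[name] = pd.read_csv(f)
    return GroundTruth(**kwargs)


def save_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())
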