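"""Frame acquisition and trace serialisation.

Frames come either from a video container (MP4/AVI, via imageio) or from a
directory of numbered still images with an explicitly stated frame rate.
Timestamps are always ``index / fps`` — kinetics downstream assume uniform
sampling, so variable-frame-rate input is rejected rather than resampled.
Decoded colour is taken to be 8-bit sRGB as consumer cameras emit it; no
colour management is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

TRACE_COLUMNS = ["label", "time_s", "R", "G", "B", "L", "a", "b", "H", "S", "V", "deltaE"]


@dataclass(frozen=True)
class FrameRecord:
    """One decoded video frame: 0-based index, timestamp (s), H×W×3 image."""

    index: int
    timestamp: float
    image: np.ndarray

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] < 3:
            raise ValueError("frame image must be height x width x 3 (RGB)")


def _as_rgb(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:  # greyscale still: promote
        img = np.stack([img] * 3, axis=-1)
    return np.ascontiguousarray(img[..., :3])


def _numeric_key(p: Path) -> tuple:
    m = re.findall(r"\d+", p.stem)
    return (tuple(int(x) for x in m), p.name)


def read_frames(source: str | Path, fps_override: float | None = None) -> list[FrameRecord]:
    """Read a video file or a numbered image directory into FrameRecords.

    For image directories ``fps_override`` is mandatory (stills carry no
    rate).  For containers the rate comes from metadata unless overridden.
    """
    source = Path(source)
    if fps_override is not None and fps_override <= 0:
        raise ValueError("fps_override must be positive")
    if source.is_dir():
        files = sorted(
            (p for p in source.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"no image files found in directory {source}")
        if fps_override is None:
            raise ValueError("an image sequence has no intrinsic rate; pass fps_override")
        fps = fps_override
        images = [_as_rgb(iio.imread(p)) for p in files]
    elif source.is_file():
        try:
            meta = iio.immeta(source)
            images = [_as_rgb(im) for im in iio.imiter(source)]
        except Exception as exc:  # codec/backend missing or corrupt file
            raise ValueError(f"could not decode video file {source}: {exc}") from exc
        if not images:
            raise ValueError(f"video file {source} contains no frames")
        fps = fps_override if fps_override is not None else meta.get("fps")
        if not fps or fps <= 0:
            raise ValueError(
                f"no frame rate in metadata of {source}; pass fps_override"
            )
        if meta.get("codec") and meta.get("duration") is None and fps_override is None:
            raise ValueError(f"{source} appears to have a variable frame rate; refusing")
    else:
        raise FileNotFoundError(f"input source {source} does not exist")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("frames have inconsistent dimensions")
    return [FrameRecord(index=i, timestamp=i / fps, image=im) for i, im in enumerate(images)]


def write_traces(traces: Sequence, path: str | Path) -> None:
    """Write traces to long-format CSV: one row per (ROI, frame).

    Columns: label, time_s, R, G, B, L, a, b, H, S, V, deltaE.  Values are
    written with enough digits to round-trip to at least 6 significant
    figures.
    """
    if len(traces) == 0:
        raise ValueError("no traces to write")
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "label": t.label,
                    "time_s": t.times,
                    "R": t.rgb[:, 0],
                    "G": t.rgb[:, 1],
                    "B": t.rgb[:, 2],
                    "L": t.lab[:, 0],
                    "a": t.lab[:, 1],
                    "b": t.lab[:, 2],
                    "H": t.hsv[:, 0],
                    "S": t.hsv[:, 1],
                    "V": t.hsv[:, 2],
                    "deltaE": t.delta_e,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_traces(path: str | Path) -> list:
    """Read a long-format trace CSV back into ColourTrace objects."""
    from .kinetics import ColourTrace

    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV is missing columns: {sorted(missing)}")
    traces = []
    for label, g in df.groupby("label", sort=False):
        traces.append(
            ColourTrace(
                label=str(label),
                times=g["time_s"].to_numpy(),
                rgb=g[["R", "G", "B"]].to_numpy(),
                lab=g[["L", "a", "b"]].to_numpy(),
                hsv=g[["H", "S", "V"]].to_numpy(),
                delta_e=g["deltaE"].to_numpy(),
            )
        )
    return traces


def iter_images(frames: Sequence[FrameRecord]) -> Iterator[np.ndarray]:
    for f in frames:
        yield f.image
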