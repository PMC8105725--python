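"""Reading and writing the pipeline's on-disk formats.

Movies are multi-page TIFF, 16-bit unsigned, one page per frame; channels
go to separate files suffixed ``_C0`` / ``_C1``.  Tables (tracks, ground
truth, per-cell results) are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Movie, Track, tracks_from_dataframe, tracks_to_dataframe


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as multi-page uint16 TIFF with resolution metadata."""
    frames = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        str(path), frames, photometric="minisblack",
        resolution=(1.0 / movie.pixel_size_um, 1.0 / movie.pixel_size_um),
        metadata={"axes": "TYX", "frame_interval_s": movie.frame_interval_s,
                  "pixel_size_um": movie.pixel_size_um, "channel": movie.channel},
    )


def read_movie(path: str | Path, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None, channel: str = "C0") -> Movie:
    """Read a multi-page TIFF; metadata arguments override what the file has."""
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(
        frames=frames.astype(float),
        pixel_size_um=pixel_size_um or float(meta.get("pixel_size_um", 0.15)),
        frame_interval_s=frame_interval_s or float(meta.get("frame_interval_s", 1.0)),
        channel=str(meta.get("channel", channel)),
    )


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image).astype(np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_tracks(path: str | Path, tracks: list[Track], frame_interval_s: float = 1.0) -> None:
    tracks_to_dataframe(tracks, frame_interval_s).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    return tracks_from_dataframe(pd.read_csv(path))
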