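"""Core containers shared across the pipeline.

A :class:`Movie` is a time-ordered single-channel image stack with physical
calibration (pixel size in micrometers, frame interval in seconds).  A
:class:`Track` is one punctum's per-frame sub-pixel positions and
background-subtracted 3x3 intensities.  Physical coordinates use the
pixel-center convention: ``x_um = (col_index + 0.5) * pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: TIRF pixel size of the acquisition geometry emulated throughout (150 nm).
DEFAULT_PIXEL_SIZE_UM = 0.15


@dataclass
class Movie:
    """A single-channel image stack with acquisition metadata.

    Parameters
    ----------
    frames : ndarray of shape (T, H, W)
        Per-frame images.  Kept in floating point through the analysis so
        corrected intensities may be negative; written to disk as uint16.
    pixel_size_um : float
        Physical pixel size in micrometers.
    frame_interval_s : float
        Time between consecutive frames in seconds.
    channel : str
        Channel label ("C0" reference / "C1" partner by convention).
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = 1.0
    channel: str = "C0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class SpotDetection:
    """A single-frame detection with sub-pixel center and detector response."""

    frame: int
    x_px: float
    y_px: float
    quality: float


@dataclass
class Track:
    """One punctum's linked per-frame observations.

    ``frames`` are strictly increasing but may contain gaps up to the
    linker's ``max_gap``.  ``intensity`` holds the 3x3 background-subtracted
    sums in ADU (NaN where unmeasured, e.g. a border frame).
    """

    track_id: int
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    intensity: np.ndarray | None = None
    cell_id: int | None = None
    channel: str = "C0"
    censored: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_frames(self) -> int:
        """Number of observed frames (gaps are not counted)."""
        return int(self.frames.size)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])


TRACK_COLUMNS = ["track_id", "channel", "frame", "time_s", "x_um", "y_um", "intensity_adu", "cell_id"]


def tracks_to_dataframe(tracks: list[Track], frame_interval_s: float = 1.0) -> pd.DataFrame:
    """Flatten a list of tracks into the long-format track table."""
    rows = []
    for t in tracks:
        inten = t.intensity if t.intensity is not None else np.full(t.n_frames, np.nan)
        for i in range(t.n_frames):
            rows.append(
                (t.track_id, t.channel, int(t.frames[i]), t.frames[i] * frame_interval_s,
                 t.x_um[i], t.y_um[i], inten[i], t.cell_id)
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def tracks_from_dataframe(df: pd.DataFrame) -> list[Track]:
    """Inverse of :func:`tracks_to_dataframe`."""
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        cell = g["cell_id"].iloc[0]
        tracks.append(
            Track(
                track_id=int(tid),
                frames=g["frame"].to_numpy(),
                x_um=g["x_um"].to_numpy(),
                y_um=g["y_um"].to_numpy(),
                intensity=g["intensity_adu"].to_numpy(),
                cell_id=None if pd.isna(cell) else int(cell),
                channel=str(g["channel"].iloc[0]),
            )
        )
    return tracks
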