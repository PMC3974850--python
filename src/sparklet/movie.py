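"""Core data containers for fluorescence movies and cell label masks.

A :class:`Movie` is a 3-D intensity stack (frame x row x col) together with the
acquisition metadata needed to convert frames to seconds and pixels to
micrometres.  A :class:`CellMask` is a single label image (0 = background,
k = cell k) sharing the movie's pixel grid.  Movies are stored on disk as
multi-page 16-bit TIFF, masks as single-page 16-bit TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["AcquisitionParams", "Movie", "CellMask"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings of a TIRF recording.

    Parameters
    ----------
    n_frames : int
        Number of frames in the recording (default 2000).
    frame_rate : float
        Acquisition rate in Hz (default 150).
    pixel_size : float
        Pixel pitch in micrometres per pixel.
    frame_shape : tuple of int
        (rows, cols) of each frame.
    """

    n_frames: int = 2000
    frame_rate: float = 150.0
    pixel_size: float = 0.4
    frame_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 1:
            raise ValueError("frame_shape must be (rows, cols) with positive sizes")

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size**2


@dataclass
class Movie:
    """A grayscale fluorescence stack with acquisition metadata.

    ``data`` has shape ``(n_frames, rows, cols)``; intensities are arbitrary
    camera units (the analysis self-normalizes to F/F0 per ROI).
    """

    data: np.ndarray
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D (frame, row, col)")
        t, r, c = self.data.shape
        if (t, (r, c)) != (self.acq.n_frames, tuple(self.acq.frame_shape)):
            # keep metadata authoritative about shape
            object.__setattr__(self, "acq", AcquisitionParams(
                n_frames=t,
                frame_rate=self.acq.frame_rate,
                pixel_size=self.acq.pixel_size,
                frame_shape=(r, c),
            ))

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def save(self, path: str | Path) -> None:
        """Write as multi-page unsigned 16-bit TIFF, one page per frame."""
        arr = np.clip(np.rint(self.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(
            str(path),
            arr,
            metadata={
                "frame_rate_hz": self.acq.frame_rate,
                "pixel_size_um": self.acq.pixel_size,
            },
        )

    @classmethod
    def load(cls, path: str | Path, frame_rate: float, pixel_size: float) -> "Movie":
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        t, r, c = data.shape
        acq = AcquisitionParams(
            n_frames=t, frame_rate=frame_rate, pixel_size=pixel_size, frame_shape=(r, c)
        )
        return cls(data=data.astype(np.float32), acq=acq)


@dataclass
class CellMask:
    """Per-pixel cell label image (0 = background, k = cell k)."""

    labels: np.ndarray
    pixel_size: float = 0.4

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D image")
        if np.any(self.labels < 0):
            raise ValueError("mask labels must be non-negative integers")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def pixel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(n) for i, n in zip(ids, counts) if i > 0}

    def areas_mm2(self) -> dict[int, float]:
        """Membrane area per cell: pixel count x pixel_size^2, in mm^2."""
        f = self.pixel_size**2 * 1e-6  # um^2 -> mm^2
        return {k: n * f for k, n in self.pixel_counts().items()}

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.labels.astype(np.uint16))

    @classmethod
    def load(cls, path: str | Path, pixel_size: float) -> "CellMask":
        labels = tifffile.imread(str(path))
        return cls(labels=np.asarray(labels).astype(np.int32), pixel_size=pixel_size)
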