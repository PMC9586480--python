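"""Image stack container and TIFF round-trip.

Frames are stored as a ``(T, H, W)`` float array together with the physical
calibration (pixel size in micrometres per pixel, frame interval in seconds).
On disk a stack is a multi-page 16-bit grayscale TIFF accompanied by a JSON
sidecar holding the calibration, so the pair survives tools that strip TIFF
tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import DataError

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    frames: np.ndarray  # (T, H, W)
    pixel_size: float  # um / px
    frame_interval: float  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DataError(f"expected (T, H, W) frames, got shape {self.frames.shape}")
        if self.frames.shape[0] == 0:
            raise DataError("empty stack")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise DataError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def save(self, path: str | Path) -> Path:
        """Write a 16-bit unsigned multi-page TIFF plus a ``.json`` sidecar."""
        path = Path(path)
        data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            **self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None,
             frame_interval: float | None = None) -> "ImageStack":
        """Read a TIFF written by :meth:`save`.

        Calibration is taken from the sidecar when present; explicit arguments
        override it.
        """
        path = Path(path)
        frames = tifffile.imread(path).astype(np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        px = pixel_size if pixel_size is not None else meta.pop("pixel_size_um", None)
        dt = frame_interval if frame_interval is not None else meta.pop("frame_interval_s", None)
        if px is None or dt is None:
            raise DataError(f"no calibration for {path}; pass pixel_size/frame_interval")
        return cls(frames, float(px), float(dt), meta)
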