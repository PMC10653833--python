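"""In-memory fluorescence frames and TIFF I/O.

Analysis is done in floating point; images are stored on disk as 16-bit
unsigned TIFF (one page per frame), the acquisition format of typical sCMOS
cameras.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile

__all__ = ["FluorFrame", "write_frames_tiff", "read_frames_tiff"]


@dataclass
class FluorFrame:
    """A single-channel 2D fluorescence image.

    Parameters
    ----------
    image : 2D float array, linear intensity (a.u.)
    pixel_size : µm per pixel
    time_min : acquisition time in minutes (time-lapse only)
    background_corrected : whether the background has been subtracted
    """

    image: np.ndarray
    pixel_size: float
    time_min: float | None = None
    background_corrected: bool = False

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("FluorFrame.image must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self):
        return self.image.shape

    def with_image(self, image, **kw) -> "FluorFrame":
        out = replace(self, **kw)
        out.image = np.asarray(image, dtype=float)
        return out


def write_frames_tiff(frames, path) -> None:
    """Write frames as a multi-page 16-bit unsigned TIFF (values clipped)."""
    frames = [frames] if isinstance(frames, FluorFrame) else list(frames)
    stack = np.stack([np.clip(np.rint(f.image), 0, 65535).astype(np.uint16) for f in frames])
    tifffile.imwrite(str(path), stack)


def read_frames_tiff(path, pixel_size: float, frame_interval: float | None = None):
    """Read a (multi-page) TIFF into a list of :class:`FluorFrame`.

    ``frame_interval`` (min) assigns timestamps ``i * frame_interval``.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    out = []
    for i, page in enumerate(arr):
        t = None if frame_interval is None else i * frame_interval
        out.append(FluorFrame(page.astype(float), pixel_size=pixel_size, time_min=t))
    return out
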