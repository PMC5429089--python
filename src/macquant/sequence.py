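"""Calibrated multi-frame two-channel image stacks and their TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageSequence", "load_tiff", "save_tiff"]


@dataclass
class ImageSequence:
    """A time-lapse raster stack with physical calibration.

    data
        Array of shape (n_frames, n_channels, rows, cols), float intensities.
    pixel_size_um
        Lateral pixel size in micrometers per pixel.
    frame_interval_s
        Time between consecutive frames in seconds.
    channel_names
        One name per channel; by convention channel 0 is the membrane dye
        (labels the Ld phase) and channel 1 the labeled actin.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple = ("membrane", "actin")

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None, None]
        elif self.data.ndim == 3:
            self.data = self.data[:, None]
        if self.data.ndim != 4:
            raise ValueError("data must have shape (frames, channels, rows, cols)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[1]))

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple:
        return self.data.shape[2:]

    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes (frame 0 = 0 min)."""
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0

    def channel(self, name_or_index) -> np.ndarray:
        """Stack (frames, rows, cols) of one channel, by name or index."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(f"no channel named {name_or_index!r}; "
                               f"have {self.channel_names}") from None
        else:
            idx = int(name_or_index)
        return self.data[:, idx]


def save_tiff(seq: ImageSequence, path, interleaved: bool = True) -> list:
    """Write a sequence as multi-page TIFF.

    With ``interleaved=True`` a single file with pages ordered
    frame0/ch0, frame0/ch1, frame1/ch0, ... is written (mirroring
    interleaved two-color acquisition); otherwise one file per channel
    (suffix ``_<channel>.tif``).  Returns the list of written paths.
    """
    path = Path(path)
    meta = {"pixel_size_um": seq.pixel_size_um,
            "frame_interval_s": seq.frame_interval_s,
            "channel_names": list(seq.channel_names)}
    written = []
    if interleaved:
        pages = seq.data.reshape(-1, *seq.shape).astype(np.float32)
        tifffile.imwrite(path, pages, metadata=meta, photometric="minisblack")
        written.append(path)
    else:
        for i, name in enumerate(seq.channel_names):
            p = path.with_name(f"{path.stem}_{name}.tif")
            tifffile.imwrite(p, seq.data[:, i].astype(np.float32), metadata=meta,
                             photometric="minisblack")
            written.append(p)
    return written


def load_tiff(path, pixel_size_um: float | None = None,
              frame_interval_s: float | None = None,
              n_channels: int = 2) -> ImageSequence:
    """Read an interleaved multi-page TIFF back into an ImageSequence.

    Calibration is taken from the TIFF metadata written by :func:`save_tiff`
    when present; explicit arguments override it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    names = tuple(meta.get("channel_names", ())) or tuple(f"ch{i}" for i in range(n_channels))
    if px is None or dt is None:
        raise ValueError("pixel size and frame interval must come from metadata or arguments")
    if pages.ndim == 2:
        pages = pages[None]
    nc = len(names)
    if pages.shape[0] % nc:
        raise ValueError(f"page count {pages.shape[0]} not divisible by {nc} channels")
    data = pages.reshape(pages.shape[0] // nc, nc, *pages.shape[1:])
    return ImageSequence(data=data, pixel_size_um=float(px),
                         frame_interval_s=float(dt), channel_names=names)
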