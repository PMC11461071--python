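"""Field-image container and TIFF/CSV I/O.

A *field* is one multi-channel 2D fluorescence image: a set of named
channels (e.g. ``dapi``, ``marker_nuclear``, ``marker_cyto``, ``protein``)
on a common raster, with a physical pixel size in micrometres.  Channels
are stored as float arrays in raw intensity units; label maps are integer
arrays with 0 = background.

Multi-channel TIFFs are written one page per channel with the channel
name (and pixel size) recorded as JSON in the page description, so a
round trip preserves channel identity without side-car files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

DEFAULT_PIXEL_SIZE_UM = 0.102


@dataclass
class FieldImage:
    """Named fluorescence channels on a common raster.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2D array of non-negative, finite
        intensities.  All channels must share one shape.
    pixel_size_um
        Physical edge length of a pixel in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channels must be 2D, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channels do not share one shape: {shapes}")
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def write_field_tiff(fieldimg: FieldImage, path) -> None:
    """Write a field as a multi-page TIFF, one page per channel."""
    with tifffile.TiffWriter(path) as tif:
        for name, ch in fieldimg.channels.items():
            desc = json.dumps({"channel": name, "pixel_size_um": fieldimg.pixel_size_um})
            tif.write(ch.astype(np.float32), description=desc, contiguous=False)


def read_field_tiff(path) -> FieldImage:
    """Read a multi-page TIFF written by :func:`write_field_tiff`.

    Pages without a JSON description fall back to names ``ch0``, ``ch1``...
    """
    channels: dict[str, np.ndarray] = {}
    pixel_size = DEFAULT_PIXEL_SIZE_UM
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = f"ch{i}"
            desc = page.description
            if desc:
                try:
                    meta = json.loads(desc)
                    name = meta.get("channel", name)
                    pixel_size = float(meta.get("pixel_size_um", pixel_size))
                except (json.JSONDecodeError, TypeError):
                    pass
            channels[name] = page.asarray().astype(float)
    return FieldImage(channels=channels, pixel_size_um=pixel_size)


def write_label_tiff(labels: np.ndarray, path) -> None:
    """Write an integer label map (0 = background) as a TIFF."""
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label maps must be non-negative")
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


def read_label_tiff(path) -> np.ndarray:
    labels = tifffile.imread(path)
    return np.asarray(labels).astype(np.int32)
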