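"""Multichannel image and label-mask I/O on multi-page TIFF.

Channel stacks are written one page per marker with the channel names and
pixel size embedded as JSON in the ImageDescription tag, so a stack can be
matched back to its panel either by embedded name or by page order.
Coordinates are micrometers with the origin at the center of pixel (0, 0),
x increasing along columns and y along rows.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError
from .panel import MarkerPanel


@dataclass
class MultichannelImage:
    """One 2-D nonnegative intensity grid per marker, all of one shape."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0

    def __post_init__(self):
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel grids have differing shapes: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    @property
    def marker_names(self) -> list[str]:
        return list(self.channels)


def write_image(image: MultichannelImage, path) -> None:
    names = image.marker_names
    stack = np.stack([image.channels[m] for m in names]).astype(np.float32)
    meta = {"channels": names, "pixel_size_um": image.pixel_size_um}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, stack, photometric="minisblack", description=json.dumps(meta)
    )


def read_image(path, panel: MarkerPanel) -> MultichannelImage:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(f"expected a 2-D page stack, got shape {stack.shape}")

    names = None
    pixel_size = 1.0
    if desc:
        try:
            meta = json.loads(desc)
            names = meta.get("channels")
            pixel_size = float(meta.get("pixel_size_um", 1.0))
        except (json.JSONDecodeError, TypeError, AttributeError):
            names = None
    if names is not None:
        unknown = [n for n in names if n not in panel]
        if unknown:
            raise FormatError(f"channels not in panel: {unknown}")
        if len(names) != stack.shape[0]:
            raise FormatError(
                f"metadata lists {len(names)} channels but stack has "
                f"{stack.shape[0]} pages"
            )
    else:
        if stack.shape[0] != len(panel):
            raise FormatError(
                f"stack has {stack.shape[0]} pages but panel has "
                f"{len(panel)} entries and no embedded channel names"
            )
        names = panel.markers
    channels = {n: np.asarray(stack[i], dtype=np.float64) for i, n in enumerate(names)}
    return MultichannelImage(channels=channels, pixel_size_um=pixel_size)


def write_label_mask(labels: np.ndarray, path) -> None:
    """Write an integer cell-label grid as 16-bit unsigned TIFF (0 = background)."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.int64)
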