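"""Multi-channel image container with TIFF round-tripping.

A :class:`MultiChannelImage` holds one 2D raster per named channel
(e.g. ``"nuclei"``, ``"cytoplasm"``, ``"LAMP2"``) together with the pixel
size in micrometres. All downstream segmentation and scoring stages consume
this container; channel roles are carried by name, not by position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["MultiChannelImage", "LabelMask"]


@dataclass
class MultiChannelImage:
    """Named 2D intensity channels sharing one pixel grid.

    Parameters
    ----------
    channels
        Mapping channel name -> 2D float array (arbitrary intensity units,
        finite and non-negative).
    pixel_size_um
        Physical pixel size in micrometres per pixel.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channels must be 2D, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=np.float64)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def save(self, path) -> None:
        """Write as a multi-page float32 TIFF; channel names and pixel size
        go into the ImageDescription tag as JSON."""
        names = list(self.channels)
        stack = np.stack([self.channels[n] for n in names]).astype(np.float32)
        meta = {"channels": names, "pixel_size_um": self.pixel_size_um}
        tifffile.imwrite(
            path, stack, photometric="minisblack", description=json.dumps(meta)
        )

    @classmethod
    def load(cls, path) -> "MultiChannelImage":
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        if stack.ndim == 2:
            stack = stack[None]
        channels = {n: stack[i].astype(np.float64) for i, n in enumerate(meta["channels"])}
        return cls(channels=channels, pixel_size_um=float(meta["pixel_size_um"]))


@dataclass
class LabelMask:
    """Integer-labelled segmentation (0 = background, k >= 1 = object k).

    ``kind`` records what the objects are ("nucleus" or "cell");
    ``provenance`` records how the mask was produced (threshold method and
    value, flags for degenerate objects) so results are reproducible.
    """

    labels: np.ndarray
    kind: str = "nucleus"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must have an integer dtype")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def ids(self) -> np.ndarray:
        """Sorted object labels present (excluding background)."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label

    def save(self, path) -> None:
        tifffile.imwrite(
            path,
            self.labels.astype(np.int32),
            description=json.dumps({"kind": self.kind}),
        )

    @classmethod
    def load(cls, path, kind: str | None = None) -> "LabelMask":
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description
        if kind is None:
            try:
                kind = json.loads(desc).get("kind", "nucleus")
            except (json.JSONDecodeError, TypeError):
                kind = "nucleus"
        return cls(labels=arr.astype(np.int32), kind=kind)
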