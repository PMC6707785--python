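"""Core in-memory containers for multiplexed ion-count images.

Imaging mass cytometry produces one intensity channel per metal-tagged
antibody, acquired shot-by-shot along laser raster lines at ~1 µm spot
size.  The containers here hold the reconstructed pixel grids plus the
physical pixel size needed for all downstream morphometry in µm/mm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MultichannelImage", "LineScanStack"]


@dataclass
class MultichannelImage:
    """Named marker channels on a shared pixel grid.

    Parameters
    ----------
    channels
        Mapping of marker name to 2D non-negative float array (ion counts
        or normalized intensities). All channels must share one shape.
    pixel_size_um
        Physical edge length of one pixel in µm. 1.0 matches a 1 µm × 1 µm
        laser spot.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultichannelImage requires at least one channel")
        names = list(self.channels)
        if len(names) != len(set(names)):
            raise ValueError("marker names must be unique")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2D, got shape {shape}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=np.float64)
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def markers(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, marker: str) -> np.ndarray:
        return self.channels[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self.channels

    def copy(self) -> "MultichannelImage":
        return MultichannelImage(
            {k: v.copy() for k, v in self.channels.items()},
            pixel_size_um=self.pixel_size_um,
        )


@dataclass
class LineScanStack:
    """Per-shot channel intensities in acquisition order.

    The laser rasters line by line; shot ``i`` lands at pixel
    ``(i // row_width, i % row_width)``. ``values`` has one row per shot
    and one column per channel.
    """

    values: np.ndarray  # (n_shots, n_channels)
    row_width: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2 or self.values.shape[0] == 0:
            raise ValueError("values must be a non-empty (n_shots, n_channels) array")
        if self.row_width < 1:
            raise ValueError("row_width must be >= 1")

    @property
    def n_shots(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]
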