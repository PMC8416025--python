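"""Core voxel container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_CHANNELS = ("total", "tyr", "ac")


@dataclass
class ChannelStack:
    """Calibrated multi-channel 3D voxel data.

    Parameters
    ----------
    voxels
        Array of shape ``(n_channels, nz, ny, nx)`` holding photon counts.
    channel_names
        Ordered channel labels, by convention ``("total", "tyr", "ac")``.
    voxel_size
        ``(x, y, z)`` voxel dimensions in micrometres (post-expansion, i.e.
        as acquired).
    expansion_factor
        Physical gel expansion factor; 1.0 for non-expanded samples.
        Biological lengths are recovered by dividing acquired lengths by it.
    """

    voxels: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    voxel_size: tuple[float, float, float] = (0.03, 0.03, 0.15)
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (C, Z, Y, X), got shape {self.voxels.shape}"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"invalid voxel_size {self.voxel_size}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        if self.voxels.min() < 0:
            raise ValueError("voxels contain negative intensities")
        if self.expansion_factor < 1.0:
            raise ValueError("expansion_factor must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) of a single channel."""
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's (Z, Y, X) volume by label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None
        return self.voxels[idx]

    def with_voxels(self, voxels: np.ndarray) -> "ChannelStack":
        return ChannelStack(
            voxels=voxels,
            channel_names=self.channel_names,
            voxel_size=self.voxel_size,
            expansion_factor=self.expansion_factor,
        )
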