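"""Voxel-volume containers with isotropic µm voxel size.

Volumes store a 3D array plus the world-space metadata needed to convert
between voxel indices and µm coordinates (isotropic ``voxel_size`` and the µm
position of the centre of voxel (0, 0, 0)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["BinaryVolume", "LabelVolume"]


@dataclass
class _Volume:
    data: np.ndarray
    voxel_size: float  # µm, isotropic
    origin: np.ndarray = None  # µm position of voxel (0,0,0) centre

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_index(self, pos: np.ndarray) -> np.ndarray:
        """µm coordinates -> (possibly fractional) voxel indices."""
        return (np.asarray(pos, dtype=float) - self.origin) / self.voxel_size

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.voxel_size + self.origin

    def contains(self, pos: np.ndarray) -> bool:
        idx = np.rint(self.world_to_index(pos)).astype(int)
        return bool(np.all(idx >= 0) and np.all(idx < np.array(self.shape)))

    def value_at(self, pos: np.ndarray):
        """Nearest-neighbour sample at a µm position (None outside bounds)."""
        idx = np.rint(self.world_to_index(pos)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            return None
        return self.data[tuple(idx)]

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def write_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            self.data.astype(np.uint8),
            metadata={"voxel_size_um": self.voxel_size, "origin_um": list(self.origin)},
        )

    @classmethod
    def read_tiff(cls, path, voxel_size: float, origin=None):
        data = tifffile.imread(path)
        return cls(data=data, voxel_size=voxel_size, origin=origin)


@dataclass
class BinaryVolume(_Volume):
    """3D boolean mask (e.g. a vessel segmentation)."""

    def __post_init__(self):
        super().__post_init__()
        self.data = self.data.astype(bool)

    def foreground_volume(self) -> float:
        """Total foreground volume, µm³."""
        return float(self.data.sum()) * self.voxel_volume


@dataclass
class LabelVolume(_Volume):
    """3D integer label field with a legend mapping labels to names."""

    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        self.data = self.data.astype(np.int32)

    def label_volumes(self, include_background: bool = False) -> dict[str, float]:
        """Tissue volume per label name, µm³."""
        out = {}
        for lab, name in self.legend.items():
            if not include_background and name == "background":
                continue
            out[name] = float((self.data == lab).sum()) * self.voxel_volume
        return out
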