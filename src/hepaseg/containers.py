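"""Core in-memory containers shared across the pipeline.

Volumes are stored ``(z, y, x)`` with 0-based voxel indices; ``spacing_mm``
follows the same axis order.  The z axis is the slice (through-plane)
direction, which in abdominal MR is the coarse one (5 mm slices vs 1 mm
in-plane), so anisotropy-aware code always treats axis 0 specially.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Label values used throughout: 0 background, 1 liver, 2 tumor.
BACKGROUND, LIVER, TUMOR = 0, 1, 2


@dataclass
class MultisequenceVolume:
    """Two co-registered 3D MR intensity channels on one voxel grid.

    Parameters
    ----------
    channels
        Float array of shape ``(2, z, y, x)``: channel 0 is the arterial
        phase (tumor hyperintense), channel 1 the T2-weighted sequence.
    spacing_mm
        Voxel size per axis ``(z, y, x)`` in millimetres.
    origin_mm
        Physical coordinate of voxel ``(0, 0, 0)``.
    """

    channels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 4 or self.channels.shape[0] != 2:
            raise ValueError(
                f"channels must have shape (2, z, y, x), got {self.channels.shape}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(s) for s in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("channel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]

    @property
    def arterial(self) -> np.ndarray:
        return self.channels[0]

    @property
    def t2(self) -> np.ndarray:
        return self.channels[1]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_channels(self, channels: np.ndarray) -> "MultisequenceVolume":
        return replace(self, channels=np.asarray(channels, dtype=np.float64))


@dataclass
class SegmentationMask:
    """Integer label volume on the same grid as a :class:`MultisequenceVolume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(s) for s in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def binary(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities from a network's final softmax.

    ``classes`` has shape ``(n_classes, z, y, x)`` and sums to 1 over axis 0.
    For the binary stages used here, class 1 is the foreground
    (liver in stage 1, tumor in stage 2).
    """

    classes: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.float64)
        if self.classes.ndim != 4:
            raise ValueError("classes must have shape (n_classes, z, y, x)")

    @property
    def foreground(self) -> np.ndarray:
        return self.classes[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.classes.shape[1:]


def check_same_grid(a, b, what: str = "operands") -> None:
    """Raise if two grid-bearing objects disagree on shape or spacing."""
    if tuple(a.shape) != tuple(b.shape):
        raise ValueError(f"{what} on different grids: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm):
        raise ValueError(
            f"{what} with different spacing: {a.spacing_mm} vs {b.spacing_mm}"
        )
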