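"""In-memory image containers.

The engine passes a single *current image* from module to module.  That image
is always a :class:`VoxelGrid` — a calibrated scalar stack indexed ``(z, y,
x)`` — or one of its two specialised flavours, :class:`BinaryMask` (the output
of thresholding) and :class:`LabelMap` (background 0, objects ``1..N``).
Multi-channel / multi-frame files live in a :class:`MultiDimImage` with fixed
axis order ``(t, c, z, y, x)``; a mono-channel plane is pulled out with
:func:`extract_plane` before any processing happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StoreError


@dataclass(frozen=True)
class Calibration:
    """Physical voxel size: isotropic in XY, separate Z step, plus a unit name."""

    pixel_size_xy: float = 1.0
    pixel_size_z: float = 1.0
    unit: str = "pixel"

    def __post_init__(self):
        if not (self.pixel_size_xy > 0 and self.pixel_size_z > 0):
            raise StoreError(
                f"calibration sizes must be positive, got xy={self.pixel_size_xy}, "
                f"z={self.pixel_size_z}"
            )

    @property
    def voxel_volume(self) -> float:
        return self.pixel_size_xy * self.pixel_size_xy * self.pixel_size_z


_PATH_SEPS = ("/", "\\")


@dataclass(frozen=True, order=True)
class ImageRef:
    """Identity of one database image: project / dataset / image name (no extension)."""

    project: str
    dataset: str
    image: str

    def __post_init__(self):
        for fieldname in ("project", "dataset", "image"):
            value = getattr(self, fieldname)
            if not value:
                raise StoreError(f"ImageRef.{fieldname} must be non-empty")
            if any(sep in value for sep in _PATH_SEPS):
                raise StoreError(
                    f"ImageRef.{fieldname} may not contain a path separator: {value!r}"
                )

    def __str__(self) -> str:
        return f"{self.project}/{self.dataset}/{self.image}"


@dataclass
class ImageInfo:
    """Provenance of the current image.

    ``ref`` always names the ORIGINAL database image of the batch item; it is
    never rewritten by processing modules, which is what keeps ``?image?``
    naming correct throughout a protocol.  ``channel`` and ``frame`` are
    1-based and default to 1 when no specific plane was selected.
    """

    ref: ImageRef
    channel: int = 1
    frame: int = 1


class VoxelGrid:
    """A calibrated scalar image stack, indexed ``(z, y, x)``.

    2D images are represented with ``nz == 1``.
    """

    kind = "intensity"

    def __init__(self, data: np.ndarray, calibration: Calibration | None = None):
        data = np.asarray(data)
        if data.ndim == 2:
            data = data[np.newaxis, ...]
        if data.ndim != 3:
            raise StoreError(f"VoxelGrid expects 2D or 3D data, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise StoreError(f"VoxelGrid extents must be >= 1, got {data.shape}")
        self.data = data
        self.calibration = calibration if calibration is not None else Calibration()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid of the same class and calibration around ``data``."""
        return type(self)(data, self.calibration)

    def with_calibration(self, calibration: Calibration) -> "VoxelGrid":
        return type(self)(self.data, calibration)

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}(shape={self.data.shape}, dtype={self.data.dtype}, "
            f"xy={self.calibration.pixel_size_xy}, z={self.calibration.pixel_size_z} "
            f"{self.calibration.unit})"
        )


class BinaryMask(VoxelGrid):
    """Boolean foreground mask."""

    kind = "binary"

    def __init__(self, data, calibration: Calibration | None = None):
        super().__init__(np.asarray(data).astype(bool, copy=False), calibration)


class LabelMap(VoxelGrid):
    """Non-negative integer objects image: background 0, objects ``1..N``."""

    kind = "label"

    def __init__(self, data, calibration: Calibration | None = None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.integer):
            raise StoreError(f"LabelMap requires integer data, got {data.dtype}")
        if data.size and data.min() < 0:
            raise StoreError("LabelMap values must be non-negative")
        super().__init__(data, calibration)

    @property
    def n_labels(self) -> int:
        return int(self.data.max())

    def labels(self) -> np.ndarray:
        """Sorted array of the label ids present (excluding background)."""
        ids = np.unique(self.data)
        return ids[ids > 0]


_GRID_KINDS = {cls.kind: cls for cls in (VoxelGrid, BinaryMask, LabelMap)}


def grid_class(kind: str) -> type[VoxelGrid]:
    return _GRID_KINDS.get(kind, VoxelGrid)


@dataclass
class MultiDimImage:
    """A full multi-dimensional image, axes ``(t, c, z, y, x)``, all extents >= 1."""

    data: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    kind: str = "intensity"

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim > 5:
            raise StoreError(f"at most 5 axes (t,c,z,y,x) supported, got {data.ndim}")
        while data.ndim < 5:
            data = data[np.newaxis, ...]
        self.data = data

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def extract_plane(img: MultiDimImage, channel: int = 1, frame: int = 1) -> VoxelGrid:
    """Pull the mono-channel Z-stack for a 1-based (channel, frame) pair."""
    if not 1 <= channel <= img.n_channels:
        raise StoreError(
            f"channel {channel} out of range: image has {img.n_channels} channel(s)"
        )
    if not 1 <= frame <= img.n_frames:
        raise StoreError(
            f"frame {frame} out of range: image has {img.n_frames} frame(s)"
        )
    cls = grid_class(img.kind)
    return cls(img.data[frame - 1, channel - 1], img.calibration)
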