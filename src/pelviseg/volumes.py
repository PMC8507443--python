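"""In-memory containers for CT data and derived masks/labels.

All grids use a fixed internal axis order ``(x, y, z)``: ``data[i, j, k]`` is
the voxel at physical position ``origin + direction @ (i*sx, j*sy, k*sz)``.
File readers convert on-disk layouts (e.g. the z-fastest order of SimpleITK
arrays, or DICOM's row/column order) into this convention, so no downstream
operator has to care about storage order.

Intensities are always Hounsfield units (HU); raw stored values are rescaled
on read.  Label volumes use the codes ``0`` (background), ``1`` (compact
bone) and ``2`` (filled bone interior / marrow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ParameterError

#: Label codes used throughout the package.
BACKGROUND, COMPACT_BONE, INTERIOR = 0, 1, 2
LABEL_CODES = (BACKGROUND, COMPACT_BONE, INTERIOR)


def _identity_direction() -> np.ndarray:
    return np.eye(3)


@dataclass
class _Grid:
    """Shared geometry bookkeeping for all 3D grids."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=_identity_direction)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ParameterError(
                f"expected a 3D grid with each dimension >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ParameterError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing components must be strictly positive: {self.spacing}")
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3, 3):
            raise ParameterError("direction must be a 3x3 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def geometry(self) -> tuple:
        return (self.spacing, self.origin, self.direction)

    def same_grid(self, other: "_Grid") -> bool:
        """True when shapes and geometry agree (within float tolerance)."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.direction, other.direction)
        )

    def require_same_grid(self, other: "_Grid", what: str = "grids") -> None:
        if not self.same_grid(other):
            raise AlignmentError(
                f"{what} are not aligned: {self.shape}/{self.spacing} vs "
                f"{other.shape}/{other.spacing}"
            )


@dataclass
class CTVolume(_Grid):
    """A 3D scalar CT volume in Hounsfield units."""

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data, dtype=np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("CT intensities must be finite")

    def with_data(self, data: np.ndarray) -> "CTVolume":
        """New volume with the same geometry and different intensities."""
        return CTVolume(data, self.spacing, self.origin, self.direction.copy())


@dataclass
class BinaryMask(_Grid):
    """A boolean mask aligned to a parent :class:`CTVolume`."""

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data, dtype=bool)

    @classmethod
    def like(cls, parent: _Grid, data: np.ndarray) -> "BinaryMask":
        mask = cls(np.asarray(data, dtype=bool), parent.spacing, parent.origin,
                   parent.direction.copy())
        if mask.shape != parent.shape:
            raise AlignmentError(f"mask shape {mask.shape} != parent shape {parent.shape}")
        return mask

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume(_Grid):
    """Segmentation labels: 0 background, 1 compact bone, 2 interior/marrow.

    The union of codes 1 and 2 is the final "bone" region: enclosed cavities
    are deliberately kept as a separate code because downstream material
    decomposition assigns them marrow composition.
    """

    def __post_init__(self):
        super().__post_init__()
        data = np.asarray(self.data)
        if not np.isin(np.unique(data), LABEL_CODES).all():
            raise ParameterError(
                f"label volume may only contain codes {LABEL_CODES}, got {np.unique(data)}"
            )
        self.data = data.astype(np.uint8)

    @classmethod
    def like(cls, parent: _Grid, data: np.ndarray) -> "LabelVolume":
        lab = cls(data, parent.spacing, parent.origin, parent.direction.copy())
        if lab.shape != parent.shape:
            raise AlignmentError(f"label shape {lab.shape} != parent shape {parent.shape}")
        return lab

    def bone_mask(self) -> BinaryMask:
        """Binary mask of the full bone region (codes 1 and 2 pooled)."""
        return BinaryMask.like(self, self.data > 0)
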