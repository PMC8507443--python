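"""Dual-threshold segmentation, local-maximum mask, and seeded 3D region growing.

The region-growing admissibility criteria are precomputed once before
growth, which turns growing into a pure reachability problem over the
admissible voxel graph — both an optimization and the correctness contract
(the result cannot depend on growth order).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import ParameterError
from .preprocessing import DEFAULT_AIR_THRESHOLD
from .volumes import BinaryMask, CTVolume

log = logging.getLogger("pelviseg")

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PipelineParams:
    """All tunable pipeline parameters, in Hounsfield units and millimetres.

    ``t_bone`` (the lower threshold) selects most of the compact bone;
    ``t_seed`` (strictly larger) selects the seed regions for region
    growing.  ``box_n`` is the odd side length, in voxels, of the box filter
    used for the local-maximum criterion.  ``accept_low``/``accept_high``
    bound the intensity acceptance range during growing (open above by
    default: dense cortical bone must never be excluded).
    ``merge_radius_mm`` controls how far apart bone parts may be and still
    be merged before hole filling.

    Default HU values follow the partial-volume half-maximum rule: under
    blur, the unbiased iso-contour between two tissues lies at the midpoint
    of their intensities, so the bone threshold sits halfway between
    nominal cortical bone (~1200 HU) and soft tissue (~0-50 HU), the seed
    threshold well inside compact bone, and the growing acceptance at the
    half-maximum for reduced-density cortical bone so that growth can
    recover weak-boundary bone the main threshold misses.
    """

    t_bone: float = 600.0
    t_seed: float = 900.0
    box_n: int = 9
    accept_low: float = 450.0
    accept_high: float = float("inf")
    merge_radius_mm: float = 3.0
    air_threshold: float = DEFAULT_AIR_THRESHOLD

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.t_seed > self.t_bone:
            raise ParameterError(
                f"t_seed ({self.t_seed}) must be larger than t_bone ({self.t_bone})")
        if self.box_n % 2 == 0 or self.box_n < 3:
            raise ParameterError(f"box_n must be odd and >= 3, got {self.box_n}")
        if not self.accept_low <= self.accept_high:
            raise ParameterError(
                f"accept_low ({self.accept_low}) must be <= accept_high ({self.accept_high})")
        if self.merge_radius_mm < 0:
            raise ParameterError("merge_radius_mm must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown pipeline parameters: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def threshold_segment(vol: CTVolume, params: PipelineParams
                      ) -> tuple[BinaryMask, BinaryMask]:
    """Dual-threshold segmentation.

    Returns ``(bone_mask, seed_mask)`` where ``bone_mask = {v >= t_bone}``
    captures most of the compact bone and ``seed_mask = {v >= t_seed}`` the
    high-confidence seed regions (a subset of ``bone_mask``).
    """
    params.validate()
    bone = vol.data >= params.t_bone
    seed = vol.data >= params.t_seed
    if not bone.any():
        log.info("threshold_segment: bone mask is empty")
    log.info("threshold_segment: bone=%d seed=%d voxels", int(bone.sum()), int(seed.sum()))
    return BinaryMask.like(vol, bone), BinaryMask.like(vol, seed)


def _box_sums_and_counts(data: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding n^3 box sums and window sizes with shrinking windows at borders.

    Separable cumulative-sum implementation; exact for integer-valued HU
    data (sums stay below 2**53), so strict comparisons are not affected by
    filter round-off.
    """
    r = n // 2
    sums = data.astype(np.float64)
    counts = np.ones(data.shape, dtype=np.float64)
    for axis in range(3):
        for arr_name in ("sums", "counts"):
            arr = sums if arr_name == "sums" else counts
            cs = np.cumsum(arr, axis=axis)
            cs = np.concatenate([np.zeros_like(np.take(cs, [0], axis=axis)), cs],
                                axis=axis)
            length = data.shape[axis]
            hi = np.minimum(np.arange(length) + r, length - 1) + 1
            lo = np.maximum(np.arange(length) - r, 0)
            windowed = np.take(cs, hi, axis=axis) - np.take(cs, lo, axis=axis)
            if arr_name == "sums":
                sums = windowed
            else:
                counts = windowed
    return sums, counts


def local_maximum_mask(vol: CTVolume, box_n: int = 9) -> BinaryMask:
    """Voxels whose intensity strictly exceeds their n^3 box-filter mean.

    The resulting mask is an accurate binary representation of the compact
    bone (plus structures from lower-intensity tissues).  At the volume
    border the mean is taken over the intersection of the box with the
    volume (shrinking window), avoiding the spurious border maxima that
    zero-padding would create.  Ties count as 0, so a constant volume gives
    an all-zero mask, and the mask is invariant under adding a constant to
    all intensities.
    """
    if box_n % 2 == 0 or box_n < 3:
        raise ParameterError(f"box_n must be odd and >= 3, got {box_n}")
    data = vol.data.astype(np.float64)
    sums, counts = _box_sums_and_counts(data, box_n)
    # data > sums/counts, rearranged to avoid division round-off
    mask = data * counts > sums
    return BinaryMask.like(vol, mask)


def region_grow(vol: CTVolume, seed_mask: BinaryMask, lmax_mask: BinaryMask,
                params: PipelineParams) -> BinaryMask:
    """Seeded 3D region growing with 26-connectivity.

    A voxel is added iff it is 26-connected to the growing region and meets
    both precomputed criteria: (a) its intensity strictly exceeds its local
    box-filter mean (``lmax_mask``) and (b) its intensity lies inside the
    acceptance range ``[accept_low, accept_high]``.  Seed voxels are always
    included.  Because admissibility is precomputed, the result is the set
    of admissible voxels 26-connected to a seed — independent of growth
    order.
    """
    vol.require_same_grid(seed_mask, "volume and seed mask")
    vol.require_same_grid(lmax_mask, "volume and local-maximum mask")
    params.validate()
    if not seed_mask.data.any():
        warnings.warn("region_grow: empty seed mask, returning empty result",
                      stacklevel=2)
        return BinaryMask.like(vol, np.zeros(vol.shape, dtype=bool))

    in_range = (vol.data >= params.accept_low) & (vol.data <= params.accept_high)
    admissible = lmax_mask.data & in_range
    allowed = admissible | seed_mask.data
    labels, _ = ndimage.label(allowed, structure=_CONN26)
    seed_labels = np.unique(labels[seed_mask.data])
    seed_labels = seed_labels[seed_labels > 0]
    grown = np.isin(labels, seed_labels)
    log.info("region_grow: seeds=%d grown=%d voxels",
             seed_mask.count(), int(grown.sum()))
    return BinaryMask.like(vol, grown)


def combine_masks(grown: BinaryMask, bone_mask: BinaryMask) -> BinaryMask:
    """Voxelwise union of the region-growing and threshold results."""
    grown.require_same_grid(bone_mask, "masks to combine")
    return BinaryMask.like(grown, grown.data | bone_mask.data)
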