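"""Intensity normalization and patient-table removal.

The first pipeline stage makes volumes from different scanners/tube voltages
comparable by matching each volume's intensity distribution to a stored
reference (classical monotone CDF/quantile matching), and removes everything
that is not the patient's body (table, cushions) by keeping the largest
above-air connected component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import EmptyBodyError, ParameterError
from .volumes import BinaryMask, CTVolume

log = logging.getLogger("pelviseg")

#: HU histogram support: 1-HU-wide bins over [-1024, 3072).
HU_MIN = -1024.0
HU_MAX = 3072.0
DEFAULT_AIR_THRESHOLD = -500.0

_BIN_EDGES = np.arange(HU_MIN, HU_MAX + 1.0)  # 4097 edges -> 4096 bins


@dataclass
class ReferenceHistogram:
    """Compressed empirical CDF of body-voxel intensities of a reference CT.

    ``bin_edges`` are ascending HU values and ``cdf`` the cumulative
    probability at each edge; the curve is interpreted piecewise-linearly.
    The first point anchors the curve at the bottom of the HU range with
    probability 0 so that sub-body intensities (air) map near themselves.
    """

    bin_edges: np.ndarray
    cdf: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cdf = np.asarray(self.cdf, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.shape != self.cdf.shape:
            raise ParameterError("bin_edges and cdf must be 1D arrays of equal length")
        if len(self.bin_edges) < 2:
            raise ParameterError("reference histogram needs at least two points")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ParameterError("bin_edges must be strictly increasing")
        if self.cdf[0] < 0 or not np.isclose(self.cdf[-1], 1.0):
            raise ParameterError("cdf must start >= 0 and end at 1")
        if np.any(np.diff(self.cdf) < 0):
            raise ParameterError("cdf must be nondecreasing")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_volume(cls, vol: CTVolume,
                    air_threshold: float = DEFAULT_AIR_THRESHOLD,
                    source_id: str = "") -> "ReferenceHistogram":
        """Build the reference from the body voxels of a CT volume."""
        body = vol.data[vol.data > air_threshold]
        if body.size == 0:
            raise EmptyBodyError("no voxel above the air threshold")
        edges, cdf = _empirical_cdf(body)
        return cls(edges, cdf, source_id=source_id)

    @classmethod
    def from_file(cls, path: str | Path) -> "ReferenceHistogram":
        """Load from a 2-column CSV (``bin_edge,cdf``; '#' comments allowed)."""
        arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        return cls(arr[:, 0], arr[:, 1], source_id=str(path))

    def to_file(self, path: str | Path) -> None:
        header = f"pelviseg reference histogram; source_id={self.source_id}"
        np.savetxt(path, np.column_stack([self.bin_edges, self.cdf]),
                   delimiter=",", fmt=["%.1f", "%.8f"], header=header)

    # -- evaluation ------------------------------------------------------

    def quantile(self, q) -> np.ndarray:
        """Piecewise-linear inverse CDF (HU value at cumulative probability q)."""
        return np.interp(q, self.cdf, self.bin_edges)


def _empirical_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-HU-binned CDF of `values`, compressed to its breakpoints.

    Returns strictly increasing edges with strictly increasing cdf, anchored
    at (HU_MIN, 0).  Values are clipped into the HU support first.
    """
    clipped = np.clip(values, HU_MIN, HU_MAX - 1e-6)
    counts, _ = np.histogram(clipped, bins=_BIN_EDGES)
    cdf = np.cumsum(counts, dtype=float) / clipped.size  # at right bin edges
    right_edges = _BIN_EDGES[1:]
    keep = np.empty(len(cdf), dtype=bool)
    keep[0] = cdf[0] > 0
    keep[1:] = np.diff(cdf) > 0
    edges = np.concatenate([[HU_MIN], right_edges[keep]])
    probs = np.concatenate([[0.0], cdf[keep]])
    probs[-1] = 1.0
    return edges, probs


def default_reference() -> ReferenceHistogram:
    """The packaged reference histogram (built from the default phantom)."""
    from importlib import resources

    with resources.as_file(resources.files("pelviseg") / "data" /
                           "reference_histogram.csv") as p:
        return ReferenceHistogram.from_file(p)


def match_histogram(vol: CTVolume, ref: ReferenceHistogram,
                    air_threshold: float = DEFAULT_AIR_THRESHOLD) -> CTVolume:
    """Map the volume's intensities onto the reference distribution.

    The mapping is monotone nondecreasing quantile matching: a voxel at body
    quantile ``q`` is sent to the reference value at quantile ``q``.  Air
    voxels (``<= air_threshold``) are excluded when the source CDF is
    estimated but are still passed through the same monotone map, which is
    anchored at the bottom of the HU range so air stays near air.

    A constant (degenerate) volume is mapped entirely to the reference value
    at the CDF midpoint quantile, with a warning.
    """
    body = vol.data[vol.data > air_threshold]
    if body.size == 0:
        warnings.warn("no voxels above the air threshold; histogram matching skipped",
                      stacklevel=2)
        return vol.with_data(vol.data.copy())
    if np.ptp(body) == 0:
        warnings.warn("degenerate input for histogram matching: constant body; "
                      "mapping all voxels to the reference median", stacklevel=2)
        out = np.full_like(vol.data, ref.quantile(0.5))
        return vol.with_data(out)

    src_edges, src_cdf = _empirical_cdf(body)
    q = np.interp(vol.data, src_edges, src_cdf, left=0.0, right=1.0)
    mapped = ref.quantile(q)
    return vol.with_data(mapped.astype(np.float32))


def remove_table(vol: CTVolume, air_threshold: float = DEFAULT_AIR_THRESHOLD,
                 closing_radius_vox: int = 2) -> tuple[CTVolume, BinaryMask]:
    """Keep only the patient's body; set everything else to -1000 HU.

    The body is the largest 26-connected component of above-air voxels after
    one morphological closing pass (ball radius ``closing_radius_vox``
    voxels) that bridges thin skin gaps.  Disjoint structures such as the
    patient table or cushions are removed.  Returns the cleaned volume and
    the retained body mask.
    """
    above_air = vol.data > air_threshold
    if not above_air.any():
        raise EmptyBodyError("empty body: no voxel above the air threshold")

    closed = _close_ball(above_air, closing_radius_vox)
    labels, n = ndimage.label(closed, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:  # cannot happen given above_air.any(), defensive
        raise EmptyBodyError("empty body after closing")
    # choose the component holding the most above-air voxels, so the largest
    # raw component is never discarded
    counts = ndimage.sum_labels(above_air, labels, index=np.arange(1, n + 1))
    body_label = int(np.argmax(counts)) + 1
    body = labels == body_label

    cleaned = np.where(body, vol.data, np.float32(-1000.0)).astype(np.float32)
    n_removed = int(above_air.sum() - (above_air & body).sum())
    log.info("remove_table: body=%d voxels, removed %d above-air voxels",
             int(body.sum()), n_removed)
    return vol.with_data(cleaned), BinaryMask.like(vol, body)


def _close_ball(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing with a voxel ball, padded so the border acts as open space."""
    if radius <= 0:
        return mask.copy()
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    ball = xx ** 2 + yy ** 2 + zz ** 2 <= r ** 2
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    closed = ndimage.binary_closing(padded, structure=ball)
    return closed[r:-r, r:-r, r:-r]
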