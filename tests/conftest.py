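"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own algorithms: box means
by explicit neighbourhood summation, region growing by literal breadth-first
search, hole filling by flood fill from the border.  They are slow and
simple on purpose.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pelviseg import BinaryMask, CTVolume


# ---------------------------------------------------------------- oracles

def box_mean_oracle(data: np.ndarray, n: int) -> np.ndarray:
    """Neighbourhood mean by explicit summation with shrinking windows."""
    r = n // 2
    out = np.empty(data.shape, dtype=float)
    for i, j, k in itertools.product(*map(range, data.shape)):
        block = data[max(i - r, 0):i + r + 1,
                     max(j - r, 0):j + r + 1,
                     max(k - r, 0):k + r + 1]
        out[i, j, k] = block.mean()
    return out


def bfs_region_grow_oracle(admissible: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Literal BFS over the 26-connected admissible graph, seeds always in."""
    shape = admissible.shape
    visited = np.zeros(shape, dtype=bool)
    frontier = list(zip(*np.nonzero(seeds)))
    for v in frontier:
        visited[v] = True
    offsets = [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1)
               for dk in (-1, 0, 1) if (di, dj, dk) != (0, 0, 0)]
    while frontier:
        i, j, k = frontier.pop()
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            if visited[ni, nj, nk] or not admissible[ni, nj, nk]:
                continue
            visited[ni, nj, nk] = True
            frontier.append((ni, nj, nk))
    return visited


def border_flood_oracle(fg: np.ndarray) -> np.ndarray:
    """Enclosed background via 6-connected flood fill from the border."""
    shape = fg.shape
    reach = np.zeros(shape, dtype=bool)
    frontier = []
    for i, j, k in itertools.product(*map(range, shape)):
        on_border = i in (0, shape[0] - 1) or j in (0, shape[1] - 1) \
            or k in (0, shape[2] - 1)
        if on_border and not fg[i, j, k]:
            reach[i, j, k] = True
            frontier.append((i, j, k))
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while frontier:
        i, j, k = frontier.pop()
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            if reach[ni, nj, nk] or fg[ni, nj, nk]:
                continue
            reach[ni, nj, nk] = True
            frontier.append((ni, nj, nk))
    return ~fg & ~reach


# ------------------------------------------------------------- geometry

def hollow_sphere_mask(shape=(24, 24, 24), outer=10, inner=7, spacing=(1, 1, 1)):
    """A closed spherical shell; its cavity is the canonical enclosed hole."""
    center = np.asarray(shape) / 2.0 - 0.5
    idx = np.indices(shape)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    shell = (d2 <= outer ** 2) & (d2 > inner ** 2)
    cavity = d2 <= inner ** 2
    return BinaryMask(shell, spacing), cavity


def open_tube_mask(shape=(20, 20, 20), r_out=6, r_in=4, spacing=(1, 1, 1)):
    """An axially open tube: closed annulus in every slice, open along z."""
    center = (np.asarray(shape[:2]) / 2.0 - 0.5)
    idx = np.indices(shape)
    rho2 = (idx[0] - center[0]) ** 2 + (idx[1] - center[1]) ** 2
    tube = (rho2 <= r_out ** 2) & (rho2 > r_in ** 2)
    lumen = rho2 <= r_in ** 2
    return BinaryMask(tube, spacing), lumen


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


@pytest.fixture
def small_volume(rng):
    data = rng.integers(-200, 1400, size=(12, 13, 11)).astype(float)
    return CTVolume(data, spacing=(0.8, 0.8, 1.5))


# --------------------------------------------------------------- DICOM

def write_dicom_series(directory, data_xyz: np.ndarray, spacing=(0.7, 0.7, 2.0),
                       origin=(0.0, 0.0, 0.0), slope=1.0, intercept=-1024.0,
                       filename_order=None, pixel_spacing_per_slice=None):
    """Write a synthetic axial CT DICOM series with pydicom.

    ``data_xyz`` holds HU values; stored pixels are
    ``(HU - intercept) / slope``.  ``filename_order`` permutes which slice
    goes into which file (for testing position-based sorting).
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    nx, ny, nz = data_xyz.shape
    study_uid, series_uid = generate_uid(), generate_uid()
    order = filename_order if filename_order is not None else list(range(nz))
    for file_idx, k in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID, ds.SeriesInstanceUID = study_uid, series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = ny, nx
        ps = (pixel_spacing_per_slice[file_idx] if pixel_spacing_per_slice
              else [spacing[1], spacing[0]])  # DICOM: [row=y, col=x]
        ds.PixelSpacing = [str(v) for v in ps]
        ds.SliceThickness = str(spacing[2])
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [str(origin[0]), str(origin[1]),
                                   str(origin[2] + k * spacing[2])]
        ds.InstanceNumber = k + 1
        ds.RescaleSlope, ds.RescaleIntercept = str(slope), str(intercept)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0  # unsigned stored pixels
        stored = np.round((data_xyz[:, :, k] - intercept) / slope).astype(np.uint16)
        ds.PixelData = stored.T.tobytes()  # rows (y) vary slowest
        ds.save_as(str(directory / f"slice_{file_idx:03d}.dcm"),
                   enforce_file_format=True)
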