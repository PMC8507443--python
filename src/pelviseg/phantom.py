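"""Synthetic pelvic CT phantoms with exact ground truth.

The phantom emulates the features that make pelvic bone segmentation hard:
high-intensity cortical shells enclosing low-intensity marrow, cortical
perforations (foramina) that defeat naive hole filling, a femoral head
sitting close to the acetabulum (near-contact between bones), a detached
patient table, partial-volume blur and additive noise.  It is not an
anatomically accurate pelvis: structures are spheres, cylinders, tori and
spherical-shell sectors whose proportions scale with the volume extent.

Ground-truth labels (1 = cortical bone, 2 = marrow) are derived from the
pre-blur geometry, so Dice scores against the truth measure the algorithm,
not the corruption.  Two independent RNG streams are derived from the
single seed: one for geometry (foramina placement, part of the truth) and
one for noise, so the truth is independent of the noise stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import PhantomSpecError
from .volumes import CTVolume, LabelVolume

_CUP_MAX_ANGLE_DEG = 100.0  # acetabular cup coverage (polar angle from +z)


@dataclass
class PhantomSpec:
    """Geometric and intensity parameters of the synthetic pelvic phantom.

    Intensities are HU; distances are mm.  ``osteoporosis_factor`` in
    (0, 1] scales the cortical intensity down to emulate reduced
    bone/soft-tissue contrast.  ``joint_gap_mm`` is the minimum distance
    between the femoral head and the acetabular cup (at the cup rim; the
    gap widens toward the cup pole).  ``layout`` selects the structure set:
    ``"pelvis"`` (default) or ``"canal"`` (a single axially open tube, for
    contrasting 2D and 3D hole filling).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_hu: float = 0.0
    muscle_hu: float = 50.0
    cortical_hu: float = 1200.0
    marrow_hu: float = 150.0
    table_hu: float = -300.0
    cortical_thickness_mm: float = 2.0
    n_foramina: int = 4
    foramen_radius_mm: float = 1.0
    joint_gap_mm: float = 8.0
    osteoporosis_factor: float = 1.0
    blur_sigma_mm: float = 0.8
    noise_sd_hu: float = 15.0
    include_table: bool = True
    layout: str = "pelvis"
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.validate()

    def validate(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 32:
            raise PhantomSpecError(f"shape must be 3 integers >= 32, got {self.shape}")
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise PhantomSpecError("spacing must be 3 positive values")
        if not (0 < self.osteoporosis_factor <= 1):
            raise PhantomSpecError("osteoporosis_factor must be in (0, 1]")
        if not (self.cortical_hu * self.osteoporosis_factor > self.marrow_hu
                > self.body_hu):
            raise PhantomSpecError(
                "contrast ordering violated: need cortical*factor > marrow > body")
        for name in ("cortical_thickness_mm", "foramen_radius_mm"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be positive")
        if self.joint_gap_mm <= 0:
            raise PhantomSpecError("joint_gap_mm must be positive")
        if self.blur_sigma_mm < 0 or self.noise_sd_hu < 0 or self.n_foramina < 0:
            raise PhantomSpecError("blur, noise and foramina count must be >= 0")
        if self.layout not in ("pelvis", "canal"):
            raise PhantomSpecError(f"unknown layout '{self.layout}'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("shape", "spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["shape"] = list(d["shape"])
        d["spacing"] = list(d["spacing"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def preset_specs() -> dict[str, PhantomSpec]:
    """Named phantom presets covering the documented difficulty factors."""
    return {
        "default": PhantomSpec(),
        "osteoporosis": PhantomSpec(osteoporosis_factor=0.5),
        "kissing_joint": PhantomSpec(joint_gap_mm=1.0),
        "perforated": PhantomSpec(n_foramina=8),
        "canal": PhantomSpec(layout="canal"),
    }


class _Geometry:
    """Derived physical geometry of the pelvis layout for a given spec."""

    def __init__(self, spec: PhantomSpec):
        ext = np.asarray(spec.shape, dtype=float) * np.asarray(spec.spacing)
        self.ext = ext
        self.center = ext / 2.0
        self.body_semi = np.array([0.44, 0.36, 0.47]) * ext
        self.head_r = 0.105 * min(ext[0], ext[1])
        self.head_dx = 0.16 * ext[0]
        self.head_z = self.center[2] - 0.083 * ext[2]
        self.shaft_r = 0.7 * self.head_r
        self.shaft_z_bot = 0.09 * ext[2]
        self.tube_r = 0.055 * min(ext[0], ext[1])
        self.cup_offset = 0.057 * ext[0]  # eccentricity along +z
        t = spec.cortical_thickness_mm
        cos_max = math.cos(math.radians(_CUP_MAX_ANGLE_DEG))
        # inner radius chosen so the minimum head-cup gap (at the rim) is
        # exactly joint_gap_mm; the gap widens toward the cup pole
        self.cup_r_in = self.head_r + spec.joint_gap_mm - self.cup_offset * cos_max
        self.cup_r_out = self.cup_r_in + t
        self.arch_z = self.head_z + self.cup_offset + self.cup_r_out
        self.arch_R = self.head_dx

    def head_centers(self):
        cx, cy, _ = self.center
        return [np.array([cx - self.head_dx, cy, self.head_z]),
                np.array([cx + self.head_dx, cy, self.head_z])]

    def probe_points(self):
        """Extreme points of bone structures; all must lie inside the body."""
        pts = []
        for hc in self.head_centers():
            for d in (np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]),
                      np.array([0, 1.0, 0]), np.array([0, -1.0, 0])):
                pts.append(hc + np.array([0, 0, self.cup_offset]) + d * self.cup_r_out)
            pts.append(hc + np.array([0, 0, self.cup_offset + self.cup_r_out]))
            pts.append(np.array([hc[0], hc[1], self.shaft_z_bot]))
        cx, cy, _ = self.center
        for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            pts.append(np.array([cx + d[0] * (self.arch_R + self.tube_r),
                                 cy + d[1] * (self.arch_R + self.tube_r),
                                 self.arch_z]))
        pts.append(np.array([cx, cy, self.arch_z + self.tube_r]))
        return pts

    def check_inside_body(self):
        for p in self.probe_points():
            v = np.sum(((p - self.center) / self.body_semi) ** 2)
            if v > 1.0:
                raise PhantomSpecError(
                    f"geometrically impossible spec: bone structure at {p} "
                    f"exceeds the body ellipsoid")


def _grids(spec: PhantomSpec):
    """Broadcastable physical voxel-center coordinates (mm)."""
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(spec.shape, spec.spacing)]
    return (axes[0][:, None, None], axes[1][None, :, None], axes[2][None, None, :])


def _sphere(X, Y, Z, c, r):
    return (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r ** 2


def _cylinder_z(X, Y, Z, cx, cy, r, z0, z1):
    return ((X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2) & (Z >= z0) & (Z <= z1)


def _torus_xy(X, Y, Z, c, R, r):
    rho = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2)
    return (rho - R) ** 2 + (Z - c[2]) ** 2 <= r ** 2


def _cup_shell(X, Y, Z, center, r_in, r_out):
    """Spherical-shell sector covering polar angles up to the cup limit."""
    dx, dy, dz = X - center[0], Y - center[1], Z - center[2]
    d = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(d > 0, dz / np.maximum(d, 1e-12), 1.0)
    cos_max = math.cos(math.radians(_CUP_MAX_ANGLE_DEG))
    return (d >= r_in) & (d <= r_out) & (cos_theta >= cos_max)


def _pelvis_masks(spec: PhantomSpec, geo: _Geometry, rng_geom: np.random.Generator):
    X, Y, Z = _grids(spec)
    t = spec.cortical_thickness_mm
    cx, cy, _ = geo.center

    cortical_parts = []
    marrow = np.zeros(spec.shape, dtype=bool)

    # femurs: sphere head + cylindrical shaft, shared marrow cavity
    for hc in geo.head_centers():
        outer = _sphere(X, Y, Z, hc, geo.head_r) | _cylinder_z(
            X, Y, Z, hc[0], hc[1], geo.shaft_r, geo.shaft_z_bot, hc[2])
        inner = _sphere(X, Y, Z, hc, geo.head_r - t) | _cylinder_z(
            X, Y, Z, hc[0], hc[1], geo.shaft_r - t, geo.shaft_z_bot + t, hc[2])
        cortical_parts.append(outer & ~inner)
        marrow |= inner

    # pelvic arch: horizontal torus with marrow core
    arch_c = (cx, cy, geo.arch_z)
    arch_outer = _torus_xy(X, Y, Z, arch_c, geo.arch_R, geo.tube_r)
    arch_inner = _torus_xy(X, Y, Z, arch_c, geo.arch_R, geo.tube_r - t)
    cortical_parts.append(arch_outer & ~arch_inner)
    marrow |= arch_inner

    # acetabular cups: eccentric spherical-shell sectors over each head
    for hc in geo.head_centers():
        cup_c = hc + np.array([0.0, 0.0, geo.cup_offset])
        cortical_parts.append(_cup_shell(X, Y, Z, cup_c, geo.cup_r_in, geo.cup_r_out))

    cortical = np.zeros(spec.shape, dtype=bool)
    for part in cortical_parts:
        cortical |= part
    cortical &= ~marrow

    # foramina: radial perforations through the arch wall
    if spec.n_foramina > 0:
        phis = rng_geom.uniform(0.0, 2 * math.pi, size=spec.n_foramina)
        carve = np.zeros(spec.shape, dtype=bool)
        for phi in phis:
            d = np.array([math.cos(phi), math.sin(phi), 0.0])
            p = np.array([cx + geo.arch_R * d[0], cy + geo.arch_R * d[1], geo.arch_z])
            vx, vy, vz = X - p[0], Y - p[1], Z - p[2]
            s = vx * d[0] + vy * d[1]
            dist2 = vx ** 2 + vy ** 2 + vz ** 2 - s ** 2
            carve |= ((dist2 <= spec.foramen_radius_mm ** 2)
                      & (s >= geo.tube_r - t - 0.5) & (s <= geo.tube_r + 0.6))
        cortical &= ~carve

    return cortical, marrow


def _canal_masks(spec: PhantomSpec):
    X, Y, Z = _grids(spec)
    ext = np.asarray(spec.shape, dtype=float) * np.asarray(spec.spacing)
    cx, cy = ext[0] / 2, ext[1] / 2
    r_out = 0.08 * min(ext[0], ext[1])
    r_in = r_out - spec.cortical_thickness_mm
    rho2 = (X - cx) ** 2 + (Y - cy) ** 2 + 0 * Z
    shell = (rho2 <= r_out ** 2) & (rho2 > r_in ** 2)
    lumen = rho2 <= r_in ** 2
    return shell, lumen


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelVolume]:
    """Generate the phantom volume and its exact ground-truth labels.

    Returns ``(CTVolume, LabelVolume)``; truth codes are 1 (cortical) and
    2 (marrow), computed from the pre-blur geometry.  Deterministic for a
    fixed spec (including its seed).
    """
    spec.validate()
    rng_geom = np.random.default_rng([int(spec.seed), 17])
    rng_noise = np.random.default_rng([int(spec.seed), 23])

    ext = np.asarray(spec.shape, dtype=float) * np.asarray(spec.spacing)
    X, Y, Z = _grids(spec)
    center = ext / 2.0
    body_semi = np.array([0.44, 0.36, 0.47]) * ext
    body = (((X - center[0]) / body_semi[0]) ** 2
            + ((Y - center[1]) / body_semi[1]) ** 2
            + ((Z - center[2]) / body_semi[2]) ** 2) <= 1.0

    vol = np.full(spec.shape, -1000.0)
    vol[body] = spec.body_hu

    if spec.layout == "pelvis":
        geo = _Geometry(spec)
        geo.check_inside_body()
        # paraspinal-like muscle blocks, anterior to the bones
        for sign in (-1.0, 1.0):
            mc = (center[0] + sign * 0.19 * ext[0], center[1] - 0.22 * ext[1],
                  center[2])
            msemi = (0.08 * ext[0], 0.06 * ext[1], 0.25 * ext[2])
            muscle = (((X - mc[0]) / msemi[0]) ** 2 + ((Y - mc[1]) / msemi[1]) ** 2
                      + ((Z - mc[2]) / msemi[2]) ** 2) <= 1.0
            vol[muscle & body] = spec.muscle_hu
        cortical, marrow = _pelvis_masks(spec, geo, rng_geom)
    else:
        # canal lumen holds marrow-like tissue but is open, hence not truth bone
        cortical, marrow = _canal_masks(spec)

    vol[marrow] = spec.marrow_hu
    vol[cortical] = spec.cortical_hu * spec.osteoporosis_factor

    if spec.include_table:
        table = ((Y >= 0.915 * ext[1]) & (Y <= 0.97 * ext[1])
                 & (X >= 0.1 * ext[0]) & (X <= 0.9 * ext[0]) & (Z >= 0))
        vol[table] = spec.table_hu

    truth = np.zeros(spec.shape, dtype=np.uint8)
    truth[cortical] = 1
    if spec.layout == "pelvis":
        truth[marrow] = 2

    if spec.blur_sigma_mm > 0:
        sigma = [spec.blur_sigma_mm / s for s in spec.spacing]
        vol = ndimage.gaussian_filter(vol, sigma=sigma)
    if spec.noise_sd_hu > 0:
        vol = vol + rng_noise.normal(0.0, spec.noise_sd_hu, size=spec.shape)

    ct = CTVolume(vol.astype(np.float32), spec.spacing)
    labels = LabelVolume(truth, spec.spacing)
    return ct, labels


def joint_space_mask(spec: PhantomSpec) -> np.ndarray:
    """Voxels of the hip-joint space (between head surface and cup inner surface).

    Utility for tests/analyses of the joint-bridging failure mode; only
    meaningful for the ``pelvis`` layout.
    """
    if spec.layout != "pelvis":
        raise PhantomSpecError("joint_space_mask requires the pelvis layout")
    geo = _Geometry(spec)
    X, Y, Z = _grids(spec)
    out = np.zeros(spec.shape, dtype=bool)
    cos_max = math.cos(math.radians(_CUP_MAX_ANGLE_DEG))
    for hc in geo.head_centers():
        cup_c = hc + np.array([0.0, 0.0, geo.cup_offset])
        dh = np.sqrt((X - hc[0]) ** 2 + (Y - hc[1]) ** 2 + (Z - hc[2]) ** 2)
        dxc, dyc, dzc = X - cup_c[0], Y - cup_c[1], Z - cup_c[2]
        dc = np.sqrt(dxc ** 2 + dyc ** 2 + dzc ** 2)
        cos_theta = np.where(dc > 0, dzc / np.maximum(dc, 1e-12), 1.0)
        out |= (dh > geo.head_r) & (dc < geo.cup_r_in) & (cos_theta >= cos_max)
    # exclude any bone (e.g. the arch tube dipping toward the cup top)
    rng_geom = np.random.default_rng([int(spec.seed), 17])
    cortical, marrow = _pelvis_masks(spec, geo, rng_geom)
    return out & ~cortical & ~marrow
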