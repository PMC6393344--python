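"""Synthetic voxel tomograms of notched bast fibers.

Real micro-CT stacks of hemp fibers are rarely shareable, so this module
generates two-phase (air/solid) voxel volumes that emulate their reported
statistical structure: an elliptical solid cross-section, a tubular lumen
spanning the full fiber length, machined V- or U-notches whose opening
angle follows ``tan(theta/2) = w / (2 h)``, and correlated surface
roughness standing in for extraction-induced surface flaws.

Axis convention: axis 0 of every volume is X, the fiber longitudinal and
loading axis. Lengths are micrometres throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy import ndimage

__all__ = [
    "AIR",
    "SOLID",
    "FiberSpec",
    "NotchType",
    "NotchGeometry",
    "VoxelVolume",
    "InvalidGeometryError",
    "DimensionError",
    "notch_angle",
    "generate_fiber",
    "carve_notch",
    "add_surface_roughness",
    "preset",
    "scaled_preset",
    "PRESET_NAMES",
]

AIR = 0
SOLID = 255

#: diameter range observed for hemp bundles and elementary fibers (um)
DIAMETER_RANGE_UM = (13.0, 224.0)
#: machinable notch width range (um)
NOTCH_WIDTH_RANGE_UM = (4.0, 108.0)
#: scaled notch depth range h/d
NOTCH_DEPTH_RATIO_RANGE = (0.1, 0.6)


def physical_volume(n_voxels: float, voxel_size: float = 0.28) -> float:
    """Physical volume (um^3) of ``n_voxels`` isotropic voxels."""
    return n_voxels * voxel_size**3


class InvalidGeometryError(ValueError):
    """Raised for non-physical fiber or notch geometry."""


class DimensionError(ValueError):
    """Raised when a fiber cannot fit the requested voxel grid."""


class NotchType(str, Enum):
    V = "V"
    U = "U"


def notch_angle(w: float, h: float) -> float:
    """Opening angle (degrees) of a notch of width ``w`` and depth ``h``.

    The flanks of a V-notch of opening ``w`` and depth ``h`` subtend
    ``theta`` with ``tan(theta/2) = w / (2 h)``; the same scaling
    quantity is used to characterise U-notches.
    """
    if w <= 0 or h <= 0:
        raise InvalidGeometryError(f"notch width and depth must be positive, got w={w}, h={h}")
    return math.degrees(2.0 * math.atan(w / (2.0 * h)))


@dataclass(frozen=True)
class NotchGeometry:
    """Machined surface notch: triangular (V) or semi-elliptical (U) prism.

    ``w`` is the opening measured along the fiber axis, ``h`` the radial
    depth. ``axial_position`` is the offset of the notch centre from fiber
    mid-length (um); ``azimuth`` rotates the notch about the fiber axis.
    """

    type: NotchType
    w: float
    h: float
    axial_position: float = 0.0
    azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise InvalidGeometryError(f"notch requires w > 0 and h > 0, got w={self.w}, h={self.h}")
        object.__setattr__(self, "type", NotchType(self.type))

    @property
    def theta(self) -> float:
        """Opening angle in degrees."""
        return notch_angle(self.w, self.h)

    def validate_against(self, diameter: float) -> None:
        """Warn when outside the ranges machinable by laser micro-dissection."""
        lo, hi = NOTCH_WIDTH_RANGE_UM
        if not lo <= self.w <= hi:
            warnings.warn(f"notch width {self.w} um outside the typical range {lo}-{hi} um", stacklevel=2)
        rlo, rhi = NOTCH_DEPTH_RATIO_RANGE
        ratio = self.h / diameter
        if not rlo <= ratio <= rhi:
            warnings.warn(
                f"scaled notch depth h/d = {ratio:.2f} outside the typical range ({rlo}, {rhi})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class FiberSpec:
    """Geometric description of a synthetic bast fiber.

    ``diameter`` is the equivalent diameter of the solid cross-section
    (diameter of the circle with the same area). ``shape_factor`` is the
    major/minor semi-axis ratio of the outer ellipse. The lumen, when
    present, is a coaxial elliptical tube spanning the entire fiber length
    whose cross-section occupies ``lumen_area_fraction`` of the outer
    ellipse area (this equals the fiber porosity).
    """

    diameter: float
    length: float
    shape_factor: float = 1.0
    lumen: bool = True
    lumen_area_fraction: float = 0.10
    lumen_aspect: float = 2.0
    roughness_amplitude: float = 0.0
    roughness_correlation: float = 5.0
    voxel_size: float = 0.28
    gray_levels: tuple[int, int] = (AIR, SOLID)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidGeometryError("diameter must be positive")
        if self.length <= 0:
            raise InvalidGeometryError("length must be positive")
        if self.shape_factor < 1.0:
            raise InvalidGeometryError("shape factor is major/minor, must be >= 1")
        if self.voxel_size <= 0:
            raise InvalidGeometryError("voxel size must be positive")
        if self.lumen and not 0.0 <= self.lumen_area_fraction <= 0.2:
            raise InvalidGeometryError("lumen area fraction must lie in [0, 0.2]")
        if self.lumen and self.lumen_aspect < 1.0:
            raise InvalidGeometryError("lumen aspect is major/minor, must be >= 1")
        if self.roughness_amplitude < 0:
            raise InvalidGeometryError("roughness amplitude must be >= 0")

    def validate_presets(self) -> None:
        """Warn when the diameter leaves the range reported for hemp."""
        lo, hi = DIAMETER_RANGE_UM
        if not lo <= self.diameter <= hi:
            warnings.warn(
                f"diameter {self.diameter} um outside the observed hemp range {lo}-{hi} um",
                stacklevel=2,
            )

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(major, minor) semi-axes (um) of the outer ellipse.

        Chosen so the ellipse area equals that of a circle of the
        equivalent diameter: a*b = (d/2)^2 with a/b = shape_factor.
        """
        r = self.diameter / 2.0
        s = math.sqrt(self.shape_factor)
        return r * s, r / s

    @property
    def lumen_semi_axes(self) -> tuple[float, float]:
        """(major, minor) semi-axes (um) of the lumen ellipse (0, 0 if absent)."""
        if not self.lumen or self.lumen_area_fraction == 0.0:
            return 0.0, 0.0
        a, b = self.semi_axes
        prod = self.lumen_area_fraction * a * b  # al*bl
        s = math.sqrt(self.lumen_aspect)
        root = math.sqrt(prod)
        return root * s, root / s


@dataclass
class VoxelVolume:
    """A 3D gray-level image with isotropic voxels.

    ``data`` is indexed ``[x, y, z]`` with X the fiber/loading axis;
    values are integers in [0, 255]. After segmentation only the two
    phase levels {0, 255} (air, solid) occur.
    """

    data: np.ndarray
    voxel_size: float = 0.28

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.voxel_size <= 0:
            raise InvalidGeometryError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    def physical_volume(self) -> float:
        """Total physical volume of the grid in um^3."""
        return self.n_voxels * self.voxel_size**3

    def solid_mask(self) -> np.ndarray:
        return self.data == SOLID

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (AIR, SOLID)).all())

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.voxel_size)


# ---------------------------------------------------------------------------
# generation

def _cross_section_masks(spec: FiberSpec, ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (outer-ellipse, lumen) masks on the (y, z) voxel grid."""
    vox = spec.voxel_size
    cy, cz = (ny / 2.0) * vox, (nz / 2.0) * vox
    y = (np.arange(ny) + 0.5) * vox - cy
    z = (np.arange(nz) + 0.5) * vox - cz
    yy, zz = np.meshgrid(y, z, indexing="ij")
    a, b = spec.semi_axes  # major along Y
    outer = (yy / a) ** 2 + (zz / b) ** 2 <= 1.0
    al, bl = spec.lumen_semi_axes
    if al > 0:
        # calibrate the rasterized lumen so the voxel-count porosity hits
        # the requested area fraction despite discretization bias; the
        # sub-voxel centre offset breaks the 4-fold symmetry that would
        # otherwise quantize the count in steps of 4
        rho2 = ((yy - 0.37 * vox) / al) ** 2 + ((zz - 0.23 * vox) / bl) ** 2
        target = spec.lumen_area_fraction * int(outer.sum())
        best_t, best_err = 1.0, np.inf
        for t in np.linspace(0.7, 1.4, 141):
            cnt = int((rho2 <= t * t).sum())
            err = abs(cnt - target)
            if err < best_err:
                best_t, best_err = t, err
        lum = rho2 <= best_t * best_t
    else:
        lum = np.zeros_like(outer)
    return outer, lum


def generate_fiber(
    spec: FiberSpec,
    seed: int,
    shape: tuple[int, int, int] | None = None,
    margin: int = 2,
) -> VoxelVolume:
    """Rasterize a two-phase fiber volume from ``spec``.

    The solid phase is the outer ellipse minus the lumen tube; the lumen
    spans the full fiber length, emulating the tubular porosity of bast
    fibers. Surface roughness, when requested in the spec, is applied as
    a correlated radial perturbation (see :func:`add_surface_roughness`).

    Parameters
    ----------
    spec : FiberSpec
    seed : int
        Seed for the roughness field; required explicitly even when the
        geometry is deterministic.
    shape : optional (nx, ny, nz)
        Grid size override; by default the grid is sized to fit the fiber
        plus ``margin`` air voxels on each transverse side.
    """
    vox = spec.voxel_size
    a, _ = spec.semi_axes
    nx = max(1, round(spec.length / vox))
    lateral = 2 * (math.ceil((a + spec.roughness_amplitude * 3) / vox) + margin)
    if shape is None:
        shape = (nx, lateral, lateral)
    nx_, ny, nz = shape
    if (a + spec.roughness_amplitude) * 2 >= min(ny, nz) * vox:
        raise DimensionError(
            f"fiber of major axis {2 * a:.1f} um does not fit a "
            f"{ny}x{nz}-voxel cross-section at {vox} um/voxel"
        )
    outer, lum = _cross_section_masks(spec, ny, nz)
    solid2d = outer & ~lum
    if not solid2d.any():
        raise DimensionError("cross-section rasterizes to zero solid voxels; refine voxel size")
    data = np.zeros((nx_, ny, nz), dtype=np.uint8)
    data[:, solid2d] = SOLID
    volume = VoxelVolume(data, vox)
    if spec.roughness_amplitude > 0:
        volume = add_surface_roughness(
            volume,
            spec.roughness_amplitude,
            spec.roughness_correlation,
            seed,
            lumen_clearance=max(spec.lumen_semi_axes) + vox,
        )
    return volume


def add_surface_roughness(
    volume: VoxelVolume,
    amplitude: float,
    correlation: float,
    seed: int,
    lumen_clearance: float | None = None,
    n_azimuth: int = 128,
) -> VoxelVolume:
    """Perturb the outer solid boundary with a correlated radial field.

    A Gaussian random field ``delta(x, phi)`` with RMS ``amplitude`` (um)
    and correlation length ``correlation`` (um) along the fiber axis is
    added to the local outer radius: voxels with radius between the
    original and perturbed boundary flip phase. Amplitude 0 is the
    identity. The perturbation is clipped so an interior lumen is never
    breached.
    """
    if amplitude < 0:
        raise InvalidGeometryError("roughness amplitude must be >= 0")
    if amplitude == 0:
        return volume.copy()
    vox = volume.voxel_size
    nx, ny, nz = volume.shape
    rng = np.random.default_rng(seed)
    field2d = rng.standard_normal((nx, n_azimuth))
    sig_x = max(correlation / vox, 1e-6)
    # approximate arc-length correlation along the azimuth from the mean radius
    solid = volume.solid_mask()
    if not solid.any():
        return volume.copy()

    # protect interior cavities: air not connected to the lateral boundary
    # faces (the lumen opens through the axial ends) must never be filled
    air = ~solid
    air_labels, n_air = ndimage.label(air, structure=ndimage.generate_binary_structure(3, 1))
    boundary_lbls = np.unique(np.concatenate([
        air_labels[:, 0].ravel(), air_labels[:, -1].ravel(),
        air_labels[:, :, 0].ravel(), air_labels[:, :, -1].ravel(),
    ]))
    protected = air & ~np.isin(air_labels, boundary_lbls[boundary_lbls > 0])
    cy = (ny / 2.0) * vox
    cz = (nz / 2.0) * vox
    yy = (np.arange(ny) + 0.5) * vox - cy
    zz = (np.arange(nz) + 0.5) * vox - cz
    Y, Z = np.meshgrid(yy, zz, indexing="ij")
    R = np.sqrt(Y**2 + Z**2)
    mean_radius = float(R[solid.any(axis=0)].mean())
    sig_phi = correlation / (2 * math.pi * mean_radius / n_azimuth)
    field2d = ndimage.gaussian_filter(field2d, sigma=(sig_x, max(sig_phi, 1e-6)), mode="wrap")
    rms = float(np.sqrt(np.mean(field2d**2)))
    field2d *= amplitude / max(rms, 1e-12)

    phi = np.arctan2(Z, Y)  # azimuth 0 along +Y
    phi_idx = ((phi + math.pi) / (2 * math.pi) * n_azimuth).astype(int) % n_azimuth

    # per-slice outer radius at each azimuth bin, from the unperturbed volume
    data = volume.data.copy()
    if lumen_clearance is None:
        lumen_clearance = float(R[protected.any(axis=0)].max()) + vox if protected.any() else 0.0
    max_lumen = lumen_clearance
    for i in range(nx):
        sl = solid[i]
        if not sl.any():
            continue
        delta = field2d[i][phi_idx]  # (ny, nz) radial perturbation
        # outer boundary radius per azimuth bin
        rmax = np.full(n_azimuth, -1.0)
        np.maximum.at(rmax, phi_idx[sl], R[sl])
        local_r = rmax[phi_idx]
        # clip so the perturbed boundary stays outside the lumen
        delta = np.maximum(delta, -(local_r - max_lumen - vox))
        new_solid = (R <= local_r + delta) & (local_r > 0)
        # roughness edits only near the boundary: keep the interior solid
        interior = sl & (R <= np.maximum(local_r - 3 * amplitude, 0))
        out = new_solid | interior
        out &= ~protected[i]
        data[i] = np.where(out, SOLID, AIR).astype(np.uint8)
    return VoxelVolume(data, vox)


def carve_notch(volume: VoxelVolume, notch: NotchGeometry) -> VoxelVolume:
    """Remove a notch-shaped prism of solid voxels from the fiber surface.

    A V-notch removes a triangular prism (opening ``w`` along the fiber
    axis, radial depth ``h``); a U-notch removes a semi-elliptical prism
    with semi-axes ``w/2`` (axial) and ``h`` (radial). The prism extends
    through the fiber transverse to the notch direction, and removal only
    converts solid voxels to air.
    """
    vox = volume.voxel_size
    nx, ny, nz = volume.shape
    solid = volume.solid_mask()
    if not solid.any():
        raise InvalidGeometryError("cannot notch an empty volume")

    alpha = math.radians(notch.azimuth)
    cy = (ny / 2.0) * vox
    cz = (nz / 2.0) * vox
    yy = (np.arange(ny) + 0.5) * vox - cy
    zz = (np.arange(nz) + 0.5) * vox - cz
    Y, Z = np.meshgrid(yy, zz, indexing="ij")
    # radial coordinate along the notch direction (azimuth 0 = +Y)
    U = math.cos(alpha) * Y + math.sin(alpha) * Z

    any_solid = solid.any(axis=0)
    u_surf = float(U[any_solid].max()) + 0.5 * vox  # outer surface plane
    local_radius = u_surf  # distance from axis to surface along the notch direction
    if notch.h >= local_radius:
        raise InvalidGeometryError(
            f"notch depth {notch.h} um exceeds the local fiber radius {local_radius:.2f} um"
        )

    x = (np.arange(nx) + 0.5) * vox
    x0 = nx * vox / 2.0 + notch.axial_position
    dx = np.abs(x - x0)
    pen2d = u_surf - U  # penetration depth from the surface plane, (ny, nz)

    if notch.type is NotchType.V:
        # remove where penetration < h * (1 - 2|dx|/w)
        depth_at_x = notch.h * (1.0 - 2.0 * dx / notch.w)  # (nx,)
        mask = pen2d[None, :, :] <= depth_at_x[:, None, None]
    else:
        # semi-ellipse: (2 dx / w)^2 + (p / h)^2 <= 1
        val = (2.0 * dx / notch.w) ** 2
        mask = val[:, None, None] + (pen2d[None, :, :] / notch.h) ** 2 <= 1.0
    mask &= pen2d[None, :, :] >= 0

    data = volume.data.copy()
    data[mask & solid] = AIR
    return VoxelVolume(data, vox)


# ---------------------------------------------------------------------------
# presets emulating the four imaged hemp configurations

PRESET_NAMES = ("FXU4", "FU", "FIV15", "FU19")

_PRESETS: dict[str, tuple[FiberSpec, NotchGeometry]] = {
    # U-notched bundle: largest lumen (porosity 9%), most elongated
    # cross-section (shape factor 3.23), lateral dimension 232 um, ROI 573 um.
    "FXU4": (
        FiberSpec(diameter=232.0, length=573.0, shape_factor=3.23,
                  lumen=True, lumen_area_fraction=0.09, lumen_aspect=2.43,
                  roughness_amplitude=3.0, roughness_correlation=20.0),
        NotchGeometry(NotchType.U, w=60.0, h=40.0),
    ),
    # U-notched bundle: porosity 4%, nearly round (1.28), d = 44 um, ROI 240 um.
    "FU": (
        FiberSpec(diameter=44.0, length=240.0, shape_factor=1.28,
                  lumen=True, lumen_area_fraction=0.04, lumen_aspect=2.43,
                  roughness_amplitude=1.0, roughness_correlation=10.0),
        NotchGeometry(NotchType.U, w=16.0, h=10.0),
    ),
    # V-notched elementary fiber: smallest lateral dimension (18 um), no lumen.
    "FIV15": (
        FiberSpec(diameter=18.0, length=580.0, shape_factor=1.1,
                  lumen=False, lumen_area_fraction=0.0,
                  roughness_amplitude=0.4, roughness_correlation=5.0),
        NotchGeometry(NotchType.V, w=7.7, h=2.8),
    ),
    # U-notched fiber: 23 um, no lumen, shape factor 1.78, ROI ~160 um.
    "FU19": (
        FiberSpec(diameter=23.0, length=160.0, shape_factor=1.78,
                  lumen=False, lumen_area_fraction=0.0,
                  roughness_amplitude=0.5, roughness_correlation=5.0),
        NotchGeometry(NotchType.U, w=9.0, h=5.0),
    ),
}


def preset(name: str) -> tuple[FiberSpec, NotchGeometry]:
    """Fiber + notch specs for the four imaged hemp configurations."""
    try:
        spec, notch = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    return replace(spec), replace(notch)


def scaled_preset(
    name: str,
    diameter_voxels: int = 14,
    length_diameters: float = 4.0,
) -> tuple[FiberSpec, NotchGeometry]:
    """A desk-scale version of a preset.

    Keeps every physical descriptor (diameter, shape factor, porosity,
    notch w/d and h/d) and coarsens the voxel size so the equivalent
    diameter spans ``diameter_voxels`` voxels; the length is capped at
    ``length_diameters`` diameters so full damage sweeps stay cheap.
    """
    spec, notch = preset(name)
    vox = spec.diameter / diameter_voxels
    length = min(spec.length, length_diameters * spec.diameter)
    spec = replace(
        spec,
        voxel_size=vox,
        length=length,
        roughness_amplitude=min(spec.roughness_amplitude, 0.75 * vox),
        roughness_correlation=max(spec.roughness_correlation, 3 * vox),
    )
    return spec, notch
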