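import math

import numpy as np
import pytest

from fibrekin.segmentation import extract_lumen, fiber_descriptors, porosity
from fibrekin.synthetic import (
    AIR,
    SOLID,
    DimensionError,
    FiberSpec,
    InvalidGeometryError,
    NotchGeometry,
    VoxelVolume,
    add_surface_roughness,
    carve_notch,
    generate_fiber,
    notch_angle,
    preset,
    scaled_preset,
)


class TestNotchAngle:
    @pytest.mark.parametrize(
        "w, h, expected",
        [
            (30.0, 15.0, 90.0),  # w = 2h -> tan(theta/2) = 1
            (40.0, 15.0, 2 * math.degrees(math.atan(40 / 30))),  # bundle notch
            (7.7, 2.8, 2 * math.degrees(math.atan(7.7 / 5.6))),  # elementary fiber notch
        ],
    )
    def test_against_closed_form(self, w, h, expected):
        assert notch_angle(w, h) == pytest.approx(expected, abs=1e-9)

    def test_known_fiber_notches(self):
        # the imaged bundle notch (40 um x 15 um) and elementary-fiber
        # notch (7.7 um x 2.8 um) opening angles
        assert notch_angle(40, 15) == pytest.approx(106.26, abs=0.01)
        assert notch_angle(7.7, 2.8) == pytest.approx(107.95, abs=0.01)

    @pytest.mark.parametrize("w, h", [(0, 1), (1, 0), (-1, 1), (1, -1)])
    def test_rejects_nonpositive_geometry(self, w, h):
        with pytest.raises(InvalidGeometryError):
            notch_angle(w, h)


class TestFiberSpec:
    def test_semi_axes_preserve_equivalent_area(self):
        spec = FiberSpec(diameter=40, length=100, shape_factor=2.5)
        a, b = spec.semi_axes
        assert a / b == pytest.approx(2.5)
        assert a * b == pytest.approx((40 / 2) ** 2)

    def test_lumen_fraction_bounds(self):
        with pytest.raises(InvalidGeometryError):
            FiberSpec(diameter=40, length=100, lumen=True, lumen_area_fraction=0.5)

    def test_shape_factor_below_one_rejected(self):
        with pytest.raises(InvalidGeometryError):
            FiberSpec(diameter=40, length=100, shape_factor=0.8)


class TestGenerateFiber:
    def test_two_valued_output(self, tube_volume):
        assert set(np.unique(tube_volume.data)) <= {AIR, SOLID}

    def test_porosity_recovery(self):
        # measured porosity tracks the requested lumen area fraction
        spec = FiberSpec(diameter=32, length=40, shape_factor=2.0,
                         lumen=True, lumen_area_fraction=0.09, voxel_size=1.0)
        vol = generate_fiber(spec, seed=2)
        p = porosity(vol, extract_lumen(vol))
        assert p == pytest.approx(0.09, abs=0.01)

    def test_no_lumen_means_zero_porosity(self, plain_cylinder):
        p = porosity(plain_cylinder, extract_lumen(plain_cylinder))
        assert p == 0.0

    def test_circular_spec_gives_unit_aspect(self, plain_cylinder):
        desc = fiber_descriptors(plain_cylinder)
        assert desc.shape_factor == pytest.approx(1.0, abs=0.05)

    def test_does_not_fit_raises(self):
        spec = FiberSpec(diameter=50, length=20, voxel_size=1.0)
        with pytest.raises(DimensionError):
            generate_fiber(spec, seed=0, shape=(20, 20, 20))

    def test_deterministic(self):
        spec = FiberSpec(diameter=20, length=20, roughness_amplitude=1.5, voxel_size=1.0)
        a = generate_fiber(spec, seed=9)
        b = generate_fiber(spec, seed=9)
        assert np.array_equal(a.data, b.data)


class TestCarveNotch:
    @pytest.fixture
    def slab(self):
        return VoxelVolume(np.full((64, 40, 12), SOLID, dtype=np.uint8), 1.0)

    def test_v_notch_removed_area(self, slab):
        notched = carve_notch(slab, NotchGeometry("V", w=40, h=15))
        removed = int(slab.solid_mask().sum() - notched.solid_mask().sum())
        area = removed / slab.shape[2]
        assert area == pytest.approx(40 * 15 / 2, rel=0.10)

    def test_u_notch_removed_area(self, slab):
        notched = carve_notch(slab, NotchGeometry("U", w=40, h=15))
        removed = int(slab.solid_mask().sum() - notched.solid_mask().sum())
        area = removed / slab.shape[2]
        assert area == pytest.approx(math.pi * 20 * 15 / 2, rel=0.10)

    def test_zero_depth_rejected(self):
        with pytest.raises(InvalidGeometryError):
            NotchGeometry("V", w=10, h=0)

    def test_small_notch_strictly_decreases_volume(self, slab):
        notched = carve_notch(slab, NotchGeometry("V", w=3, h=1.2))
        before = int(slab.solid_mask().sum())
        after = int(notched.solid_mask().sum())
        assert 0 < before - after < 50

    def test_removal_only_converts_solid_to_air(self, tube_volume):
        notched = carve_notch(tube_volume, NotchGeometry("U", w=8, h=4))
        flipped = tube_volume.data != notched.data
        assert (tube_volume.data[flipped] == SOLID).all()
        assert (notched.data[flipped] == AIR).all()

    def test_too_deep_notch_rejected(self, tube_volume):
        with pytest.raises(InvalidGeometryError):
            carve_notch(tube_volume, NotchGeometry("V", w=10, h=30))

    def test_opening_angle_round_trip(self, slab):
        # carve a V-notch, then measure opening and depth back from the
        # voxel volume; theta must agree with the analytic value
        w, h = 24.0, 12.0
        notched = carve_notch(slab, NotchGeometry("V", w=w, h=h, axial_position=0.5))
        removed = slab.solid_mask() & ~notched.solid_mask()
        sl = removed[:, :, 6]
        xs = np.flatnonzero(sl.any(axis=1))
        w_meas = xs.max() - xs.min() + 1
        h_meas = sl.sum(axis=1).max()  # deepest removed column
        theta = notch_angle(w_meas, h_meas)
        assert theta == pytest.approx(notch_angle(w, h), abs=5.0)


class TestSurfaceRoughness:
    def test_zero_amplitude_is_identity(self, tube_volume):
        out = add_surface_roughness(tube_volume, 0.0, 5.0, seed=1)
        assert np.array_equal(out.data, tube_volume.data)

    def test_same_seed_same_output(self, tube_volume):
        a = add_surface_roughness(tube_volume, 2.0, 5.0, seed=3)
        b = add_surface_roughness(tube_volume, 2.0, 5.0, seed=3)
        assert np.array_equal(a.data, b.data)

    def test_rms_amplitude_matches_request(self):
        # wide cylinder so the radial profile is well resolved
        spec = FiberSpec(diameter=40, length=60, lumen=False, voxel_size=1.0)
        vol = generate_fiber(spec, seed=0)
        amp = 2.5
        rough = add_surface_roughness(vol, amp, correlation=6.0, seed=5)
        ny, nz = vol.shape[1:]
        cy, cz = ny / 2.0, nz / 2.0
        yy, zz = np.meshgrid(np.arange(ny) + 0.5 - cy, np.arange(nz) + 0.5 - cz, indexing="ij")
        R = np.sqrt(yy**2 + zz**2)
        nbins = 24
        phi_bin = ((np.arctan2(zz, yy) + np.pi) / (2 * np.pi) * nbins).astype(int) % nbins
        devs = []
        for i in range(vol.shape[0]):
            for b in range(nbins):
                sel0 = vol.solid_mask()[i] & (phi_bin == b)
                sel1 = rough.solid_mask()[i] & (phi_bin == b)
                if sel0.any() and sel1.any():
                    devs.append(R[sel1].max() - R[sel0].max())
        rms = float(np.sqrt(np.mean(np.square(devs))))
        assert rms == pytest.approx(amp, rel=0.35)

    def test_lumen_never_breached(self, tube_volume):
        rough = add_surface_roughness(tube_volume, 2.0, 5.0, seed=3)
        p = porosity(rough, extract_lumen(rough))
        assert p > 0.05  # tubular cavity survives the perturbation


class TestPresets:
    def test_fxu4_descriptors(self):
        spec, notch = preset("FXU4")
        assert spec.lumen_area_fraction == pytest.approx(0.09)
        assert spec.shape_factor == pytest.approx(3.23)
        assert notch.type.value == "U"

    def test_fu_descriptors(self):
        spec, _ = preset("FU")
        assert spec.shape_factor == pytest.approx(1.28)
        assert spec.diameter == pytest.approx(44.0)
        assert spec.lumen_area_fraction == pytest.approx(0.04)

    def test_fiv15_descriptors(self):
        spec, notch = preset("FIV15")
        assert not spec.lumen
        assert spec.diameter == pytest.approx(18.0)
        assert notch.type.value == "V"

    def test_fu19_descriptors(self):
        spec, _ = preset("FU19")
        assert not spec.lumen
        assert spec.diameter == pytest.approx(23.0)
        assert spec.shape_factor == pytest.approx(1.78)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset("FXQ9")

    def test_scaled_preset_keeps_dimensionless_descriptors(self):
        full, fn = preset("FXU4")
        small, sn = scaled_preset("FXU4", diameter_voxels=12)
        assert small.shape_factor == full.shape_factor
        assert small.lumen_area_fraction == full.lumen_area_fraction
        assert small.diameter / small.voxel_size == pytest.approx(12)
        assert sn.w / small.diameter == pytest.approx(fn.w / full.diameter)
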