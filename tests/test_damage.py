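import numpy as np
import pytest

import fibrekin as fk
from fibrekin.damage import (
    CRITERIA,
    DamageCriterion,
    DamageSchedule,
    SaturationSignal,
    apply_damage,
    criterion_values,
    force_displacement,
    run_damage_simulation,
    select_damage_set,
)
from fibrekin.meshing import assign_materials, build_mesh
from fibrekin.solver import LoadCase, StressState, element_stresses, reaction_force, solve_tension
from fibrekin.synthetic import SOLID, VoxelVolume


def _stress_state(voigt_rows):
    """StressState from raw Voigt rows (XX, YY, ZZ, XY, XZ, YZ)."""
    tensor = np.atleast_2d(np.asarray(voigt_rows, dtype=float))
    T = np.zeros((len(tensor), 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = tensor[:, 0], tensor[:, 1], tensor[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = tensor[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = tensor[:, 4]
    T[:, 1, 2] = T[:, 2, 1] = tensor[:, 5]
    principal = np.linalg.eigvalsh(T)[:, ::-1]
    return StressState(tensor=tensor, principal=principal)


def _notched_bar(nx=24, s=6):
    data = np.full((nx + 1, s + 4, s), SOLID, dtype=np.uint8)
    vol = VoxelVolume(data, 1.0)
    vol = fk.carve_notch(vol, fk.NotchGeometry("V", w=6, h=3, axial_position=0.5))
    mesh = build_mesh(vol)
    return vol, mesh


class TestCriterionValues:
    def test_uniaxial_state(self):
        st = _stress_state([[5.0, 0, 0, 0, 0, 0]])
        assert criterion_values(st, "S_XX")[0] == 5.0
        assert criterion_values(st, "S_YZ")[0] == 0.0
        assert criterion_values(st, "S_1")[0] == pytest.approx(5.0)
        assert criterion_values(st, "S_I")[0] == pytest.approx(5.0)

    def test_pure_shear_intensity_is_twice_tau(self):
        st = _stress_state([[0, 0, 0, 3.0, 0, 0]])
        assert criterion_values(st, "S_I")[0] == pytest.approx(6.0)
        assert criterion_values(st, "S_1")[0] == pytest.approx(3.0)

    def test_hydrostatic_state_has_zero_intensity(self):
        st = _stress_state([[2.0, 2.0, 2.0, 0, 0, 0]])
        assert criterion_values(st, "S_I")[0] == pytest.approx(0.0)

    def test_shear_criteria_use_absolute_value(self):
        st = _stress_state([[0, 0, 0, -4.0, 0, 0]])
        assert criterion_values(st, "S_XY")[0] == 4.0

    def test_normal_criteria_keep_sign(self):
        st = _stress_state([[-4.0, 0, 0, 0, 0, 0]])
        assert criterion_values(st, "S_XX")[0] == -4.0


class TestSelectDamageSet:
    def test_sort_oracle(self):
        values = np.arange(1.0, 11.0)  # 1..10
        intact = np.ones(10, dtype=bool)
        ids = select_damage_set(values, intact, f=0.11)  # ceil(1.1) = 2
        assert sorted(ids) == [8, 9]  # the values 9 and 10

    def test_ties_broken_by_lower_index(self):
        values = np.ones(10)
        intact = np.ones(10, dtype=bool)
        ids = select_damage_set(values, intact, f=0.3)
        assert sorted(ids) == [0, 1, 2]

    def test_f_one_selects_all_intact(self):
        values = np.random.default_rng(0).random(7)
        intact = np.array([True, False, True, True, False, True, True])
        ids = select_damage_set(values, intact, f=1.0)
        assert sorted(ids) == [0, 2, 3, 5, 6]

    def test_damaged_excluded(self):
        values = np.array([10.0, 9.0, 1.0])
        intact = np.array([False, True, True])
        ids = select_damage_set(values, intact, f=0.5)
        assert list(ids) == [1]

    def test_saturation_signal(self):
        with pytest.raises(SaturationSignal):
            select_damage_set(np.array([1.0]), np.array([False]), f=0.5)


class TestApplyDamage:
    def _materials(self, n=5):
        return fk.MaterialField(
            E=np.full(n, 1000.0), nu=np.full(n, 0.3), E0=1000.0, nu0=0.3, ground=1e-6
        )

    def test_empty_set_is_noop(self):
        mat = self._materials()
        before = mat.E.copy()
        apply_damage(mat, np.array([], dtype=int))
        assert np.array_equal(mat.E, before)

    def test_single_element_ground_level(self):
        mat = self._materials()
        apply_damage(mat, np.array([2]))
        assert mat.E[2] == pytest.approx(1e-6 * 1000.0)
        assert mat.damaged[2]
        assert (mat.E[[0, 1, 3, 4]] == 1000.0).all()
        assert mat.nu[2] == 0.3

    def test_redamage_asserts(self):
        mat = self._materials()
        apply_damage(mat, np.array([1]))
        with pytest.raises(AssertionError):
            apply_damage(mat, np.array([1]))

    def test_force_drops_after_damage(self, solid_bar):
        mesh = build_mesh(solid_bar)
        mat = assign_materials(mesh, solid_bar)
        L = mesh.length
        load = LoadCase(U=0.1, L=L)
        u = solve_tension(mesh, mat, load)
        F0 = reaction_force(mesh, mat, u)
        st = element_stresses(mesh, mat, u)
        ids = select_damage_set(criterion_values(st, "S_1"), mat.intact, f=0.05)
        apply_damage(mat, ids)
        u2 = solve_tension(mesh, mat, load)
        assert reaction_force(mesh, mat, u2) < F0


class TestRunDamageSimulation:
    def test_zero_increments_empty_history(self, solid_bar):
        mesh = build_mesh(solid_bar)
        mat = assign_materials(mesh, solid_bar)
        sched = DamageSchedule(U0=0.01, U_break=0.1, n_increments=0)
        hist = run_damage_simulation(mesh, mat, "S_1", sched)
        assert hist.increments == []
        assert hist.final_ratio == 0.0

    def test_first_damage_localizes_at_notch_root(self):
        vol, mesh = _notched_bar()
        mat = assign_materials(mesh, vol)
        L = mesh.length
        sched = DamageSchedule(U0=0.005 * L, U_break=0.02 * L, n_increments=5, f=0.002)
        hist = run_damage_simulation(mesh, mat, "S_1", sched)
        first = hist.increments[0].new_damaged

        # exhaustive oracle: rank all elements by S_1 on the undamaged solve
        mat0 = assign_materials(mesh, vol)
        u = solve_tension(mesh, mat0, LoadCase(U=sched.U0, L=L))
        vals = criterion_values(element_stresses(mesh, mat0, u), "S_1")
        k = len(first)
        expect = np.flatnonzero(np.ones(len(vals), dtype=bool))
        order = np.lexsort((expect, -vals))
        assert set(first) == set(expect[order[:k]])

        # and those elements sit within 3 voxels of the notch root
        root = np.array([mesh.grid_shape[0] / 2, vol.data.shape[1] - 4, 0])
        for e in first:
            i, j, _ = mesh.voxel_index[e]
            assert abs(i - root[0]) <= 4 and abs(j - root[1]) <= 3

    @pytest.mark.parametrize("criterion", [c.value for c in CRITERIA])
    def test_ratio_monotone_in_unit_interval(self, criterion):
        vol, mesh = _notched_bar(nx=12, s=4)
        mat = assign_materials(mesh, vol)
        L = mesh.length
        sched = DamageSchedule(U0=0.005 * L, U_break=0.03 * L, n_increments=8, f=0.01)
        hist = run_damage_simulation(mesh, mat, criterion, sched)
        r = hist.ratios
        assert (np.diff(r) >= 0).all()
        assert 0 <= r.min() and r.max() <= 1

    def test_deterministic(self):
        vol, mesh = _notched_bar(nx=12, s=4)
        histories = []
        for _ in range(2):
            mat = assign_materials(mesh, vol)
            sched = DamageSchedule(U0=0.05, U_break=0.3, n_increments=6, f=0.02)
            histories.append(run_damage_simulation(mesh, mat, "S_I", sched))
        a, b = histories
        assert a.ratios.tolist() == b.ratios.tolist()
        assert [i.new_damaged for i in a.increments] == [i.new_damaged for i in b.increments]

    def test_threshold_mode_waits_for_critical_stress(self, solid_bar):
        mesh = build_mesh(solid_bar)
        mat = assign_materials(mesh, solid_bar)
        L = mesh.length
        # nominal stress ramps 40 -> 400 MPa; nothing may damage before
        # the field reaches sigma_c
        sched = DamageSchedule(U0=0.002 * L, U_break=0.02 * L, n_increments=10,
                               f=1.0, mode="threshold", sigma_c=200.0)
        hist = run_damage_simulation(mesh, mat, "S_XX", sched)
        r = hist.ratios
        assert r[:3].max() == 0.0
        assert hist.final_ratio > 0.5

    def test_fraction_mode_damages_every_increment(self, solid_bar):
        mesh = build_mesh(solid_bar)
        mat = assign_materials(mesh, solid_bar)
        sched = DamageSchedule(U0=0.05, U_break=0.2, n_increments=4, f=0.01)
        hist = run_damage_simulation(mesh, mat, "S_1", sched)
        assert all(len(i.new_damaged) >= 1 for i in hist.increments)


class TestForceDisplacement:
    def test_undamaged_ramp_is_linear(self, solid_bar):
        mesh = build_mesh(solid_bar)
        mat = assign_materials(mesh, solid_bar)
        # critical stress far above the field: no element damages and the
        # response stays strictly proportional to the applied displacement
        sched = DamageSchedule(U0=0.02, U_break=0.1, n_increments=5, f=1.0,
                               mode="threshold", sigma_c=1e9)
        hist = run_damage_simulation(mesh, mat, "S_1", sched)
        curve = force_displacement(hist)
        stiffness = curve[:, 1] / curve[:, 0]
        assert stiffness == pytest.approx(stiffness[0], rel=1e-6)

    def test_heavy_damage_softens_response(self, solid_bar):
        mesh = build_mesh(solid_bar)
        mat = assign_materials(mesh, solid_bar)
        L = mesh.length
        sched = DamageSchedule(U0=0.05, U_break=0.4, n_increments=8, f=0.08)
        hist = run_damage_simulation(mesh, mat, "S_1", sched)
        curve = force_displacement(hist)
        undamaged_slope = curve[0, 1] / curve[0, 0]
        assert curve[-1, 1] < undamaged_slope * curve[-1, 0]

    def test_monotone_displacement_ordering(self, solid_bar):
        mesh = build_mesh(solid_bar)
        mat = assign_materials(mesh, solid_bar)
        sched = DamageSchedule(U0=0.02, U_break=0.1, n_increments=5, f=0.01)
        hist = run_damage_simulation(mesh, mat, "S_1", sched)
        curve = force_displacement(hist)
        assert (np.diff(curve[:, 0]) > 0).all()

    def test_empty_history_rejected(self):
        hist = fk.DamageHistory(criterion=DamageCriterion.S_1)
        with pytest.raises(ValueError):
            force_displacement(hist)
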