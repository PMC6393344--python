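"""Iterative stress-criterion damage accumulation.

The quasi-static tensile solve is repeated over a displacement ramp; at
each load increment the most stressed intact elements — ranked by one of
eight scalar stress criteria (stress intensity S_I, first principal
stress S_1, the three normal and the three shear components) — have
their modulus converted to the near-zero "ground level". The damage
ratio (cumulative damaged elements over all damageable elements) versus
load increment is the damage-kinetics curve the analysis consumes.

Two conversion rules are provided:

``fraction``
    a fixed fraction ``f`` of the intact elements, the top-ranked ones,
    is converted each increment (the literal reading of "the elements of
    the highest stress levels").
``threshold``
    elements are converted when their criterion value exceeds a critical
    stress ``sigma_c`` *and* lies within a relative band of the current
    maximum, capped at ``ceil(f * n_intact)`` per increment. Damage then
    starts only once the load concentrates stress past the material
    strength, so onset, growth rate and saturation level become
    criterion-dependent, which is what distinguishes aggressive,
    intermediate and inefficient criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .meshing import HexMesh, MaterialField
from .solver import (
    LoadCase,
    StiffnessAssembler,
    StressState,
    StructureDisconnectedError,
    element_stresses,
    solve_tension,
)

__all__ = [
    "DamageCriterion",
    "CRITERIA",
    "DamageSchedule",
    "DamageIncrement",
    "DamageHistory",
    "SaturationSignal",
    "criterion_values",
    "select_damage_set",
    "apply_damage",
    "run_damage_simulation",
    "force_displacement",
]


class DamageCriterion(str, Enum):
    """Scalar stress measure driving element conversion.

    Normal and principal criteria use the signed value (damage is
    tension-driven); shear criteria use the absolute value.
    """

    S_I = "S_I"
    S_1 = "S_1"
    S_XX = "S_XX"
    S_YY = "S_YY"
    S_ZZ = "S_ZZ"
    S_XY = "S_XY"
    S_XZ = "S_XZ"
    S_YZ = "S_YZ"

    @property
    def is_shear(self) -> bool:
        return self in (DamageCriterion.S_XY, DamageCriterion.S_XZ, DamageCriterion.S_YZ)


CRITERIA = tuple(DamageCriterion)


class SaturationSignal(RuntimeError):
    """No intact damageable element remains."""


def criterion_values(stress: StressState, criterion: DamageCriterion | str) -> np.ndarray:
    """Per-element criterion scalar (MPa)."""
    criterion = DamageCriterion(criterion)
    if criterion is DamageCriterion.S_I:
        return stress.intensity
    if criterion is DamageCriterion.S_1:
        return stress.s1
    vals = stress.component(criterion.value[2:])
    if criterion.is_shear:
        return np.abs(vals)
    return vals


def select_damage_set(values: np.ndarray, intact: np.ndarray, f: float) -> np.ndarray:
    """Ids of the ceil(f * n_intact) intact elements with the largest values.

    Ties are broken toward the lower element index; already-damaged
    elements are never selected. Raises :class:`SaturationSignal` when no
    intact element remains.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"damage fraction must lie in (0, 1], got {f}")
    ids = np.flatnonzero(intact)
    if len(ids) == 0:
        raise SaturationSignal("all damageable elements are damaged")
    k = int(np.ceil(f * len(ids)))
    vals = np.asarray(values)[ids]
    order = np.lexsort((ids, -vals))  # descending value, then ascending id
    return ids[order[:k]]


def apply_damage(materials: MaterialField, ids: np.ndarray) -> MaterialField:
    """Convert the listed elements to ground-level stiffness, in place.

    Irreversible; re-damaging an element is a logic error and asserts.
    """
    ids = np.asarray(ids, dtype=np.int64)
    if len(ids) == 0:
        return materials
    assert not materials.damaged[ids].any(), "attempt to re-damage an element"
    materials.E[ids] = materials.ground * materials.E0
    materials.damaged[ids] = True
    return materials


@dataclass(frozen=True)
class DamageSchedule:
    """Displacement ramp and conversion rule for a damage simulation.

    ``U0`` to ``U_break`` (um) over ``n_increments`` equal steps;
    ``f`` is the per-increment conversion quantum (fraction of intact
    elements, the cap in threshold mode). ``sigma_c`` (MPa) switches on
    the threshold rule; ``band`` keeps only candidates above
    ``band * current_max``. ``stop_fraction``: the run stops early when
    the max criterion value over intact elements falls below this
    fraction of its initial value (localized damage has exhausted the
    stress field).
    """

    U0: float
    U_break: float
    n_increments: int
    f: float = 0.005
    mode: str = "fraction"
    sigma_c: float | None = None
    band: float = 0.0
    stop_fraction: float = 0.01
    resolve_inner: bool = False
    solver_method: str = "auto"

    def __post_init__(self) -> None:
        if self.n_increments < 0:
            raise ValueError("n_increments must be >= 0")
        if not 0.0 < self.f <= 1.0:
            raise ValueError("f must lie in (0, 1]")
        if self.mode not in ("fraction", "threshold"):
            raise ValueError(f"unknown damage mode {self.mode!r}")
        if self.mode == "threshold" and self.sigma_c is None:
            raise ValueError("threshold mode requires sigma_c")

    def displacements(self) -> np.ndarray:
        """Linear ramp of applied end displacements, one per increment."""
        if self.n_increments == 0:
            return np.empty(0)
        if self.n_increments == 1:
            return np.array([self.U_break])
        return np.linspace(self.U0, self.U_break, self.n_increments)


@dataclass(frozen=True)
class DamageIncrement:
    increment: int
    U: float  # um
    new_damaged: tuple[int, ...]
    damage_ratio: float
    force: float  # uN
    max_criterion: float  # MPa over intact elements, before conversion


@dataclass
class DamageHistory:
    """Per-increment record of a damage simulation."""

    criterion: DamageCriterion
    increments: list[DamageIncrement] = field(default_factory=list)
    n_damageable: int = 0
    stopped: str = ""  # "", "saturation", "stress_collapse", "disconnected"

    @property
    def ratios(self) -> np.ndarray:
        return np.array([inc.damage_ratio for inc in self.increments])

    @property
    def forces(self) -> np.ndarray:
        return np.array([inc.force for inc in self.increments])

    @property
    def displacements(self) -> np.ndarray:
        return np.array([inc.U for inc in self.increments])

    @property
    def final_ratio(self) -> float:
        return self.increments[-1].damage_ratio if self.increments else 0.0


_MAX_INNER_PASSES = 8


def _threshold_set(values: np.ndarray, intact: np.ndarray, schedule: DamageSchedule) -> np.ndarray:
    """Intact elements exceeding the critical stress (and the relative
    band, if any), truncated to the top ceil(f * n_intact) by value."""
    exceed = intact & (values >= schedule.sigma_c)
    if schedule.band > 0:
        exceed &= values >= schedule.band * float(values[intact].max())
    if not exceed.any():
        return np.empty(0, dtype=np.int64)
    cap = int(np.ceil(schedule.f * intact.sum()))
    cand = np.flatnonzero(exceed)
    order = np.lexsort((cand, -values[cand]))
    return cand[order[:cap]]


def _solve_once(
    mesh: HexMesh,
    materials: MaterialField,
    load: LoadCase,
    method: str,
    assembler: StiffnessAssembler | None = None,
    x0: np.ndarray | None = None,
):
    """(displacements, reaction force) with a single assembly."""
    if assembler is None:
        assembler = StiffnessAssembler(mesh, materials.nu0)
    K = assembler.assemble(materials.E)
    u = solve_tension(mesh, materials, load, method=method, K=K, x0=x0)
    R = K @ u.reshape(-1)
    _, right = mesh.end_nodes()
    return u, float(R[3 * right].sum())


def run_damage_simulation(
    mesh: HexMesh,
    materials: MaterialField,
    criterion: DamageCriterion | str,
    schedule: DamageSchedule,
) -> DamageHistory:
    """Displacement-ramped damage accumulation under one stress criterion.

    For each increment: solve the tensile problem, evaluate the criterion
    on every element, convert the selected intact elements to ground
    level, and record applied displacement, reaction force, damage ratio
    and the pre-conversion maximum criterion value. Stops early on
    saturation, stress collapse (threshold/stop rule) or loss of the
    spanning load path. ``materials`` is mutated in place.
    """
    criterion = DamageCriterion(criterion)
    history = DamageHistory(criterion=criterion, n_damageable=mesh.n_elements)
    assembler = StiffnessAssembler(mesh, materials.nu0)
    initial_max: float | None = None
    u_prev: np.ndarray | None = None
    for i, U in enumerate(schedule.displacements()):
        load = LoadCase(U=U, L=mesh.length)
        try:
            u, force = _solve_once(
                mesh, materials, load, schedule.solver_method, assembler, x0=u_prev
            )
            u_prev = u
        except StructureDisconnectedError:
            history.stopped = "disconnected"
            break
        stress = element_stresses(mesh, materials, u)
        values = criterion_values(stress, criterion)
        intact = materials.intact
        if not intact.any():
            history.stopped = "saturation"
            break
        vmax = float(values[intact].max())
        if initial_max is None:
            initial_max = max(vmax, 1e-30)
        if vmax < schedule.stop_fraction * initial_max:
            history.increments.append(
                DamageIncrement(i, U, (), history.final_ratio, force, vmax)
            )
            history.stopped = "stress_collapse"
            break

        if schedule.mode == "fraction":
            ids = select_damage_set(values, intact, schedule.f)
            apply_damage(materials, ids)
        else:
            ids = _threshold_set(values, intact, schedule)
            apply_damage(materials, ids)
            if schedule.resolve_inner and len(ids):
                # quasi-static cascade: re-equilibrate and keep converting
                # until no intact element exceeds the critical stress
                all_ids = list(ids)
                for _ in range(_MAX_INNER_PASSES):
                    try:
                        u, _f2 = _solve_once(
                            mesh, materials, load, schedule.solver_method, assembler, x0=u
                        )
                    except StructureDisconnectedError:
                        break
                    values = criterion_values(element_stresses(mesh, materials, u), criterion)
                    more = _threshold_set(values, materials.intact, schedule)
                    if len(more) == 0:
                        break
                    apply_damage(materials, more)
                    all_ids += list(more)
                ids = np.asarray(all_ids, dtype=np.int64)
        ratio = materials.damaged.sum() / history.n_damageable
        history.increments.append(
            DamageIncrement(i, U, tuple(int(e) for e in ids), float(ratio), force, vmax)
        )
        if not materials.intact.any():
            history.stopped = "saturation"
            break
    return history


def force_displacement(history: DamageHistory) -> np.ndarray:
    """(n, 2) array of (applied displacement U, reaction force F) pairs."""
    if not history.increments:
        raise ValueError("empty damage history")
    return np.column_stack([history.displacements, history.forces])
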