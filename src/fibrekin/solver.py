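"""Linear elastic tensile solve on the voxel hex mesh.

The tensile test is modelled after the glued-end fiber experiment: the
x = 0 end face is fully clamped and the x = L face is displaced by U
along X with its lateral motion suppressed,

    (Ux, Uy, Uz)|x=0 = (0, 0, 0);   (Ux, Uy, Uz)|x=L = (U, 0, 0).

Elements are identical trilinear cuboids integrated with a 2x2x2 Gauss
rule; the global system is assembled sparse and solved either by a
direct sparse factorization or by Jacobi-preconditioned conjugate
gradients on the reduced (free-dof) system. Per-element stresses are
evaluated at the element centroid and decomposed into principal values
S1 >= S2 >= S3 and the stress intensity S_I = S1 - S3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import HexMesh, MaterialField, connected_components

__all__ = [
    "LoadCase",
    "StressState",
    "SolverError",
    "StructureDisconnectedError",
    "hex_stiffness",
    "elastic_D",
    "assemble_stiffness",
    "solve_tension",
    "element_stresses",
    "reaction_force",
    "lateral_contraction",
]

#: Voigt component order used throughout: XX, YY, ZZ, XY, XZ, YZ
VOIGT = ("XX", "YY", "ZZ", "XY", "XZ", "YZ")


class SolverError(RuntimeError):
    """Iterative solve failed to converge; carries the final residual."""


class StructureDisconnectedError(RuntimeError):
    """No load path connects the two end faces."""


@dataclass(frozen=True)
class LoadCase:
    """Applied end displacement U (um) over fiber length L (um), axis X."""

    U: float
    L: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("fiber length must be positive")

    @property
    def nominal_strain(self) -> float:
        return self.U / self.L


def elastic_D(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (engineering shear strains)."""
    if not nu < 0.5:
        raise ValueError(f"nu = {nu} >= 0.5: incompressible limit not supported")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


# local corner coordinates in the element reference cube [-1, 1]^3,
# matching the mesh corner ordering
_XI = np.array(
    [
        (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
    ],
    dtype=float,
)


def _b_matrix(xi: np.ndarray, edges: tuple[float, float, float]) -> np.ndarray:
    """6x24 strain-displacement matrix at reference point ``xi``."""
    hx, hy, hz = edges
    # dN/dxi for trilinear shape functions
    dN = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        dN[a, 0] = xa * (1 + ya * xi[1]) * (1 + za * xi[2]) / 8.0
        dN[a, 1] = (1 + xa * xi[0]) * ya * (1 + za * xi[2]) / 8.0
        dN[a, 2] = (1 + xa * xi[0]) * (1 + ya * xi[1]) * za / 8.0
    dN[:, 0] *= 2.0 / hx
    dN[:, 1] *= 2.0 / hy
    dN[:, 2] *= 2.0 / hz
    B = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        B[0, c] = dN[a, 0]
        B[1, c + 1] = dN[a, 1]
        B[2, c + 2] = dN[a, 2]
        B[3, c] = dN[a, 1]; B[3, c + 1] = dN[a, 0]      # gamma_xy
        B[4, c] = dN[a, 2]; B[4, c + 2] = dN[a, 0]      # gamma_xz
        B[5, c + 1] = dN[a, 2]; B[5, c + 2] = dN[a, 1]  # gamma_yz
    return B


def hex_stiffness(E: float, nu: float, edges: tuple[float, float, float]) -> np.ndarray:
    """24x24 stiffness of a trilinear cuboid element (2x2x2 Gauss).

    Symmetric positive semi-definite with exactly six rigid-body
    zero-energy modes. Scales linearly with E at fixed nu.
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    D = elastic_D(E, nu)
    hx, hy, hz = edges
    detJ = (hx / 2) * (hy / 2) * (hz / 2)
    g = 1.0 / np.sqrt(3.0)
    K = np.zeros((24, 24))
    for sx in (-g, g):
        for sy in (-g, g):
            for sz in (-g, g):
                B = _b_matrix(np.array([sx, sy, sz]), edges)
                K += B.T @ D @ B * detJ
    return 0.5 * (K + K.T)


def _edofs(mesh: HexMesh) -> np.ndarray:
    """(n_elements, 24) global dof indices (3 per node, x/y/z interleaved)."""
    return (mesh.elements[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(-1, 24)


class StiffnessAssembler:
    """Reusable global-stiffness assembler with a cached sparsity structure.

    All elements are geometrically identical cuboids, so the global
    matrix is ``sum_e E_e * scatter(K_unit)``; the scatter pattern is
    computed once and reassembly for new per-element moduli (damage
    loops) reduces to a gather + segmented sum.
    """

    def __init__(self, mesh: HexMesh, nu0: float):
        h = mesh.voxel_size
        self.K_unit = hex_stiffness(1.0, nu0, (h, h, h))
        edofs = _edofs(mesh)
        rows = np.repeat(edofs, 24, axis=1).ravel()
        cols = np.tile(edofs, (1, 24)).ravel()
        self.n = 3 * mesh.n_nodes
        key = rows * self.n + cols
        self._order = np.argsort(key, kind="stable")
        skey = key[self._order]
        boundaries = np.flatnonzero(np.diff(skey)) + 1
        self._starts = np.concatenate([[0], boundaries])
        ukey = skey[self._starts]
        urows = (ukey // self.n).astype(np.int32)
        self._indices = (ukey % self.n).astype(np.int32)
        self._indptr = np.concatenate(
            [[0], np.cumsum(np.bincount(urows, minlength=self.n))]
        ).astype(np.int64)

    def assemble(self, E: np.ndarray) -> sp.csr_matrix:
        data = (np.asarray(E)[:, None] * self.K_unit.reshape(1, -1)).ravel()
        summed = np.add.reduceat(data[self._order], self._starts)
        return sp.csr_matrix((summed, self._indices, self._indptr), shape=(self.n, self.n))


def assemble_stiffness(mesh: HexMesh, materials: MaterialField) -> sp.csr_matrix:
    """Global sparse stiffness; all elements share one unit-E matrix."""
    return StiffnessAssembler(mesh, materials.nu0).assemble(materials.E)


def _boundary_dofs(mesh: HexMesh, load: LoadCase) -> tuple[np.ndarray, np.ndarray]:
    """(constrained dof ids, prescribed values) for the tensile BCs."""
    left, right = mesh.end_nodes()
    dofs = []
    vals = []
    for nid in left:
        dofs += [3 * nid, 3 * nid + 1, 3 * nid + 2]
        vals += [0.0, 0.0, 0.0]
    for nid in right:
        dofs += [3 * nid, 3 * nid + 1, 3 * nid + 2]
        vals += [load.U, 0.0, 0.0]
    return np.asarray(dofs, dtype=np.int64), np.asarray(vals)


def solve_tension(
    mesh: HexMesh,
    materials: MaterialField,
    load: LoadCase,
    tolerance: float = 1e-8,
    method: str = "auto",
    x0: np.ndarray | None = None,
    K: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Nodal displacement field (n_nodes, 3) under the tensile BCs.

    ``method`` is one of "direct" (sparse LU on the reduced system),
    "cg" (Jacobi-preconditioned conjugate gradients, relative residual
    ``tolerance``) or "auto" (direct below 2e5 free dofs, CG above —
    the contract is on the solution, not on the storage scheme).
    ``K`` may carry a pre-assembled global stiffness to avoid repeated
    assembly in iterative damage loops.
    Raises :class:`StructureDisconnectedError` when no intact load path
    spans the two end faces, :class:`SolverError` on CG stagnation.
    """
    report = connected_components(mesh, element_mask=materials.intact)
    if not any(report.spanning):
        raise StructureDisconnectedError("no intact component spans both loading ends")

    if K is None:
        K = assemble_stiffness(mesh, materials)
    n = K.shape[0]
    cdofs, cvals = _boundary_dofs(mesh, load)
    free = np.ones(n, dtype=bool)
    free[cdofs] = False
    u = np.zeros(n)
    u[cdofs] = cvals

    rhs = -K[:, cdofs] @ cvals
    rhs = rhs[free]
    Kff = K[free][:, free].tocsc()

    fallback = False
    if method == "auto":
        # direct factorization wins on small systems; Jacobi-CG scales
        # better and gets a free warm start in damage loops
        method = "direct" if Kff.shape[0] <= 4000 else "cg"
        fallback = True
    if method == "cg":
        diag = Kff.diagonal()
        diag[diag <= 0] = 1.0
        M = sp.diags(1.0 / diag)
        maxiter = max(1000, int(10 * np.sqrt(Kff.shape[0])))
        uf0 = np.asarray(x0).reshape(-1)[free] if x0 is not None else None
        uf, info = spla.cg(Kff, rhs, rtol=tolerance, atol=0.0, M=M, maxiter=maxiter, x0=uf0)
        if info != 0:
            if not fallback:
                res = np.linalg.norm(Kff @ uf - rhs) / max(np.linalg.norm(rhs), 1e-30)
                raise SolverError(
                    f"CG did not converge in {maxiter} iterations (relative residual {res:.3e})"
                )
            method = "direct"
    if method == "direct":
        lu = spla.splu(Kff.tocsc(), permc_spec="MMD_AT_PLUS_A")
        uf = lu.solve(rhs)
    elif method != "cg":
        raise ValueError(f"unknown method {method!r}")
    u[free] = uf
    return u.reshape(-1, 3)


@dataclass
class StressState:
    """Per-element centroid stresses, principal values and intensity."""

    tensor: np.ndarray  # (n_elements, 6) Voigt XX, YY, ZZ, XY, XZ, YZ (MPa)
    principal: np.ndarray  # (n_elements, 3) S1 >= S2 >= S3 (MPa)

    @property
    def s1(self) -> np.ndarray:
        return self.principal[:, 0]

    @property
    def s3(self) -> np.ndarray:
        return self.principal[:, 2]

    @property
    def intensity(self) -> np.ndarray:
        """S_I = S1 - S3 = max pairwise principal-stress difference."""
        return self.principal[:, 0] - self.principal[:, 2]

    def component(self, name: str) -> np.ndarray:
        return self.tensor[:, VOIGT.index(name.upper())]


def element_stresses(
    mesh: HexMesh, materials: MaterialField, displacements: np.ndarray
) -> StressState:
    """Centroid stress tensor and principal decomposition per element."""
    h = mesh.voxel_size
    B0 = _b_matrix(np.zeros(3), (h, h, h))  # 6x24 at the centroid
    D_unit = elastic_D(1.0, materials.nu0)
    u = np.asarray(displacements).reshape(-1)
    ue = u[_edofs(mesh)]  # (n_elements, 24)
    strain = ue @ B0.T
    stress = (strain @ D_unit.T) * materials.E[:, None]

    T = np.empty((mesh.n_elements, 3, 3))
    T[:, 0, 0] = stress[:, 0]
    T[:, 1, 1] = stress[:, 1]
    T[:, 2, 2] = stress[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = stress[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = stress[:, 4]
    T[:, 1, 2] = T[:, 2, 1] = stress[:, 5]
    evals = np.linalg.eigvalsh(T)  # ascending
    principal = evals[:, ::-1]
    return StressState(tensor=stress, principal=principal)


def reaction_force(
    mesh: HexMesh,
    materials: MaterialField,
    displacements: np.ndarray,
    load: LoadCase | None = None,
) -> float:
    """Axial reaction (uN) summed over the x = L face nodes.

    Equals minus the sum over the x = 0 face within solver tolerance
    (global equilibrium).
    """
    K = assemble_stiffness(mesh, materials)
    R = K @ np.asarray(displacements).reshape(-1)
    _, right = mesh.end_nodes()
    return float(R[3 * right].sum())


def end_reactions(mesh: HexMesh, materials: MaterialField, displacements: np.ndarray) -> tuple[float, float]:
    """(sum Rx at x = 0, sum Rx at x = L) for equilibrium checks."""
    K = assemble_stiffness(mesh, materials)
    R = K @ np.asarray(displacements).reshape(-1)
    left, right = mesh.end_nodes()
    return float(R[3 * left].sum()), float(R[3 * right].sum())


def strain_energy(mesh: HexMesh, materials: MaterialField, displacements: np.ndarray) -> float:
    """Stored elastic energy 0.5 u^T K u (uN.um = pJ)."""
    K = assemble_stiffness(mesh, materials)
    u = np.asarray(displacements).reshape(-1)
    return float(0.5 * u @ (K @ u))


def lateral_contraction(
    mesh: HexMesh, displacements: np.ndarray, region: tuple[float, float] = (1 / 3, 2 / 3)
) -> float:
    """Mean inward radial displacement (um) of mid-span nodes.

    Averaged over nodes whose axial position falls in ``region`` (as a
    fraction of the mesh length), away from the constrained ends where
    Poisson contraction is suppressed. Positive values mean contraction.
    """
    u = np.asarray(displacements).reshape(-1, 3)
    x = mesh.nodes[:, 0]
    lo = x.min() + region[0] * (x.max() - x.min())
    hi = x.min() + region[1] * (x.max() - x.min())
    sel = (x >= lo) & (x <= hi)
    yz = mesh.nodes[sel, 1:]
    c = yz.mean(axis=0)
    d = yz - c
    r = np.linalg.norm(d, axis=1)
    ok = r > 1e-9
    radial = (u[sel][ok, 1:] * (d[ok] / r[ok, None])).sum(axis=1)
    return float(-radial.mean())
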