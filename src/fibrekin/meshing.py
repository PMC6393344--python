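"""Voxel-to-element conversion and material assignment.

Every solid voxel of a segmented volume becomes one 8-node cuboid
(trilinear hexahedron) element; nodes on shared faces, edges and corners
are merged exactly, so the mesh is conforming by construction. Air
voxels are not meshed (their stiffness is zero); damaged elements, by
contrast, stay in the mesh with a near-zero "ground level" stiffness so
the system matrix remains non-singular.

Units: lengths um, moduli MPa, forces uN (consistent um-MPa-uN system).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import AIR, SOLID, VoxelVolume

__all__ = [
    "HexMesh",
    "MaterialField",
    "ComponentReport",
    "build_mesh",
    "assign_materials",
    "connected_components",
]

# local corner offsets in VTK hexahedron order: bottom z-face counter-
# clockwise in (x, y), then the top z-face in the same order
_CORNERS = np.array(
    [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ],
    dtype=np.int64,
)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class HexMesh:
    """Conforming 8-node cuboid mesh built from solid voxels.

    ``nodes`` are physical coordinates (um), ``elements`` the per-element
    node indices in the fixed corner ordering, ``voxel_index`` the (i, j, k)
    source voxel of each element, in lexicographic voxel order.
    """

    nodes: np.ndarray  # (n_nodes, 3) um
    elements: np.ndarray  # (n_elements, 8) int
    voxel_index: np.ndarray  # (n_elements, 3) int
    voxel_size: float
    grid_shape: tuple[int, int, int]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def length(self) -> float:
        """Extent of the mesh along the loading axis X (um)."""
        return float(self.nodes[:, 0].max() - self.nodes[:, 0].min())

    def volume(self) -> float:
        return self.n_elements * self.voxel_size**3

    def solid_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[tuple(self.voxel_index.T)] = True
        return mask

    def end_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """(node ids at x = 0, node ids at x = L) of the mesh extent."""
        x = self.nodes[:, 0]
        return np.flatnonzero(x == x.min()), np.flatnonzero(x == x.max())


def build_mesh(seg: VoxelVolume) -> HexMesh:
    """Convert every solid voxel into one cuboid element with shared nodes.

    Element order is the lexicographic voxel order; node numbering is the
    lexicographic order of occupied grid vertices. Deterministic.
    """
    solid = seg.data == SOLID
    if not solid.any():
        raise ValueError("cannot mesh a volume with no solid voxels")
    nx, ny, nz = solid.shape
    vox_ijk = np.argwhere(solid)  # lexicographic order
    gy, gz = ny + 1, nz + 1

    # global vertex linear ids for the 8 corners of each voxel
    corner_ids = (
        (vox_ijk[:, None, 0] + _CORNERS[None, :, 0]) * (gy * gz)
        + (vox_ijk[:, None, 1] + _CORNERS[None, :, 1]) * gz
        + (vox_ijk[:, None, 2] + _CORNERS[None, :, 2])
    )
    used, elements = np.unique(corner_ids, return_inverse=True)
    elements = elements.reshape(corner_ids.shape).astype(np.int64)

    ii = used // (gy * gz)
    jj = (used // gz) % gy
    kk = used % gz
    nodes = np.column_stack([ii, jj, kk]).astype(float) * seg.voxel_size
    return HexMesh(
        nodes=nodes,
        elements=elements,
        voxel_index=vox_ijk,
        voxel_size=seg.voxel_size,
        grid_shape=(nx, ny, nz),
    )


@dataclass
class MaterialField:
    """Per-element isotropic elastic constants.

    Intact elements carry (E0, nu0); damaged elements keep nu0 but their
    modulus is converted to ``ground * E0``, a near-zero residual that
    removes load-carrying capacity while keeping the mesh connected.
    """

    E: np.ndarray  # (n_elements,) MPa
    nu: np.ndarray  # (n_elements,)
    E0: float
    nu0: float
    ground: float = 1e-6
    damaged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 < self.nu0 < 0.5:
            raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {self.nu0}")
        if self.damaged is None:
            self.damaged = np.zeros(len(self.E), dtype=bool)

    @property
    def intact(self) -> np.ndarray:
        return ~self.damaged

    def copy(self) -> "MaterialField":
        return MaterialField(
            self.E.copy(), self.nu.copy(), self.E0, self.nu0, self.ground, self.damaged.copy()
        )


def assign_materials(
    mesh: HexMesh,
    gray: VoxelVolume,
    E0: float = 20000.0,
    nu0: float = 0.3,
    ground: float = 1e-6,
) -> MaterialField:
    """Map the two gray levels onto elastic constants.

    Solid voxels (gray 255) receive the solid-phase constants (E0, nu0);
    air voxels (gray 0) carry no stiffness and are not meshed. Gray
    values outside {0, 255} mean the volume was never segmented and are
    rejected.
    """
    if not np.isin(gray.data, (AIR, SOLID)).all():
        raise ValueError("gray levels outside {0, 255}: segment the volume first")
    g = gray.data[tuple(mesh.voxel_index.T)]
    if (g != SOLID).any():
        raise ValueError("mesh contains elements on non-solid voxels")
    n = mesh.n_elements
    return MaterialField(
        E=np.full(n, float(E0)),
        nu=np.full(n, float(nu0)),
        E0=float(E0),
        nu0=float(nu0),
        ground=float(ground),
    )


@dataclass(frozen=True)
class ComponentReport:
    labels: np.ndarray  # (n_elements,) 1-based component label
    sizes: tuple[int, ...]
    spanning: tuple[bool, ...]  # component touches both loading ends

    @property
    def n_components(self) -> int:
        return len(self.sizes)

    @property
    def non_spanning(self) -> tuple[int, ...]:
        """1-based labels of components not attached to both loading ends."""
        return tuple(i + 1 for i, s in enumerate(self.spanning) if not s)


def connected_components(mesh: HexMesh, element_mask: np.ndarray | None = None) -> ComponentReport:
    """Face-connected components of (a subset of) the mesh elements.

    Elements sharing only an edge or corner are *not* considered
    connected here: corner-linked chains carry no meaningful load path.
    Components not attached to both loading ends (the x extremes of the
    mesh) are flagged — they mirror delaminated parts that are imaged but
    carry no load.
    """
    mask = mesh.solid_mask()
    if element_mask is not None:
        keep = np.zeros(mesh.grid_shape, dtype=bool)
        keep[tuple(mesh.voxel_index[element_mask].T)] = True
        mask = keep
    labels3d, n = ndimage.label(mask, structure=_STRUCT6)
    elem_labels = labels3d[tuple(mesh.voxel_index.T)]
    x = mesh.voxel_index[:, 0]
    x_lo, x_hi = x.min(), x.max()
    sizes = []
    spanning = []
    for lbl in range(1, n + 1):
        sel = elem_labels == lbl
        sizes.append(int(sel.sum()))
        if sizes[-1] == 0:
            spanning.append(False)
            continue
        xs = x[sel]
        spanning.append(bool(xs.min() == x_lo and xs.max() == x_hi))
    return ComponentReport(labels=elem_labels, sizes=tuple(sizes), spanning=tuple(spanning))
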