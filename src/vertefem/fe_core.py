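"""Voxel hexahedral linear-elasticity engine.

Every non-background voxel becomes one trilinear 8-node hexahedron (hex8)
with 2x2x2 Gauss quadrature on a uniform grid, so the element geometry is
exact and a single reference stiffness matrix serves every element of a
given material.  A mean-dilatation (B-bar) variant of the element is
available for nearly incompressible tissues, where full integration is
known to lock volumetrically.

Loading replicates an axial-compression platen test: the bottom plate node
set is fully fixed; the top plate nodes move as a rigid body whose
reference point (mid-point of the anterior-posterior diameter of the top
plate) carries the prescribed axial displacement.  Plate rotations are free
by default, emulating load transfer through a ball seat; a locked-rotation
mode is available.  Units are mm, N, MPa throughout (MPa * mm^2 = N).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse import csgraph

from .grids import LabelMap, LABEL_IDS
from .imaging import ModulusField
from .materials import (
    BONE_POISSON,
    Material,
    constitutive_matrix,
    cylindrical_rotation,
    healthy_annulus,
    healthy_nucleus,
    housing_material,
)

__all__ = [
    "Model",
    "SolveResult",
    "StiffnessResult",
    "build_model",
    "element_stiffness_hex8",
    "assemble",
    "assemble_and_solve",
    "solve_system",
    "element_stresses",
    "von_mises",
    "segment_stiffness",
]

# hex8 corner offsets and matching natural coordinates
_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]]
)
_XI = 2.0 * _CORNERS - 1.0


@functools.lru_cache(maxsize=8)
def _b_matrices(h: float, formulation: str) -> tuple[np.ndarray, float]:
    """Strain-displacement matrices (8 Gauss points, 6, 24) for a cube of
    side ``h``, and the Gauss-point volume weight."""
    g = 1.0 / np.sqrt(3.0)
    B = np.zeros((8, 6, 24))
    for q, (x, y, z) in enumerate(_XI * g):
        dN = np.empty((8, 3))
        for a in range(8):
            sx, sy, sz = _XI[a]
            dN[a] = (
                sx * (1 + sy * y) * (1 + sz * z) / 8.0,
                (1 + sx * x) * sy * (1 + sz * z) / 8.0,
                (1 + sx * x) * (1 + sy * y) * sz / 8.0,
            )
        dN /= h / 2.0  # constant Jacobian of the cube
        for a in range(8):
            bx, by, bz = dN[a]
            c = 3 * a
            B[q, 0, c] = bx
            B[q, 1, c + 1] = by
            B[q, 2, c + 2] = bz
            B[q, 3, c] = by
            B[q, 3, c + 1] = bx
            B[q, 4, c + 1] = bz
            B[q, 4, c + 2] = by
            B[q, 5, c] = bz
            B[q, 5, c + 2] = bx
    if formulation == "bbar":
        # mean-dilatation: replace the pointwise volumetric strain with its
        # element average to relieve volumetric locking
        m = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        bvol = B[:, :3, :].sum(axis=1)  # (8, 24) volumetric strain rows
        bbar = bvol.mean(axis=0)
        B = B + (m[None, :, None] / 3.0) * (bbar[None, None, :] - bvol[:, None, :])
    elif formulation != "full":
        raise ValueError(f"unknown element formulation {formulation!r}")
    weight = (h / 2.0) ** 3  # detJ; all Gauss weights are 1
    return B, weight


def element_stiffness_hex8(
    material: "Material | np.ndarray", voxel_size: float, formulation: str = "full"
) -> np.ndarray:
    """24x24 stiffness of a single cubic hex8 element (N/mm).

    Symmetric positive semi-definite with exactly six rigid-body zero-energy
    modes.  ``material`` may be a :class:`Material` or a ready 6x6
    constitutive matrix.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    D = material if isinstance(material, np.ndarray) else constitutive_matrix(material)
    B, w = _b_matrices(float(voxel_size), formulation)
    K = np.einsum("qai,ab,qbj->ij", B, D, B) * w
    return 0.5 * (K + K.T)


def _batch_stiffness(D: np.ndarray, voxel_size: float, formulation: str) -> np.ndarray:
    """Element stiffness for a batch of constitutive matrices (m, 6, 6)."""
    B, w = _b_matrices(float(voxel_size), formulation)
    return np.einsum("qai,eab,qbj->eij", B, D, B, optimize=True) * w


@dataclass
class Model:
    """A voxel FE problem: mesh, per-element materials, plate constraints.

    ``elem_E``/``elem_nu`` hold the current isotropic constants for every
    element; annulus elements (flagged in ``annulus_mask``) are instead
    governed by the orthotropic ``annulus`` material in cylindrical axes
    around the body axis.  ``base_bone_E`` preserves the greyscale-derived
    modulus of every bone and cement-labelled element so treatment
    operators can restore it exactly.
    """

    labels: LabelMap
    voxel_size: float
    conn: np.ndarray  # (ne, 8) node ids
    elem_voxel: np.ndarray  # (ne, 3) voxel indices
    node_coords: np.ndarray  # (nn, 3) world mm
    elem_label: np.ndarray  # (ne,)
    elem_E: np.ndarray  # (ne,)
    elem_nu: np.ndarray  # (ne,)
    annulus_mask: np.ndarray  # (ne,) bool
    annulus: Material
    base_bone_E: np.ndarray  # (ne,)
    top_nodes: np.ndarray
    bottom_nodes: np.ndarray
    ref_point: np.ndarray
    rotations_free: bool = True
    formulation: str = "full"
    augmented: dict = field(default_factory=dict)  # level -> cement E (MPa)

    @property
    def n_elements(self) -> int:
        return len(self.conn)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def copy(self) -> "Model":
        return replace(
            self,
            elem_E=self.elem_E.copy(),
            elem_nu=self.elem_nu.copy(),
            base_bone_E=self.base_bone_E.copy(),
            augmented=dict(self.augmented),
        )

    def element_mask(self, *label_names: str) -> np.ndarray:
        ids = [LABEL_IDS[n] for n in label_names]
        return np.isin(self.elem_label, ids)

    def annulus_rotations(self) -> np.ndarray:
        """(m, 3, 3) cylindrical material frames of the annulus elements."""
        centres = (self.elem_voxel[self.annulus_mask] + 0.5) * self.voxel_size
        cx, cy = self.ref_point[0], self.ref_point[1]
        return np.stack(
            [cylindrical_rotation(c[0] - cx, c[1] - cy) for c in centres]
        )


def build_model(
    labels: LabelMap,
    modulus: ModulusField,
    *,
    annulus: "Material | None" = None,
    nucleus: "Material | None" = None,
    housing: "Material | None" = None,
    bone_poisson: float = BONE_POISSON,
    rotations_free: bool = True,
    formulation: str = "full",
) -> Model:
    """Assemble the FE problem definition from labels and mapped moduli.

    Disc materials default to the healthy reference set.  Cement-labelled
    elements initially carry their underlying greyscale-derived bone
    modulus (the pre-treatment state); :func:`vertefem.treatment.apply_augmentation`
    switches them to cement.  Pass the modulus field built from the
    pre-treatment label map so those underlying values are meaningful.
    """
    annulus = annulus if annulus is not None else healthy_annulus()
    nucleus = nucleus if nucleus is not None else healthy_nucleus()
    housing = housing if housing is not None else housing_material()
    if annulus.kind != "orthotropic" or nucleus.kind != "isotropic":
        raise ValueError("annulus must be orthotropic and nucleus isotropic")

    lab = labels.data
    fg = lab > 0
    elem_voxel = np.argwhere(fg)
    ne = len(elem_voxel)
    if ne == 0:
        raise ValueError("label map contains no tissue voxels")

    shape = np.array(lab.shape) + 1
    node_id = -np.ones(shape, dtype=np.int64)
    ii, jj, kk = elem_voxel.T
    for di, dj, dk in _CORNERS:
        node_id[ii + di, jj + dj, kk + dk] = 0
    nn = int((node_id == 0).sum())
    node_id[node_id == 0] = np.arange(nn)
    conn = np.stack(
        [node_id[ii + d[0], jj + d[1], kk + d[2]] for d in _CORNERS], axis=1
    ).astype(np.int64)
    node_idx = np.argwhere(node_id >= 0)
    order = node_id[node_id >= 0]
    coords = np.empty((nn, 3))
    coords[order] = node_idx * labels.voxel_size

    elem_label = lab[ii, jj, kk]
    elem_E = modulus.data[ii, jj, kk].copy()
    elem_nu = np.full(ne, bone_poisson)
    names = labels.names

    def stem_mask(stem: str) -> np.ndarray:
        ids = [lid for lid, n in names.items() if n.split("_")[0] == stem]
        return np.isin(elem_label, ids)

    nuc = stem_mask("nucleus")
    elem_E[nuc] = nucleus.E
    elem_nu[nuc] = nucleus.nu
    hou = stem_mask("housing")
    elem_E[hou] = housing.E
    elem_nu[hou] = housing.nu
    ann = stem_mask("annulus")
    elem_E[ann] = annulus.E3  # placeholder scalar; annulus uses the full matrix
    elem_nu[ann] = 0.0

    # underlying bone modulus of bone AND cement voxels, for exact restores
    base_bone_E = modulus.data[ii, jj, kk].copy()

    nz = lab.shape[2]
    bottom_nodes = np.sort(np.unique(conn[elem_voxel[:, 2] == 0][:, :4].ravel()))
    top_nodes = np.sort(np.unique(conn[elem_voxel[:, 2] == nz - 1][:, 4:].ravel()))
    if len(bottom_nodes) == 0 or len(top_nodes) == 0:
        raise ValueError("model has no plate contact at the grid ends")

    top_xy = coords[top_nodes]
    ref = np.array(
        [
            0.5 * (top_xy[:, 0].min() + top_xy[:, 0].max()),
            0.5 * (top_xy[:, 1].min() + top_xy[:, 1].max()),
            top_xy[:, 2].max(),
        ]
    )

    return Model(
        labels=labels,
        voxel_size=labels.voxel_size,
        conn=conn,
        elem_voxel=elem_voxel,
        node_coords=coords,
        elem_label=elem_label,
        elem_E=elem_E,
        elem_nu=elem_nu,
        annulus_mask=ann,
        annulus=annulus,
        base_bone_E=base_bone_E,
        top_nodes=top_nodes,
        bottom_nodes=bottom_nodes,
        ref_point=ref,
        rotations_free=rotations_free,
        formulation=formulation,
    )


def _annulus_D_batch(model: Model) -> np.ndarray:
    D0 = constitutive_matrix(model.annulus)
    R = model.annulus_rotations()
    # rotate the fourth-order tensor once per element frame
    from .materials import _tensor_to_voigt, _voigt_to_tensor

    C = _voigt_to_tensor(D0)
    Crot = np.einsum("eia,ejb,ekc,eld,abcd->eijkl", R, R, R, R, C, optimize=True)
    m = len(R)
    D = np.empty((m, 6, 6))
    from .materials import _VOIGT_PAIRS

    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            D[:, a, b] = Crot[:, i, j, k, l]
    return D


def assemble(model: Model, element_mask: "np.ndarray | None" = None) -> sp.csr_matrix:
    """Global stiffness (3n x 3n, N/mm) over ``element_mask`` (default all).

    Isotropic elements reuse one reference element matrix per distinct
    Poisson ratio, scaled by the element modulus; annulus elements get
    individually rotated orthotropic matrices.
    """
    ne = model.n_elements
    sel = np.ones(ne, bool) if element_mask is None else np.asarray(element_mask, bool)
    ndof = 3 * model.n_nodes
    edof = (3 * model.conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)

    rows_list, cols_list, vals_list = [], [], []

    def add_block(mask: np.ndarray, K_e: np.ndarray) -> None:
        # K_e: (m, 24, 24) or (24, 24) shared
        ed = edof[mask]
        m = len(ed)
        if m == 0:
            return
        r = np.repeat(ed, 24, axis=1).ravel()
        c = np.tile(ed, (1, 24)).ravel()
        if K_e.ndim == 2:
            v = np.broadcast_to(K_e.ravel(), (m, 576)).ravel()
        else:
            v = K_e.reshape(m, 576).ravel()
        rows_list.append(r)
        cols_list.append(c)
        vals_list.append(v)

    iso = sel & ~model.annulus_mask
    for nu in np.unique(model.elem_nu[iso]):
        mask = iso & (model.elem_nu == nu)
        K_unit = element_stiffness_hex8(
            Material.isotropic(1.0, float(nu)), model.voxel_size, model.formulation
        )
        add_block(mask, model.elem_E[mask][:, None, None] * K_unit[None])

    ann = sel & model.annulus_mask
    if ann.any():
        D_all = _annulus_D_batch(model)
        D_sel = D_all[ann[model.annulus_mask]]
        add_block(ann, _batch_stiffness(D_sel, model.voxel_size, model.formulation))

    K = sp.coo_matrix(
        (np.concatenate(vals_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
        shape=(ndof, ndof),
    ).tocsr()
    return K


@dataclass
class SolveResult:
    """Displacements, plate reactions and solve diagnostics."""

    displacements: np.ndarray  # (n_nodes, 3) mm
    reaction: float  # axial force on the driven plate, N (compression positive)
    applied_displacement: float  # mm (compression positive)
    reaction_bottom: float
    equilibrium_residual: float
    plate_rotation: np.ndarray  # (3,) rad, zero when rotations are locked
    solver: str
    #: reduced-system solution, reusable as a warm start for a nearby model
    reduced: "np.ndarray | None" = None

    def scaled(self, factor: float) -> "SolveResult":
        return replace(
            self,
            displacements=self.displacements * factor,
            reaction=self.reaction * factor,
            applied_displacement=self.applied_displacement * factor,
            reaction_bottom=self.reaction_bottom * factor,
        )


@dataclass(frozen=True)
class StiffnessResult:
    """Segmental stiffness k = reaction / applied displacement (N/mm)."""

    k: float


def _check_connected(model: Model) -> None:
    n = model.n_nodes
    c0 = model.conn[:, 0]
    rows = np.repeat(c0, 7)
    cols = model.conn[:, 1:].ravel()
    g = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, comp = csgraph.connected_components(g, directed=False)
    if ncomp > 1:
        raise ValueError(
            f"mesh is disconnected: {ncomp} components; "
            f"{ncomp - 1} of them float free of the load path"
        )


def solve_system(
    model: Model,
    K: sp.csr_matrix,
    applied_displacement: float,
    solver: str = "auto",
    x0: "np.ndarray | None" = None,
    cg_rtol: float = 1e-10,
) -> SolveResult:
    """Apply plate constraints to an assembled stiffness and solve.

    ``applied_displacement`` is the axial compression of the top plate
    reference point (positive shortens the segment).  The reduced symmetric
    system is solved directly (sparse LU, symmetric-mode minimum-degree
    ordering) for small grids, otherwise by Jacobi-preconditioned
    conjugate gradients to a relative residual of 1e-8 or better; both
    paths are deterministic.
    """
    if applied_displacement == 0:
        raise ValueError("applied displacement must be non-zero")
    _check_connected(model)
    ndof = K.shape[0]
    nn = model.n_nodes

    fixed = (3 * model.bottom_nodes[:, None] + np.arange(3)).ravel()
    slave = (3 * model.top_nodes[:, None] + np.arange(3)).ravel()
    interior = np.setdiff1d(np.arange(ndof), np.concatenate([fixed, slave]))

    m = len(model.top_nodes)
    r = model.node_coords[model.top_nodes] - model.ref_point
    G_t = np.tile(np.eye(3), (m, 1))  # (3m, 3)
    G_r = np.zeros((3 * m, 3))  # u = theta x r
    G_r[0::3, 1] = r[:, 2]
    G_r[0::3, 2] = -r[:, 1]
    G_r[1::3, 0] = -r[:, 2]
    G_r[1::3, 2] = r[:, 0]
    G_r[2::3, 0] = r[:, 1]
    G_r[2::3, 1] = -r[:, 0]
    p = np.array([0.0, 0.0, -applied_displacement])

    K_II = K[interior][:, interior]
    K_IS = K[interior][:, slave]
    K_SS = K[slave][:, slave]

    us_p = G_t @ p
    if model.rotations_free:
        K_IS_Gr = K_IS @ G_r  # (nI, 3) dense
        A = sp.bmat(
            [[K_II, sp.csr_matrix(K_IS_Gr)], [sp.csr_matrix(K_IS_Gr.T), sp.csr_matrix(G_r.T @ (K_SS @ G_r))]],
            format="csr",
        )
        b = -np.concatenate([K_IS @ us_p, G_r.T @ (K_SS @ us_p)])
    else:
        A = K_II.tocsr()
        b = -(K_IS @ us_p)

    nun = A.shape[0]
    if solver == "auto":
        solver = "direct" if nun < 3_000 else "cg"
    if solver == "direct":
        lu = spla.splu(
            A.tocsc(), permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True)
        )
        x = lu.solve(b)
    elif solver == "cg":
        M = sp.diags(1.0 / A.diagonal())
        if x0 is not None and x0.shape != b.shape:
            x0 = None  # incompatible warm start (different mesh/partition)
        x, info = spla.cg(A, b, rtol=cg_rtol, atol=0.0, maxiter=50_000, M=M, x0=x0)
        if info != 0:
            raise RuntimeError(f"conjugate-gradient solver failed to converge (info={info})")
    else:
        raise ValueError(f"unknown solver {solver!r}")
    rres = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300)
    if rres > 1e-8:
        raise RuntimeError(f"solver residual {rres:.2e} exceeds 1e-8")

    u = np.zeros(ndof)
    u[interior] = x[: len(interior)]
    theta = x[len(interior):] if model.rotations_free else np.zeros(3)
    u[slave] = us_p + G_r @ theta

    f = K @ u
    F_top = float(f[slave][2::3].sum())
    F_bot = float(f[fixed][2::3].sum())
    scale = max(abs(F_top), 1e-300)
    eq = abs(F_top + F_bot) / scale

    return SolveResult(
        displacements=u.reshape(nn, 3),
        reaction=-F_top,
        applied_displacement=applied_displacement,
        reaction_bottom=F_bot,
        equilibrium_residual=eq,
        plate_rotation=theta,
        solver=solver,
        reduced=x,
    )


def assemble_and_solve(
    model: Model,
    applied_displacement: float,
    solver: str = "auto",
    x0: "np.ndarray | None" = None,
) -> SolveResult:
    """Assemble the model and run the displacement-controlled solve."""
    return solve_system(model, assemble(model), applied_displacement, solver, x0)


def element_stresses(model: Model, result: SolveResult) -> np.ndarray:
    """Centroid stress tensors (ne, 6) in Voigt order, MPa.

    Strain is evaluated with the element's strain-displacement operator
    averaged over the Gauss points (which, on a cube, is its centroid
    value), then mapped through the element constitutive matrix.
    """
    B, _ = _b_matrices(model.voxel_size, model.formulation)
    B_c = B.mean(axis=0)  # (6, 24)
    u = result.displacements.reshape(-1)
    edof = (3 * model.conn[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    strain = u[edof] @ B_c.T  # (ne, 6)

    stress = np.empty_like(strain)
    iso = ~model.annulus_mask
    for nu in np.unique(model.elem_nu[iso]):
        mask = iso & (model.elem_nu == nu)
        D_unit = constitutive_matrix(Material.isotropic(1.0, float(nu)))
        stress[mask] = (strain[mask] @ D_unit.T) * model.elem_E[mask][:, None]
    if model.annulus_mask.any():
        D_ann = _annulus_D_batch(model)
        stress[model.annulus_mask] = np.einsum(
            "eab,eb->ea", D_ann, strain[model.annulus_mask]
        )
    return stress


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Scalar von Mises equivalent of Voigt stress tensors (..., 6)."""
    s = np.asarray(stress, float)
    s11, s22, s33, s12, s23, s31 = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s23**2 + s31**2)
    )


def segment_stiffness(result: SolveResult) -> StiffnessResult:
    """Segmental stiffness from a displacement-controlled solve.

    For a linear model the load-displacement curve is a line through the
    origin, so the experimental average-gradient definition collapses to
    reaction over applied displacement.
    """
    if result.applied_displacement == 0:
        raise ValueError("applied displacement is zero; stiffness undefined")
    return StiffnessResult(k=result.reaction / result.applied_displacement)
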