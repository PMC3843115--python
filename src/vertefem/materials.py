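"""Linear-elastic materials: isotropic and orthotropic constitutive models.

Voigt ordering used throughout the package: (11, 22, 33, 12, 23, 31) with
engineering shear strains.  Orthotropic material axes follow the disc
convention 1 = radial, 2 = circumferential, 3 = axial; the axial direction
coincides with the grid's third axis, while radial/circumferential vary per
element around the body axis (see :func:`rotate_constitutive`).

Reference property sets for every model component live here: bone is
element-specific (Poisson 0.3) from the greyscale mapping; housing 2450 MPa,
injected cement 2040 MPa; nucleus pulposus 1 MPa / nu 0.499 healthy and
4.9 MPa / nu 0.43 degenerated; annulus fibrosus orthotropic with healthy
(E1, E2, E3) = (0.2, 35, 8) MPa and degenerated (0.53, 91.9, 21) MPa.  The
annulus shear moduli are not part of the reference data; Huber-type
estimates G_ij = sqrt(E_i E_j) / (2 (1 + sqrt(nu_ij nu_ji))) are supplied
as defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Material",
    "constitutive_matrix",
    "rotate_constitutive",
    "huber_shear_moduli",
    "BONE_POISSON",
    "bone_material",
    "cement_material",
    "housing_material",
    "healthy_nucleus",
    "degenerated_nucleus",
    "healthy_annulus",
    "degenerated_annulus",
]

#: Voigt index pairs for order (11, 22, 33, 12, 23, 31)
_VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0))

BONE_POISSON = 0.3


@dataclass(frozen=True)
class Material:
    """Isotropic (E, nu) or orthotropic 9-constant linear-elastic material.

    Orthotropic constants are given in material axes (1 radial,
    2 circumferential, 3 axial); positive definiteness of the resulting
    6x6 stiffness is enforced at construction.
    """

    kind: str
    E: float = 0.0
    nu: float = 0.0
    E1: float = 0.0
    E2: float = 0.0
    E3: float = 0.0
    nu12: float = 0.0
    nu13: float = 0.0
    nu23: float = 0.0
    G12: float = 0.0
    G13: float = 0.0
    G23: float = 0.0

    @classmethod
    def isotropic(cls, E: float, nu: float) -> "Material":
        return cls(kind="isotropic", E=E, nu=nu)

    @classmethod
    def orthotropic(
        cls,
        E1: float,
        E2: float,
        E3: float,
        nu12: float,
        nu13: float,
        nu23: float,
        G12: "float | None" = None,
        G13: "float | None" = None,
        G23: "float | None" = None,
    ) -> "Material":
        if G12 is None or G13 is None or G23 is None:
            g12, g13, g23 = huber_shear_moduli(E1, E2, E3, nu12, nu13, nu23)
            G12 = G12 if G12 is not None else g12
            G13 = G13 if G13 is not None else g13
            G23 = G23 if G23 is not None else g23
        return cls(
            kind="orthotropic",
            E1=E1, E2=E2, E3=E3,
            nu12=nu12, nu13=nu13, nu23=nu23,
            G12=G12, G13=G13, G23=G23,
        )

    def __post_init__(self) -> None:
        if self.kind == "isotropic":
            if self.E <= 0:
                raise ValueError("isotropic modulus must be positive")
            if not -1.0 < self.nu < 0.5:
                raise ValueError("isotropic Poisson ratio must lie in (-1, 0.5)")
        elif self.kind == "orthotropic":
            for name in ("E1", "E2", "E3", "G12", "G13", "G23"):
                if getattr(self, name) <= 0:
                    raise ValueError(f"orthotropic {name} must be positive")
            constitutive_matrix(self)  # raises if not positive definite
        else:
            raise ValueError(f"unknown material kind {self.kind!r}")

    def scaled(self, factor: float) -> "Material":
        """All stiffness constants (E's and G's) multiplied by ``factor``;
        Poisson ratios untouched, so anisotropy ratios are preserved
        exactly."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        if self.kind == "isotropic":
            return replace(self, E=self.E * factor)
        return replace(
            self,
            E1=self.E1 * factor, E2=self.E2 * factor, E3=self.E3 * factor,
            G12=self.G12 * factor, G13=self.G13 * factor, G23=self.G23 * factor,
        )


def huber_shear_moduli(
    E1: float, E2: float, E3: float, nu12: float, nu13: float, nu23: float
) -> tuple[float, float, float]:
    """Huber-type shear modulus estimates for an orthotropic solid,
    ``G_ij = sqrt(E_i E_j) / (2 (1 + sqrt(nu_ij nu_ji)))`` with the
    reciprocal ratios nu_ji = nu_ij E_j / E_i."""
    nu21 = nu12 * E2 / E1
    nu31 = nu13 * E3 / E1
    nu32 = nu23 * E3 / E2
    G12 = math.sqrt(E1 * E2) / (2.0 * (1.0 + math.sqrt(nu12 * nu21)))
    G13 = math.sqrt(E1 * E3) / (2.0 * (1.0 + math.sqrt(nu13 * nu31)))
    G23 = math.sqrt(E2 * E3) / (2.0 * (1.0 + math.sqrt(nu23 * nu32)))
    return G12, G13, G23


def constitutive_matrix(m: Material) -> np.ndarray:
    """6x6 stiffness matrix in Voigt order (11, 22, 33, 12, 23, 31).

    Isotropic materials use the Lame form; orthotropic materials invert the
    compliance assembled from the nine engineering constants.  The result is
    symmetric positive definite, otherwise a ``ValueError`` reports the
    offending eigenvalue.
    """
    if m.kind == "isotropic":
        lam = m.E * m.nu / ((1 + m.nu) * (1 - 2 * m.nu))
        mu = m.E / (2 * (1 + m.nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[3, 3] = D[4, 4] = D[5, 5] = mu
        return D

    S = np.zeros((6, 6))
    S[0, 0] = 1.0 / m.E1
    S[1, 1] = 1.0 / m.E2
    S[2, 2] = 1.0 / m.E3
    S[0, 1] = S[1, 0] = -m.nu12 / m.E1
    S[0, 2] = S[2, 0] = -m.nu13 / m.E1
    S[1, 2] = S[2, 1] = -m.nu23 / m.E2
    S[3, 3] = 1.0 / m.G12
    S[4, 4] = 1.0 / m.G23
    S[5, 5] = 1.0 / m.G13
    eig = np.linalg.eigvalsh(S[:3, :3])
    if eig[0] <= 0:
        raise ValueError(
            "orthotropic constants are not positive definite: smallest "
            f"compliance eigenvalue {eig[0]:.3e} <= 0"
        )
    D = np.linalg.inv(S)
    return 0.5 * (D + D.T)


def _voigt_to_tensor(D: np.ndarray) -> np.ndarray:
    C = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            C[i, j, k, l] = C[j, i, k, l] = C[i, j, l, k] = C[j, i, l, k] = D[a, b]
    return C


def _tensor_to_voigt(C: np.ndarray) -> np.ndarray:
    D = np.zeros((6, 6))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            D[a, b] = C[i, j, k, l]
    return D


def rotate_constitutive(D: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Express a stiffness matrix in a rotated frame.

    ``R`` maps material-axis components to grid-axis components (columns are
    the material axes in grid coordinates).  Implemented through the full
    fourth-order tensor transform, which is immune to Voigt bookkeeping
    errors and fast enough for per-element use.
    """
    C = _voigt_to_tensor(np.asarray(D, float))
    C = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, C, optimize=True)
    return _tensor_to_voigt(C)


def cylindrical_rotation(dx: float, dy: float) -> np.ndarray:
    """Rotation whose columns are (radial, circumferential, axial) unit
    vectors at an offset (dx, dy) from the body axis.  On the axis the
    radial direction defaults to +x."""
    r = math.hypot(dx, dy)
    if r < 1e-12:
        e_r = np.array([1.0, 0.0, 0.0])
    else:
        e_r = np.array([dx / r, dy / r, 0.0])
    e_c = np.array([-e_r[1], e_r[0], 0.0])
    e_a = np.array([0.0, 0.0, 1.0])
    return np.column_stack([e_r, e_c, e_a])


# -- reference property sets ----------------------------------------------

def bone_material(E: float) -> Material:
    return Material.isotropic(E, BONE_POISSON)


def cement_material(E: float = 2040.0) -> Material:
    return Material.isotropic(E, 0.3)


def housing_material() -> Material:
    return Material.isotropic(2450.0, 0.3)


def healthy_nucleus() -> Material:
    return Material.isotropic(1.0, 0.499)


def degenerated_nucleus() -> Material:
    return Material.isotropic(4.9, 0.43)


def healthy_annulus() -> Material:
    return Material.orthotropic(0.2, 35.0, 8.0, 0.02, 0.065, 1.2)


def degenerated_annulus() -> Material:
    return Material.orthotropic(0.53, 91.9, 21.0, 0.022, 0.072, 1.32)
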