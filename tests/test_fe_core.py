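"""FE engine oracles: closed forms, patch test, dense-solve equivalence."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from conftest import column_model
from vertefem.fe_core import (
    Model,
    assemble,
    assemble_and_solve,
    element_stiffness_hex8,
    element_stresses,
    segment_stiffness,
    solve_system,
    von_mises,
)
from vertefem.grids import LabelMap
from vertefem.imaging import ModulusField
from vertefem.fe_core import build_model
from vertefem.materials import Material, constitutive_matrix


class TestElementStiffness:
    def test_symmetry(self):
        K = element_stiffness_hex8(Material.isotropic(100.0, 0.3), 1.4)
        assert np.array_equal(K, K.T)

    def test_rigid_body_modes(self):
        K = element_stiffness_hex8(Material.isotropic(50.0, 0.25), 1.0)
        w = np.linalg.eigvalsh(K)
        assert np.all(w[:6] < 1e-9 * w[-1])  # exactly six zero-energy modes
        assert w[6] > 1e-6 * w[-1]

    def test_rigid_translation_gives_zero_force(self):
        K = element_stiffness_hex8(Material.isotropic(10.0, 0.3), 2.0)
        u = np.tile([1.0, -2.0, 0.5], 8)
        assert np.allclose(K @ u, 0.0, atol=1e-10)

    def test_uniform_compression_closed_form(self):
        # unit cube, E=100, nu=0: axial springs EA/L -> total axial force
        # E * delta, split over the face nodes
        E, d = 100.0, 0.01
        K = element_stiffness_hex8(Material.isotropic(E, 0.0), 1.0)
        u = np.zeros(24)
        u[np.arange(4, 8) * 3 + 2] = -d  # top nodes move down
        f = K @ u
        top_axial = f[np.arange(4, 8) * 3 + 2].sum()
        assert top_axial == pytest.approx(-E * d, rel=1e-12)

    def test_bbar_matches_full_for_constant_strain(self):
        # the mean-dilatation correction vanishes for uniform strain states
        E, d = 10.0, 0.05
        u = np.zeros(24)
        u[np.arange(4, 8) * 3 + 2] = -d
        for nu in (0.0, 0.3):
            Kf = element_stiffness_hex8(Material.isotropic(E, nu), 1.0, "full")
            Kb = element_stiffness_hex8(Material.isotropic(E, nu), 1.0, "bbar")
            assert np.allclose(Kf @ u, Kb @ u, atol=1e-12)


class TestColumnOracles:
    def test_single_element_ea_over_l(self):
        model = column_model([100.0])
        res = assemble_and_solve(model, 0.01)
        assert res.reaction == pytest.approx(1.0, rel=1e-10)
        assert segment_stiffness(res).k == pytest.approx(100.0, rel=1e-10)

    def test_series_springs(self):
        E = np.array([50.0, 200.0, 50.0, 200.0, 125.0, 80.0])
        model = column_model(E)
        res = assemble_and_solve(model, 0.1)
        k_exact = 1.0 / np.sum(1.0 / E)  # unit area, unit lengths
        assert segment_stiffness(res).k == pytest.approx(k_exact, rel=1e-8)

    def test_linearity_in_displacement(self):
        model = column_model([50.0, 150.0, 100.0])
        r1 = assemble_and_solve(model, 0.05)
        r2 = assemble_and_solve(model, 0.10)
        assert r2.reaction == pytest.approx(2 * r1.reaction, rel=1e-10)
        assert np.allclose(r2.displacements, 2 * r1.displacements, atol=1e-13)
        assert segment_stiffness(r1).k == pytest.approx(segment_stiffness(r2).k)

    def test_stiffness_scales_with_modulus(self):
        E = np.array([120.0, 30.0, 75.0])
        m1 = column_model(E)
        m2 = column_model(3.0 * E)
        k1 = segment_stiffness(assemble_and_solve(m1, 0.1)).k
        k2 = segment_stiffness(assemble_and_solve(m2, 0.1)).k
        assert k2 == pytest.approx(3.0 * k1, rel=1e-10)

    def test_equilibrium(self):
        model = column_model(np.linspace(50, 250, 8))
        res = assemble_and_solve(model, 0.2)
        assert res.equilibrium_residual <= 1e-6

    def test_zero_displacement_rejected(self):
        model = column_model([100.0])
        with pytest.raises(ValueError):
            assemble_and_solve(model, 0.0)


class TestStresses:
    def test_homogeneous_column_uniaxial(self):
        # nu=0 so the state is uniaxial: sigma_zz = -E*delta/L everywhere
        E, d, n = 100.0, 0.05, 5
        model = column_model(np.full(n, E))
        res = assemble_and_solve(model, d)
        s = element_stresses(model, res)
        expected = np.array([0, 0, -E * d / n, 0, 0, 0])
        assert np.allclose(s, expected[None, :], atol=1e-10)

    def test_rigid_translation_zero_stress(self):
        model = column_model([10.0, 20.0])
        res = assemble_and_solve(model, 0.1)
        shifted = res.scaled(1.0)
        shifted.displacements = shifted.displacements + np.array([1.0, -0.3, 2.0])
        s = element_stresses(model, shifted) - element_stresses(model, res)
        assert np.allclose(s, 0.0, atol=1e-9)

    def test_patch_linear_field_exact(self):
        """Imposing an arbitrary linear displacement field on a 2x2x2 block
        recovers the exact constant stress in every element (patch test)."""
        lab = LabelMap(np.ones((2, 2, 2), dtype=np.int64), 1.0)
        mod = ModulusField(np.full((2, 2, 2), 37.0), lab)
        model = build_model(lab, mod, bone_poisson=0.27)
        A = np.array([[1.0, 0.4, -0.2], [0.1, -0.5, 0.3], [0.2, 0.0, 0.8]]) * 1e-3
        u = model.node_coords @ A.T
        res_like = assemble_and_solve(model, 0.01)
        res_like.displacements = u
        stress = element_stresses(model, res_like)
        eps = 0.5 * (A + A.T)
        strain_voigt = np.array(
            [eps[0, 0], eps[1, 1], eps[2, 2], 2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[2, 0]]
        )
        D = constitutive_matrix(Material.isotropic(37.0, 0.27))
        expected = D @ strain_voigt
        assert np.allclose(stress, expected[None, :], atol=1e-10)


class TestVonMises:
    @pytest.mark.parametrize(
        "stress,expected",
        [
            ([100, 0, 0, 0, 0, 0], 100.0),
            ([50, 50, 50, 0, 0, 0], 0.0),
            ([0, 0, 0, 10, 0, 0], 10 * np.sqrt(3)),
        ],
    )
    def test_closed_forms(self, stress, expected):
        assert von_mises(np.array(stress, float)) == pytest.approx(expected, abs=1e-10)

    def test_frame_invariance(self):
        rng = np.random.default_rng(11)
        s = np.array([12.0, -5.0, 3.0, 4.0, -2.0, 7.0])
        T = np.array(
            [[s[0], s[3], s[5]], [s[3], s[1], s[4]], [s[5], s[4], s[2]]]
        )
        vm0 = von_mises(s)
        for R in special_ortho_group.rvs(3, size=5, random_state=rng):
            Tr = R @ T @ R.T
            sr = np.array(
                [Tr[0, 0], Tr[1, 1], Tr[2, 2], Tr[0, 1], Tr[1, 2], Tr[2, 0]]
            )
            assert von_mises(sr) == pytest.approx(vm0, rel=1e-12)


def _dense_oracle_solve(E_grid: np.ndarray, nu: float, h: float, delta: float):
    """Independent first-principles hex8 solve: explicit shape-function
    differentiation, 3x3x3 Gauss quadrature (exact for the same integrand),
    dense assembly and boundary-condition elimination by row deletion."""
    nx, ny, nz = E_grid.shape
    nodes = {}
    for i in range(nx + 1):
        for j in range(ny + 1):
            for k in range(nz + 1):
                nodes[(i, j, k)] = len(nodes)
    nn = len(nodes)
    K = np.zeros((3 * nn, 3 * nn))
    gp, gw = np.polynomial.legendre.leggauss(3)
    corners = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]

    def dN(xi, eta, zeta):
        out = np.zeros((8, 3))
        for a, (ci, cj, ck) in enumerate(corners):
            sx, sy, sz = 2 * ci - 1, 2 * cj - 1, 2 * ck - 1
            out[a] = (
                sx * (1 + sy * eta) * (1 + sz * zeta) / 8,
                (1 + sx * xi) * sy * (1 + sz * zeta) / 8,
                (1 + sx * xi) * (1 + sy * eta) * sz / 8,
            )
        return out * (2.0 / h)

    lam = lambda E: E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = lambda E: E / (2 * (1 + nu))

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                E = E_grid[i, j, k]
                D = np.zeros((6, 6))
                D[:3, :3] = lam(E)
                D[np.arange(3), np.arange(3)] += 2 * mu(E)
                D[3, 3] = D[4, 4] = D[5, 5] = mu(E)
                Ke = np.zeros((24, 24))
                for a, wa in zip(gp, gw):
                    for b, wb in zip(gp, gw):
                        for c, wc in zip(gp, gw):
                            g = dN(a, b, c)
                            B = np.zeros((6, 24))
                            for n in range(8):
                                bx, by, bz = g[n]
                                col = 3 * n
                                B[0, col] = bx
                                B[1, col + 1] = by
                                B[2, col + 2] = bz
                                B[3, col] = by
                                B[3, col + 1] = bx
                                B[4, col + 1] = bz
                                B[4, col + 2] = by
                                B[5, col] = bz
                                B[5, col + 2] = bx
                            Ke += wa * wb * wc * (h / 2) ** 3 * B.T @ D @ B
                ids = [nodes[(i + ci, j + cj, k + ck)] for ci, cj, ck in corners]
                dofs = np.array([3 * n + d for n in ids for d in range(3)])
                K[np.ix_(dofs, dofs)] += Ke

    u = np.zeros(3 * nn)
    fixed, presc = [], []
    for (i, j, k), n in nodes.items():
        if k == 0:
            fixed += [3 * n, 3 * n + 1, 3 * n + 2]
        elif k == nz:
            presc += [3 * n, 3 * n + 1, 3 * n + 2]
            u[3 * n + 2] = -delta
    known = np.array(fixed + presc)
    free = np.setdiff1d(np.arange(3 * nn), known)
    u[free] = np.linalg.solve(K[np.ix_(free, free)], -K[np.ix_(free, known)] @ u[known])
    f = K @ u
    reaction = -sum(f[3 * nodes[(i, j, k)] + 2] for (i, j, k) in nodes if k == nz)
    return u, reaction, nodes


def test_dense_oracle_equivalence():
    """Sparse MPC solve matches an independently assembled dense solve on a
    heterogeneous 3x3x3 grid (locked plate rotations = prescribed nodes)."""
    rng = np.random.default_rng(3)
    E_grid = rng.uniform(50.0, 400.0, (3, 3, 3))
    h, delta, nu = 1.4, 0.02, 0.3
    lab = LabelMap(np.ones((3, 3, 3), dtype=np.int64), h)
    mod = ModulusField(E_grid.copy(), lab)
    model = build_model(lab, mod, rotations_free=False)
    res = solve_system(model, assemble(model), delta, solver="direct")

    u_oracle, reaction_oracle, nodes = _dense_oracle_solve(E_grid, nu, h, delta)
    assert res.reaction == pytest.approx(reaction_oracle, rel=1e-9)
    # compare full displacement fields node by node
    for (i, j, k), n in nodes.items():
        idx = np.flatnonzero(
            (model.node_coords[:, 0] == i * h)
            & (model.node_coords[:, 1] == j * h)
            & (model.node_coords[:, 2] == k * h)
        )[0]
        assert np.allclose(res.displacements[idx], u_oracle[3 * n : 3 * n + 3], atol=1e-12)


def test_stiffness_monotone_in_element_modulus():
    """Raising any single element's modulus never lowers the segmental
    stiffness (energy argument), probed by random perturbations."""
    rng = np.random.default_rng(5)
    E = rng.uniform(50, 150, 8)
    base = column_model(E, voxel_size=1.0)
    k0 = segment_stiffness(assemble_and_solve(base, 0.1)).k
    for _ in range(5):
        idx = rng.integers(0, 8)
        E2 = E.copy()
        E2[idx] *= 1.0 + rng.uniform(0.1, 2.0)
        k1 = segment_stiffness(assemble_and_solve(column_model(E2), 0.1)).k
        assert k1 >= k0 - 1e-9


def test_disconnected_mesh_rejected():
    data = np.zeros((1, 1, 5), dtype=np.int64)
    data[0, 0, 0] = 1
    data[0, 0, 4] = 1  # two blocks with a gap: floating pieces
    lab = LabelMap(data, 1.0)
    E = np.zeros((1, 1, 5))
    E[0, 0, 0] = E[0, 0, 4] = 100.0
    mod = ModulusField(E, lab)
    model = build_model(lab, mod)
    with pytest.raises(ValueError, match="disconnected"):
        assemble_and_solve(model, 0.1)


def test_free_rotations_match_locked_on_symmetric_column():
    # symmetric 2x2 cross-section: the ball seat finds no moment to relax
    lab = LabelMap(np.ones((2, 2, 3), dtype=np.int64), 1.0)
    rng = np.random.default_rng(9)
    E = np.full((2, 2, 3), 100.0)
    mod = ModulusField(E, lab)
    m_free = build_model(lab, mod, rotations_free=True)
    m_lock = build_model(lab, mod, rotations_free=False)
    k_free = segment_stiffness(assemble_and_solve(m_free, 0.05)).k
    k_lock = segment_stiffness(assemble_and_solve(m_lock, 0.05)).k
    assert k_free == pytest.approx(k_lock, rel=1e-9)
    assert np.allclose(
        assemble_and_solve(m_free, 0.05).plate_rotation, 0.0, atol=1e-9
    )
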