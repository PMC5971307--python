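"""Checks of the low-level FE machinery: tangent consistency, frame
invariance, the cavity functional, and a single-element uniform-state test."""

import numpy as np
import pytest

from ivcsim.fem import CavityFunctional, FEModel
from ivcsim.materials import passive_stress


@pytest.fixture(scope="module")
def small_model(coarse_mesh, passive_scaled, active_params):
    return FEModel(coarse_mesh.nodes, coarse_mesh.hexes, coarse_mesh.fibres,
                   passive_scaled, active_params)


class TestTangent:
    def test_stiffness_matches_finite_difference_columns(self, small_model, rng):
        u = 0.02 * rng.standard_normal(small_model.ndof)
        small_model.set_activation(np.full(small_model.hexes.shape[0], -0.02),
                                   np.ones(small_model.hexes.shape[0], bool))
        K = small_model.stiffness(u, with_active=True)
        h = 1e-6
        for d in rng.choice(small_model.ndof, 5, replace=False):
            up, um = u.copy(), u.copy()
            up[d] += h
            um[d] -= h
            col_fd = (small_model.internal_force(up, True)
                      - small_model.internal_force(um, True)) / (2 * h)
            col = K[:, d].toarray().ravel()
            assert np.abs(col - col_fd).max() / max(np.abs(col_fd).max(), 1.0) < 1e-6
        small_model.set_activation(np.zeros(small_model.hexes.shape[0]),
                                   np.zeros(small_model.hexes.shape[0], bool))

    def test_zero_force_at_rest_and_under_translation(self, small_model):
        assert np.abs(small_model.internal_force(
            np.zeros(small_model.ndof), False)).max() < 1e-10
        u_rigid = np.tile([1.0, -2.0, 0.5], small_model.n_nodes)
        assert np.abs(small_model.internal_force(u_rigid, False)).max() < 1e-7

    def test_zero_force_under_finite_rotation(self, small_model):
        from scipy.spatial.transform import Rotation

        Q = Rotation.from_euler("xyz", [0.2, -0.1, 0.3]).as_matrix()
        X = small_model.X
        u = (X @ Q.T - X).ravel()
        f = small_model.internal_force(u, False)
        assert np.abs(f).max() < 1e-6 * max(1.0, np.abs(X).max())


class TestCavityFunctional:
    def test_gradient_matches_finite_differences(self, coarse_mesh, rng):
        cav = CavityFunctional(coarse_mesh.nodes, coarse_mesh.endo_faces)
        u = 0.1 * rng.standard_normal((coarse_mesh.n_nodes, 3))
        g = cav.gradient(u)
        h = 1e-5
        for d in rng.choice(coarse_mesh.n_nodes * 3, 6, replace=False):
            up, um = u.copy(), u.copy()
            up.ravel()[d] += h
            um.ravel()[d] -= h
            fd = (cav.volume(up) - cav.volume(um)) / (2 * h)
            assert g[d] == pytest.approx(fd, rel=1e-5, abs=1e-4)

    def test_hessian_matches_finite_differences(self, coarse_mesh, rng):
        cav = CavityFunctional(coarse_mesh.nodes, coarse_mesh.endo_faces)
        u = 0.05 * rng.standard_normal((coarse_mesh.n_nodes, 3))
        H = cav.hessian(u)
        h = 1e-4
        for d in rng.choice(coarse_mesh.n_nodes * 3, 3, replace=False):
            up, um = u.copy(), u.copy()
            up.ravel()[d] += h
            um.ravel()[d] -= h
            col_fd = (cav.gradient(up) - cav.gradient(um)) / (2 * h)
            col = H[:, d].toarray().ravel()
            assert np.abs(col - col_fd).max() < 1e-6 * max(1.0, np.abs(col_fd).max())


class TestSingleElementUniformState:
    """A unit cube under a homogeneous deformation reproduces the
    constitutive stress exactly (patch-style consistency)."""

    def _cube_model(self, passive, active, fibre=(1.0, 0.0, 0.0)):
        nodes = np.array([[x, y, z] for z in (0, 1) for y in (0, 1)
                          for x in (0, 1)], float)
        hexes = np.array([[0, 1, 3, 2, 4, 5, 7, 6]])
        return FEModel(nodes, hexes, np.array([fibre]), passive, active)

    def test_internal_force_consistent_with_uniform_piola_stress(
            self, passive_scaled, active_params):
        from ivcsim.materials import pk1_passive_deviatoric, pk1_volumetric

        model = self._cube_model(passive_scaled, active_params)
        F = np.array([[1.04, 0.02, 0.0], [0.0, 0.98, 0.01], [0.0, 0.0, 1.0]])
        u = (model.X @ (F - np.eye(3)).T).ravel()
        f = model.internal_force(u, with_active=False)
        a0 = np.array([1.0, 0.0, 0.0])
        P = pk1_passive_deviatoric(F, a0, passive_scaled) + \
            pk1_volumetric(F, passive_scaled)
        # nodal force of a uniform stress state: f_ai = sum_g w P_iJ dN_a/dX_J
        # (for homogeneous F the reduced volumetric quadrature is exact too)
        f_expect = np.einsum("iJ,gaJ,g->ai", P, model.dNdX[0], model.wdetJ[0])
        # f_expect rows follow element-local node order
        assert np.allclose(f.reshape(-1, 3)[model.hexes[0]], f_expect, atol=1e-10)

    def test_equilibrium_stress_matches_constitutive_oracle(
            self, passive_scaled, active_params):
        """Stretch the cube along x with lateral faces free: the converged
        state carries the uniaxial stress predicted by the material law."""
        import scipy.sparse.linalg as spla

        model = self._cube_model(passive_scaled, active_params,
                                 fibre=(0.0, 1.0, 0.0))
        lam = 1.05
        fixed = np.zeros((8, 3), bool)
        fixed[:, 0] = True                      # prescribe x-motion
        fixed[model.X[:, 1] == 0, 1] = True     # symmetry planes
        fixed[model.X[:, 2] == 0, 2] = True
        u = np.zeros((8, 3))
        u[:, 0] = (lam - 1.0) * model.X[:, 0]
        free = np.flatnonzero(~fixed.ravel())
        for _ in range(30):
            R = model.internal_force(u.ravel(), False)[free]
            if np.abs(R).max() < 1e-12:
                break
            K = model.stiffness(u.ravel(), False)[free][:, free]
            du = spla.spsolve(K.tocsc(), -R)
            u.ravel()[free] += du
        F = np.eye(3) + np.array([[u[7, 0] - u[0, 0], 0, 0],
                                  [0, u[7, 1] - u[0, 1], 0],
                                  [0, 0, u[7, 2] - u[0, 2]]]) / 1.0
        sig = passive_stress(F, np.array([0.0, 1.0, 0.0]), passive_scaled)
        assert abs(sig[1, 1]) < 1e-8      # lateral directions traction-free
        assert abs(sig[2, 2]) < 1e-8
        assert sig[0, 0] > 0.0
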