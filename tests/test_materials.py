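import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivcsim import (ActiveParams, PassiveParams, active_fibre_stress,
                    apply_rate_factor, passive_energy, passive_stress)
from ivcsim.materials import (pk1_passive_deviatoric, pk1_volumetric,
                              strain_energy_density)


class TestPassiveEnergy:
    def test_zero_at_reference(self, passive_params):
        assert passive_energy(3.0, 1.0, passive_params) == 0.0

    def test_hand_evaluated_isotropic_point(self, passive_params):
        # a1*0.01 + a2*1e-4 + a3*1e-6 with the published constants
        assert passive_energy(3.01, 1.0, passive_params) == pytest.approx(
            0.004862, abs=2e-6)

    def test_hand_evaluated_fibre_point(self, passive_params):
        # b1*0.01 + b2*1e-4 with the published constants
        assert passive_energy(3.0, 1.1, passive_params) == pytest.approx(
            0.007129, abs=2e-6)

    def test_fibre_term_even_in_I4(self, passive_params):
        for x in (0.01, 0.05, 0.2):
            assert passive_energy(3.0, 1.0 + x, passive_params) == pytest.approx(
                passive_energy(3.0, 1.0 - x, passive_params), rel=1e-12)

    def test_nonfinite_raises(self, passive_params):
        with pytest.raises(ValueError):
            passive_energy(np.nan, 1.0, passive_params)


class TestRateFactor:
    def test_scales_all_stiffness_constants(self):
        p = apply_rate_factor(PassiveParams())
        assert p.a1 == pytest.approx(0.347 * 6)      # 2.082
        assert p.b2 == pytest.approx(27.692 * 6)     # 166.152
        assert p.kappa == PassiveParams().kappa
        assert p.rate_factor == 1.0

    def test_identity_factor(self):
        p0 = PassiveParams(rate_factor=1.0)
        assert apply_rate_factor(p0) == p0


class TestActiveLaw:
    def test_relaxed_and_compressed_fibres_carry_no_stress(self, active_params):
        assert active_fibre_stress(0.0, active_params) == 0.0
        assert active_fibre_stress(-0.05, active_params) == 0.0

    def test_hand_evaluated_tension(self, active_params):
        expect = 200.0 * np.exp(0.1) * (np.exp(0.1) - 1.0)
        assert active_fibre_stress(0.1, active_params) == pytest.approx(expect)
        assert expect == pytest.approx(23.25, abs=0.01)

    def test_small_strain_slope_is_E0(self, active_params):
        eps = 1e-7
        assert active_fibre_stress(eps, active_params) / eps == pytest.approx(
            active_params.E0, rel=1e-5)

    @given(st.floats(min_value=1e-4, max_value=0.3),
           st.floats(min_value=1e-4, max_value=0.3))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_convex_in_tension(self, e1, e2):
        act = ActiveParams()
        lo, hi = sorted((e1, e2))
        s_lo, s_hi = active_fibre_stress(lo, act), active_fibre_stress(hi, act)
        assert s_hi >= s_lo
        mid = 0.5 * (lo + hi)
        assert active_fibre_stress(mid, act) <= 0.5 * (s_lo + s_hi) + 1e-12


def _random_states(rng, n, jmin=0.95, jmax=1.05):
    """Random deformation gradients with J in [jmin, jmax] and random fibres."""
    for _ in range(n):
        F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
        J = np.linalg.det(F)
        if J <= 0.2:
            continue
        F = F * (rng.uniform(jmin, jmax) / J) ** (1.0 / 3.0)
        a0 = rng.standard_normal(3)
        a0 /= np.linalg.norm(a0)
        yield F, a0


class TestStressEnergyConsistency:
    def test_stress_matches_energy_differentiation(self, passive_params, rng):
        """Cauchy stress equals the push-forward of the numerically
        differentiated strain energy for >= 100 random states."""
        h = 1e-6
        checked = 0
        for F, a0 in _random_states(rng, 140):
            sig = passive_stress(F, a0, passive_params)
            P_fd = np.zeros((3, 3))
            for i in range(3):
                for J in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, J] += h
                    Fm[i, J] -= h
                    P_fd[i, J] = (strain_energy_density(Fp, a0, passive_params)
                                  - strain_energy_density(Fm, a0, passive_params)) / (2 * h)
            sig_fd = P_fd @ F.T / np.linalg.det(F)
            scale = max(np.abs(sig_fd).max(), 1e-6)
            assert np.abs(sig - sig_fd).max() / scale < 1e-5
            checked += 1
        assert checked >= 100

    def test_zero_energy_and_stress_at_identity(self, passive_params):
        a0 = np.array([1.0, 0.0, 0.0])
        assert strain_energy_density(np.eye(3), a0, passive_params) == 0.0
        assert np.allclose(passive_stress(np.eye(3), a0, passive_params), 0.0)

    def test_objectivity_under_rotation(self, passive_params, rng):
        from scipy.spatial.transform import Rotation

        for F, a0 in _random_states(rng, 20):
            W = strain_energy_density(F, a0, passive_params)
            for Q in Rotation.random(3, rng=7).as_matrix():
                assert strain_energy_density(Q @ F, a0, passive_params) == \
                    pytest.approx(W, rel=1e-10)

    def test_pure_rotation_gives_zero_stress(self, passive_params):
        from scipy.spatial.transform import Rotation

        a0 = np.array([0.0, 1.0, 0.0])
        Q = Rotation.from_euler("xyz", [0.3, -0.4, 0.9]).as_matrix()
        assert np.abs(passive_stress(Q, a0, passive_params)).max() < 1e-9

    def test_symmetry_of_stress(self, passive_params, rng):
        for F, a0 in _random_states(rng, 10):
            sig = passive_stress(F, a0, passive_params)
            assert np.allclose(sig, sig.T, atol=1e-10 * max(1.0, np.abs(sig).max()))

    def test_nonpositive_jacobian_raises(self, passive_params):
        F = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            passive_stress(F, np.array([1.0, 0, 0]), passive_params)


def test_deviatoric_plus_volumetric_matches_total_energy_gradient(passive_params, rng):
    """The split kernels used by the solver sum to dW/dF."""
    h = 1e-7
    for F, a0 in _random_states(rng, 5, 0.98, 1.02):
        P = pk1_passive_deviatoric(F, a0, passive_params) + \
            pk1_volumetric(F, passive_params)
        for i in range(3):
            for J in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, J] += h
                Fm[i, J] -= h
                fd = (strain_energy_density(Fp, a0, passive_params)
                      - strain_energy_density(Fm, a0, passive_params)) / (2 * h)
                assert P[i, J] == pytest.approx(fd, rel=2e-5, abs=1e-6)
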