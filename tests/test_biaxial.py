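import numpy as np
import pytest
from dataclasses import replace

from ivcsim import (BiaxialProtocol, PassiveParams, biaxial_stress_closed_form,
                    fit_passive_params, generate_biaxial_dataset, passive_energy)


class TestClosedForm:
    def test_zero_at_unit_stretches(self, passive_params):
        sf, sc = biaxial_stress_closed_form(1.0, 1.0, passive_params)
        assert sf == 0.0 and sc == 0.0

    def test_matches_energy_differentiation(self, passive_params):
        """Membrane stresses equal lambda dW/dlambda under incompressible
        biaxial kinematics (sigma_i = lambda_i dW/dlambda_i, no sum)."""
        h = 1e-7
        rng = np.random.default_rng(3)
        for _ in range(25):
            lf, lc = rng.uniform(1.0, 1.15, 2)

            def W(lamf, lamc):
                lt2 = 1.0 / (lamf * lamc) ** 2
                return passive_energy(lamf**2 + lamc**2 + lt2, lamf**2,
                                      passive_params)

            sf, sc = biaxial_stress_closed_form(lf, lc, passive_params)
            sf_fd = lf * (W(lf + h, lc) - W(lf - h, lc)) / (2 * h)
            sc_fd = lc * (W(lf, lc + h) - W(lf, lc - h)) / (2 * h)
            assert sf == pytest.approx(sf_fd, rel=1e-5, abs=1e-8)
            assert sc == pytest.approx(sc_fd, rel=1e-5, abs=1e-8)

    def test_fibre_term_hand_expansion(self, passive_params):
        """Fibre contribution at lambda_f=1.1 equals 2 lf^2 W4 at I4=1.21."""
        p0 = replace(passive_params, b1=0.0, b2=0.0)
        sf_full, _ = biaxial_stress_closed_form(1.1, 1.0, passive_params)
        sf_iso, _ = biaxial_stress_closed_form(1.1, 1.0, p0)
        I4 = 1.21
        W4 = 2 * passive_params.b1 * (I4 - 1) + 4 * passive_params.b2 * (I4 - 1) ** 3
        assert sf_full - sf_iso == pytest.approx(2 * 1.21 * W4 / 2 * 2, rel=1e-12)

    def test_nonpositive_stretch_raises(self, passive_params):
        with pytest.raises(ValueError):
            biaxial_stress_closed_form(-1.0, 1.0, passive_params)


class TestDatasetGeneration:
    def test_noiseless_data_lies_on_surface(self, passive_params):
        proto = BiaxialProtocol(noise_sd=0.0)
        d = generate_biaxial_dataset(proto, passive_params)
        sf, sc = biaxial_stress_closed_form(d.lam_fibre, d.lam_cross, passive_params)
        assert np.allclose(d.sigma_fibre, sf)
        assert np.allclose(d.sigma_cross, sc)

    def test_fixed_seed_is_bit_identical(self, passive_params):
        a = generate_biaxial_dataset(BiaxialProtocol(seed=42), passive_params)
        b = generate_biaxial_dataset(BiaxialProtocol(seed=42), passive_params)
        assert np.array_equal(a.sigma_fibre, b.sigma_fibre)
        assert np.array_equal(a.sigma_cross, b.sigma_cross)


class TestParameterRecovery:
    def test_noiseless_recovery_within_1_percent(self, passive_params):
        data = generate_biaxial_dataset(BiaxialProtocol(noise_sd=0.0),
                                        passive_params)
        init = replace(passive_params, a1=2 * passive_params.a1,
                       a2=2 * passive_params.a2, a3=2 * passive_params.a3,
                       b1=2 * passive_params.b1, b2=2 * passive_params.b2)
        fit = fit_passive_params(data, init)
        assert max(fit.recovery_error.values()) < 0.01

    def test_residual_invariant_to_record_order(self, passive_params):
        data = generate_biaxial_dataset(BiaxialProtocol(seed=5), passive_params)
        perm = np.random.default_rng(0).permutation(data.lam_fibre.size)
        shuffled = replace(data, lam_fibre=data.lam_fibre[perm],
                           lam_cross=data.lam_cross[perm],
                           sigma_fibre=data.sigma_fibre[perm],
                           sigma_cross=data.sigma_cross[perm])
        f1 = fit_passive_params(data)
        f2 = fit_passive_params(shuffled)
        assert f1.residual == pytest.approx(f2.residual, rel=1e-8)

    def test_unstretched_fibre_flags_nonidentifiability(self, passive_params):
        proto = BiaxialProtocol(ratios=((0.0, 1.0),), noise_sd=0.0,
                                samples_per_path=20)
        data = generate_biaxial_dataset(proto, passive_params)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_passive_params(data)

    def test_standard_error_scales_inverse_sqrt_n(self, passive_params):
        """Doubling samples shrinks the a1 estimate spread ~ 1/sqrt(2)."""
        spreads = []
        for n in (10, 40):   # 4x samples -> ~2x smaller spread
            ests = []
            for seed in range(40):
                proto = BiaxialProtocol(samples_per_path=n, noise_sd=0.3,
                                        seed=seed)
                data = generate_biaxial_dataset(proto, passive_params)
                ests.append(fit_passive_params(data).params.a1)
            spreads.append(np.std(ests))
        ratio = spreads[0] / spreads[1]
        assert 1.4 < ratio < 2.9
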