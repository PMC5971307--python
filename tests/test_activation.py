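import numpy as np
import pytest

from ivcsim import (ScenarioSpec, build_schedule, contraction_strain,
                    electrical_activation_time, emd_at_depth, msv_rate)


def spec(name="control", scale=2e-3, **kw):
    return ScenarioSpec(name=name, msv_scale=scale, **kw)


class TestElectricalActivation:
    def test_endocardial_surface_depolarises_at_zero(self):
        assert electrical_activation_time(0.0, spec()) == 0.0

    def test_full_wall_conduction_time(self):
        assert electrical_activation_time(9.0, spec()) == pytest.approx(9.0 / 0.47)

    def test_intramural_inner_half_depolarises_at_zero(self):
        t = electrical_activation_time(np.array([3.6]), spec("intramural"),
                                       depth_fraction=np.array([0.4]),
                                       wall_thickness_mm=np.array([9.0]))
        assert t[0] == 0.0

    def test_intramural_outer_half_conducted_from_midwall(self):
        t = electrical_activation_time(np.array([6.75]), spec("intramural"),
                                       depth_fraction=np.array([0.75]),
                                       wall_thickness_mm=np.array([9.0]))
        assert t[0] == pytest.approx((6.75 - 4.5) / 0.47)


class TestEMD:
    def test_endocardial_and_epicardial_anchors(self):
        s = spec()
        assert emd_at_depth(0.0, 9.0, s) == 47.0
        assert emd_at_depth(9.0, 9.0, s) == pytest.approx(28.0)

    def test_gradient_is_2_1_ms_per_mm(self):
        s = spec()
        assert round(s.emd_gradient, 1) == 2.1

    def test_const_emd_uniform(self):
        s = spec("const_emd")
        assert np.all(emd_at_depth(np.linspace(0, 9, 5), 9.0, s) == 47.0)


class TestMSV:
    def test_endocardial_reference_and_epicardial_doubling(self):
        s = spec()
        assert msv_rate(0.0, s) == pytest.approx(2e-3)
        assert msv_rate(1.0, s) == pytest.approx(4e-3)
        assert msv_rate(0.5, s) == pytest.approx(3e-3)

    def test_const_msv_uniform(self):
        s = spec("const_msv")
        assert np.all(msv_rate(np.linspace(0, 1, 7), s) == 2e-3)

    def test_unset_scale_raises(self):
        with pytest.raises(ValueError):
            msv_rate(0.5, ScenarioSpec())


class TestContractionStrain:
    def test_zero_before_and_at_onset(self):
        assert contraction_strain(46.9, 47.0, 2e-3) == 0.0
        assert contraction_strain(47.0, 47.0, 2e-3) == 0.0

    def test_log_of_linear_length_shortening(self):
        # 2% length shortening after 10 ms at rate 0.002/ms
        assert contraction_strain(57.0, 47.0, 2e-3) == pytest.approx(np.log(0.98))
        # first-order equivalence with the small-strain ramp
        assert contraction_strain(47.1, 47.0, 2e-3) == pytest.approx(-2e-4, rel=1e-3)

    def test_safety_cap(self):
        assert contraction_strain(1e5, 0.0, 2e-3) == pytest.approx(-0.25)

    def test_nonpositive_rate_raises(self):
        with pytest.raises(ValueError):
            contraction_strain(50.0, 47.0, 0.0)


class TestSchedules:
    def test_control_onsets_nearly_simultaneous(self, coarse_mesh):
        sch = build_schedule(coarse_mesh, spec())
        assert sch.onset.max() - sch.onset.min() <= 1.0
        assert np.allclose(sch.onset, sch.electrical_time + sch.emd)

    def test_const_emd_spread_equals_conduction_spread(self, coarse_mesh):
        sch = build_schedule(coarse_mesh, spec("const_emd"))
        depth_span = coarse_mesh.depth_mm.max() - coarse_mesh.depth_mm.min()
        assert sch.onset.max() - sch.onset.min() == pytest.approx(
            depth_span / 0.47, abs=0.1)

    def test_control_rates_increase_with_depth(self, coarse_mesh):
        sch = build_schedule(coarse_mesh, spec())
        order = np.argsort(coarse_mesh.depth_fraction)
        assert np.all(np.diff(sch.rate[order]) >= 0)
        assert np.any(np.diff(sch.rate[order]) > 0)

    def test_const_both_uniform_rate_and_emd(self, coarse_mesh):
        sch = build_schedule(coarse_mesh, spec("const_both"))
        assert np.all(sch.rate == sch.rate[0])
        assert np.all(sch.emd == 47.0)

    def test_intramural_inner_half_simultaneous(self, coarse_mesh):
        sch = build_schedule(coarse_mesh, spec("intramural"))
        inner = coarse_mesh.depth_fraction <= 0.5
        assert np.all(sch.electrical_time[inner] == 0.0)
        assert np.all(sch.electrical_time[~inner] > 0.0)


def test_invalid_scenario_name_raises():
    with pytest.raises(ValueError):
        ScenarioSpec(name="bogus")
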