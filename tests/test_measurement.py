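import numpy as np
import pytest

from actomyosim.builders import SystemSpec, build_network, \
    build_two_filament_system
from actomyosim.measurement import (Measurement, acp_arm_tensions,
                                    cross_section_forces, efficiency,
                                    motor_axial_forces, motor_max_force,
                                    section_totals, steady_state_window,
                                    total_force)
from actomyosim.model import build_filament, build_motor
from actomyosim.state import Domain, SystemAssembler

from conftest import make_two_filament_state


class TestCrossSections:
    def test_plane_layout(self, params):
        st = build_two_filament_system(
            SystemSpec(kind="two_filament", seed=0), params)
        recs = cross_section_forces(st, "z", 200.0)
        assert len(recs) == 100                # 20 µm / 200 nm
        assert recs[0].coordinate == pytest.approx(100.0)

    def test_spacing_must_be_positive(self, small_state):
        with pytest.raises(ValueError):
            cross_section_forces(small_state, "z", 0.0)

    def test_stretched_segment_counts_as_tension(self, params):
        dom = Domain.from_um((5, 5, 4), (1, 1, 0))
        asm = SystemAssembler(params, dom)
        asm.add_filament(build_filament(140, origin=(2500, 2500, 2000),
                                        direction=(0, 0, 1), params=params))
        st = asm.build()
        st.pos[1, 2] += 10.0                    # stretch by 10 nm
        coords, sums = section_totals(st, "z", 200.0)
        crossing = (coords > 2000) & (coords < 2150)
        expected = params.kappa_s_A * 1e3 * 10.0
        assert np.allclose(sums[crossing, 0], expected)
        assert np.all(sums[~crossing] == 0)
        # compression counts negative
        st.pos[1, 2] -= 20.0
        _, sums = section_totals(st, "z", 200.0)
        assert sums[:, 0].min() == pytest.approx(-expected)

    def test_category_decomposition_and_total(self, params):
        st = make_two_filament_state(params, n_acp=3, seed=1)
        st.arm_bound[0] = 1
        st.arm_seg[0], st.arm_site[0] = 7, 5
        st.occupancy[7, 5] = 2
        rng = np.random.default_rng(0)
        st.pos += rng.normal(0, 2.0, st.pos.shape)
        for rec in cross_section_forces(st, "z", 200.0):
            assert rec.total == pytest.approx(
                rec.actin + rec.acp + rec.motor_arm + rec.motor_backbone)

    def test_fresh_system_reads_zero(self, params):
        st = build_two_filament_system(
            SystemSpec(kind="two_filament", N_ACP=0, seed=0), params)
        _, sums = section_totals(st, "z", 200.0)
        assert np.abs(sums).max() < 1e-6

    def test_network_protocol_uses_40_planes(self, params):
        spec = SystemSpec(kind="network", N_M=2, N_ACP=0, seed=1,
                          network_target_segments=200,
                          network_mean_length_nm=1400.0,
                          domain_um=(6.0, 6.0, 0.1))
        st = build_network(spec, params)
        meas = Measurement(st, mode="network")
        meas.sample()
        assert len(meas.frame_planes[0]) == 40   # 20 per axis

    def test_periodic_wrap_aware_crossing(self, params):
        """A segment through the periodic z boundary crosses the edge planes."""
        dom = Domain.from_um((5, 5, 4), (1, 1, 1))
        asm = SystemAssembler(params, dom)
        asm.add_filament(build_filament(140, origin=(2500, 2500, 3950),
                                        direction=(0, 0, 1), params=params))
        st = asm.build()
        st.pos[1, 2] = (3950 + 150) % 4000      # stretched through the seam
        _, sums = section_totals(st, "z", 100.0)
        assert sums[:, 0].max() > 0


class TestMotorMaxForce:
    def _synthetic(self, params, pull=10.0):
        """One motor; its lower arm bound straight below its anchor.

        The anchor sits exactly over site 10 of segment 0 at a vertical
        distance ``r0_M2 + pull``, so the arm force is a pure transverse
        stretch of ``kappa_s_M2 * pull`` along z (zero axial offset).
        """
        dom = Domain.from_um((5, 5, 4), (1, 1, 0))
        asm = SystemAssembler(params, dom)
        asm.add_filament(build_filament(280, origin=(2300, 2500, 2000),
                                        direction=(1, 0, 0), params=params))
        # 42-nm backbone along z; its lower vertex is the arm-0 anchor
        asm.add_motor(build_motor(4, 42, 42,
                                  center=(2370, 2500, 2021 + 13.5 + pull),
                                  direction=(0, 0, 1), params=params))
        st = asm.build()
        st.arm_bound[0] = 1
        st.arm_seg[0], st.arm_site[0] = 0, 10      # x = 2370 exactly
        st.occupancy[0, 10] = 2
        return st, pull

    def test_single_arm_known_geometry(self, params):
        st, pull = self._synthetic(params)
        # transverse spring stretched by `pull` along z; no axial offset
        expected = params.kappa_s_M2 * 1e3 * pull
        fm = motor_axial_forces(st, "z")
        assert fm[0] == pytest.approx(expected, rel=1e-3)
        assert motor_max_force(st, "bundle") == pytest.approx(expected / 2,
                                                              rel=1e-3)

    def test_network_mode_quarter_sum(self, params):
        st, pull = self._synthetic(params)
        fx = motor_axial_forces(st, "x").sum()
        fy = motor_axial_forces(st, "y").sum()
        assert motor_max_force(st, "network") == pytest.approx(
            0.25 * (fx + fy))

    def test_no_motors_rejected(self, params):
        st = make_two_filament_state(params, with_motor=False, n_acp=0)
        with pytest.raises(ValueError):
            motor_max_force(st, "bundle")

    def test_additive_over_motors(self, params):
        st = make_two_filament_state(params, n_acp=0)
        st.arm_bound[0] = 1
        st.arm_seg[0], st.arm_site[0] = 3, 10
        st.occupancy[3, 10] = 2
        single = motor_max_force(st, "bundle")
        assert single > 0
        fm = motor_axial_forces(st, "z")
        assert motor_max_force(st, "bundle") == pytest.approx(fm.sum() / 2)


class TestEfficiency:
    def test_ratio(self):
        assert efficiency(273.6, 547.2) == pytest.approx(0.5)
        assert efficiency(547.2, 547.2) == pytest.approx(1.0)

    def test_undefined_without_motor_force(self):
        with pytest.raises(ValueError):
            efficiency(1.0, 0.0)


class TestSteadyWindow:
    def test_constant_series_is_entirely_steady(self):
        s = np.full(120, 5.0)
        i0, i1, found = steady_state_window(s)
        assert (i0, i1, found) == (0, 120, True)

    def test_plateau_onset_detected(self):
        s = np.concatenate([np.linspace(0, 1, 20), np.ones(100)])
        onset = int(np.argmax(s >= 1.0))       # first frame at plateau level
        i0, i1, found = steady_state_window(s)
        assert found and i1 == len(s)
        assert abs(i0 - onset) <= 2

    def test_noise_around_mean_qualifies(self):
        rng = np.random.default_rng(3)
        s = 10.0 + rng.normal(0, 0.1, 150)
        i0, _, found = steady_state_window(s)
        assert found and i0 < 50

    def test_monotone_ramp_falls_back_with_warning(self):
        s = np.linspace(0, 1, 100)
        with pytest.warns(UserWarning, match="steady"):
            i0, i1, found = steady_state_window(s)
        assert not found and i1 - i0 == 20

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            steady_state_window(np.ones(30))


class TestTotalForce:
    def test_uniform_planes(self):
        frames = np.full((12, 10), 7.0)
        assert total_force(frames) == pytest.approx(7.0)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            total_force(np.ones((5, 10)))


def test_acp_tension_readout(params):
    st = make_two_filament_state(params, n_acp=4, seed=5)
    t0 = acp_arm_tensions(st)
    assert t0.shape == (4,)
    # stretch the whole box in z: every linker arm goes taut
    st.pos[:, 2] *= 1.02
    assert np.all(acp_arm_tensions(st) >= t0 - 1e-9)
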