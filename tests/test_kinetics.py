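import numpy as np
import pytest
from scipy import stats

from actomyosim import ParameterSet
from actomyosim.kinetics import (MotorKinetics, arm_unbind, arm_walk,
                                 attempt_arm_binding, candidate_sites,
                                 init_crosslinks)
from actomyosim.model import build_filament, build_motor
from actomyosim.state import Domain, SystemAssembler

from conftest import make_two_filament_state


class TestRateLaws:
    def test_unloaded_walking_velocity(self, params):
        kin = MotorKinetics.from_params(params)
        assert kin.walk_rate(0.0) * kin.step_size == pytest.approx(140.0)

    def test_stall(self, params):
        kin = MotorKinetics.from_params(params)
        assert kin.walk_rate(45.6) == 0.0
        assert kin.walk_rate(100.0) == 0.0
        assert kin.walk_rate(45.6 / 2) * kin.step_size == pytest.approx(70.0)

    def test_rates_non_increasing_in_load(self, params):
        kin = MotorKinetics.from_params(params)
        loads = np.linspace(0, 2 * kin.F_stall_arm, 200)
        kw = [kin.walk_rate(F) for F in loads]
        ku = [kin.unbind_rate(F) for F in loads]
        assert np.all(np.diff(kw) <= 0)
        assert np.all(np.diff(ku) <= 0)

    def test_unbind_rate_never_zero(self, params):
        kin = MotorKinetics.from_params(params)
        assert kin.unbind_rate(0.0) == pytest.approx(params.k_u0)
        assert kin.unbind_rate(1e4) > 0


class TestBinding:
    def test_per_tick_probability(self, params):
        # 8 heads at 40/s each: rate 320/s, p = 1 - exp(-320*dt) ~ 3.67e-3
        p = -np.expm1(-params.k_bind_per_head * params.N_h * params.dt)
        assert p == pytest.approx(3.67e-3, rel=2e-3)

    def test_binding_rate_statistics(self, params):
        st = make_two_filament_state(params, n_acp=0)
        rng = np.random.default_rng(7)
        n_try, hits = 120_000, 0
        for _ in range(n_try):
            if attempt_arm_binding(st, 0, params.dt, rng):
                s, k = st.arm_seg[0], st.arm_site[0]
                st.occupancy[s, k] = 0
                st.arm_bound[0] = 0
                st.arm_seg[0] = st.arm_site[0] = -1
                hits += 1
        p = -np.expm1(-320 * params.dt)
        assert hits / n_try == pytest.approx(p, rel=0.15)

    def test_misaligned_arm_never_binds(self, params):
        """An arm whose walking direction opposes the barbed-end direction
        of every reachable filament has no candidates."""
        dom = Domain.from_um((5, 5, 4), (1, 1, 0))
        asm = SystemAssembler(params, dom)
        # barbed end at the BOTTOM: barbed direction is -z everywhere
        asm.add_filament(build_filament(2000, origin=(2500 - 13.5, 2500, 1000),
                                        direction=(0, 0, 1), params=params))
        asm.add_motor(build_motor(4, 42, 42, center=(2500, 2500, 2000),
                                  direction=(0, 0, 1), params=params))
        st = asm.build()
        right_arms = [a for a in range(st.n_arms)
                      if (st.pos[st.arm_anchor[a]] -
                          st.pos[st.arm_ref[a]])[2] > 0]
        for a in right_arms:        # walk +z: opposed to barbed direction
            assert candidate_sites(st, a) == []
        left_arms = [a for a in range(st.n_arms) if a not in right_arms]
        assert any(candidate_sites(st, a) for a in left_arms)

    def test_sibling_arms_exclude_same_filament(self, params):
        st = make_two_filament_state(params, n_acp=0)
        # bind arm 0 somewhere on filament 0
        cands = candidate_sites(st, 0)
        on_fil0 = [c for c in cands if st.seg_fil[c[0]] == 0]
        s, k, _ = on_fil0[0]
        st.arm_bound[0] = 1
        st.arm_seg[0], st.arm_site[0] = s, k
        st.occupancy[s, k] = 2
        sib = int(st.arm_sibling[0])
        assert all(st.seg_fil[c[0]] != 0 for c in candidate_sites(st, sib))

    def test_occupied_sites_excluded(self, params):
        st = make_two_filament_state(params, n_acp=0)
        cands = candidate_sites(st, 0)
        s, k, _ = cands[0]
        st.occupancy[s, k] = 1
        assert (s, k) not in [(c[0], c[1]) for c in candidate_sites(st, 0)]


class TestWalking:
    def _bound_state(self, params):
        st = make_two_filament_state(params, n_acp=0)
        s, k, _ = min(candidate_sites(st, 0), key=lambda c: c[2])
        st.arm_bound[0] = 1
        st.arm_seg[0], st.arm_site[0] = s, k
        st.occupancy[s, k] = 2
        return st

    def test_walks_toward_barbed_end_only(self, params):
        """The axial coordinate is non-increasing toward the barbed end."""
        st = self._bound_state(params)
        rng = np.random.default_rng(1)
        coord = lambda: st.arm_seg[0] * 20 + st.arm_site[0]
        last = coord()
        moved = 0
        for _ in range(4000):
            if arm_walk(st, 0, 1e-3, rng, load=0.0):
                assert coord() == last - 1
                moved += 1
            last = coord()
        assert moved > 0

    def test_stalled_arm_never_steps(self, params):
        st = self._bound_state(params)
        rng = np.random.default_rng(2)
        assert not any(arm_walk(st, 0, 1.0, rng, load=45.6)
                       for _ in range(200))

    def test_occupied_target_blocks_step(self, params):
        st = self._bound_state(params)
        s, k = int(st.arm_seg[0]), int(st.arm_site[0])
        st.occupancy[s, k - 1] = 1
        rng = np.random.default_rng(3)
        assert not any(arm_walk(st, 0, 1.0, rng, load=0.0)
                       for _ in range(50))
        assert (st.arm_seg[0], st.arm_site[0]) == (s, k)

    def test_barbed_terminal_site_is_absorbing(self, params):
        st = self._bound_state(params)
        fil = st.seg_fil[st.arm_seg[0]]
        first = int(st.fil_first_seg[fil])
        st.occupancy[st.arm_seg[0], st.arm_site[0]] = 0
        st.arm_seg[0], st.arm_site[0] = first, 0
        st.occupancy[first, 0] = 2
        rng = np.random.default_rng(4)
        assert not any(arm_walk(st, 0, 1.0, rng, load=0.0)
                       for _ in range(50))


class TestUnbinding:
    def test_waiting_times_exponential(self, params):
        """Release times under fixed load follow 1 - exp(-k_u(F) t).

        10^4 events, KS at alpha = 0.01; tick times use the midpoint
        continuity correction for the geometric/exponential comparison.
        """
        st = make_two_filament_state(params, n_acp=0)
        s, k, _ = candidate_sites(st, 0)[0]
        rng = np.random.default_rng(11)
        load = 10.0
        kin = MotorKinetics.from_params(params)
        rate = kin.unbind_rate(load)
        # k*dt = 0.008: the discrete-tick atom (k*dt/2) stays well below
        # the KS critical distance at n = 1e4
        dt = 0.008 / rate
        waits = np.empty(10_000)
        for i in range(waits.size):
            st.arm_bound[0] = 1
            st.arm_seg[0], st.arm_site[0] = s, k
            st.occupancy[s, k] = 2
            n = 1
            while not arm_unbind(st, 0, dt, rng, load=load):
                n += 1
            waits[i] = (n - 0.5) * dt
        d, p = stats.kstest(waits, "expon", args=(0, 1.0 / rate))
        assert p > 0.01

    def test_released_site_freed(self, params):
        st = make_two_filament_state(params, n_acp=0)
        s, k, _ = candidate_sites(st, 0)[0]
        st.arm_bound[0] = 1
        st.arm_seg[0], st.arm_site[0] = s, k
        st.occupancy[s, k] = 2
        rng = np.random.default_rng(5)
        while not arm_unbind(st, 0, 1e-3, rng, load=0.0):
            pass
        assert st.occupancy[s, k] == 0 and st.arm_bound[0] == 0

    def test_isolated_arm_duty_ratio_low(self, params):
        """Bound-time fraction of an arm parked next to a filament < 0.5."""
        st = make_two_filament_state(params, n_acp=0)
        rng = np.random.default_rng(6)
        dt = 5e-5
        bound_ticks = 0
        n_ticks = 60_000
        for _ in range(n_ticks):
            if st.arm_bound[0]:
                bound_ticks += 1
                arm_unbind(st, 0, dt, rng, load=0.0)
            else:
                attempt_arm_binding(st, 0, dt, rng)
        duty = bound_ticks / n_ticks
        assert 0.3 < duty < 0.5


class TestCrosslinks:
    def test_links_join_distinct_filaments_within_reach(self, params):
        st = make_two_filament_state(params, n_acp=6, seed=3)
        assert st.n_acps == 6
        for n in range(st.n_acps):
            f0 = st.seg_fil[st.acp_seg[n, 0]]
            f1 = st.seg_fil[st.acp_seg[n, 1]]
            assert f0 != f1
            p0 = st.site_position(int(st.acp_seg[n, 0]),
                                  int(st.acp_site[n, 0]))
            p1 = st.site_position(int(st.acp_seg[n, 1]),
                                  int(st.acp_site[n, 1]))
            d = np.linalg.norm(st.domain.min_image(p1 - p0))
            assert 0.7 * 47.0 <= d <= 1.1 * 47.0
            # both sites marked with the cross-linker occupancy code
            assert st.occupancy[st.acp_seg[n, 0], st.acp_site[n, 0]] == 1
            assert st.occupancy[st.acp_seg[n, 1], st.acp_site[n, 1]] == 1

    def test_zero_crosslinks_is_valid(self, params):
        st = make_two_filament_state(params, n_acp=0)
        assert st.n_acps == 0

    def test_shortfall_warns(self, params):
        dom = Domain.from_um((5, 5, 4), (1, 1, 0))
        asm = SystemAssembler(params, dom)
        # single filament: no distinct-filament partner exists
        asm.add_filament(build_filament(1400, origin=(2500, 2500, 1000),
                                        direction=(0, 0, 1), params=params))
        with pytest.warns(UserWarning, match="cross-link"):
            placed = init_crosslinks(asm, 3, np.random.default_rng(0),
                                     max_tries=200)
        assert placed == 0


def test_engine_occupancy_stays_consistent(params):
    """Site occupancy is exclusive and matches the arm bookkeeping."""
    from actomyosim.integrator import Engine

    st = make_two_filament_state(params, n_acp=3, seed=2)
    eng = Engine(st, seed=4)
    eng.settle(3000)
    eng.run(20_000)
    occ = st.occupancy
    assert set(np.unique(occ)) <= {0, 1, 2}
    # every bound arm sits on a site marked as arm-occupied
    arm_sites = set()
    for a in np.nonzero(st.arm_bound)[0]:
        key = (int(st.arm_seg[a]), int(st.arm_site[a]))
        assert key not in arm_sites         # exclusivity
        arm_sites.add(key)
        assert occ[key] == 2
    assert len(arm_sites) == int((occ == 2).sum())
    assert int((occ == 1).sum()) == 2 * st.n_acps
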