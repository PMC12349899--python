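import numpy as np
import pytest

from actomyosim.overlap import (MotorPlacement, critical_length,
                                estimate_force, pairwise_xi,
                                sample_bundle_placements, xi_from_overlap,
                                xi_max)


def brute_force_xi_max(centers, L_M, L_c, box=None):
    """Independent oracle: explicit nested loops over motors and sides.

    A neighbor counts on side L (R) if its center offset is <= 0 (>= 0) or
    its span contains the reference motor's center; its weight is the
    three-branch overlap rule.
    """
    best = 0.0
    n = len(centers)
    for i in range(n):
        for side in ("L", "R"):
            total = 1.0
            for k in range(n):
                if k == i:
                    continue
                d = centers[k] - centers[i]
                if box is not None:
                    d -= box * round(d / box)
                ov = L_M - abs(d)
                if ov <= 0:
                    continue
                spans = abs(d) < L_M / 2
                if side == "L" and not (d <= 0 or spans):
                    continue
                if side == "R" and not (d >= 0 or spans):
                    continue
                if L_c <= 0 or ov >= L_c:
                    total += 1.0
                else:
                    total += ov / L_c
            best = max(best, total)
    return best


class TestCriticalLength:
    @pytest.mark.parametrize("N_a,L_sp,L_c", [
        (24, 42, 420.0), (4, 42, 0.0), (16, 42, 252.0), (48, 42, 924.0),
        (16, 138, 828.0),
    ])
    def test_values(self, N_a, L_sp, L_c):
        assert critical_length(N_a, L_sp) == pytest.approx(L_c)

    @pytest.mark.parametrize("N_a", [3, 10, 0])
    def test_invalid_arm_count(self, N_a):
        with pytest.raises(ValueError):
            critical_length(N_a, 42)


class TestXiBranches:
    def test_no_overlap(self):
        assert xi_from_overlap(0.0, 420.0) == 0.0

    def test_full_cooperation(self):
        assert xi_from_overlap(420.0, 420.0) == 1.0
        assert xi_from_overlap(462.0, 420.0) == 1.0

    def test_partial(self):
        assert xi_from_overlap(210.0, 420.0) == pytest.approx(0.5)

    def test_zero_critical_length_counts_any_contact(self):
        assert xi_from_overlap(1.0, 0.0) == 1.0

    def test_negative_overlap_rejected(self):
        with pytest.raises(ValueError):
            xi_from_overlap(-1.0, 420.0)


class TestXiMax:
    def test_single_motor(self):
        rep = xi_max([MotorPlacement(center=0.0)])
        assert rep.Xi == 1.0

    def test_stacked_motors_reach_the_motor_count(self):
        motors = [MotorPlacement(center=0.0) for _ in range(7)]
        assert xi_max(motors).Xi == pytest.approx(7.0)

    def test_three_motor_half_cooperative_example(self):
        # k fully overlaps i; m overlaps half-critically on i's left
        i = MotorPlacement(center=0.0)
        k = MotorPlacement(center=0.0)
        m = MotorPlacement(center=-(i.L_M - 210.0))
        assert xi_max([i, k, m]).Xi == pytest.approx(2.5)

    def test_zero_motors_rejected(self):
        with pytest.raises(ValueError):
            xi_max([])

    def test_matches_brute_force_oracle(self):
        """Exact agreement on 500 random configurations, N_M <= 30."""
        rng = np.random.default_rng(0)
        for trial in range(500):
            n = int(rng.integers(1, 31))
            box = 20000.0 if trial % 2 else None
            centers = rng.uniform(0, 20000.0, n)
            motors = [MotorPlacement(center=float(c)) for c in centers]
            got = xi_max(motors, box=box).Xi
            want = brute_force_xi_max(centers, motors[0].L_M, motors[0].L_c,
                                      box=box)
            assert got == pytest.approx(want, abs=1e-12)

    def test_xi_bounds_and_matrix_range(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            motors = [MotorPlacement(center=float(c))
                      for c in rng.uniform(0, 10000.0, n)]
            rep = xi_max(motors, box=10000.0)
            assert 1.0 <= rep.Xi <= n + 1e-12
            assert np.all(rep.xi >= 0) and np.all(rep.xi <= 1)


class TestEstimateForce:
    def test_reference_values(self):
        assert estimate_force(1.0, 24) == pytest.approx(547.2)
        assert estimate_force(2.0, 24) == pytest.approx(1094.4)

    def test_linear_in_xi(self):
        assert estimate_force(3.0, 24) == pytest.approx(3 * 547.2)

    def test_xi_below_one_rejected(self):
        with pytest.raises(ValueError):
            estimate_force(0.5, 24)


class TestEnsembleTrends:
    def test_localization_raises_expected_cooperativity(self):
        """E[Xi] grows as the motor region shrinks (fixed N_M)."""
        means = []
        for f in (1.0, 0.25, 0.06):
            vals = [xi_max(sample_bundle_placements(
                52, np.random.default_rng(1000 + s), f=f), box=20000.0).Xi
                for s in range(200)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_bare_zone_variant_dominates_spacing_variant(self):
        """At equal L_M and arm budget the long-bare-zone architecture has
        the smaller L_c, hence pointwise larger Xi."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            centers = rng.uniform(0, 20000.0, 26)
            bz = [MotorPlacement(center=c, N_a=16, L_bz=714, L_sp=42)
                  for c in centers]
            sp = [MotorPlacement(center=c, N_a=16, L_bz=138, L_sp=138)
                  for c in centers]
            assert bz[0].L_M == sp[0].L_M == pytest.approx(966.0)
            assert xi_max(bz, box=20000.0).Xi >= \
                xi_max(sp, box=20000.0).Xi - 1e-12

    def test_more_motors_never_less_cooperative(self):
        means = []
        for n in (4, 10, 26, 52):
            vals = [xi_max(sample_bundle_placements(
                n, np.random.default_rng(2000 + s)), box=20000.0).Xi
                for s in range(200)]
            means.append(np.mean(vals))
        assert np.all(np.diff(means) >= 0)


class TestNetworkMode:
    def _mot(self, x, y, ang_deg):
        a = np.deg2rad(ang_deg)
        return MotorPlacement(center=np.array([x, y]),
                              direction=np.array([np.cos(a), np.sin(a)]))

    def test_parallel_coincident_pair_is_cooperative(self):
        rep = xi_max([self._mot(0, 0, 0), self._mot(20, 0, 5)],
                     mode="network")
        assert rep.Xi == pytest.approx(2.0)

    def test_perpendicular_pair_does_not_interact(self):
        rep = xi_max([self._mot(0, 0, 0), self._mot(0, 0, 90)],
                     mode="network")
        assert rep.Xi == pytest.approx(1.0)

    def test_antiparallel_axes_are_equivalent(self):
        # bipolar filaments: the axis sign carries no meaning
        rep = xi_max([self._mot(0, 0, 0), self._mot(20, 0, 180)],
                     mode="network")
        assert rep.Xi == pytest.approx(2.0)

    def test_beyond_angle_cutoff_excluded(self):
        rep = xi_max([self._mot(0, 0, 0), self._mot(0, 0, 35)],
                     mode="network")
        assert rep.Xi == pytest.approx(1.0)
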