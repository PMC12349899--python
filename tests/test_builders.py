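import numpy as np
import pytest
from scipy import stats

from actomyosim.builders import (SystemSpec, build_bundle, build_network,
                                 build_two_filament_system,
                                 calibrate_polymerization,
                                 density_calibration, grow_network_filaments)
from actomyosim.parameters import ParameterSet


def _motor_center_z(state, m):
    """Motor backbone midpoint, wrap-aware."""
    first, last = m.first_vertex, m.first_vertex + m.n_vertices - 1
    d = state.domain.min_image(state.pos[last] - state.pos[first])
    L = state.domain.box[2]
    return float((state.pos[first, 2] + d[2] / 2.0) % L)


class TestSpec:
    def test_bundle_filament_count(self):
        assert SystemSpec(kind="bundle", N_F=2).bundle_filament_count == 8
        assert SystemSpec(kind="bundle", N_F=7).bundle_filament_count == 98

    def test_actin_amount_ratio_thick_vs_thin(self):
        thick = SystemSpec(kind="bundle", N_F=7).bundle_filament_count
        thin = SystemSpec(kind="bundle", N_F=2).bundle_filament_count
        assert thick / thin == pytest.approx(12.25)

    @pytest.mark.parametrize("bad", [{"f": 0.0}, {"f": 1.2},
                                     {"kind": "nonsense"},
                                     {"kind": "bundle", "N_F": 0}])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            SystemSpec(**bad)

    def test_density_pairs(self):
        assert density_calibration(0.005, 2) == 4
        assert density_calibration(0.005, 7) == 52
        with pytest.raises(KeyError):
            density_calibration(0.005, 4)


class TestTwoFilament:
    def test_full_scale_reference_system(self, params):
        st = build_two_filament_system(
            SystemSpec(kind="two_filament", N_M=2, N_ACP=16, seed=0), params)
        assert len(st.filaments) == 2
        assert all(f.n_segments == 136 for f in st.filaments)
        assert len(st.motors) == 2
        assert st.n_acps == 16
        assert st.n_arms == 48
        # barbed ends clamped at the opposing z boundaries
        clamped = np.nonzero(st.mobile == 0)[0]
        assert len(clamped) == 2
        zs = sorted(st.pos[clamped, 2])
        assert zs[0] == pytest.approx(0.0, abs=1e-9)
        assert zs[1] == pytest.approx(st.domain.box[2], abs=1e-9)

    def test_motors_only_control(self, params):
        st = build_two_filament_system(
            SystemSpec(kind="two_filament", N_M=2, N_ACP=0, seed=1), params)
        assert st.n_acps == 0

    def test_seeds_give_distinct_arrangements(self, params):
        spec = dict(kind="two_filament", N_M=2, N_ACP=16)
        zs = set()
        for seed in range(5):
            st = build_two_filament_system(SystemSpec(**spec, seed=seed),
                                           params)
            zs.add(tuple(round(_motor_center_z(st, m)) for m in st.motors))
        assert len(zs) == 5

    def test_oversized_filament_rejected(self, params):
        with pytest.raises(ValueError):
            build_two_filament_system(
                SystemSpec(kind="two_filament", filament_length_nm=30_000),
                params)

    def test_non_overlapping_pair_rejected(self, params):
        with pytest.raises(ValueError, match="overlap"):
            build_two_filament_system(
                SystemSpec(kind="two_filament", filament_length_nm=6000),
                params)

    def test_reproducible(self, params):
        spec = SystemSpec(kind="two_filament", N_M=2, N_ACP=8, seed=3)
        a = build_two_filament_system(spec, params)
        b = build_two_filament_system(spec, params)
        assert np.array_equal(a.pos, b.pos)


class TestBundle:
    def test_filament_counts(self, params):
        st = build_bundle(SystemSpec(kind="bundle", N_F=2, N_M=0, N_ACP=0),
                          params)
        assert len(st.filaments) == 8
        st7 = build_bundle(SystemSpec(kind="bundle", N_F=7, N_M=0, N_ACP=0),
                           params)
        assert len(st7.filaments) == 98
        assert len(st7.filaments) / len(st.filaments) == pytest.approx(12.25)

    def test_lane_grid_and_length(self, params):
        st = build_bundle(SystemSpec(kind="bundle", N_F=2, N_M=0, N_ACP=0,
                                     seed=1), params)
        assert all(f.n_segments == 64 for f in st.filaments)
        xy = {(round(st.pos[f.first_vertex, 0], 3),
               round(st.pos[f.first_vertex, 1], 3)) for f in st.filaments}
        assert len(xy) == 4                     # 2x2 lanes, 2 filaments each
        xs = sorted({p[0] for p in xy})
        assert xs[1] - xs[0] == pytest.approx(27.0)

    def test_polarity_is_unbiased(self, params):
        signs = []
        for seed in range(40):
            st = build_bundle(SystemSpec(kind="bundle", N_F=2, N_M=0,
                                         N_ACP=0, seed=seed), params)
            for f in st.filaments:
                d = st.domain.min_image(st.pos[f.first_vertex + 1] -
                                        st.pos[f.first_vertex])
                signs.append(d[2] > 0)
        frac = np.mean(signs)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(signs)) + 0.02

    def test_motor_localization_window(self, params):
        spec = SystemSpec(kind="bundle", N_F=2, N_M=6, N_ACP=0, f=0.06,
                          seed=2)
        st = build_bundle(spec, params)
        lz = st.domain.box[2]
        centers = [_motor_center_z(st, m) for m in st.motors]
        assert all(0.47 * lz <= c <= 0.53 * lz for c in centers)

    def test_unlocalized_motors_cover_the_box_uniformly(self, params):
        centers = []
        for seed in range(40):
            st = build_bundle(SystemSpec(kind="bundle", N_F=2, N_M=4,
                                         N_ACP=0, f=1.0, seed=seed), params)
            centers += [_motor_center_z(st, m) / st.domain.box[2]
                        for m in st.motors]
        _, p = stats.kstest(centers, "uniform")
        assert p > 0.01

    def test_reproducible(self, params):
        spec = SystemSpec(kind="bundle", N_F=2, N_M=4, N_ACP=10, seed=9)
        assert np.array_equal(build_bundle(spec, params).pos,
                              build_bundle(spec, params).pos)


class TestNetwork:
    def test_mean_length_calibration(self, params):
        """>= 200 filaments average ~10 µm after rate calibration."""
        rng = np.random.default_rng(0)
        target = 15_000
        k_p = calibrate_polymerization(params.k_n_A, target, 10_000.0)
        counts = np.array(grow_network_filaments(params, rng, target, k_p=k_p))
        assert len(counts) >= 200
        mean_um = counts.mean() * 0.14
        assert 9.0 <= mean_um <= 11.0

    def test_growth_matches_gillespie_oracle(self, params):
        """Builder lengths vs an independent event-driven simulation."""
        rng = np.random.default_rng(1)
        target = 4000
        ours = np.array(grow_network_filaments(params, rng, target, k_p=10.0))

        def oracle(seed):
            r = np.random.default_rng(seed)
            counts = []
            total = 0
            while total < target:
                rates = np.array([params.k_n_A, 10.0 * len(counts)])
                if len(counts) == 0 or r.uniform() < rates[0] / rates.sum():
                    counts.append(1)
                else:
                    counts[r.integers(len(counts))] += 1
                total += 1
            return np.array(counts)

        ref = oracle(2)
        _, p = stats.ks_2samp(ours, ref)
        assert p > 0.01

    def test_filaments_lie_in_plane(self, params):
        spec = SystemSpec(kind="network", N_M=0, N_ACP=0, seed=3,
                          network_target_segments=300,
                          network_mean_length_nm=1400.0,
                          domain_um=(6.0, 6.0, 0.1))
        st = build_network(spec, params)
        for f in st.filaments:
            p = st.pos[f.first_vertex:f.first_vertex + f.n_segments + 1]
            d = st.domain.min_image(np.diff(p, axis=0))
            u = d / np.linalg.norm(d, axis=1, keepdims=True)
            assert np.all(np.abs(u[:, 2]) < 1e-6)

    def test_motors_in_plane_random_orientation(self, params):
        spec = SystemSpec(kind="network", N_M=6, N_ACP=0, seed=4,
                          network_target_segments=300,
                          network_mean_length_nm=1400.0,
                          domain_um=(6.0, 6.0, 0.1))
        st = build_network(spec, params)
        assert len(st.motors) == 6
        dirs = []
        for m in st.motors:
            d = st.domain.min_image(
                st.pos[m.first_vertex + m.n_vertices - 1] -
                st.pos[m.first_vertex])
            dirs.append(d / np.linalg.norm(d))
        dirs = np.array(dirs)
        assert np.all(np.abs(dirs[:, 2]) < 1e-6)
        assert len({round(x, 3) for x in dirs[:, 0]}) > 1
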