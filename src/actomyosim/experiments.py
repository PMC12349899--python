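"""Canned experiments: the measurement protocols behind the headline numbers.

Each function builds its system from scratch, runs the engine and measures
one published observable:

* :func:`persistence_length` — worm-like-chain recovery of Lp from the
  tangent-tangent correlation of free thermal filaments.
* :func:`gliding_velocity` — unloaded walking speed of bound motor arms.
* :func:`stall_force_per_head` — smallest arm load with zero walking rate,
  per myosin head.
* :func:`run_two_filament` — the minimal two-filament contraction assay
  (force bounds and the ACP-placement dichotomy).
* :func:`run_thin_bundle` — the sparse-motor thin-bundle efficiency
  (eta ~ 1/N_M).

Desk-scale geometry: the two-filament assay uses 6-µm filaments in a
5x5x6 µm box (the pair overlaps over the whole box) with the cross-linker
count scaled to the full-scale linear density (16 per 18 µm of overlap);
the thin bundle uses 6-µm filaments in a 14-µm box.  Scaled problem sizes
are stated in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .builders import SystemSpec, build_bundle, build_two_filament_system
from .integrator import Engine
from .kinetics import MotorKinetics
from .measurement import Measurement, MeasurementResult, acp_arm_tensions
from .model import build_filament, build_motor
from .parameters import ParameterSet
from .state import Domain, SystemAssembler

__all__ = ["persistence_length", "free_bead_msd", "gliding_velocity",
           "stall_force_per_head", "run_two_filament", "run_thin_bundle",
           "TwoFilamentOutcome", "DESK_TWO_FILAMENT", "DESK_THIN_BUNDLE"]

#: desk-scale presets (full scale: 19-µm filaments in a 20-µm box, 16 ACPs;
#: 9-µm filaments in a 20-µm box for bundles).  The two-filament desk box
#: equals the filament length so the antiparallel pair overlaps everywhere,
#: and the cross-linker count keeps the full-scale linear density
#: (16 per 18 µm of overlap).
DESK_TWO_FILAMENT = dict(domain_um=(5.0, 5.0, 6.0), filament_length_nm=6000.0,
                         N_M=2, N_ACP=5)
DESK_THIN_BUNDLE = dict(domain_um=(5.0, 5.0, 14.0), filament_length_nm=6000.0,
                        N_F=2, N_M=4, N_ACP=100, f=1.0,
                        min_motor_gap_nm=280.0)


# ----------------------------------------------------------------------
def persistence_length(seed: int = 0, n_filaments: int = 20,
                       length_nm: float = 9000.0,
                       equilibration_steps: int = 20_000,
                       sampling_steps: int = 200_000,
                       sample_every: int = 2_000,
                       fit_range_nm: float = 700.0,
                       params: ParameterSet | None = None) -> float:
    """Recover the actin persistence length (µm) from tangent correlations.

    An ensemble of free filaments is initialized from the worm-like-chain
    equilibrium distribution (per-joint tangent rotations with variance
    ``kBT/kappa_b`` in each transverse direction), evolved with thermal
    dynamics — which must maintain that distribution — and sampled; the
    ensemble-averaged tangent correlation ``<t(s) . t(0)> = exp(-s / Lp)``
    is fit (log-linear, through the origin) over separations up to
    ``fit_range_nm``.
    """
    params = params or ParameterSet()
    dom = Domain.from_um((100.0, 100.0, 100.0), (0, 0, 0))
    asm = SystemAssembler(params, dom)
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_filaments)))
    n_seg = max(1, round(length_nm / params.r0_A))
    sig = np.sqrt(params.kBT / params.kappa_b_A)     # per transverse direction
    for i in range(n_filaments):
        # well-separated origins: ensemble members never touch
        origin = np.array((2e4 + 15e3 * (i % side),
                           2e4 + 15e3 * (i // side), 5e4))
        t = rng.standard_normal(3)
        t /= np.linalg.norm(t)
        pos = [origin]
        for _ in range(n_seg):
            pos.append(pos[-1] + params.r0_A * t)
            # rotate the tangent by equilibrium joint angles
            e1 = np.cross(t, [0.0, 0.0, 1.0])
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.cross(t, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            a, b = rng.normal(0.0, sig, size=2)
            t = t + a * e1 + b * e2
            t /= np.linalg.norm(t)
        fil = build_filament(length_nm, origin=origin, params=params)
        fil.positions = np.array(pos)
        asm.add_filament(fil)
    st = asm.build(seed=seed)
    # free diffusion in open space: disable the box walls by centering far
    # from the boundaries; wall forces never engage at these time scales
    eng = Engine(st, seed=seed, bind=False, walk=False, unbind=False)
    eng.run(equilibration_steps)

    n_fit = int(fit_range_nm / params.r0_A)
    corr = np.zeros(n_fit + 1)
    counts = np.zeros(n_fit + 1)
    n_samples = sampling_steps // sample_every
    for _ in range(n_samples):
        eng.run(sample_every)
        for fi in st.filaments:
            p = st.pos[fi.first_vertex:fi.first_vertex + fi.n_segments + 1]
            t = np.diff(p, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            for lag in range(n_fit + 1):
                c = np.einsum("ij,ij->i", t[:len(t) - lag], t[lag:])
                corr[lag] += c.sum()
                counts[lag] += len(c)
    corr /= counts
    s = np.arange(n_fit + 1) * params.r0_A
    # log-linear fit through the origin: ln C = -s/Lp
    y = np.log(np.clip(corr, 1e-12, None))
    slope = np.sum(s * y) / np.sum(s * s)
    return float(-1.0 / slope / 1000.0)    # nm -> µm


# ----------------------------------------------------------------------
def free_bead_msd(seed: int = 0, n_beads: int = 200, n_steps: int = 3000,
                  lag: int = 150,
                  params: ParameterSet | None = None) -> tuple[float, float]:
    """Mean squared displacement of free beads vs the Einstein relation.

    Returns ``(msd_measured, msd_expected)`` in nm² at ``lag`` steps, with
    ``msd_expected = 6 kBT t / zeta`` for an actin-segment-sized bead.
    Non-overlapping time origins over an ensemble keep the estimate within
    a percent.
    """
    params = params or ParameterSet()
    sp = params.sim()
    dom = Domain.from_um((1000.0, 1000.0, 1000.0), (0, 0, 0))
    n = n_beads
    arrays = {
        "pos": np.full((n, 3), 4e5) + np.arange(n)[:, None] * 1e3,
        "zeta": np.full(n, sp.zeta_A),
        "mobile": np.ones(n, dtype=np.uint8),
        "vkind": np.zeros(n, dtype=np.int8),
        "bond_i": np.zeros(0, dtype=np.int64),
        "bond_j": np.zeros(0, dtype=np.int64),
        "bond_r0": np.zeros(0), "bond_k": np.zeros(0),
        "bond_kind": np.zeros(0, dtype=np.int8),
        "ang_a": np.zeros(0, dtype=np.int64),
        "ang_b": np.zeros(0, dtype=np.int64),
        "ang_c": np.zeros(0, dtype=np.int64), "ang_k": np.zeros(0),
        "seg_v1": np.zeros(0, dtype=np.int64),
        "seg_v2": np.zeros(0, dtype=np.int64),
        "seg_fil": np.zeros(0, dtype=np.int64),
        "fil_first_seg": np.zeros(0, dtype=np.int64),
        "occupancy": np.zeros((0, sp.n_sites), dtype=np.int8),
        "site_frac": np.arange(sp.n_sites) * sp.site_spacing / sp.r0_A,
        "acp_center": np.zeros(0, dtype=np.int64),
        "acp_seg": np.zeros((0, 2), dtype=np.int64),
        "acp_site": np.zeros((0, 2), dtype=np.int64),
        "arm_anchor": np.zeros(0, dtype=np.int64),
        "arm_ref": np.zeros(0, dtype=np.int64),
        "arm_sibling": np.zeros(0, dtype=np.int64),
        "arm_motor": np.zeros(0, dtype=np.int64),
        "arm_bound": np.zeros(0, dtype=np.uint8),
        "arm_seg": np.zeros(0, dtype=np.int64),
        "arm_site": np.zeros(0, dtype=np.int64),
    }
    from .state import SimulationState
    st = SimulationState(params, dom, arrays, [], [], seed)
    eng = Engine(st, seed=seed, bind=False, walk=False, unbind=False)
    frames = [st.pos.copy()]
    for _ in range(n_steps // lag):
        eng.run(lag)
        frames.append(st.pos.copy())
    frames = np.array(frames)
    disp = frames[1:] - frames[:-1]
    msd = float(np.mean(np.sum(disp ** 2, axis=-1)))
    expected = 6.0 * sp.kBT * (lag * params.dt) / sp.zeta_A
    return msd, expected


# ----------------------------------------------------------------------
def gliding_velocity(seed: int = 0, n_walkers: int = 10,
                     duration_s: float = 10.0,
                     params: ParameterSet | None = None) -> float:
    """Mean unloaded walking velocity (nm/s) of bound motor arms.

    Several minimal motors are pre-bound near the pointed end of a long
    straight filament; arm springs are released (zero stiffness: the load
    stays clamped at zero), unbinding is disabled, and the arms walk
    freely toward the barbed end.  Velocity = site displacement / time.
    """
    base = (params or ParameterSet()).to_dict()
    base.update(kappa_s_M2=1e-30, kappa_s_M3=1e-30, k_u0=0.0)
    params = ParameterSet.from_dict(base)
    sp = params.sim()
    length = 19_000.0
    dom = Domain.from_um((5.0, 5.0, 20.0), (1, 1, 0))
    asm = SystemAssembler(params, dom)
    asm.add_filament(build_filament(length, origin=(2500.0 - 13.5, 2500.0, 500.0),
                                    direction=(0, 0, 1), params=params),
                     clamp_barbed=True, clamp_pointed=True)
    z0 = 500.0 + length - 1000.0
    for w in range(n_walkers):
        # walkers 1.5 µm apart: far beyond the ~0.15 µm diffusive spread of
        # their walked distances, so they never queue on the site lattice
        asm.add_motor(build_motor(4, 42.0, 42.0,
                                  center=(2500.0, 2500.0, z0 - 1500.0 * w),
                                  direction=(0, 0, 1), params=params))
    st = asm.build(seed=seed)
    # bind one left-side arm of each motor by hand at the nearest site
    start_pos = np.empty(st.n_arms)
    for a in range(st.n_arms):
        w = st.pos[st.arm_anchor[a]] - st.pos[st.arm_ref[a]]
        if w[2] >= 0:          # right-side arm: walks +z, filament barbed at -z
            continue
        sib = st.arm_sibling[a]
        if sib >= 0 and st.arm_bound[sib]:
            continue
        za = st.pos[st.arm_anchor[a], 2]
        seg = int(np.clip((za - 500.0) // params.r0_A, 0, st.n_segments - 1))
        site = sp.n_sites // 2
        if st.occupancy[seg, site] == 0:
            st.arm_bound[a] = 1
            st.arm_seg[a] = seg
            st.arm_site[a] = site
            st.occupancy[seg, site] = 2
    bound = np.nonzero(st.arm_bound)[0]
    start_pos = (st.arm_seg[bound] * sp.n_sites + st.arm_site[bound]).astype(float)

    eng = Engine(st, seed=seed, thermal=False, bind=False, unbind=False,
                 freeze_actin=True)
    eng.run(int(round(duration_s / params.dt)))
    end_pos = (st.arm_seg[bound] * sp.n_sites + st.arm_site[bound]).astype(float)
    sites_advanced = start_pos - end_pos       # walking lowers the site index
    return float(sites_advanced.mean() * params.site_spacing / duration_s)


def stall_force_per_head(params: ParameterSet | None = None,
                         resolution_pN: float = 0.01) -> float:
    """Per-head stall force (pN): smallest load with zero walking rate / N_h.

    Deterministic ramp of a static opposing load through the walking-rate
    law; no simulation required.
    """
    params = params or ParameterSet()
    kin = MotorKinetics.from_params(params)
    loads = np.arange(0.0, 2.0 * kin.F_stall_arm + resolution_pN,
                      resolution_pN)
    rates = np.array([kin.walk_rate(F) for F in loads])
    stalled = np.nonzero(rates <= 0.0)[0]
    if len(stalled) == 0:
        raise RuntimeError("walking rate never reached zero")
    return float(loads[stalled[0]] / params.N_h)


# ----------------------------------------------------------------------
@dataclass
class TwoFilamentOutcome:
    """One seed of the two-filament assay with its ACP-placement class."""

    result: MeasurementResult
    eta: float
    motor_spans: list[tuple[float, float]]
    acp_z: np.ndarray
    acp_tension: np.ndarray

    @property
    def gap(self) -> tuple[float, float]:
        spans = sorted(self.motor_spans)
        return (spans[0][1], spans[1][0])

    @property
    def n_acp_between(self) -> int:
        lo, hi = self.gap
        return int(np.sum((self.acp_z > lo) & (self.acp_z < hi))) if hi > lo else 0

    @property
    def n_acp_inside(self) -> int:
        """ACPs anywhere inside the union of the two motor spans + gap."""
        lo = min(s[0] for s in self.motor_spans)
        hi = max(s[1] for s in self.motor_spans)
        return int(np.sum((self.acp_z > lo) & (self.acp_z < hi)))

    @property
    def placement_class(self) -> str:
        """'cooperative' (no ACP in the joint span), 'divided' (ACP in the
        gap of separated motors), or 'intermediate'."""
        if self.n_acp_inside == 0:
            return "cooperative"
        if self.n_acp_between > 0:
            return "divided"
        return "intermediate"


def run_two_filament(seed: int, duration_s: float = 12.0,
                     desk: bool = True, params: ParameterSet | None = None,
                     sample_every_s: float = 0.05,
                     settle_steps: int = 6_000,
                     spec_overrides: dict | None = None) -> TwoFilamentOutcome:
    """One seed of the two-filament contraction assay."""
    params = params or ParameterSet()
    kw = dict(DESK_TWO_FILAMENT) if desk else dict(N_M=2, N_ACP=16)
    kw.update(spec_overrides or {})
    spec = SystemSpec(kind="two_filament", seed=seed, **kw)
    st = build_two_filament_system(spec, params)
    eng = Engine(st, seed=seed, kinetics_stride=4)
    eng.settle(settle_steps)
    meas = Measurement(st, mode="bundle")
    steps = int(round(sample_every_s / params.dt))
    for _ in range(int(round(duration_s / sample_every_s))):
        eng.run(steps)
        meas.sample()
    res = meas.result()
    spans = []
    for m in st.motors:
        z = st.pos[m.first_vertex:m.first_vertex + m.n_vertices, 2]
        spans.append((float(z.min()), float(z.max())))
    return TwoFilamentOutcome(result=res, eta=res.eta, motor_spans=spans,
                              acp_z=st.pos[st.acp_center, 2].copy(),
                              acp_tension=acp_arm_tensions(st))


def run_thin_bundle(seed: int, duration_s: float = 12.0,
                    params: ParameterSet | None = None,
                    sample_every_s: float = 0.05,
                    settle_steps: int = 6_000,
                    spec_overrides: dict | None = None) -> MeasurementResult:
    """One seed of the sparse-motor thin-bundle efficiency experiment."""
    params = params or ParameterSet()
    kw = dict(DESK_THIN_BUNDLE)
    kw.update(spec_overrides or {})
    spec = SystemSpec(kind="bundle", seed=seed, **kw)
    st = build_bundle(spec, params)
    eng = Engine(st, seed=seed, kinetics_stride=4)
    eng.settle(settle_steps)
    meas = Measurement(st, mode="bundle")
    steps = int(round(sample_every_s / params.dt))
    for _ in range(int(round(duration_s / sample_every_s))):
        eng.run(steps)
        meas.sample()
    return meas.result()
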