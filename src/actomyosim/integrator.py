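"""Overdamped Langevin time stepping.

Inertia is neglected: each vertex moves by ``(F + F^T) * dt / zeta`` per
explicit-Euler step, where the thermal force ``F^T`` has independent
components of variance ``2*kBT*zeta/dt`` (fluctuation-dissipation).  The
:class:`Engine` drives the fused compiled loop in :mod:`actomyosim._core`;
:func:`step` is a transparent single-step reference used in tests.
"""

from __future__ import annotations

import numpy as np

from . import _core, mechanics
from .parameters import ParameterSet
from .state import Domain, SimulationState, VKIND_ACTIN

__all__ = ["thermal_sigma", "sample_thermal_forces", "step",
           "apply_boundaries", "Engine", "InstabilityError"]


class InstabilityError(RuntimeError):
    """A per-step displacement exceeded half an actin segment.

    Signals a mis-set stiffness / time-step combination (or a zero-length
    segment); the trajectory up to the failing step is preserved.
    """


def thermal_sigma(zeta, params: ParameterSet):
    """Per-component thermal force std dev (pN) for drag ``zeta`` (pN·s/nm)."""
    sp = params.sim()
    return np.sqrt(2.0 * sp.kBT * np.asarray(zeta) / params.dt)


def sample_thermal_forces(zeta: float, params: ParameterSet,
                          rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Draw ``n`` thermal force 3-vectors (pN) for a vertex of drag ``zeta``.

    ``zeta`` is in pN·s/nm.  Mean 0, per-component variance
    ``2*kBT*zeta/dt``, independent across components and draws.
    """
    sigma = float(thermal_sigma(zeta, params))
    return rng.normal(0.0, sigma, size=(n, 3))


def apply_boundaries(positions: np.ndarray, domain: Domain,
                     kwall: float) -> tuple[np.ndarray, np.ndarray]:
    """Wrap periodic axes and compute harmonic wall forces on the others.

    Returns ``(wrapped_positions, wall_forces)``; a vertex penetrating a
    repulsive wall by depth ``p`` feels ``kwall * p`` toward the interior.
    """
    wrapped = domain.wrap(positions)
    f = np.zeros_like(wrapped)
    for ax in range(3):
        if domain.periodic[ax]:
            continue
        x = wrapped[..., ax]
        f[..., ax] += kwall * np.where(x < 0.0, -x, 0.0)
        f[..., ax] += kwall * np.where(x > domain.box[ax],
                                       domain.box[ax] - x, 0.0)
    return wrapped, f


def step(state: SimulationState, rng: np.random.Generator | None = None,
         thermal: bool = True,
         extra_forces: np.ndarray | None = None) -> None:
    """Advance one Euler step in plain numpy (reference path, no kinetics)."""
    f = mechanics.all_forces(state).total
    if extra_forces is not None:
        f = f + extra_forces
    if thermal:
        if rng is None:
            raise ValueError("thermal stepping needs an rng")
        sigma = thermal_sigma(state.zeta, state.params)
        f = f + sigma[:, None] * rng.standard_normal((state.n_vertices, 3))
    disp = f * (state.params.dt / state.zeta[:, None])
    disp[state.mobile == 0] = 0.0
    if np.max(np.sum(disp ** 2, axis=1)) > (0.5 * state.params.r0_A) ** 2:
        raise InstabilityError("per-step displacement exceeded r0_A/2")
    state.pos[:] = state.domain.wrap(state.pos + disp)
    state.time += state.params.dt


class Engine:
    """Compiled Brownian-dynamics driver for a :class:`SimulationState`.

    One engine owns one trajectory.  All randomness (thermal kicks and
    kinetic events) derives from ``seed``; identical seeds give bit-identical
    trajectories.  ``freeze_actin`` holds actin vertices fixed (the
    initialization phase in which binders attach to a stationary scaffold).
    """

    #: extra reach of the Verlet pair list beyond the repulsion cutoff (nm)
    SKIN = 15.0

    def __init__(self, state: SimulationState, seed: int | None = None,
                 thermal: bool = True, bind: bool = True, walk: bool = True,
                 unbind: bool = True, freeze_actin: bool = False,
                 kinetics_stride: int = 1):
        self.state = state
        self.seed = int(state.seed if seed is None else seed)
        self.thermal = thermal
        self.flags = np.array([bind, walk, unbind], dtype=np.uint8)
        self.freeze_actin = freeze_actin
        self.kinetics_stride = int(kinetics_stride)
        self._chunk = 0
        sp = state.params.sim()
        self._sp = sp
        self._f = np.zeros((state.n_vertices, 3))
        self._sigma = np.asarray(thermal_sigma(state.zeta, state.params))
        self._pairs = np.zeros((max(4096, 60 * max(1, state.n_segments)), 2),
                               dtype=np.int64)
        self._prm = np.array([sp.ks_ACP, sp.r0_ACP, sp.kb_ACP, sp.ks_M2,
                              sp.r0_M2, sp.ks_M3, sp.kr_A, sp.rc_A, sp.kr_A])
        p_bind = -np.expm1(-sp.k_bind * sp.dt * self.kinetics_stride)
        capture = sp.r0_M2 + 2.0 * sp.site_spacing
        self._kin = np.array([p_bind, capture, sp.k_w0, sp.k_u0,
                              1.0 / sp.F_cat, sp.ku_floor, sp.F_stall_arm])

    def _mobile(self) -> np.ndarray:
        if not self.freeze_actin:
            return self.state.mobile
        m = self.state.mobile.copy()
        m[self.state.vkind == VKIND_ACTIN] = 0
        return m

    def run(self, nsteps: int) -> None:
        """Advance ``nsteps`` steps; raises :class:`InstabilityError` on blowup."""
        s = self.state
        chunk_seed = (self.seed * 1048573 + self._chunk * 7919 + 1) % (2 ** 31)
        self._chunk += 1
        status, done = _core.run_chunk(
            nsteps, chunk_seed,
            s.pos, self._f, s.zeta, self._sigma, self._mobile(),
            s.bond_i, s.bond_j, s.bond_r0, s.bond_k,
            s.ang_a, s.ang_b, s.ang_c, s.ang_k,
            s.seg_v1, s.seg_v2, s.seg_fil, s.fil_first_seg,
            s.occupancy, s.site_frac,
            s.acp_center, s.acp_seg, s.acp_site,
            s.arm_bound, s.arm_anchor, s.arm_ref, s.arm_sibling,
            s.arm_seg, s.arm_site,
            self._pairs, self._prm, self._kin,
            s.domain.box, s.domain.periodic,
            s.params.dt, self.SKIN, self.thermal, self.flags,
            self.kinetics_stride)
        s.time += done * s.params.dt
        if status != _core.OK:
            raise InstabilityError(
                f"integration unstable after {done} steps at t={s.time:.3g} s")

    def run_time(self, seconds: float) -> None:
        self.run(int(round(seconds / self.state.params.dt)))

    def settle(self, nsteps: int = 10_000) -> None:
        """Initialization phase: binders attach while actin stays frozen."""
        frozen = self.freeze_actin
        self.freeze_actin = True
        try:
            self.run(nsteps)
        finally:
            self.freeze_actin = frozen
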