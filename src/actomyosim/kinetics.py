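"""Stochastic binding, walking and unbinding of motor arms; cross-linking.

The motor mechanochemistry is a pluggable strategy.  The default
:class:`MotorKinetics` uses a linear force-velocity law calibrated to the
unloaded gliding speed (140 nm/s) and the per-arm stall force
(``F_st * N_h``), and a catch-bond unbinding rate ``k_u0 * exp(-F/F_cat)``
(release slows under load), floored at ``k_u_floor_frac * k_u0``.  The compiled engine
implements this parametric family; the functions here are the transparent
single-event reference path with identical semantics, used directly in
tests and for custom rate laws.

Binding rules: an arm binds free 7-nm sites within a capture radius of its
anchor, only on filaments whose barbed-end direction aligns with the arm's
walking direction, and never on the filament its sibling arm (same anchor
point) already holds.  Cross-linkers are permanent once both arms engage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _core, mechanics
from .parameters import ParameterSet
from .state import SimulationState, SystemAssembler

__all__ = ["MotorKinetics", "attempt_arm_binding", "arm_walk", "arm_unbind",
           "init_crosslinks", "capture_radius"]


def capture_radius(params: ParameterSet) -> float:
    """Site-search radius around an arm anchor (nm): ``r0_M2 + 2*spacing``."""
    return params.r0_M2 + 2.0 * params.site_spacing


@dataclass
class MotorKinetics:
    """Load-dependent walking and unbinding rates of one motor arm.

    ``walk_rate(0) * step_size = v0`` and ``walk_rate(F >= F_stall_arm) = 0``;
    both rates are non-increasing in load (catch-bond release).
    """

    k_w0: float = 20.0          # unloaded walking rate (1/s)
    step_size: float = 7.0      # walking step (nm), one binding site
    k_u0: float = 350.0         # unloaded unbinding rate (1/s)
    F_cat: float = 6.0          # catch-bond force scale (pN)
    F_stall_arm: float = 45.6   # stall force of one arm (pN) = F_st * N_h
    floor_frac: float = 1e-3    # k_u never drops below floor_frac * k_u0

    @classmethod
    def from_params(cls, params: ParameterSet) -> "MotorKinetics":
        return cls(k_w0=params.v0 / params.site_spacing,
                   step_size=params.site_spacing, k_u0=params.k_u0,
                   F_cat=params.F_cat, F_stall_arm=params.F_stall_arm,
                   floor_frac=params.k_u_floor_frac)

    def walk_rate(self, F: float) -> float:
        """Walking rate (1/s) under load ``F`` (pN) opposing motion."""
        return self.k_w0 * max(0.0, 1.0 - max(F, 0.0) / self.F_stall_arm)

    def unbind_rate(self, F: float) -> float:
        """Unbinding rate (1/s) under load ``F`` (pN); never exactly zero."""
        return max(self.k_u0 * np.exp(-max(F, 0.0) / self.F_cat),
                   self.floor_frac * self.k_u0)

    @property
    def unloaded_velocity(self) -> float:
        return self.k_w0 * self.step_size


# ----------------------------------------------------------------------
# single-arm reference operations
# ----------------------------------------------------------------------
def _walking_direction(state: SimulationState, arm: int) -> np.ndarray:
    w = state.pos[state.arm_anchor[arm]] - state.pos[state.arm_ref[arm]]
    w = state.domain.min_image(w)
    n = np.linalg.norm(w)
    if n < 1e-12:
        raise ValueError("degenerate backbone: walking direction undefined")
    return w / n


def candidate_sites(state: SimulationState, arm: int) -> list[tuple[int, int, float]]:
    """Admissible (segment, site, distance) targets for an unbound arm.

    Applies the capture radius, the polarity-alignment test and the
    sibling-arm same-filament exclusion; occupied sites are excluded.
    """
    p = state.params
    cap = capture_radius(p)
    anchor = state.pos[state.arm_anchor[arm]]
    w = _walking_direction(state, arm)
    sib = state.arm_sibling[arm]
    sib_fil = -1
    if sib >= 0 and state.arm_bound[sib]:
        sib_fil = state.seg_fil[state.arm_seg[sib]]
    out = []
    for s in range(state.n_segments):
        if state.seg_fil[s] == sib_fil:
            continue
        v1, v2 = state.seg_v1[s], state.seg_v2[s]
        d = state.domain.min_image(state.pos[v2] - state.pos[v1])
        # barbed-end direction of the filament is -d (v1 is barbed side)
        if float(-d @ w) <= 0.0:
            continue
        for k in range(len(state.site_frac)):
            if state.occupancy[s, k] != _core.FREE:
                continue
            site = state.pos[v1] + state.site_frac[k] * d
            dist = np.linalg.norm(state.domain.min_image(site - anchor))
            if dist < cap:
                out.append((s, k, float(dist)))
    return out


def attempt_arm_binding(state: SimulationState, arm: int, dt: float,
                        rng: np.random.Generator,
                        params: ParameterSet | None = None) -> bool:
    """One binding attempt of an unbound arm over an interval ``dt``.

    Succeeds with probability ``1 - exp(-k_bind * dt)`` where
    ``k_bind = 40 * N_h`` per second; on success the nearest admissible
    site is occupied.  Returns True if the arm bound.
    """
    p = params or state.params
    if state.arm_bound[arm]:
        raise ValueError("arm already bound")
    if rng.random() >= -np.expm1(-p.k_bind_per_head * p.N_h * dt):
        return False
    cands = candidate_sites(state, arm)
    if not cands:
        return False
    s, k, _ = min(cands, key=lambda c: c[2])
    state.arm_bound[arm] = 1
    state.arm_seg[arm] = s
    state.arm_site[arm] = k
    state.occupancy[s, k] = _core.OCC_ARM
    return True


def arm_load(state: SimulationState, arm: int) -> float:
    """Load (pN) opposing barbed-ward walking of a bound arm."""
    return float(mechanics.arm_loads(state)[arm])


def arm_walk(state: SimulationState, arm: int, dt: float,
             rng: np.random.Generator,
             kinetics: MotorKinetics | None = None,
             load: float | None = None) -> bool:
    """One walking attempt of a bound arm: one site toward the barbed end.

    The step fires with probability ``1 - exp(-k_w(F) * dt)`` and is blocked
    by an occupied target site or the barbed-end terminal site.
    """
    if not state.arm_bound[arm]:
        raise ValueError("arm is not bound")
    kin = kinetics or MotorKinetics.from_params(state.params)
    F = arm_load(state, arm) if load is None else load
    kw = kin.walk_rate(F)
    if kw <= 0.0 or rng.random() >= -np.expm1(-kw * dt):
        return False
    s, k = int(state.arm_seg[arm]), int(state.arm_site[arm])
    n_sites = len(state.site_frac)
    if k > 0:
        tgt = (s, k - 1)
    elif s > state.fil_first_seg[state.seg_fil[s]]:
        tgt = (s - 1, n_sites - 1)
    else:
        return False            # barbed-end terminal site
    if state.occupancy[tgt] != _core.FREE:
        return False
    state.occupancy[s, k] = _core.FREE
    state.occupancy[tgt] = _core.OCC_ARM
    state.arm_seg[arm], state.arm_site[arm] = tgt
    return True


def arm_unbind(state: SimulationState, arm: int, dt: float,
               rng: np.random.Generator,
               kinetics: MotorKinetics | None = None,
               load: float | None = None) -> bool:
    """One unbinding attempt of a bound arm (catch bond: slower under load)."""
    if not state.arm_bound[arm]:
        raise ValueError("arm is not bound")
    kin = kinetics or MotorKinetics.from_params(state.params)
    F = arm_load(state, arm) if load is None else load
    if rng.random() >= -np.expm1(-kin.unbind_rate(F) * dt):
        return False
    state.occupancy[state.arm_seg[arm], state.arm_site[arm]] = _core.FREE
    state.arm_bound[arm] = 0
    state.arm_seg[arm] = -1
    state.arm_site[arm] = -1
    return True


# ----------------------------------------------------------------------
# cross-linker placement
# ----------------------------------------------------------------------
def init_crosslinks(asm: SystemAssembler, n_acp: int,
                    rng: np.random.Generator,
                    z_range: tuple[float, float] | None = None,
                    max_tries: int | None = None) -> int:
    """Place ``n_acp`` permanent cross-linkers on a frozen actin structure.

    Each linker binds two free sites on two *distinct* filaments whose
    separation is geometrically reachable by the two 23.5-nm arms
    (0.7-1.1 x the 47-nm rest span).  ``z_range`` optionally restricts the
    first site's z coordinate (e.g. to the antiparallel overlap of a
    two-filament system).  Returns the number actually placed; a shortfall
    emits a warning.
    """
    p = asm.params
    span = 2.0 * p.r0_ACP
    lo, hi = 0.7 * span, 1.1 * span
    placed = 0
    tries = 0
    max_tries = max_tries or 400 * n_acp
    n_sites = asm.sp.n_sites
    while placed < n_acp and tries < max_tries:
        tries += 1
        s0 = int(rng.integers(asm.n_segments))
        k0 = int(rng.integers(n_sites))
        if not asm.site_is_free(s0, k0):
            continue
        p0 = asm._site_pos(s0, k0)
        if z_range is not None and not (z_range[0] <= p0[2] <= z_range[1]):
            continue
        fid0 = asm.segment_filament(s0)
        cands = []
        for s1 in range(asm.n_segments):
            if asm.segment_filament(s1) == fid0:
                continue
            a, b = asm.segment_endpoints(s1)
            mid = a + 0.5 * asm.domain.min_image(b - a)
            if np.linalg.norm(asm.domain.min_image(mid - p0)) > hi + p.r0_A:
                continue
            for k1 in range(n_sites):
                if not asm.site_is_free(s1, k1):
                    continue
                d = np.linalg.norm(asm.domain.min_image(
                    asm._site_pos(s1, k1) - p0))
                if lo <= d <= hi:
                    cands.append((s1, k1))
        if not cands:
            continue
        s1, k1 = cands[int(rng.integers(len(cands)))]
        asm.add_acp(s0, k0, s1, k1)
        placed += 1
    if placed < n_acp:
        msg = f"placed only {placed}/{n_acp} cross-linkers (no admissible site pairs)"
        warnings.warn(msg)
        asm.warnings.append(msg)
    return placed
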