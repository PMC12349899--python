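"""Deterministic forces and their potentials.

The production force evaluation lives in the compiled kernels of
:mod:`actomyosim._core`; this module wraps them per category into a
:class:`ForceAccumulator` and, separately, implements the corresponding
potential energies in plain numpy.  The energies are written independently
of the kernels (straight from the harmonic potentials), which makes
``-dU/dr`` a finite-difference oracle for every force path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .state import SimulationState

__all__ = ["ForceAccumulator", "stretch_forces", "bend_forces",
           "repulsive_forces", "acp_forces", "motor_arm_forces",
           "wall_forces", "all_forces", "distribute_to_endpoints",
           "stretch_energy", "bend_energy", "repulsion_energy",
           "acp_energy", "motor_arm_energy", "wall_energy", "total_energy",
           "neighbor_pairs", "arm_loads"]

CATEGORIES = ("stretch", "bend", "repulsion", "acp", "motor_arm", "wall")


@dataclass
class ForceAccumulator:
    """Per-vertex force sums (pN), decomposed by physical origin."""

    n_vertices: int
    parts: dict = field(default_factory=dict)

    def add(self, category: str, forces: np.ndarray) -> None:
        self.parts[category] = self.parts.get(
            category, np.zeros((self.n_vertices, 3))) + forces

    @property
    def total(self) -> np.ndarray:
        out = np.zeros((self.n_vertices, 3))
        for f in self.parts.values():
            out += f
        return out


def _empty(state: SimulationState) -> np.ndarray:
    return np.zeros((state.n_vertices, 3))


def _prm(state: SimulationState) -> np.ndarray:
    sp = state.params.sim()
    return np.array([sp.ks_ACP, sp.r0_ACP, sp.kb_ACP, sp.ks_M2, sp.r0_M2,
                     sp.ks_M3, sp.kr_A, sp.rc_A, sp.kr_A])


def stretch_forces(state: SimulationState) -> np.ndarray:
    """Extensional forces of all actin and backbone segments."""
    f = _empty(state)
    st = _core.stretch_forces(state.pos, f, state.bond_i, state.bond_j,
                              state.bond_r0, state.bond_k,
                              state.domain.box, state.domain.periodic)
    if st != _core.OK:
        raise ValueError("zero-length segment: stretch direction undefined")
    return f


def bend_forces(state: SimulationState) -> np.ndarray:
    """Bending forces of all three-vertex joints (actin and backbone)."""
    f = _empty(state)
    _core.bend_forces(state.pos, f, state.ang_a, state.ang_b, state.ang_c,
                      state.ang_k, state.domain.box, state.domain.periodic)
    return f


def neighbor_pairs(state: SimulationState, skin: float = 15.0) -> np.ndarray:
    """Actin segment pairs within repulsion range + ``skin`` (nm)."""
    buf = np.zeros((max(1024, 50 * state.n_segments), 2), dtype=np.int64)
    n = _core.build_pair_list(state.pos, state.seg_v1, state.seg_v2,
                              state.seg_fil, buf, state.params.sim().rc_A,
                              skin, state.domain.box, state.domain.periodic)
    if n < 0:
        raise RuntimeError("neighbor pair buffer overflow")
    return buf[:n]


def repulsive_forces(state: SimulationState,
                     pairs: np.ndarray | None = None) -> np.ndarray:
    """Harmonic volume-exclusion forces between overlapping actin segments."""
    if pairs is None:
        pairs = neighbor_pairs(state)
    f = _empty(state)
    sp = state.params.sim()
    if len(pairs):
        _core.repulsive_forces(state.pos, f, pairs, len(pairs),
                               state.seg_v1, state.seg_v2, sp.kr_A, sp.rc_A,
                               state.domain.box, state.domain.periodic)
    return f


def acp_forces(state: SimulationState) -> np.ndarray:
    """Cross-linker arm springs and hinge forces."""
    f = _empty(state)
    sp = state.params.sim()
    _core.acp_forces(state.pos, f, state.acp_center, state.acp_seg,
                     state.acp_site, state.seg_v1, state.seg_v2,
                     state.site_frac, sp.ks_ACP, sp.r0_ACP, sp.kb_ACP,
                     state.domain.box, state.domain.periodic)
    return f


def motor_arm_forces(state: SimulationState) -> np.ndarray:
    """Two-spring forces of every bound motor arm (and their reactions)."""
    f = _empty(state)
    sp = state.params.sim()
    _core.motor_arm_forces(state.pos, f, state.arm_bound, state.arm_anchor,
                           state.arm_seg, state.arm_site, state.seg_v1,
                           state.seg_v2, state.site_frac, sp.ks_M2, sp.r0_M2,
                           sp.ks_M3, state.domain.box, state.domain.periodic)
    return f


def wall_forces(state: SimulationState) -> np.ndarray:
    """Harmonic repulsive walls on non-periodic axes."""
    f = _empty(state)
    _core.wall_forces(state.pos, f, state.domain.box, state.domain.periodic,
                      state.params.sim().kr_A)
    return f


def all_forces(state: SimulationState,
               pairs: np.ndarray | None = None) -> ForceAccumulator:
    acc = ForceAccumulator(state.n_vertices)
    acc.add("stretch", stretch_forces(state))
    acc.add("bend", bend_forces(state))
    acc.add("repulsion", repulsive_forces(state, pairs))
    acc.add("acp", acp_forces(state))
    acc.add("motor_arm", motor_arm_forces(state))
    acc.add("wall", wall_forces(state))
    return acc


def arm_loads(state: SimulationState) -> np.ndarray:
    """Load opposing walking (pN) for every arm; 0 for unbound arms."""
    sp = state.params.sim()
    out = np.zeros(state.n_arms)
    for a in range(state.n_arms):
        if not state.arm_bound[a]:
            continue
        s = state.arm_seg[a]
        _, _, _, load = _core.arm_spring_force(
            state.pos, state.arm_anchor[a], state.seg_v1[s], state.seg_v2[s],
            state.site_frac[state.arm_site[a]], sp.ks_M2, sp.r0_M2, sp.ks_M3,
            state.domain.box, state.domain.periodic)
        out[a] = load
    return out


def distribute_to_endpoints(point_force: np.ndarray, s: float):
    """Split a point force applied at axial fraction ``s`` of a segment.

    The barbed-end vertex receives ``(1-s)*F`` and the pointed-end vertex
    ``s*F``; the shares always sum to the applied force exactly.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"axial fraction must be in [0, 1], got {s}")
    point_force = np.asarray(point_force, dtype=float)
    return (1.0 - s) * point_force, s * point_force


# ----------------------------------------------------------------------
# potentials (independent of the kernels; finite-difference oracle)
# ----------------------------------------------------------------------
def _mi(state, d):
    return state.domain.min_image(d)


def stretch_energy(state: SimulationState) -> float:
    d = _mi(state, state.pos[state.bond_j] - state.pos[state.bond_i])
    r = np.linalg.norm(d, axis=1)
    return float(0.5 * np.sum(state.bond_k * (r - state.bond_r0) ** 2))


def bend_energy(state: SimulationState) -> float:
    u = _mi(state, state.pos[state.ang_b] - state.pos[state.ang_a])
    v = _mi(state, state.pos[state.ang_c] - state.pos[state.ang_b])
    return float(np.sum(0.5 * state.ang_k * _angle(u, v) ** 2))


def _angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between consecutive segment directions (0 = straight)."""
    cu = np.linalg.norm(u, axis=-1)
    cv = np.linalg.norm(v, axis=-1)
    c = np.clip(np.einsum("...k,...k->...", u, v) / (cu * cv), -1.0, 1.0)
    return np.arccos(c)


def repulsion_energy(state: SimulationState,
                     pairs: np.ndarray | None = None) -> float:
    if pairs is None:
        pairs = neighbor_pairs(state)
    sp = state.params.sim()
    e = 0.0
    for s1, s2 in pairs:
        d = _segment_min_distance(state, int(s1), int(s2))
        if d < sp.rc_A:
            e += 0.5 * sp.kr_A * (d - sp.rc_A) ** 2
    return float(e)


def _segment_min_distance(state: SimulationState, s1: int, s2: int) -> float:
    p1 = state.pos[state.seg_v1[s1]]
    q1 = state.pos[state.seg_v2[s1]]
    p2 = state.pos[state.seg_v1[s2]]
    q2 = state.pos[state.seg_v2[s2]]
    shift = _mi(state, 0.5 * (p2 + q2) - 0.5 * (p1 + q1)) - \
        (0.5 * (p2 + q2) - 0.5 * (p1 + q1))
    _, _, _, _, _, dist = _core._segment_closest(p1, q1, p2 + shift, q2 + shift)
    return float(dist)


def acp_energy(state: SimulationState) -> float:
    sp = state.params.sim()
    e = 0.0
    for n in range(state.n_acps):
        c = state.pos[state.acp_center[n]]
        att = []
        for arm in range(2):
            s = state.acp_seg[n, arm]
            p = state.site_position(int(s), int(state.acp_site[n, arm]))
            d = _mi(state, p - c)
            e += 0.5 * sp.ks_ACP * (np.linalg.norm(d) - sp.r0_ACP) ** 2
            att.append(c + d)
        u = c - att[0]
        v = att[1] - c
        e += 0.5 * sp.kb_ACP * _angle(u[None], v[None])[0] ** 2
    return float(e)


def motor_arm_energy(state: SimulationState) -> float:
    sp = state.params.sim()
    e = 0.0
    for a in range(state.n_arms):
        if not state.arm_bound[a]:
            continue
        s = int(state.arm_seg[a])
        anchor = state.pos[state.arm_anchor[a]]
        p = state.site_position(s, int(state.arm_site[a]))
        d = _mi(state, p - anchor)
        seg = _mi(state, state.pos[state.seg_v2[s]] - state.pos[state.seg_v1[s]])
        u = seg / np.linalg.norm(seg)
        e += 0.5 * sp.ks_M2 * (np.linalg.norm(d) - sp.r0_M2) ** 2
        e += 0.5 * sp.ks_M3 * float(d @ u) ** 2
    return float(e)


def wall_energy(state: SimulationState) -> float:
    sp = state.params.sim()
    e = 0.0
    for ax in range(3):
        if state.domain.periodic[ax]:
            continue
        x = state.pos[:, ax]
        low = np.minimum(x, 0.0)
        high = np.maximum(x - state.domain.box[ax], 0.0)
        e += 0.5 * sp.kr_A * float(np.sum(low ** 2) + np.sum(high ** 2))
    return e


def total_energy(state: SimulationState,
                 pairs: np.ndarray | None = None) -> float:
    """Total potential energy (pN·nm) of the current configuration."""
    return (stretch_energy(state) + bend_energy(state) +
            repulsion_energy(state, pairs) + acp_energy(state) +
            motor_arm_energy(state) + wall_energy(state))
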