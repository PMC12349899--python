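"""Simulation state: the flat-array representation the engine advances.

A :class:`SystemAssembler` collects filaments, motors and cross-linkers
(produced by :mod:`actomyosim.model`) and finalizes them into a
:class:`SimulationState` whose numpy arrays feed the numba kernels directly.

Vertex kinds: 0 = actin, 1 = motor backbone, 2 = cross-linker center.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .model import Filament, MotorFilament
from .parameters import ParameterSet

__all__ = ["Domain", "SimulationState", "SystemAssembler",
           "VKIND_ACTIN", "VKIND_BACKBONE", "VKIND_ACP"]

VKIND_ACTIN = 0
VKIND_BACKBONE = 1
VKIND_ACP = 2

BOND_ACTIN = 0
BOND_BACKBONE = 1


@dataclass
class Domain:
    """Rectangular simulation box (nm) with per-axis boundary kind.

    Periodic axes use minimum-image distances everywhere; non-periodic axes
    carry harmonic repulsive walls at the two box faces.
    """

    box: np.ndarray
    periodic: np.ndarray

    @classmethod
    def from_um(cls, dims, periodic) -> "Domain":
        return cls(box=np.asarray(dims, dtype=float) * 1e3,
                   periodic=np.asarray(periodic, dtype=np.uint8))

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap coordinates on periodic axes into [0, box)."""
        out = np.array(positions, dtype=float, copy=True)
        for ax in range(3):
            if self.periodic[ax]:
                out[..., ax] %= self.box[ax]
        return out

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vector(s)."""
        out = np.array(d, dtype=float, copy=True)
        for ax in range(3):
            if self.periodic[ax]:
                out[..., ax] -= self.box[ax] * np.rint(out[..., ax] / self.box[ax])
        return out


@dataclass
class MotorInfo:
    """Bookkeeping for one motor filament inside a state."""

    first_vertex: int
    n_vertices: int
    N_a: int
    L_bz: float
    L_sp: float
    L_M: float
    arm_start: int        # index into the flat arm arrays
    arm_stop: int
    bare_zone: tuple[int, int]


@dataclass
class FilamentInfo:
    first_vertex: int
    n_segments: int
    first_segment: int


class SimulationState:
    """All vertices, connectivity, occupancy and kinetic state of a system.

    Instances are produced by :class:`SystemAssembler.build`; the attribute
    arrays are mutated in place by the engine (positions, occupancy, arm
    binding state) while the connectivity stays fixed — cross-links are
    permanent and motors neither assemble nor disassemble during a run.
    """

    def __init__(self, params: ParameterSet, domain: Domain, arrays: dict,
                 filaments: list[FilamentInfo], motors: list[MotorInfo],
                 seed: int):
        self.params = params
        self.domain = domain
        self.filaments = filaments
        self.motors = motors
        self.seed = seed
        self.time = 0.0
        for name, arr in arrays.items():
            setattr(self, name, arr)

    # -- convenience ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.pos.shape[0]

    @property
    def n_segments(self) -> int:
        return self.seg_v1.shape[0]

    @property
    def n_arms(self) -> int:
        return self.arm_anchor.shape[0]

    @property
    def n_acps(self) -> int:
        return self.acp_center.shape[0]

    def actin_vertex_mask(self) -> np.ndarray:
        return self.vkind == VKIND_ACTIN

    def site_position(self, seg: int, site: int) -> np.ndarray:
        """Cartesian position (nm) of a binding site (material point)."""
        v1, v2 = self.seg_v1[seg], self.seg_v2[seg]
        d = self.domain.min_image(self.pos[v2] - self.pos[v1])
        return self.pos[v1] + self.site_frac[site] * d

    def filament_of_segment(self, seg: int) -> int:
        return int(self.seg_fil[seg])

    def copy(self) -> "SimulationState":
        return copy.deepcopy(self)


class SystemAssembler:
    """Incremental construction of a :class:`SimulationState`.

    Filaments must be added before cross-linkers that bind them; occupancy
    is tracked during assembly so placements never double-book a site.
    """

    def __init__(self, params: ParameterSet, domain: Domain):
        self.params = params
        self.sp = params.sim()
        self.domain = domain
        self._pos: list[np.ndarray] = []
        self._zeta: list[float] = []
        self._mobile: list[bool] = []
        self._vkind: list[int] = []
        self._bonds: list[tuple[int, int, float, float, int]] = []
        self._angles: list[tuple[int, int, int, float]] = []
        self._seg: list[tuple[int, int, int]] = []   # v1, v2, filament
        self._fil: list[FilamentInfo] = []
        self._motors: list[MotorInfo] = []
        self._acp: list[tuple[int, int, int, int, int]] = []  # center, s0, k0, s1, k1
        self._occ_rows: list[np.ndarray] = []
        self._motor_models: list[MotorFilament] = []
        self.warnings: list[str] = []

    # -- vertices -------------------------------------------------------
    def _add_vertex(self, p, zeta, mobile, kind) -> int:
        self._pos.append(np.asarray(p, dtype=float))
        self._zeta.append(zeta)
        self._mobile.append(mobile)
        self._vkind.append(kind)
        return len(self._pos) - 1

    # -- elements -------------------------------------------------------
    def add_filament(self, fil: Filament, clamp_barbed: bool = False,
                     clamp_pointed: bool = False) -> int:
        """Add an actin filament; returns its filament id."""
        sp = self.sp
        first_v = len(self._pos)
        first_s = len(self._seg)
        fid = len(self._fil)
        n = fil.positions.shape[0]
        for i in range(n):
            mobile = not ((i == 0 and clamp_barbed) or
                          (i == n - 1 and clamp_pointed))
            self._add_vertex(fil.positions[i], sp.zeta_A, mobile, VKIND_ACTIN)
        for i in range(fil.segment_count):
            self._seg.append((first_v + i, first_v + i + 1, fid))
            self._bonds.append((first_v + i, first_v + i + 1,
                                fil.r0, sp.ks_A, BOND_ACTIN))
            self._occ_rows.append(np.zeros(sp.n_sites, dtype=np.int8))
        for i in range(1, fil.segment_count):
            self._angles.append((first_v + i - 1, first_v + i,
                                 first_v + i + 1, sp.kb_A))
        self._fil.append(FilamentInfo(first_v, fil.segment_count, first_s))
        return fid

    def add_motor(self, mot: MotorFilament) -> int:
        """Add a bipolar motor filament; returns its motor id."""
        sp = self.sp
        first_v = len(self._pos)
        n = mot.positions.shape[0]
        for i in range(n):
            self._add_vertex(mot.positions[i], sp.zeta_M, True, VKIND_BACKBONE)
        for i in range(mot.segment_count):
            self._bonds.append((first_v + i, first_v + i + 1,
                                float(mot.segment_lengths[i]), sp.ks_M1,
                                BOND_BACKBONE))
        for i in range(1, mot.segment_count):
            self._angles.append((first_v + i - 1, first_v + i,
                                 first_v + i + 1, sp.kb_M))
        arm_start = sum(m.N_a for m in self._motors)
        mid = len(self._motors)
        # arms are attached at assembly time through the flat arrays in build()
        self._motors.append(MotorInfo(
            first_vertex=first_v, n_vertices=n, N_a=mot.N_a, L_bz=mot.L_bz,
            L_sp=mot.L_sp, L_M=mot.L_M, arm_start=arm_start,
            arm_stop=arm_start + mot.N_a, bare_zone=mot.bare_zone))
        self._motor_models.append(mot)
        return mid

    def add_acp(self, seg0: int, site0: int, seg1: int, site1: int) -> int:
        """Add a permanent cross-linker bound to two sites.

        The two sites must be free and on distinct filaments; the center
        vertex is created at the midpoint of the two site positions.
        """
        if self._seg[seg0][2] == self._seg[seg1][2]:
            raise ValueError("cross-linker arms must bind distinct filaments")
        for s, k in ((seg0, site0), (seg1, site1)):
            if self._occ_rows[s][k] != 0:
                raise ValueError(f"site ({s}, {k}) already occupied")
        p0 = self._site_pos(seg0, site0)
        p1 = self._site_pos(seg1, site1)
        mid = p0 + 0.5 * self.domain.min_image(p1 - p0)
        c = self._add_vertex(mid, self.sp.zeta_ACP, True, VKIND_ACP)
        self._occ_rows[seg0][site0] = 1
        self._occ_rows[seg1][site1] = 1
        self._acp.append((c, seg0, site0, seg1, site1))
        return len(self._acp) - 1

    # -- queries used by placement logic --------------------------------
    def _site_pos(self, seg: int, site: int) -> np.ndarray:
        v1, v2, _ = self._seg[seg]
        frac = site * self.sp.site_spacing / self.sp.r0_A
        d = self.domain.min_image(self._pos[v2] - self._pos[v1])
        return self._pos[v1] + frac * d

    def site_is_free(self, seg: int, site: int) -> bool:
        return self._occ_rows[seg][site] == 0

    @property
    def n_filaments(self) -> int:
        return len(self._fil)

    @property
    def n_segments(self) -> int:
        return len(self._seg)

    def filament_segments(self, fid: int) -> range:
        info = self._fil[fid]
        return range(info.first_segment, info.first_segment + info.n_segments)

    def segment_filament(self, seg: int) -> int:
        return self._seg[seg][2]

    def segment_endpoints(self, seg: int) -> tuple[np.ndarray, np.ndarray]:
        v1, v2, _ = self._seg[seg]
        return self._pos[v1], self._pos[v2]

    # -- finalize -------------------------------------------------------
    def build(self, seed: int = 0) -> SimulationState:
        sp = self.sp
        n_v = len(self._pos)
        pos = self.domain.wrap(np.array(self._pos)) if n_v else np.zeros((0, 3))

        bonds = self._bonds
        angles = self._angles
        arrays = {
            "pos": np.ascontiguousarray(pos),
            "zeta": np.array(self._zeta, dtype=float),
            "mobile": np.array(self._mobile, dtype=np.uint8),
            "vkind": np.array(self._vkind, dtype=np.int8),
            "bond_i": np.array([b[0] for b in bonds], dtype=np.int64),
            "bond_j": np.array([b[1] for b in bonds], dtype=np.int64),
            "bond_r0": np.array([b[2] for b in bonds], dtype=float),
            "bond_k": np.array([b[3] for b in bonds], dtype=float),
            "bond_kind": np.array([b[4] for b in bonds], dtype=np.int8),
            "ang_a": np.array([a[0] for a in angles], dtype=np.int64),
            "ang_b": np.array([a[1] for a in angles], dtype=np.int64),
            "ang_c": np.array([a[2] for a in angles], dtype=np.int64),
            "ang_k": np.array([a[3] for a in angles], dtype=float),
            "seg_v1": np.array([s[0] for s in self._seg], dtype=np.int64),
            "seg_v2": np.array([s[1] for s in self._seg], dtype=np.int64),
            "seg_fil": np.array([s[2] for s in self._seg], dtype=np.int64),
            "fil_first_seg": np.array([f.first_segment for f in self._fil],
                                      dtype=np.int64),
            "occupancy": (np.array(self._occ_rows, dtype=np.int8)
                          if self._occ_rows else np.zeros((0, sp.n_sites),
                                                          dtype=np.int8)),
            "site_frac": np.arange(sp.n_sites) * sp.site_spacing / sp.r0_A,
        }

        # flat arm arrays
        anchors, refs, sibs, motor_of = [], [], [], []
        for mid, mot in enumerate(self._motor_models):
            info = self._motors[mid]
            fv = info.first_vertex
            for local, arm in enumerate(mot.arms):
                anchor = fv + arm.anchor_index
                if arm.side == "left":
                    ref = anchor + 1
                else:
                    ref = anchor - 1
                anchors.append(anchor)
                refs.append(ref)
                motor_of.append(mid)
                # sibling = the other arm sharing this anchor (pairs of two)
                sibs.append(info.arm_start + local + (1 if local % 2 == 0 else -1))
        n_arm = len(anchors)
        arrays.update({
            "arm_anchor": np.array(anchors, dtype=np.int64),
            "arm_ref": np.array(refs, dtype=np.int64),
            "arm_sibling": np.array(sibs, dtype=np.int64),
            "arm_motor": np.array(motor_of, dtype=np.int64),
            "arm_bound": np.zeros(n_arm, dtype=np.uint8),
            "arm_seg": np.full(n_arm, -1, dtype=np.int64),
            "arm_site": np.full(n_arm, -1, dtype=np.int64),
        })
        arrays.update({
            "acp_center": np.array([a[0] for a in self._acp], dtype=np.int64),
            "acp_seg": (np.array([(a[1], a[3]) for a in self._acp],
                                 dtype=np.int64)
                        if self._acp else np.zeros((0, 2), dtype=np.int64)),
            "acp_site": (np.array([(a[2], a[4]) for a in self._acp],
                                  dtype=np.int64)
                         if self._acp else np.zeros((0, 2), dtype=np.int64)),
        })
        state = SimulationState(self.params, self.domain, arrays,
                                list(self._fil), list(self._motors), seed)
        state.warnings = list(self.warnings)
        return state
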