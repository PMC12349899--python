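"""Coarse-grained element geometry: actin filaments, cross-linkers, motors.

The constructors here are purely deterministic geometry builders.  They know
nothing about the simulation state; :mod:`actomyosim.state` assembles their
output into flat arrays for the dynamics engine.

Conventions
-----------
* Filament vertices are ordered from the barbed end (index 0) to the pointed
  end.  Binding sites sit every ``site_spacing`` nm from the barbed-side
  endpoint of each segment, so a 140-nm segment carries 20 sites at axial
  offsets 0, 7, ..., 133 nm.
* A motor is a bipolar backbone: per side ``N_a/4 - 1`` arm-bearing segments
  of length ``L_sp`` flank a central arm-free bare zone of total length
  ``L_bz``.  Each arm-bearing endpoint carries two arms, each arm lumping
  ``N_h`` myosin heads.  Arms on the left half walk toward the left backbone
  end, arms on the right half toward the right end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterSet, drag_coefficient

__all__ = [
    "Filament", "ACP", "MotorArm", "MotorFilament",
    "build_filament", "build_motor", "drag_coefficient",
]


@dataclass
class Filament:
    """A semiflexible actin filament discretized into 140-nm segments."""

    positions: np.ndarray          # (n_vertices, 3) nm, index 0 = barbed end
    segment_count: int
    r0: float                      # segment rest length (nm)
    n_sites: int                   # binding sites per segment

    @property
    def length(self) -> float:
        return self.segment_count * self.r0

    def polarity_vectors(self) -> np.ndarray:
        """Per-segment unit vectors pointing barbed -> pointed."""
        d = np.diff(self.positions, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class ACP:
    """A permanent two-armed cross-linker (alpha-actinin-like).

    ``bound_sites`` holds up to two ``(filament, segment, site)`` triples;
    once both arms are engaged the link is never released.
    """

    center: np.ndarray             # (3,) nm
    r0_arm: float = 23.5
    bound_sites: list = field(default_factory=list)
    permanent: bool = True


@dataclass
class MotorArm:
    """One coarse motor arm standing in for ``head_count`` myosin heads."""

    anchor_index: int              # backbone vertex the arm hangs from
    side: str                      # "left" | "right"
    head_count: int = 8
    state: str = "unbound"
    bound_site: tuple | None = None


@dataclass
class MotorFilament:
    """A bipolar thick filament: backbone vertices plus paired arms."""

    positions: np.ndarray          # (n_vertices, 3) nm, left end first
    segment_lengths: np.ndarray    # (n_segments,) nm
    arms: list[MotorArm]
    N_a: int
    L_bz: float
    L_sp: float
    bare_zone: tuple[int, int]     # segment index range [start, stop) of bare zone

    @property
    def L_M(self) -> float:
        """Total backbone contour length (nm)."""
        return float(self.segment_lengths.sum())

    @property
    def segment_count(self) -> int:
        return len(self.segment_lengths)

    @property
    def arm_endpoints(self) -> list[int]:
        return sorted({a.anchor_index for a in self.arms})


def build_filament(length: float, origin=(0.0, 0.0, 0.0),
                   direction=(0.0, 0.0, 1.0),
                   params: ParameterSet | None = None) -> Filament:
    """Construct a straight filament of approximately ``length`` nm.

    The segment count is ``round(length / r0_A)`` with a minimum of one
    segment; segments keep the exact rest length ``r0_A``, so the realized
    contour length is the nearest multiple of 140 nm (a 9-µm request gives
    64 segments).  The barbed end sits at ``origin`` and the filament runs
    along ``direction``.
    """
    params = params or ParameterSet()
    if length < params.r0_A:
        raise ValueError(
            f"filament length {length} nm is below one segment ({params.r0_A} nm)")
    n_seg = max(1, round(length / params.r0_A))
    u = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    u = u / norm
    pos = np.asarray(origin, dtype=float) + \
        np.arange(n_seg + 1)[:, None] * params.r0_A * u
    return Filament(positions=pos, segment_count=n_seg, r0=params.r0_A,
                    n_sites=params.sites_per_segment)


def build_motor(N_a: int, L_bz: float, L_sp: float,
                center=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0),
                params: ParameterSet | None = None) -> MotorFilament:
    """Construct a bipolar motor filament with ``N_a`` arms.

    Parameters
    ----------
    N_a:
        Total arm count; must be >= 4 and divisible by 4 (two arms per
        endpoint, mirror-symmetric halves).
    L_bz:
        Bare-zone length (nm).  When it exceeds ``L_sp`` the bare zone is
        realized as ``ceil(L_bz / L_sp)`` equal arm-free segments (the
        bare-zone-enlarged architecture); otherwise as a single segment.
    L_sp:
        Arm spacing, i.e. the length of each arm-bearing backbone segment
        (nm).  Raising it above the 42-nm reference gives the uniformly
        stretched architecture.

    The total length satisfies ``L_M = 2*L_sp*(N_a/4 - 1) + L_bz`` exactly.
    For the degenerate ``N_a = 4`` the backbone is the bare zone alone and
    its two endpoints carry the arms.
    """
    params = params or ParameterSet()
    if N_a < 4 or N_a % 4 != 0:
        raise ValueError(f"N_a must be >= 4 and divisible by 4, got {N_a}")
    if L_bz <= 0 or L_sp <= 0:
        raise ValueError("L_bz and L_sp must be positive")

    n_side = N_a // 4 - 1                      # arm segments per side
    if L_bz > L_sp:
        m_bz = math.ceil(L_bz / L_sp)
    else:
        m_bz = 1
    bz_seg = L_bz / m_bz
    seg_lengths = np.concatenate([
        np.full(n_side, L_sp), np.full(m_bz, bz_seg), np.full(n_side, L_sp)])

    # vertex positions along `direction`, centered on the bare-zone midpoint
    s = np.concatenate([[0.0], np.cumsum(seg_lengths)])
    s -= s[-1] / 2.0
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    pos = np.asarray(center, dtype=float) + s[:, None] * u

    n_vert = len(s)
    left_endpoints = list(range(0, n_side + 1))
    right_endpoints = list(range(n_side + m_bz, n_vert))
    arms = [MotorArm(anchor_index=i, side="left", head_count=params.N_h)
            for i in left_endpoints for _ in range(2)]
    arms += [MotorArm(anchor_index=i, side="right", head_count=params.N_h)
             for i in right_endpoints for _ in range(2)]
    assert len(arms) == N_a

    return MotorFilament(positions=pos, segment_lengths=seg_lengths,
                         arms=arms, N_a=N_a, L_bz=L_bz, L_sp=L_sp,
                         bare_zone=(n_side, n_side + m_bz))
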