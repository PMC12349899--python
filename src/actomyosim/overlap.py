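"""Contractile-unit overlap theory.

Whether two bipolar motors can add their forces depends on how far they
overlap: a cross-linker between the arm-bearing stretches of two motors
counterbalances one of them, so cooperative force addition needs an overlap
of at least the critical length

    ``L_c = 2 * L_sp * (N_a / 4 - 1)``

(twice the length occupied by the arms on one side of a backbone).  The
pair weight is ``xi = 1`` for ``L_ov >= L_c``, ``L_ov / L_c`` for partial
overlap, ``0`` for none.  The effective maximum number of cooperatively
overlapping motors is

    ``Xi = max over motors i and sides j of (1 + sum_k xi_ik^j)``

which ranges from 1 (no overlap anywhere) to the motor count, and predicts
the structure-level force

    ``F_est = F_st * N_h * N_a * Xi / 2``.

The side restriction is implemented as: for side L (resp. R) of motor i,
only neighbors whose center lies at or left (resp. right) of motor i's
bare-zone center contribute; a neighbor whose span contains the center
contributes to both sides.  For 2D networks, motors pair only if their
axes differ by less than 30 degrees and overlap is measured along the
pair's mean axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterSet
from .state import SimulationState

__all__ = ["MotorPlacement", "OverlapReport", "critical_length",
           "xi_from_overlap", "overlap_length", "pairwise_xi", "xi_max",
           "estimate_force", "analyze", "placements_from_state",
           "sample_bundle_placements"]

#: maximum axis misalignment (rad) for a network motor pair to interact
NETWORK_ANGLE_CUTOFF = math.radians(30.0)


@dataclass
class MotorPlacement:
    """Geometric stand-in for one motor in the overlap analysis.

    ``center`` is a scalar z for bundles or an (x, y) pair for networks;
    ``direction`` (networks) is the in-plane backbone axis.
    """

    center: float | np.ndarray
    N_a: int = 24
    L_bz: float = 42.0
    L_sp: float = 42.0
    direction: np.ndarray | None = None

    @property
    def L_M(self) -> float:
        return 2.0 * self.L_sp * (self.N_a // 4 - 1) + self.L_bz

    @property
    def L_c(self) -> float:
        return critical_length(self.N_a, self.L_sp)


@dataclass
class OverlapReport:
    """Pairwise cooperativity and the resulting force prediction."""

    L_c: float
    xi: np.ndarray            # (N, N, 2): sides L, R; xi[i, i, :] = 0
    Xi: float
    F_est: float
    argmax: tuple[int, str]   # motor index and side realizing Xi

    def to_dict(self) -> dict:
        return {"L_c_nm": self.L_c, "Xi": self.Xi, "F_est_pN": self.F_est,
                "argmax_motor": int(self.argmax[0]),
                "argmax_side": self.argmax[1]}


def critical_length(N_a: int, L_sp: float) -> float:
    """Critical overlap length (nm) for cooperative force addition."""
    if N_a < 4 or N_a % 4 != 0:
        raise ValueError(f"N_a must be >= 4 and divisible by 4, got {N_a}")
    return 2.0 * L_sp * (N_a // 4 - 1)


def xi_from_overlap(L_ov: float, L_c: float) -> float:
    """The three-branch pair weight; degenerate ``L_c = 0`` counts any
    contact as fully cooperative."""
    if L_ov < 0:
        raise ValueError("overlap length cannot be negative")
    if L_ov == 0.0:
        return 0.0
    if L_c <= 0.0 or L_ov >= L_c:
        return 1.0
    return L_ov / L_c


def _interval_overlap(c1: float, L1: float, c2: float, L2: float,
                      box: float | None) -> tuple[float, float]:
    """Overlap length of two centered intervals and the (min-image) offset
    of center 2 relative to center 1."""
    d = c2 - c1
    if box is not None:
        d -= box * round(d / box)
    ov = 0.5 * (L1 + L2) - abs(d)
    return max(0.0, min(ov, min(L1, L2))), d


def overlap_length(m1: MotorPlacement, m2: MotorPlacement,
                   box: float | None = None,
                   mode: str = "bundle") -> tuple[float, float]:
    """Overlap length (nm) and signed center offset of motor 2 vs motor 1.

    Bundles: overlap of the backbone z intervals, minimum-image aware.
    Networks: zero unless the axes are within 30 degrees; otherwise the
    overlap of both spans projected onto the pair's mean axis.
    """
    if mode == "bundle":
        return _interval_overlap(float(m1.center), m1.L_M,
                                 float(m2.center), m2.L_M, box)
    if mode != "network":
        raise ValueError(f"unknown mode {mode!r}")
    u1 = np.asarray(m1.direction, dtype=float)[:2]
    u2 = np.asarray(m2.direction, dtype=float)[:2]
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    if u2 @ u1 < 0:                      # bipolar: axis sign is arbitrary
        u2 = -u2
    ang = math.acos(min(1.0, abs(float(u1 @ u2))))
    if ang >= NETWORK_ANGLE_CUTOFF:
        return 0.0, 0.0
    mean = u1 + u2
    mean /= np.linalg.norm(mean)
    c1 = float(np.asarray(m1.center, dtype=float)[:2] @ mean)
    c2 = float(np.asarray(m2.center, dtype=float)[:2] @ mean)
    return _interval_overlap(c1, m1.L_M, c2, m2.L_M, None)


def pairwise_xi(m1: MotorPlacement, m2: MotorPlacement, side: str,
                L_c: float, box: float | None = None,
                mode: str = "bundle") -> float:
    """Pair weight of motor 2 on the given side ('L'/'R') of motor 1."""
    L_ov, d = overlap_length(m1, m2, box, mode)
    if L_ov == 0.0:
        return 0.0
    spans_center = L_ov > 0 and abs(d) < m2.L_M / 2.0
    if side == "L":
        ok = d <= 0 or spans_center
    elif side == "R":
        ok = d >= 0 or spans_center
    else:
        raise ValueError("side must be 'L' or 'R'")
    return xi_from_overlap(L_ov, L_c) if ok else 0.0


def xi_max(motors: list[MotorPlacement], box: float | None = None,
           mode: str = "bundle") -> OverlapReport:
    """Evaluate the overlap theory for a motor configuration."""
    n = len(motors)
    if n == 0:
        raise ValueError("Xi undefined for zero motors")
    L_c = motors[0].L_c
    if mode == "bundle":
        xi = _xi_matrix_bundle(motors, L_c, box)
    else:
        xi = np.zeros((n, n, 2))
        for i, mi in enumerate(motors):
            for k, mk in enumerate(motors):
                if k == i:
                    continue
                xi[i, k, 0] = pairwise_xi(mi, mk, "L", L_c, box, mode)
                xi[i, k, 1] = pairwise_xi(mi, mk, "R", L_c, box, mode)
    totals = 1.0 + xi.sum(axis=1)          # (n, 2)
    flat = int(np.argmax(totals))
    i_best, j_best = divmod(flat, 2)
    Xi = float(totals[i_best, j_best])
    p = ParameterSet()
    F_est = estimate_force(Xi, motors[0].N_a, p.N_h, p.F_st)
    return OverlapReport(L_c=L_c, xi=xi, Xi=Xi, F_est=F_est,
                         argmax=(i_best, "L" if j_best == 0 else "R"))


def _xi_matrix_bundle(motors: list[MotorPlacement], L_c: float,
                      box: float | None) -> np.ndarray:
    """Vectorized pairwise xi for the 1D (bundle) geometry.

    Same semantics as :func:`pairwise_xi`, evaluated for all ordered pairs
    at once (needed for the dense-motor sweeps, where the pair count grows
    quadratically).
    """
    c = np.array([float(m.center) for m in motors])
    L = np.array([m.L_M for m in motors])
    d = c[None, :] - c[:, None]              # offset of k relative to i
    if box is not None:
        d -= box * np.rint(d / box)
    ov = 0.5 * (L[:, None] + L[None, :]) - np.abs(d)
    ov = np.clip(ov, 0.0, np.minimum(L[:, None], L[None, :]))
    if L_c <= 0.0:
        w = (ov > 0).astype(float)
    else:
        w = np.where(ov >= L_c, 1.0, ov / L_c)
        w[ov == 0.0] = 0.0
    spans = (ov > 0) & (np.abs(d) < L[None, :] / 2.0)
    xi = np.zeros((len(motors), len(motors), 2))
    xi[:, :, 0] = w * ((d <= 0) | spans)
    xi[:, :, 1] = w * ((d >= 0) | spans)
    np.einsum("iij->ij", xi)[:] = 0.0        # no self-pairing
    return xi


def estimate_force(Xi: float, N_a: int, N_h: int = 8,
                   F_st: float = 5.7) -> float:
    """Predicted structure-level force ``F_st * N_h * N_a * Xi / 2`` (pN)."""
    if Xi < 1.0:
        raise ValueError("Xi is at least 1")
    return F_st * N_h * N_a * Xi / 2.0


def analyze(motors: list[MotorPlacement], box: float | None = None,
            mode: str = "bundle") -> OverlapReport:
    """Alias of :func:`xi_max` under the name the CLI exposes."""
    return xi_max(motors, box, mode)


# ----------------------------------------------------------------------
def placements_from_state(state: SimulationState,
                          mode: str = "bundle") -> list[MotorPlacement]:
    """Extract nominal motor placements from a simulation state.

    Centers are backbone midpoints (bundle: z; network: x, y with the
    end-to-end axis); architecture comes from the motor records, keeping
    the nominal lengths rather than the instantaneous stretched ones.
    """
    out = []
    for m in state.motors:
        verts = state.pos[m.first_vertex:m.first_vertex + m.n_vertices]
        if mode == "bundle":
            center = float(verts[:, 2].mean())
            direction = None
        else:
            center = verts[:, :2].mean(axis=0)
            direction = verts[-1, :2] - verts[0, :2]
        out.append(MotorPlacement(center=center, N_a=m.N_a, L_bz=m.L_bz,
                                  L_sp=m.L_sp, direction=direction))
    return out


def sample_bundle_placements(n_motors: int, rng: np.random.Generator,
                             box_nm: float = 20000.0, f: float = 1.0,
                             N_a: int = 24, L_bz: float = 42.0,
                             L_sp: float = 42.0) -> list[MotorPlacement]:
    """Motor centers uniform in the f-window of a periodic bundle.

    The same placement rule the bundle builder uses, at theory level: the
    window of length ``f * box`` is centered at ``box / 2``.
    """
    z = box_nm / 2.0 + f * box_nm * (rng.uniform(size=n_motors) - 0.5)
    return [MotorPlacement(center=float(zz) % box_nm, N_a=N_a, L_bz=L_bz,
                           L_sp=L_sp) for zz in z]
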