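"""Contractile-force measurement by cross-section bookkeeping.

The structure-level tension is obtained by slicing the box with evenly
spaced planes normal to the bundle axis (every 200 nm by default), summing
the axial component of the *extensional* (spring) force of every element
crossing each plane — actin segments, cross-linker arms, motor arms and
motor backbones — and averaging over planes and steady-state frames.
Tension counts positive, compression negative, so the plane sum is the net
tensile load transmitted across the section.

The maximal motor force uses the same spring forces: per motor the summed
magnitude of the axial components of its arm forces, halved for bundles
(each side pulls one polarity) or quarter-summed over x and y for 2D
networks.  The force-generation efficiency is ``eta = F_tot / F_M_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from .state import BOND_ACTIN, BOND_BACKBONE, SimulationState

__all__ = ["CrossSectionRecord", "MeasurementResult", "cross_section_forces",
           "section_totals", "motor_axial_forces", "motor_max_force",
           "efficiency", "steady_state_window", "total_force", "Measurement",
           "acp_arm_tensions", "CATEGORY_NAMES"]

CATEGORY_NAMES = ("actin", "acp", "motor_arm", "motor_backbone")


@dataclass
class CrossSectionRecord:
    """Signed tensile force (pN) carried across one plane, by category."""

    axis: str
    coordinate: float                  # plane position (nm)
    actin: float = 0.0
    acp: float = 0.0
    motor_arm: float = 0.0
    motor_backbone: float = 0.0

    @property
    def total(self) -> float:
        return self.actin + self.acp + self.motor_arm + self.motor_backbone


@dataclass
class MeasurementResult:
    """Summary of a force measurement over the steady-state window."""

    F_tot: float
    F_M_max: float
    eta: float
    times: np.ndarray
    series: np.ndarray                 # plane-averaged total per frame
    steady_window: tuple[float, float]
    steady_flag: bool                  # True if a qualifying window was found
    F_M_per_motor: np.ndarray
    plane_profile: np.ndarray | None = None   # steady-window mean per plane

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "F_tot_pN": self.series})


# ----------------------------------------------------------------------
# instantaneous cross-section sums
# ----------------------------------------------------------------------
def _connectors(state: SimulationState):
    """All two-point force-bearing elements: (a, b, F_on_b, category).

    ``a``/``b`` are endpoint coordinates (nm, wrapped) and ``F_on_b`` the
    spring force the connector exerts on endpoint ``b``; the crossing rule
    needs exactly this pair.  Bending/hinge forces are excluded — the
    section sums count extensional forces only.
    """
    sp = state.params.sim()
    dom = state.domain
    pos = state.pos
    out_a, out_b, out_f, out_cat = [], [], [], []

    # actin + backbone bonds
    d = dom.min_image(pos[state.bond_j] - pos[state.bond_i])
    r = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = d / r[:, None]
    tension = state.bond_k * (r - state.bond_r0)
    f_on_j = -tension[:, None] * u         # stretched bond pulls j toward i
    out_a.append(pos[state.bond_i])
    out_b.append(pos[state.bond_i] + d)
    out_f.append(f_on_j)
    out_cat.append(np.where(state.bond_kind == BOND_ACTIN, 0, 3))

    # cross-linker arms: center -> attachment site
    if state.n_acps:
        for arm in range(2):
            segs = state.acp_seg[:, arm]
            v1 = state.seg_v1[segs]
            v2 = state.seg_v2[segs]
            frac = state.site_frac[state.acp_site[:, arm]][:, None]
            dseg = dom.min_image(pos[v2] - pos[v1])
            att = pos[v1] + frac * dseg
            c = pos[state.acp_center]
            d = dom.min_image(att - c)
            r = np.linalg.norm(d, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                u = np.where(r[:, None] > 0, d / np.maximum(r, 1e-12)[:, None], 0.0)
            tension = sp.ks_ACP * (r - sp.r0_ACP)
            out_a.append(c)
            out_b.append(c + d)
            out_f.append(-tension[:, None] * u)
            out_cat.append(np.full(len(segs), 1))

    # motor arms: anchor -> attachment, transverse + longitudinal springs
    bound = np.nonzero(state.arm_bound)[0]
    if len(bound):
        fa, fb, fc = [], [], []
        for a in bound:
            s = int(state.arm_seg[a])
            fx, fy, fz, _ = _core.arm_spring_force(
                pos, state.arm_anchor[a], state.seg_v1[s], state.seg_v2[s],
                state.site_frac[state.arm_site[a]], sp.ks_M2, sp.r0_M2,
                sp.ks_M3, dom.box, dom.periodic)
            anchor = pos[state.arm_anchor[a]]
            v1, v2 = state.seg_v1[s], state.seg_v2[s]
            dseg = dom.min_image(pos[v2] - pos[v1])
            att = pos[v1] + state.site_frac[state.arm_site[a]] * dseg
            d = dom.min_image(att - anchor)
            fa.append(anchor)
            fb.append(anchor + d)
            fc.append([fx, fy, fz])    # force the springs exert on the site
        out_a.append(np.array(fa))
        out_b.append(np.array(fb))
        out_f.append(np.array(fc))
        out_cat.append(np.full(len(bound), 2))

    return (np.concatenate(out_a), np.concatenate(out_b),
            np.concatenate(out_f), np.concatenate(out_cat))


def section_totals(state: SimulationState, axis: str = "z",
                   spacing: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-plane category sums of axial spring forces.

    Returns ``(coords, sums)`` where ``coords`` holds the plane positions
    (planes sit at half-spacing offsets, e.g. 100, 300, ... nm) and ``sums``
    is an ``(n_planes, 4)`` array over ``CATEGORY_NAMES``.  Crossings are
    minimum-image aware on periodic axes; each crossing contributes the
    axial component of its spring force, signed + for tension.
    """
    ax = "xyz".index(axis)
    L = state.domain.box[ax]
    n_planes = int(round(L / spacing))
    coords = (np.arange(n_planes) + 0.5) * spacing
    sums = np.zeros((n_planes, 4))

    a, b, f, cat = _connectors(state)
    xa = a[:, ax]
    xb = b[:, ax]            # = xa + min-image displacement (can leave box)
    lo = np.minimum(xa, xb)
    hi = np.maximum(xa, xb)
    # tension convention: contribution = -(force on upper endpoint) . axis
    contrib = np.where(xb >= xa, -f[:, ax], f[:, ax])

    m_lo = np.ceil(lo / spacing - 0.5).astype(int)
    m_hi = np.floor(hi / spacing - 0.5).astype(int)   # inclusive
    periodic = bool(state.domain.periodic[ax])
    for n in range(len(xa)):
        if m_hi[n] < m_lo[n]:
            continue
        for m in range(m_lo[n], m_hi[n] + 1):
            if periodic:
                sums[m % n_planes, cat[n]] += contrib[n]
            elif 0 <= m < n_planes:
                sums[m, cat[n]] += contrib[n]
    return coords, sums


def cross_section_forces(state: SimulationState, axis: str = "z",
                         spacing: float = 200.0) -> list[CrossSectionRecord]:
    """Cross-section tension records for every plane along ``axis``."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords, sums = section_totals(state, axis, spacing)
    return [CrossSectionRecord(axis=axis, coordinate=float(c),
                               actin=float(s[0]), acp=float(s[1]),
                               motor_arm=float(s[2]), motor_backbone=float(s[3]))
            for c, s in zip(coords, sums)]


# ----------------------------------------------------------------------
# motor forces and efficiency
# ----------------------------------------------------------------------
def motor_axial_forces(state: SimulationState, axis: str = "z") -> np.ndarray:
    """Per-motor sum of |axial components| of its arm spring forces (pN)."""
    sp = state.params.sim()
    ax = "xyz".index(axis)
    out = np.zeros(len(state.motors))
    for a in np.nonzero(state.arm_bound)[0]:
        s = int(state.arm_seg[a])
        fvec = _core.arm_spring_force(
            state.pos, state.arm_anchor[a], state.seg_v1[s], state.seg_v2[s],
            state.site_frac[state.arm_site[a]], sp.ks_M2, sp.r0_M2, sp.ks_M3,
            state.domain.box, state.domain.periodic)
        out[state.arm_motor[a]] += abs(fvec[ax])
    return out


def motor_max_force(state: SimulationState, mode: str = "bundle") -> float:
    """Maximal collective motor force ``F_M_max`` (pN).

    ``bundle`` (also the two-filament geometry): half the summed z-axial
    arm forces of all motors.  ``network``: a quarter of the summed x- plus
    y-axial arm forces.
    """
    if len(state.motors) == 0:
        raise ValueError("F_M_max undefined without motors")
    if mode == "bundle":
        return 0.5 * float(motor_axial_forces(state, "z").sum())
    if mode == "network":
        return 0.25 * float(motor_axial_forces(state, "x").sum() +
                            motor_axial_forces(state, "y").sum())
    raise ValueError(f"unknown mode {mode!r}")


def efficiency(F_tot: float, F_M_max: float) -> float:
    """Force-generation efficiency ``eta = F_tot / F_M_max``."""
    if F_M_max <= 0:
        raise ValueError("eta undefined for F_M_max <= 0")
    return F_tot / F_M_max


def acp_arm_tensions(state: SimulationState) -> np.ndarray:
    """Mean arm spring tension (pN) of each cross-linker."""
    sp = state.params.sim()
    out = np.zeros(state.n_acps)
    for n in range(state.n_acps):
        c = state.pos[state.acp_center[n]]
        for arm in range(2):
            p = state.site_position(int(state.acp_seg[n, arm]),
                                    int(state.acp_site[n, arm]))
            r = np.linalg.norm(state.domain.min_image(p - c))
            out[n] += 0.5 * sp.ks_ACP * (r - sp.r0_ACP)
    return out


# ----------------------------------------------------------------------
# time-series handling
# ----------------------------------------------------------------------
def steady_state_window(series: np.ndarray, min_frames: int = 20,
                        rel_slope: float = 1e-2) -> tuple[int, int, bool]:
    """Earliest steady window of a force time series.

    Scans start indices for the earliest window ``[i, end)`` of at least
    ``min_frames`` frames whose linear-trend change over the window,
    normalized by the window mean, is below ``rel_slope``.  Returns
    ``(start, stop, found)``; without a qualifying window the tail of
    ``min_frames`` frames is returned with ``found = False``.
    """
    n = len(series)
    if n < max(min_frames, 50):
        raise ValueError(f"need at least {max(min_frames, 50)} frames, got {n}")
    x = np.arange(n, dtype=float)
    for i in range(0, n - min_frames + 1):
        y = series[i:]
        slope = np.polyfit(x[i:], y, 1)[0]
        mean = np.mean(y)
        if mean == 0.0:
            continue
        if abs(slope) * len(y) / abs(mean) < rel_slope:
            return i, n, True
    warnings.warn("no steady-state window found; using trailing frames")
    return n - min_frames, n, False


def total_force(frame_sums: np.ndarray) -> float:
    """``F_tot``: mean of section totals over planes and steady frames.

    ``frame_sums`` is ``(n_frames, n_planes)``; fewer than 10 frames are
    rejected as too short to average.
    """
    frame_sums = np.atleast_2d(frame_sums)
    if frame_sums.shape[0] < 10:
        raise ValueError("steady window shorter than 10 frames")
    return float(frame_sums.mean())


class Measurement:
    """Accumulates per-frame cross-section and motor forces during a run.

    For bundles and the two-filament system sample along z; for networks
    along x and y (20 planes each by default).
    """

    def __init__(self, state: SimulationState, mode: str = "bundle",
                 spacing: float = 200.0):
        self.state = state
        self.mode = mode
        if mode == "network":
            self.spacing = (state.domain.box[0] / 20.0,
                            state.domain.box[1] / 20.0)
        else:
            self.spacing = (spacing,)
        self.times: list[float] = []
        self.plane_means: list[float] = []
        self.frame_planes: list[np.ndarray] = []
        self.frame_categories: list[np.ndarray] = []
        self.fm_per_motor: list[np.ndarray] = []

    def sample(self) -> None:
        st = self.state
        if self.mode == "network":
            _, sx = section_totals(st, "x", self.spacing[0])
            _, sy = section_totals(st, "y", self.spacing[1])
            cats = np.concatenate([sx, sy], axis=0)
            # per-motor x+y axial force; F_M_max applies the 1/4 at summary
            fm = motor_axial_forces(st, "x") + motor_axial_forces(st, "y")
        else:
            _, cats = section_totals(st, "z", self.spacing[0])
            fm = motor_axial_forces(st, "z")
        planes = cats.sum(axis=1)
        self.times.append(st.time)
        self.frame_planes.append(planes)
        self.frame_categories.append(cats)
        self.plane_means.append(float(planes.mean()))
        self.fm_per_motor.append(fm)

    def result(self) -> MeasurementResult:
        series = np.asarray(self.plane_means)
        times = np.asarray(self.times)
        i0, i1, found = steady_state_window(series)
        frames = np.asarray(self.frame_planes)[i0:i1]
        F_tot = total_force(frames)
        fm = np.asarray(self.fm_per_motor)[i0:i1].mean(axis=0)
        factor = 0.25 if self.mode == "network" else 0.5
        F_M_max = factor * float(fm.sum())
        return MeasurementResult(
            F_tot=F_tot, F_M_max=F_M_max, eta=efficiency(F_tot, F_M_max),
            times=times, series=series,
            steady_window=(float(times[i0]), float(times[i1 - 1])),
            steady_flag=found, F_M_per_motor=fm,
            plane_profile=frames.mean(axis=0))

    def export_csv(self, path) -> None:
        """One row per (time, plane) with per-category and total forces (pN)."""
        rows = []
        for t, cats in zip(self.times, self.frame_categories):
            for i, c in enumerate(cats):
                rows.append((t, i, *c, c.sum()))
        cols = (["time_s", "plane"] +
                [f"{name}_pN" for name in CATEGORY_NAMES] + ["total_pN"])
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
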