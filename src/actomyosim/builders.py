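"""Constructors for the three simulated systems.

* two-filament: an antiparallel pair of clamped filaments with motors and
  cross-linkers in the overlap — the minimal contractile unit.
* bundle: ``2*N_F**2`` filaments on an ``N_F x N_F`` lane grid (27-nm pitch),
  random z offsets and polarities, fully periodic box.
* network: a thin quasi-2D sheet of filaments grown by stochastic
  nucleation/polymerization, random in-plane orientations.

Builders are deterministic for a given spec and seed.  They only construct
geometry and place binders; the initialization phase in which motor arms
attach while actin is held frozen is the engine's ``settle`` step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import init_crosslinks
from .model import build_filament, build_motor
from .parameters import ParameterSet
from .state import Domain, SimulationState, SystemAssembler

__all__ = ["SystemSpec", "build_two_filament_system", "build_bundle",
           "build_network", "place_binders", "grow_network_filaments",
           "calibrate_polymerization", "density_calibration"]

#: printed calibration pairs between area densities and counts: at motor
#: density R_M = 0.005 the N_F = 2 bundle holds 4 motors and the N_F = 7
#: bundle 52; the cross-linker density R_ACP = 0.04 is the dense reference.
DENSITY_PAIRS = {
    ("R_M", 0.005, 2): 4,
    ("R_M", 0.005, 7): 52,
}


def density_calibration(R_M: float, N_F: int) -> int:
    """Documented density-to-count lookup (no closed formula is defined)."""
    key = ("R_M", R_M, N_F)
    if key in DENSITY_PAIRS:
        return DENSITY_PAIRS[key]
    raise KeyError(
        f"no calibration pair for R_M={R_M}, N_F={N_F}; pass N_M explicitly")


@dataclass
class SystemSpec:
    """Declarative description of a simulated system."""

    kind: str = "two_filament"       # two_filament | bundle | network
    domain_um: tuple | None = None   # box dimensions; per-kind default if None
    filament_length_nm: float | None = None
    N_F: int = 2                     # bundle lane-grid parameter
    N_M: int = 2                     # motor count
    N_ACP: int = 16                  # cross-linker count
    f: float = 1.0                   # motor-localization fraction (0, 1]
    min_motor_gap_nm: float = 0.0    # sparse placement: minimum span gap
    N_a: int = 24                    # arms per motor
    L_bz: float = 42.0               # bare-zone length (nm)
    L_sp: float = 42.0               # arm spacing (nm)
    seed: int = 0
    network_target_segments: int = 2000
    network_mean_length_nm: float = 10000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.f <= 1.0:
            raise ValueError("f must be in (0, 1]")
        if self.kind not in ("two_filament", "bundle", "network"):
            raise ValueError(f"unknown system kind {self.kind!r}")
        if self.kind == "bundle" and self.N_F < 1:
            raise ValueError("N_F must be >= 1")

    @property
    def bundle_filament_count(self) -> int:
        return 2 * self.N_F ** 2

    def domain(self) -> Domain:
        if self.domain_um is not None:
            dims = self.domain_um
        elif self.kind == "network":
            dims = (20.0, 20.0, 0.1)
        else:
            dims = (5.0, 5.0, 20.0)
        if self.kind == "bundle":
            periodic = (1, 1, 1)
        else:
            periodic = (1, 1, 0)
        return Domain.from_um(dims, periodic)


# ----------------------------------------------------------------------
def build_two_filament_system(spec: SystemSpec,
                              params: ParameterSet | None = None
                              ) -> SimulationState:
    """The minimal system: two clamped antiparallel filaments.

    One filament's barbed end is clamped at the bottom z boundary, the
    other's at the top; they run 27 nm apart in x so a motor centered
    between them sits at the 13.5-nm arm equilibrium from both.  Motors
    (backbones along z) and cross-linkers are placed at uniform random z
    inside the antiparallel overlap.
    """
    params = params or ParameterSet()
    if spec.kind != "two_filament":
        raise ValueError("spec.kind must be 'two_filament'")
    dom = spec.domain()
    L_f = spec.filament_length_nm or 19000.0
    Lz = dom.box[2]
    if L_f > Lz:
        raise ValueError(f"filament ({L_f} nm) longer than domain ({Lz} nm)")
    if 2 * L_f <= Lz:
        raise ValueError("filaments do not overlap; need 2*length > box z")
    rng = np.random.default_rng(spec.seed)
    cx, cy = dom.box[0] / 2.0, dom.box[1] / 2.0
    asm = SystemAssembler(params, dom)
    asm.add_filament(build_filament(L_f, origin=(cx - 13.5, cy, 0.0),
                                    direction=(0, 0, 1), params=params),
                     clamp_barbed=True)
    asm.add_filament(build_filament(L_f, origin=(cx + 13.5, cy, Lz),
                                    direction=(0, 0, -1), params=params),
                     clamp_barbed=True)
    z_lo, z_hi = Lz - L_f, L_f                 # antiparallel overlap
    motor = build_motor(spec.N_a, spec.L_bz, spec.L_sp, params=params)
    half = motor.L_M / 2.0
    for _ in range(spec.N_M):
        z = rng.uniform(z_lo + half, z_hi - half)
        asm.add_motor(build_motor(spec.N_a, spec.L_bz, spec.L_sp,
                                  center=(cx, cy, z), direction=(0, 0, 1),
                                  params=params))
    init_crosslinks(asm, spec.N_ACP, rng, z_range=(z_lo, z_hi))
    return asm.build(seed=spec.seed)


# ----------------------------------------------------------------------
def _lane_positions(N_F: int, box: np.ndarray, pitch: float = 27.0):
    """(x, y) lane coordinates of the N_F x N_F grid, centered in the box."""
    offs = (np.arange(N_F) - (N_F - 1) / 2.0) * pitch
    cx, cy = box[0] / 2.0, box[1] / 2.0
    return [(cx + ox, cy + oy) for ox in offs for oy in offs]


def _motor_sites(N_F: int, box: np.ndarray, pitch: float = 27.0):
    """(x, y) positions for motor backbones: interior cell centers.

    A cell center sits 19.1 nm (diagonal) from its four surrounding lanes,
    all inside the arms' capture radius, so a motor there can reach several
    filaments of each polarity — the regime in which every motor can engage
    fully.  An N_F = 1 grid has no interior cell; the lane itself is used.
    """
    if N_F < 2:
        return _lane_positions(N_F, box, pitch)
    offs = (np.arange(N_F - 1) - (N_F - 2) / 2.0) * pitch
    cx, cy = box[0] / 2.0, box[1] / 2.0
    return [(cx + ox, cy + oy) for ox in offs for oy in offs]


def _draw_filament_layout(spec: SystemSpec, rng: np.random.Generator,
                          Lz: float, L_f: float):
    """(z offset, polarity) per filament, redrawn until the bundle spans z.

    A cross-section force measurement presumes a bundle that actually spans
    the (periodic) box, and tension can only hand over from one filament to
    the next where two filaments coexist for a cross-linker to bridge.
    Short filaments at unlucky offsets can leave z intervals covered by one
    filament or none — a gap, not a bundle.  Offsets are redrawn
    (deterministically, from the same stream) until every z is covered by
    at least two filaments (or one, if the total actin cannot support two).
    """
    n_fil = 2 * spec.N_F ** 2
    need = 2 if L_f * n_fil >= 2.0 * Lz else 1
    if L_f * n_fil < Lz:
        need = 0
    zgrid = np.arange(0.0, Lz, 7.0)
    for _ in range(400):
        z0 = rng.uniform(0.0, Lz, size=n_fil)
        sign = np.where(rng.random(n_fil) < 0.5, 1.0, -1.0)
        cov = np.zeros(len(zgrid))
        for z, s in zip(z0, sign):
            rel = ((zgrid - z) * s) % Lz
            cov += rel <= L_f
        if cov.min() >= need:
            return z0, sign
    raise RuntimeError("could not draw a z-spanning bundle")


def build_bundle(spec: SystemSpec,
                 params: ParameterSet | None = None) -> SimulationState:
    """A disorganized bundle of ``2*N_F**2`` filaments.

    Two filaments per lane, each at a uniform random z offset (wrapping
    through the periodic z boundary) with random polarity, conditioned on
    the bundle spanning the box; motors and cross-linkers are then placed
    by :func:`place_binders`.
    """
    params = params or ParameterSet()
    dom = spec.domain()
    rng = np.random.default_rng(spec.seed)
    L_f = spec.filament_length_nm or 9000.0
    Lz = dom.box[2]
    asm = SystemAssembler(params, dom)
    z0s, signs = _draw_filament_layout(spec, rng, Lz, L_f)
    lanes = [xy for xy in _lane_positions(spec.N_F, dom.box) for _ in range(2)]
    for (x, y), z0, sign in zip(lanes, z0s, signs):
        asm.add_filament(build_filament(
            L_f, origin=(x, y, z0), direction=(0, 0, sign), params=params))
    place_binders(asm, spec, rng, params)
    return asm.build(seed=spec.seed)


def place_binders(asm: SystemAssembler, spec: SystemSpec,
                  rng: np.random.Generator,
                  params: ParameterSet | None = None) -> None:
    """Place motors inside the f-window and cross-linkers everywhere.

    Motor centers are drawn uniformly from a z interval of length
    ``f * Lz`` centered at the bundle midpoint (``f = 1``: anywhere, with
    wrapping); each motor runs along z at a random interior cell center of
    the lane grid, where its arms reach the four surrounding lanes.
    Initial arm attachment happens during the engine's frozen-actin
    settling phase.
    """
    params = params or asm.params
    Lz = asm.domain.box[2]
    lanes = _motor_sites(spec.N_F, asm.domain.box)
    motor = build_motor(spec.N_a, spec.L_bz, spec.L_sp, params=params)
    if spec.f * Lz < motor.L_M:
        asm.warnings.append(
            f"motor region f*Lz = {spec.f * Lz:.0f} nm shorter than "
            f"L_M = {motor.L_M:.0f} nm; backbones protrude")
    zs = _draw_motor_centers(spec, rng, Lz, motor.L_M)
    for z in zs:
        x, y = lanes[int(rng.integers(len(lanes)))]
        asm.add_motor(build_motor(spec.N_a, spec.L_bz, spec.L_sp,
                                  center=(x, y, z), direction=(0, 0, 1),
                                  params=params))
    init_crosslinks(asm, spec.N_ACP, rng)


def _draw_motor_centers(spec: SystemSpec, rng: np.random.Generator,
                        Lz: float, L_M: float) -> np.ndarray:
    """Motor center z values from the f-window, optionally sparse.

    ``min_motor_gap_nm > 0`` enforces sparse placement: centers are redrawn
    until every circular gap between motor spans is at least that wide
    (rejection sampling of the uniform distribution conditioned on
    separation) — the non-overlapping regime in which motors form
    independent contractile units.
    """
    for _ in range(2000):
        z = (Lz / 2.0 + spec.f * Lz * (rng.uniform(size=spec.N_M) - 0.5)) % Lz
        if spec.min_motor_gap_nm <= 0.0 or spec.N_M < 2:
            return z
        zs = np.sort(z)
        gaps = np.diff(np.concatenate([zs, [zs[0] + Lz]])) - L_M
        if gaps.min() >= spec.min_motor_gap_nm:
            return z
    raise RuntimeError("could not place motors with the requested gaps")


# ----------------------------------------------------------------------
def calibrate_polymerization(k_n: float, target_segments: int,
                             mean_length_nm: float, r0: float = 140.0) -> float:
    """Polymerization rate giving the requested mean filament length.

    With nucleation at constant rate ``k_n`` and every barbed end elongating
    at ``k_p`` until ``target_segments`` segments exist in total, the mean
    final length is ``sqrt(target * k_p / (2 k_n))`` segments; inverting
    gives ``k_p``.
    """
    mean_seg = mean_length_nm / r0
    return 2.0 * k_n * mean_seg ** 2 / target_segments


def grow_network_filaments(params: ParameterSet, rng: np.random.Generator,
                           target_segments: int,
                           k_p: float | None = None) -> list[int]:
    """Stochastic nucleation/elongation; returns per-filament segment counts.

    Event-driven simulation of the two Poisson processes: nucleation adds a
    one-segment seed at rate ``k_n_A``; every existing filament appends one
    segment at its barbed end at rate ``k_p``.  Growth stops when the total
    segment count reaches ``target_segments``.
    """
    k_n = params.k_n_A
    k_p = params.k_p_A if k_p is None else k_p
    counts: list[int] = []
    total = 0
    while total < target_segments:
        n_f = len(counts)
        rate_n = k_n
        rate_p = k_p * n_f
        u = rng.uniform() * (rate_n + rate_p)
        if u < rate_n or n_f == 0:
            counts.append(1)
        else:
            counts[int(rng.integers(n_f))] += 1
        total += 1
    return counts


def build_network(spec: SystemSpec,
                  params: ParameterSet | None = None) -> SimulationState:
    """A thin quasi-2D actomyosin sheet.

    Filaments are grown by nucleation/polymerization (rate ratio calibrated
    to the requested mean length), then laid out as straight rods at their
    nucleation points with uniform in-plane orientations in the box
    mid-plane.  Motors get uniform random positions and in-plane
    orientations; cross-linkers are placed wherever two filaments are in
    reach.
    """
    params = params or ParameterSet()
    if spec.kind != "network":
        raise ValueError("spec.kind must be 'network'")
    dom = spec.domain()
    rng = np.random.default_rng(spec.seed)
    k_p = calibrate_polymerization(params.k_n_A, spec.network_target_segments,
                                   spec.network_mean_length_nm, params.r0_A)
    counts = grow_network_filaments(params, rng, spec.network_target_segments,
                                    k_p=k_p)
    z_mid = dom.box[2] / 2.0
    asm = SystemAssembler(params, dom)
    for n_seg in counts:
        x, y = rng.uniform(0, dom.box[0]), rng.uniform(0, dom.box[1])
        phi = rng.uniform(0, 2 * math.pi)
        u = (math.cos(phi), math.sin(phi), 0.0)
        # polymerization extends the barbed end away from the seed
        barbed = (x + n_seg * params.r0_A * u[0],
                  y + n_seg * params.r0_A * u[1], z_mid)
        asm.add_filament(build_filament(n_seg * params.r0_A, origin=barbed,
                                        direction=(-u[0], -u[1], 0.0),
                                        params=params))
    for _ in range(spec.N_M):
        x, y = rng.uniform(0, dom.box[0]), rng.uniform(0, dom.box[1])
        phi = rng.uniform(0, 2 * math.pi)
        asm.add_motor(build_motor(spec.N_a, spec.L_bz, spec.L_sp,
                                  center=(x, y, z_mid),
                                  direction=(math.cos(phi), math.sin(phi), 0),
                                  params=params))
    init_crosslinks(asm, spec.N_ACP, rng)
    return asm.build(seed=spec.seed)
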