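"""Physical parameters of the actomyosin model.

All constants, stiffnesses, rates and reference lengths live in a single
validated :class:`ParameterSet`.  Fields use the units conventional for each
quantity (see the field table below); the simulation engine works internally
in a coherent nm / pN / s system obtained through :meth:`ParameterSet.sim`.

Unit conventions
----------------
========================  =========
quantity                  unit
========================  =========
time step ``dt``          s
thermal energy ``kBT``    J
viscosity ``mu``          Pa·s
lengths (``r0_*`` etc.)   nm
extensional ``kappa_s*``  N/m
bending ``kappa_b*``      N·m/rad² (J)
angles ``theta0_*``       rad
forces (``F_st`` ...)     pN
rates (``k_*``)           1/s
velocity ``v0``           nm/s
``Lp_A``                  µm
========================  =========
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace
from typing import Any

import yaml

__all__ = ["ParameterSet", "drag_coefficient"]

# conversion factors into the engine's nm / pN / s system
_J_TO_PN_NM = 1e21          # 1 J = 1e21 pN·nm
_NPM_TO_PN_PER_NM = 1e3     # 1 N/m = 1e3 pN/nm
_NSPM_TO_PN_S_PER_NM = 1e3  # 1 N·s/m = 1e3 pN·s/nm


def drag_coefficient(r0: float, rc: float, mu: float) -> float:
    """Drag coefficient of a cylindrical segment, in N·s/m.

    Uses the approximate cylinder form ``zeta = 3*pi*mu*rc*(3 + 2*r0/rc)/5``
    where ``r0`` is the segment length (nm), ``rc`` its diameter (nm) and
    ``mu`` the medium viscosity (Pa·s).  In the sphere-like limit
    ``r0 == rc`` this reduces to ``3*pi*mu*rc``.
    """
    if r0 <= 0 or rc <= 0 or mu <= 0:
        raise ValueError("drag_coefficient requires positive r0, rc and mu")
    return 3.0 * math.pi * mu * (rc * 1e-9) * (3.0 + 2.0 * r0 / rc) / 5.0


@dataclass
class ParameterSet:
    """All model parameters with literature defaults.

    The defaults describe non-muscle-myosin-II-like bipolar motors walking on
    140-nm-segment actin filaments: 8 heads per coarse arm, a 5.7 pN per-head
    stall force, a 140 nm/s unloaded gliding speed, binding sites every 7 nm
    and permanent two-armed cross-linkers of 23.5 nm arm length.
    """

    # integration / environment
    dt: float = 1.15e-5          # time step (s)
    kBT: float = 4.11e-21        # thermal energy (J), ~298 K
    mu: float = 8.6              # effective medium viscosity (Pa·s)

    # geometry (nm)
    r0_A: float = 140.0          # actin segment rest length
    d_A: float = 7.0             # actin segment diameter (drag + repulsion)
    r0_ACP: float = 23.5         # cross-linker arm rest length
    d_ACP: float = 10.0          # cross-linker drag diameter
    L_MB: float = 42.0           # motor backbone segment reference length
    d_M: float = 30.0            # motor backbone drag diameter
    r0_M2: float = 13.5          # motor arm transverse equilibrium distance
    r0_M3: float = 0.0           # motor arm longitudinal equilibrium offset
    rc_A: float = 7.0            # actin-actin repulsion cutoff
    site_spacing: float = 7.0    # binding-site spacing along actin

    # stiffnesses
    kappa_s_A: float = 0.12      # actin extension (N/m)
    kappa_s_ACP: float = 0.06    # cross-linker arm extension (N/m)
    kappa_s_M1: float = 0.06     # motor backbone extension (N/m)
    kappa_s_M2: float = 0.01     # motor arm transverse spring (N/m)
    kappa_s_M3: float = 0.01     # motor arm longitudinal spring (N/m)
    kappa_r_A: float = 0.02      # actin-actin repulsion / wall (N/m)
    kappa_b_ACP: float = 1e-19   # cross-linker hinge bending (N·m)
    kappa_b_M: float = 1e-17     # motor backbone bending (N·m)

    # equilibrium angles (rad)
    theta0_A: float = 0.0
    theta0_ACP: float = 0.0
    theta0_M: float = 0.0

    # motor mechanochemistry
    k_bind_per_head: float = 40.0  # arm binding rate per head (1/s)
    N_h: int = 8                   # myosin heads per coarse arm
    F_st: float = 5.7              # stall force per head (pN)
    v0: float = 140.0              # unloaded walking velocity (nm/s)
    k_u0: float = 350.0            # unloaded arm unbinding rate (1/s)
    F_cat: float = 6.0             # catch-bond force scale (pN)
    k_u_floor_frac: float = 1e-3   # k_u never drops below this * k_u0

    # network assembly
    k_n_A: float = 2.0             # nucleation rate (1/s)
    k_p_A: float = 50.0            # polymerization rate per barbed end (1/s)

    # actin bending, via persistence length
    Lp_A: float = 9.0              # actin persistence length (µm)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def kappa_b_A(self) -> float:
        """Actin bending stiffness (N·m), derived as ``Lp_A*kBT/r0_A``.

        Not an independent field: the joint stiffness of the discrete chain
        is fixed by the persistence length it must reproduce.
        """
        return (self.Lp_A * 1e-6) * self.kBT / (self.r0_A * 1e-9)

    @property
    def F_stall_arm(self) -> float:
        """Stall force of one coarse arm, ``F_st * N_h`` (pN)."""
        return self.F_st * self.N_h

    @property
    def sites_per_segment(self) -> int:
        """Number of discrete binding sites on one actin segment."""
        return int(math.floor(self.r0_A / self.site_spacing))

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kBT <= 0 or self.mu <= 0:
            raise ValueError("kBT and mu must be positive")
        for name in ("r0_A", "d_A", "r0_ACP", "d_ACP", "L_MB", "d_M",
                     "r0_M2", "rc_A", "site_spacing", "Lp_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r0_M3 != 0.0:
            raise ValueError("r0_M3 must be 0 (right-angle arm equilibrium)")
        for name in ("kappa_s_A", "kappa_s_ACP", "kappa_s_M1", "kappa_s_M2",
                     "kappa_s_M3", "kappa_r_A", "kappa_b_ACP", "kappa_b_M"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.k_u_floor_frac < 1.0:
            raise ValueError("k_u_floor_frac must be in (0, 1)")
        for name in ("k_bind_per_head", "v0", "k_u0", "F_cat",
                     "k_n_A", "k_p_A", "F_st"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.theta0_A != 0.0 or self.theta0_ACP != 0.0 or self.theta0_M != 0.0:
            raise ValueError("equilibrium angles must be 0 (straight chains)")
        if self.N_h < 1:
            raise ValueError("N_h must be at least 1")

    # ------------------------------------------------------------------
    def sim(self) -> SimpleNamespace:
        """Parameters converted to the engine's nm / pN / s unit system.

        Returns a plain namespace of floats (kappas in pN/nm, energies in
        pN·nm, drags in pN·s/nm) plus the per-element drag coefficients.
        """
        zeta_A = drag_coefficient(self.r0_A, self.d_A, self.mu)
        zeta_M = drag_coefficient(self.L_MB, self.d_M, self.mu)
        zeta_ACP = drag_coefficient(self.r0_ACP, self.d_ACP, self.mu)
        return SimpleNamespace(
            dt=self.dt,
            kBT=self.kBT * _J_TO_PN_NM,
            r0_A=self.r0_A, d_A=self.d_A, r0_ACP=self.r0_ACP,
            L_MB=self.L_MB, r0_M2=self.r0_M2, r0_M3=self.r0_M3,
            rc_A=self.rc_A, site_spacing=self.site_spacing,
            n_sites=self.sites_per_segment,
            ks_A=self.kappa_s_A * _NPM_TO_PN_PER_NM,
            ks_ACP=self.kappa_s_ACP * _NPM_TO_PN_PER_NM,
            ks_M1=self.kappa_s_M1 * _NPM_TO_PN_PER_NM,
            ks_M2=self.kappa_s_M2 * _NPM_TO_PN_PER_NM,
            ks_M3=self.kappa_s_M3 * _NPM_TO_PN_PER_NM,
            kr_A=self.kappa_r_A * _NPM_TO_PN_PER_NM,
            kb_A=self.kappa_b_A * _J_TO_PN_NM,
            kb_ACP=self.kappa_b_ACP * _J_TO_PN_NM,
            kb_M=self.kappa_b_M * _J_TO_PN_NM,
            zeta_A=zeta_A * _NSPM_TO_PN_S_PER_NM,
            zeta_M=zeta_M * _NSPM_TO_PN_S_PER_NM,
            zeta_ACP=zeta_ACP * _NSPM_TO_PN_S_PER_NM,
            k_bind=self.k_bind_per_head * self.N_h,
            k_w0=self.v0 / self.site_spacing,
            k_u0=self.k_u0,
            F_cat=self.F_cat,
            ku_floor=self.k_u0 * self.k_u_floor_frac,
            F_stall_arm=self.F_stall_arm,
            step_size=self.site_spacing,
            N_h=self.N_h,
            F_st=self.F_st,
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ParameterSet":
        """Build from a mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        """Write to a YAML (``.yml``/``.yaml``) or JSON file."""
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        if not isinstance(data, dict):
            raise ValueError(f"{path} does not contain a parameter mapping")
        return cls.from_dict(data)
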