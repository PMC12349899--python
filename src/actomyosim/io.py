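"""Configuration files, trajectory storage and run manifests.

A run is described by a YAML/JSON config with three sections::

    parameters: {...}   # ParameterSet overrides (unknown keys rejected)
    system:     {...}   # SystemSpec fields (kind, N_M, N_ACP, f, ...)
    run:                # protocol
      duration_s: 8.0
      sample_every_s: 0.05
      settle_steps: 10000
      mode: bundle          # bundle | network (measurement convention)
      kinetics_stride: 4
      trajectory_every_s: 0  # 0: no trajectory file

Trajectories are HDF5: static connectivity once, one group per snapshot
(positions, occupancy, arm state, time), plus enough metadata to rebuild
the :class:`SimulationState`; a JSON manifest ties config, seed and outputs
together and is written last, so its existence marks a complete run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .builders import (SystemSpec, build_bundle, build_network,
                       build_two_filament_system)
from .integrator import Engine
from .measurement import Measurement
from .parameters import ParameterSet
from .state import Domain, FilamentInfo, MotorInfo, SimulationState

__all__ = ["RunManifest", "load_config", "run_experiment",
           "write_trajectory", "read_trajectory", "builder_for"]

_STATE_ARRAYS_STATIC = [
    "zeta", "mobile", "vkind", "bond_i", "bond_j", "bond_r0", "bond_k",
    "bond_kind", "ang_a", "ang_b", "ang_c", "ang_k", "seg_v1", "seg_v2",
    "seg_fil", "fil_first_seg", "site_frac", "acp_center", "acp_seg",
    "acp_site", "arm_anchor", "arm_ref", "arm_sibling", "arm_motor",
]
_STATE_ARRAYS_FRAME = ["pos", "occupancy", "arm_bound", "arm_seg", "arm_site"]


@dataclass
class RunManifest:
    """Provenance record: identical manifests imply identical outputs."""

    config: dict
    seed: int
    version: str
    t_start: float
    t_end: float
    outputs: dict
    warnings: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def load_config(path: str | Path) -> dict:
    """Read and validate a run config; unknown keys are rejected early."""
    path = Path(path)
    raw = path.read_text()
    cfg = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - {"parameters", "system", "run"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    params = ParameterSet.from_dict(cfg.get("parameters", {}))
    sys_cfg = cfg.get("system", {})
    if "kind" not in sys_cfg:
        raise ValueError(f"{path}: missing required key 'kind' in [system]")
    known = {f.name for f in dataclasses.fields(SystemSpec)}
    bad = set(sys_cfg) - known
    if bad:
        raise ValueError(f"{path}: unknown system keys {sorted(bad)}")
    run_cfg = cfg.get("run", {})
    bad = set(run_cfg) - {"duration_s", "sample_every_s", "settle_steps",
                          "mode", "kinetics_stride", "trajectory_every_s"}
    if bad:
        raise ValueError(f"{path}: unknown run keys {sorted(bad)}")
    return {"parameters": params, "system": sys_cfg, "run": run_cfg,
            "raw": cfg}


def builder_for(kind: str):
    return {"two_filament": build_two_filament_system,
            "bundle": build_bundle,
            "network": build_network}[kind]


def run_experiment(config_path: str | Path, seed: int,
                   outdir: str | Path) -> RunManifest:
    """Build, settle, run and measure one configured experiment.

    Writes ``timeseries.csv`` (per time, plane), ``summary.csv`` (F_tot,
    F_M_max, eta, steady window, seed), optionally ``trajectory.h5``, and
    ``manifest.json`` last.
    """
    cfg = load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params: ParameterSet = cfg["parameters"]
    sys_cfg = dict(cfg["system"])
    sys_cfg["seed"] = seed
    if "domain_um" in sys_cfg and sys_cfg["domain_um"] is not None:
        sys_cfg["domain_um"] = tuple(sys_cfg["domain_um"])
    spec = SystemSpec(**sys_cfg)
    run_cfg = cfg["run"]
    duration = float(run_cfg.get("duration_s", 8.0))
    sample_every = float(run_cfg.get("sample_every_s", 0.05))
    settle_steps = int(run_cfg.get("settle_steps", 10_000))
    stride = int(run_cfg.get("kinetics_stride", 4))
    mode = run_cfg.get("mode", "network" if spec.kind == "network" else "bundle")
    traj_every = float(run_cfg.get("trajectory_every_s", 0.0))

    state = builder_for(spec.kind)(spec, params)
    engine = Engine(state, seed=seed, kinetics_stride=stride)
    engine.settle(settle_steps)
    meas = Measurement(state, mode=mode)
    snapshots = []
    steps = int(round(sample_every / params.dt))
    next_snap = 0.0
    for k in range(int(round(duration / sample_every))):
        engine.run(steps)
        meas.sample()
        if traj_every > 0 and state.time >= next_snap:
            snapshots.append(_frame_of(state))
            next_snap += traj_every
    warnings_list = list(getattr(state, "warnings", []))
    if len(meas.plane_means) >= 50:
        res = meas.result()
    else:
        # too short for steady-state detection: report the tail average
        from .measurement import MeasurementResult, efficiency
        tail = max(1, len(meas.plane_means) // 2)
        F_tot = float(np.mean(meas.plane_means[-tail:]))
        fm = np.mean(np.asarray(meas.fm_per_motor)[-tail:], axis=0)
        factor = 0.25 if mode == "network" else 0.5
        F_M_max = factor * float(fm.sum())
        res = MeasurementResult(
            F_tot=F_tot, F_M_max=F_M_max,
            eta=efficiency(F_tot, F_M_max) if F_M_max > 0 else float("nan"),
            times=np.asarray(meas.times),
            series=np.asarray(meas.plane_means),
            steady_window=(float(meas.times[-tail]), float(meas.times[-1])),
            steady_flag=False, F_M_per_motor=fm)
        warnings_list.append(
            f"only {len(meas.plane_means)} frames: tail average reported, "
            "no steady-state detection")

    outputs = {}
    ts_path = outdir / "timeseries.csv"
    meas.export_csv(ts_path)
    outputs["timeseries"] = str(ts_path)
    import pandas as pd
    summary = pd.DataFrame([{
        "F_tot_pN": res.F_tot, "F_M_max_pN": res.F_M_max, "eta": res.eta,
        "steady_t_start_s": res.steady_window[0],
        "steady_t_end_s": res.steady_window[1],
        "steady_found": res.steady_flag, "seed": seed,
    }])
    sm_path = outdir / "summary.csv"
    summary.to_csv(sm_path, index=False)
    outputs["summary"] = str(sm_path)
    if snapshots:
        tr_path = outdir / "trajectory.h5"
        write_trajectory(state, snapshots, tr_path)
        outputs["trajectory"] = str(tr_path)

    manifest = RunManifest(config=cfg["raw"], seed=seed, version=__version__,
                           t_start=0.0, t_end=state.time, outputs=outputs,
                           warnings=warnings_list)
    manifest.save(outdir / "manifest.json")
    return manifest


# ----------------------------------------------------------------------
def _frame_of(state: SimulationState) -> dict:
    return {name: getattr(state, name).copy() for name in _STATE_ARRAYS_FRAME} | \
        {"time": state.time}


def write_trajectory(state: SimulationState, snapshots: list[dict],
                     path: str | Path) -> None:
    """Store snapshots plus everything needed to rebuild the state."""
    if not snapshots:
        raise ValueError("need at least one snapshot")
    with h5py.File(path, "w") as h5:
        h5.attrs["params"] = json.dumps(state.params.to_dict())
        h5.attrs["box"] = state.domain.box
        h5.attrs["periodic"] = state.domain.periodic
        h5.attrs["seed"] = state.seed
        h5.attrs["filaments"] = json.dumps(
            [dataclasses.asdict(f) for f in state.filaments])
        h5.attrs["motors"] = json.dumps(
            [dataclasses.asdict(m) for m in state.motors])
        static = h5.create_group("static")
        for name in _STATE_ARRAYS_STATIC:
            static.create_dataset(name, data=getattr(state, name))
        for i, frame in enumerate(snapshots):
            g = h5.create_group(f"frames/{i:06d}")
            g.attrs["time"] = frame["time"]
            for name in _STATE_ARRAYS_FRAME:
                g.create_dataset(name, data=frame[name])


def read_trajectory(path: str | Path) -> list[SimulationState]:
    """Rebuild one :class:`SimulationState` per stored snapshot."""
    out = []
    with h5py.File(path, "r") as h5:
        params = ParameterSet.from_dict(json.loads(h5.attrs["params"]))
        domain = Domain(box=np.array(h5.attrs["box"]),
                        periodic=np.array(h5.attrs["periodic"], dtype=np.uint8))
        filaments = [FilamentInfo(**d)
                     for d in json.loads(h5.attrs["filaments"])]
        motors = [MotorInfo(**{**d, "bare_zone": tuple(d["bare_zone"])})
                  for d in json.loads(h5.attrs["motors"])]
        static = {name: h5["static"][name][...]
                  for name in _STATE_ARRAYS_STATIC}
        for key in sorted(h5["frames"]):
            g = h5["frames"][key]
            arrays = dict(static)
            for name in _STATE_ARRAYS_FRAME:
                arrays[name] = g[name][...]
            st = SimulationState(params, domain, arrays, filaments, motors,
                                 seed=int(h5.attrs["seed"]))
            st.time = float(g.attrs["time"])
            out.append(st)
    return out
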