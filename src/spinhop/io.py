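"""File formats: model documents, run configs, trajectory output, XYZ.

Model systems and run configurations are YAML (or JSON) documents with
explicit unit suffixes in key names (frequency_cm1, vertical_energies_ev,
dt_fs, ...).  JSON schemas for both documents ship under
``spinhop/schemas``; validation is performed field-by-field with
field-path error messages, and every applied default is logged.

Trajectories are written as JSON-Lines (one record per step: t_fs, coords,
momenta, active, |c|^2, |b|^2) with an accompanying hops CSV; an HDF5
container is available for large ensembles.  Round-trips are lossless to
full double precision.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .dynamics import DynamicsParams, HopEvent, Trajectory
from .model import (
    ElectronicSpec,
    ModeSpec,
    ModelSystem,
    SOCModulation,
    SOCSpec,
    build_lvc_model,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "write_trajectory",
    "read_trajectory",
    "write_hops_csv",
    "read_xyz",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


# ----------------------------------------------------------------------
# model documents

def model_to_dict(model: ModelSystem) -> dict:
    el = model.electronic
    doc = {
        "label": model.label,
        "modes": [
            {
                "frequency_cm1": m.frequency_cm1,
                "reduced_mass_amu": m.reduced_mass_amu,
                "equilibrium": m.equilibrium,
                **({"name": m.name} if m.name else {}),
            }
            for m in model.modes
        ],
        "electronic": {
            "n_singlets": el.n_singlets,
            "n_triplets": el.n_triplets,
            "vertical_energies_ev": list(map(float, el.vertical_energies_ev)),
            "oscillator_strengths": list(map(float, model.oscillator_strengths)),
        },
        "soc": {
            "base_soc_cm1": [
                {
                    "singlet": i, "triplet": j, "component": m,
                    "re_cm1": float(np.real(v)), "im_cm1": float(np.imag(v)),
                }
                for (i, j, m), v in sorted(model.soc.base_soc_cm1.items())
            ],
            "modulation": [
                {
                    "coordinate": mod.coordinate,
                    "linear_cm1": mod.linear_cm1,
                    "quadratic_cm1": mod.quadratic_cm1,
                    **(
                        {"entries": [list(e) for e in mod.entries]}
                        if mod.entries is not None
                        else {}
                    ),
                }
                for mod in model.soc.modulation
            ],
        },
    }
    if el.intrastate_gradients_ev is not None:
        doc["electronic"]["intrastate_gradients_ev"] = np.asarray(
            el.intrastate_gradients_ev, dtype=float
        ).tolist()
    if el.interstate_couplings_ev:
        doc["electronic"]["interstate_couplings_ev"] = [
            {"block": b, "i": i, "j": j, "mode": k, "value_ev": float(v)}
            for (b, i, j, k), v in sorted(el.interstate_couplings_ev.items())
        ]
    return doc


_MODE_KEYS = {"frequency_cm1", "reduced_mass_amu", "equilibrium", "name"}
_EL_KEYS = {
    "n_singlets", "n_triplets", "vertical_energies_ev",
    "intrastate_gradients_ev", "interstate_couplings_ev", "oscillator_strengths",
}
_SOC_KEYS = {"base_soc_cm1", "modulation"}


def _check_keys(d: dict, allowed: set, path: str):
    for k in d:
        if k not in allowed:
            raise ConfigError(f"{path}.{k}: unknown key")


def model_from_dict(doc: dict) -> ModelSystem:
    _check_keys(doc, {"label", "modes", "electronic", "soc"}, "model")
    modes = []
    for n, m in enumerate(doc.get("modes", [])):
        _check_keys(m, _MODE_KEYS, f"modes[{n}]")
        modes.append(
            ModeSpec(
                frequency_cm1=float(m["frequency_cm1"]),
                reduced_mass_amu=float(m["reduced_mass_amu"]),
                equilibrium=float(m.get("equilibrium", 0.0)),
                name=m.get("name"),
            )
        )
    el = doc.get("electronic", {})
    _check_keys(el, _EL_KEYS, "electronic")
    couplings: Dict = {}
    for n, c in enumerate(el.get("interstate_couplings_ev", []) or []):
        _check_keys(c, {"block", "i", "j", "mode", "value_ev"},
                    f"electronic.interstate_couplings_ev[{n}]")
        couplings[(c["block"], int(c["i"]), int(c["j"]), int(c["mode"]))] = float(
            c["value_ev"]
        )
    grads = el.get("intrastate_gradients_ev")
    espec = ElectronicSpec(
        n_singlets=int(el["n_singlets"]),
        n_triplets=int(el["n_triplets"]),
        vertical_energies_ev=[float(x) for x in el["vertical_energies_ev"]],
        intrastate_gradients_ev=None if grads is None else np.asarray(grads, float),
        interstate_couplings_ev=couplings,
        oscillator_strengths=el.get("oscillator_strengths"),
    )
    socd = doc.get("soc", {}) or {}
    _check_keys(socd, _SOC_KEYS, "soc")
    base: Dict = {}
    for n, s in enumerate(socd.get("base_soc_cm1", []) or []):
        _check_keys(s, {"singlet", "triplet", "component", "re_cm1", "im_cm1"},
                    f"soc.base_soc_cm1[{n}]")
        base[(int(s["singlet"]), int(s["triplet"]), int(s["component"]))] = complex(
            float(s.get("re_cm1", 0.0)), float(s.get("im_cm1", 0.0))
        )
    mods = []
    for n, m in enumerate(socd.get("modulation", []) or []):
        _check_keys(m, {"coordinate", "linear_cm1", "quadratic_cm1", "entries"},
                    f"soc.modulation[{n}]")
        entries = m.get("entries")
        mods.append(
            SOCModulation(
                coordinate=m["coordinate"],
                linear_cm1=float(m.get("linear_cm1", 0.0)),
                quadratic_cm1=float(m.get("quadratic_cm1", 0.0)),
                entries=None if entries is None
                else tuple(tuple(int(x) for x in e) for e in entries),
            )
        )
    return build_lvc_model(
        espec, modes, SOCSpec(base_soc_cm1=base, modulation=mods),
        label=doc.get("label", ""),
    )


def load_model(path) -> ModelSystem:
    """Read a model YAML/JSON document and build the validated ModelSystem."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: model document must be a mapping")
    return model_from_dict(doc)


def save_model(model: ModelSystem, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


# ----------------------------------------------------------------------
# run configuration

_PROTOCOL_DEFAULTS = dict(
    dt_fs=0.5, n_substeps=20, t_max_fs=200.0, temperature_k=298.0,
    n_trajectories=20, alphas=(2.0, 3.5, 5.0), initial_state="S1", seed=1,
)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the reference protocol
    (0.5 fs nuclear step, 20 substeps, 200 fs, 298 K, alphas 2/3.5/5,
    20 trajectories started in S1)."""

    model_path: str
    dt_fs: float = 0.5
    n_substeps: int = 20
    t_max_fs: float = 200.0
    t_max_per_alpha: Optional[Dict[float, float]] = None
    temperature_k: float = 298.0
    n_trajectories: int = 20
    alphas: Tuple[float, ...] = (2.0, 3.5, 5.0)
    initial_state: str = "S1"
    seed: int = 1
    output_dir: str = "spinhop_out"

    def dynamics_params(self, alpha: float = 1.0, seed: Optional[int] = None) -> DynamicsParams:
        return DynamicsParams(
            dt_fs=self.dt_fs, n_substeps=self.n_substeps, t_max_fs=self.t_max_fs,
            alpha=alpha, initial_state=self.initial_state,
            seed=self.seed if seed is None else seed,
        )


_CONFIG_KEYS = {
    "model_path", "dt_fs", "n_substeps", "t_max_fs", "t_max_per_alpha",
    "temperature_k", "n_trajectories", "alphas", "initial_state", "seed",
    "output_dir",
}


def load_config(path) -> RunConfig:
    """Load and validate a run configuration; defaults are logged as applied."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _check_keys(doc, _CONFIG_KEYS, "config")
    if "model_path" not in doc:
        raise ConfigError("config.model_path: required field missing")
    for key, default in _PROTOCOL_DEFAULTS.items():
        if key not in doc:
            logger.info("config: applying default %s = %r", key, default)
    tpa = doc.get("t_max_per_alpha")
    cfg = RunConfig(
        model_path=str(doc["model_path"]),
        dt_fs=float(doc.get("dt_fs", 0.5)),
        n_substeps=int(doc.get("n_substeps", 20)),
        t_max_fs=float(doc.get("t_max_fs", 200.0)),
        t_max_per_alpha=None if tpa is None
        else {float(k): float(v) for k, v in tpa.items()},
        temperature_k=float(doc.get("temperature_k", 298.0)),
        n_trajectories=int(doc.get("n_trajectories", 20)),
        alphas=tuple(float(a) for a in doc.get("alphas", (2.0, 3.5, 5.0))),
        initial_state=str(doc.get("initial_state", "S1")),
        seed=int(doc.get("seed", 1)),
        output_dir=str(doc.get("output_dir", "spinhop_out")),
    )
    if cfg.dt_fs <= 0:
        raise ConfigError("config.dt_fs: must be > 0")
    if cfg.temperature_k < 0:
        raise ConfigError("config.temperature_k: must be >= 0")
    if cfg.n_trajectories < 1:
        raise ConfigError("config.n_trajectories: must be >= 1")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    doc = asdict(cfg)
    doc["alphas"] = list(cfg.alphas)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ----------------------------------------------------------------------
# trajectory output

def write_trajectory(traj: Trajectory, path, fmt: str = "jsonl") -> None:
    """Write one trajectory (jsonl or hdf5); hops go to ``<path>.hops.csv``."""
    path = Path(path)
    if fmt == "jsonl":
        with open(path, "w") as fh:
            header = {
                "kind": "header", "n_singlets": traj.n_singlets,
                "n_triplets": traj.n_triplets, "alpha": traj.alpha,
                "seed": traj.seed, "truncated": traj.truncated,
            }
            fh.write(json.dumps(header) + "\n")
            for k in range(traj.n_steps):
                rec = {
                    "t_fs": float(traj.times_fs[k]),
                    "coords": traj.coords[k].tolist(),
                    "momenta": traj.momenta[k].tolist(),
                    "active": int(traj.active[k]),
                    "c_pop": traj.adiabatic_populations[k].tolist(),
                    "b_pop": traj.diabatic_populations[k].tolist(),
                    "e_total_au": float(traj.total_energy_au[k]),
                }
                fh.write(json.dumps(rec) + "\n")
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs.update(
                n_singlets=traj.n_singlets, n_triplets=traj.n_triplets,
                alpha=traj.alpha, seed=traj.seed, truncated=traj.truncated,
            )
            for name in ("times_fs", "coords", "momenta", "active",
                         "adiabatic_populations", "diabatic_populations",
                         "total_energy_au"):
                h5.create_dataset(name, data=getattr(traj, name))
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    write_hops_csv(traj.hops, str(path) + ".hops.csv")


def read_trajectory(path, fmt: str = "jsonl") -> Trajectory:
    path = Path(path)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as h5:
            traj = Trajectory(
                n_singlets=int(h5.attrs["n_singlets"]),
                n_triplets=int(h5.attrs["n_triplets"]),
                alpha=float(h5.attrs["alpha"]), seed=int(h5.attrs["seed"]),
                truncated=bool(h5.attrs["truncated"]),
            )
            for name in ("times_fs", "coords", "momenta", "active",
                         "adiabatic_populations", "diabatic_populations",
                         "total_energy_au"):
                setattr(traj, name, np.asarray(h5[name]))
        return traj
    with open(path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    header, steps = lines[0], lines[1:]
    traj = Trajectory(
        n_singlets=header["n_singlets"], n_triplets=header["n_triplets"],
        alpha=header["alpha"], seed=header["seed"],
        truncated=header.get("truncated", False),
    )
    traj.times_fs = np.array([r["t_fs"] for r in steps])
    traj.coords = np.array([r["coords"] for r in steps])
    traj.momenta = np.array([r["momenta"] for r in steps])
    traj.active = np.array([r["active"] for r in steps], dtype=int)
    traj.adiabatic_populations = np.array([r["c_pop"] for r in steps])
    traj.diabatic_populations = np.array([r["b_pop"] for r in steps])
    traj.total_energy_au = np.array([r["e_total_au"] for r in steps])
    return traj


def write_hops_csv(hops: Sequence[HopEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_fs", "from_state", "to_state", "accepted"])
        for h in hops:
            w.writerow([h.t_fs, h.from_state, h.to_state, int(h.accepted)])


def read_xyz(path) -> List[Tuple[List[str], np.ndarray]]:
    """Read a (multi-frame) XYZ file: element symbols + Cartesian Angstroms."""
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        nat = int(lines[k].split()[0])
        body = lines[k + 2 : k + 2 + nat]
        symbols, coords = [], []
        for ln in body:
            parts = ln.split()
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append((symbols, np.asarray(coords)))
        k += 2 + nat
    return frames
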