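"""Parameter-file handling for reproducible runs.

A run is described by a YAML (or JSON) file with sections::

    chamber:  {height_um, width_um, length_um}
    flow:     {q_ul_per_hr, viscosity_pa_s}
    ligand:   {mw_kda, d_cm2_s}
    receptor: {kon_per_M_s, per_cell, cell_radius_um}
    sim:      {nx, nz, coverage_fraction}          # optional
    seed:     integer                              # optional

Seeds are always explicit — no module draws from global random state — so a
config file plus package version pins a run completely.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import transport
from .transport import (
    ChamberGeometry,
    InvalidParameterError,
    LigandSpec,
    PerfusionSetting,
    ReceptorSpec,
)

DEFAULT_PARAMS: dict = {
    "chamber": {"height_um": 250.0, "width_um": 1250.0, "length_um": 13000.0},
    "flow": {"q_ul_per_hr": 33.0, "viscosity_pa_s": 1.0e-3},
    "ligand": {"mw_kda": 20.0, "d_cm2_s": 1.0e-6},
    "receptor": {"kon_per_M_s": 1.0e6, "per_cell": 1.0e4, "cell_radius_um": 10.0},
    "sim": {"nx": 261, "nz": 51, "coverage_fraction": 1.0},
    "seed": 0,
}


@dataclass(frozen=True)
class RunConfig:
    geometry: ChamberGeometry
    setting: PerfusionSetting
    ligand: LigandSpec
    receptor: ReceptorSpec
    sim: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS["sim"]))
    seed: int = 0
    raw: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        """Run manifest: config hash + seed; identical manifests ⇒ identical outputs."""
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return {
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
        }


def _section(params: dict, name: str) -> dict:
    try:
        sec = params[name]
    except KeyError as exc:
        raise InvalidParameterError(f"parameter file missing section {name!r}") from exc
    if not isinstance(sec, dict):
        raise InvalidParameterError(f"section {name!r} must be a mapping")
    return sec


def config_from_dict(params: dict) -> RunConfig:
    ch = _section(params, "chamber")
    fl = _section(params, "flow")
    li = _section(params, "ligand")
    re = _section(params, "receptor")
    try:
        geom = ChamberGeometry(height_um=float(ch["height_um"]),
                               width_um=float(ch["width_um"]),
                               length_um=float(ch["length_um"]))
        setting = PerfusionSetting(flow_rate_ul_hr=float(fl["q_ul_per_hr"]),
                                   viscosity_pa_s=float(fl.get("viscosity_pa_s", 1e-3)))
        ligand = LigandSpec(mw_kda=float(li["mw_kda"]),
                            diffusivity_cm2_s=float(li["d_cm2_s"]))
        receptor = ReceptorSpec(kon_per_M_s=float(re["kon_per_M_s"]),
                                receptors_per_cell=float(re["per_cell"]),
                                cell_radius_um=float(re["cell_radius_um"]))
    except KeyError as exc:
        raise InvalidParameterError(f"missing parameter field: {exc.args[0]}") from exc
    sim = dict(DEFAULT_PARAMS["sim"])
    sim.update(params.get("sim", {}))
    return RunConfig(geometry=geom, setting=setting, ligand=ligand,
                     receptor=receptor, sim=sim,
                     seed=int(params.get("seed", 0)), raw=params)


def load_config(path: Path | str) -> RunConfig:
    """Load a YAML/JSON parameter file into a validated RunConfig."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            params = json.load(fh)
        else:
            params = yaml.safe_load(fh)
    if not isinstance(params, dict):
        raise InvalidParameterError("parameter file must contain a mapping")
    return config_from_dict(params)


def default_config() -> RunConfig:
    """The reference design point as a RunConfig."""
    return config_from_dict(json.loads(json.dumps(DEFAULT_PARAMS)))


def uptake_velocity(cfg: RunConfig) -> float:
    return transport.uptake_velocity(cfg.receptor)
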