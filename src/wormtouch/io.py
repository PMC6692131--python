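"""Config loading, tabular schemas and provenance.

Configs are JSON (or YAML when available) with sections for geometry,
material, pressure, mesh, boundary conditions, gating, layout and
solver settings.  Quantities are SI internally; keys with unit suffixes
``_um`` (micrometres) or ``_kPa`` (kilopascals) are converted on load.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import GatingParams
from .geometry import BCMode, BoundaryCondition, ShellGeometry
from .population import LayoutParams
from .solver import SolverOptions

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "read_table",
    "write_table",
    "load_config",
]

SCHEMAS = {
    "profiles": ["y_m", "depth_m", "replicate_id"],
    "forces": ["w0_m", "F_N", "animal_id"],
    "traces": ["t_s", "I_pA", "sweep_id"],
    "field_dump": ["s_m", "phi_rad", "ux_m", "uy_m", "uz_m", "eps_xx",
                   "eps_yy", "eps_zz", "eps_xy", "contact_flag"],
    "force_curve": ["w0_m", "F_N"],
    "current_trace": ["t_s", "I_mean_pA", "I_var_pA2"],
}

_KNOWN_SECTIONS = {"geometry", "material", "pressure", "mesh", "bc",
                   "gating", "layout", "solver", "seed", "out_dir"}

_DEFAULTS = {
    # worm geometry per the standard adult preparation
    "geometry": {"R_um": 25.0, "t_um": 1.0, "L_um": 1000.0},
    "material": {"E_Pa": 4.0e6, "nu": 0.3},
    "pressure": {"p_kPa": 40.0},
    "mesh": {"n_s": 72, "n_phi": 40, "grading": 4.0, "phi_grading": 0.0},
    "bc": {"mode": "fixed_lower_half", "ends": "free"},
    "gating": {},
    "layout": {},
    "solver": {},
    "seed": 0,
    "out_dir": ".",
}


@dataclass
class RunConfig:
    geometry: ShellGeometry
    bc: BoundaryCondition
    solver: SolverOptions
    gating: GatingParams
    layout: LayoutParams
    seed: int
    out_dir: Path
    raw: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        digest = hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return {"config_sha256": digest, "seed": self.seed,
                "package": "wormtouch"}


def read_table(path, schema: str) -> pd.DataFrame:
    """CSV reader with schema validation (named column sets)."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} "
                         f"for schema {schema!r}")
    for c in SCHEMAS[schema]:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"{path}: column {c} is not numeric")
    return df


def write_table(path, df: pd.DataFrame, schema: str | None = None,
                header_meta: dict | None = None):
    """CSV writer; optional provenance comment header with units/seed."""
    if schema is not None:
        missing = [c for c in SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
    with open(path, "w") as fh:
        if header_meta:
            fh.write("# " + json.dumps(header_meta, default=float) + "\n")
        df.to_csv(fh, index=False)


def _convert_units(section: dict) -> dict:
    out = {}
    for k, v in section.items():
        if k.endswith("_um"):
            out[k[:-3]] = float(v) * 1e-6
        elif k.endswith("_kPa"):
            out[k[:-4]] = float(v) * 1e3
        elif k.endswith("_Pa"):
            out[k[:-3]] = float(v)
        else:
            out[k] = v
    return out


def load_config(path) -> RunConfig:
    """Load, validate and resolve a run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    merged = {}
    for sec, defaults in _DEFAULTS.items():
        if isinstance(defaults, dict):
            merged[sec] = {**defaults, **raw.get(sec, {})}
        else:
            merged[sec] = raw.get(sec, defaults)

    geom = _convert_units(merged["geometry"])
    mat = _convert_units(merged["material"])
    pres = _convert_units(merged["pressure"])
    if geom.get("t", 1) <= 0 or geom.get("R", 1) <= 0:
        raise ValueError("geometry: dimensions must be positive")
    geometry = ShellGeometry(R=geom["R"], t=geom["t"], L=geom["L"],
                             nu=float(mat["nu"]), E=float(mat["E"]),
                             p=float(pres["p"]))
    bc = BoundaryCondition(mode=BCMode(merged["bc"]["mode"]))
    mesh = merged["mesh"]
    solver = SolverOptions(n_s=int(mesh["n_s"]), n_phi=int(mesh["n_phi"]),
                           grading=float(mesh["grading"]),
                           phi_grading=float(mesh["phi_grading"]),
                           **merged["solver"])
    gating = GatingParams(**merged["gating"])
    lay = _convert_units(merged["layout"])
    layout_kwargs = {}
    if "mean_spacing" in lay:
        sig = float(lay.get("sigma_ln", LayoutParams.sigma_ln))
        layout_kwargs["mu_ln"] = float(np.log(lay.pop("mean_spacing"))
                                       - 0.5 * sig**2)
        lay.pop("sigma_ln", None)
        layout_kwargs["sigma_ln"] = sig
    if "extent" in lay:
        layout_kwargs["extent"] = tuple(float(v) for v in lay.pop("extent"))
    layout_kwargs.update(lay)
    layout = LayoutParams(**layout_kwargs)
    return RunConfig(geometry=geometry, bc=bc, solver=solver, gating=gating,
                     layout=layout, seed=int(merged["seed"]),
                     out_dir=Path(merged["out_dir"]), raw=raw)
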