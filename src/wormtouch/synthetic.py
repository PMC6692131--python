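"""Synthetic ground-truth datasets for fitting and pipeline tests.

Every generator runs the real solver/pipeline at known parameters, adds
i.i.d. Gaussian noise, and records the generating parameters and seed
so closed-loop parameter-recovery experiments need no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import protocols as pr
from .gating import GatingParams
from .geometry import Indenter, ShellGeometry
from .solver import (SolverOptions, calibrate_reference, deformation_profile,
                     force_displacement_curve, solve_indentation)

__all__ = [
    "FixtureSpec",
    "synth_profiles",
    "synth_force_curves",
    "synth_current_traces",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Generating parameters for one synthetic dataset."""

    seed: int
    noise_rel_sd: float = 0.01
    geometry: dict = field(default_factory=lambda: dict(
        R=25e-6, t=1e-6, L=1e-3, nu=0.3, E=4e6, p=40e3))
    Rb: float = 10e-6
    w0: float = 8e-6
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_rel_sd < 0:
            raise ValueError("noise SD must be non-negative")

    def make_geometry(self, **overrides) -> ShellGeometry:
        return ShellGeometry(**{**self.geometry, **overrides})


def _meta(spec: FixtureSpec, truth: dict) -> dict:
    return {"spec": asdict(spec), "ground_truth": truth}


def synth_profiles(spec: FixtureSpec,
                   opts: SolverOptions = SolverOptions(n_s=56, n_phi=28,
                                                       gtol=1e-8),
                   n_points: int = 25):
    """Deformation-profile dataset (columns y_m, depth_m, replicate_id).

    Solver profile at the generating p/E sampled at experiment-like
    abscissae with relative Gaussian noise.  Returns (DataFrame, meta).
    """
    geo = calibrate_reference(spec.make_geometry(), opts=opts)
    sol = solve_indentation(geo, Indenter(Rb=spec.Rb, w0=spec.w0), opts=opts)
    prof = deformation_profile(sol)
    y = np.linspace(0.0, 40e-6, n_points)
    depth = np.interp(y, prof.y - prof.center, -prof.uz)
    rng = np.random.default_rng(spec.seed)
    scale = spec.noise_rel_sd * np.max(np.abs(depth))
    rows = []
    n_rep = int(spec.extra.get("replicates", 2))
    for rep in range(n_rep):
        noisy = depth + rng.normal(0.0, scale, size=len(y))
        rows.append(pd.DataFrame({"y_m": y, "depth_m": noisy,
                                  "replicate_id": rep}))
    df = pd.concat(rows, ignore_index=True)
    truth = {"p_over_E": geo.p / geo.E, "p_Pa": geo.p, "E_Pa": geo.E}
    return df, _meta(spec, truth)


def synth_force_curves(spec: FixtureSpec,
                       opts: SolverOptions = SolverOptions(n_s=56, n_phi=28,
                                                           gtol=1e-8),
                       w0_grid: np.ndarray | None = None,
                       pressures: np.ndarray | None = None):
    """Force-indentation dataset (columns w0_m, F_N, animal_id).

    One synthetic animal per pressure (default: the generating p);
    per-animal pressures may emulate the dissection-induced spread.
    """
    if w0_grid is None:
        w0_grid = np.arange(1, 9) * 1e-6
    if pressures is None:
        pressures = np.array([spec.geometry["p"]])
    rng = np.random.default_rng(spec.seed)
    rows, truths = [], {}
    for i, p in enumerate(np.asarray(pressures, dtype=float)):
        geo = calibrate_reference(spec.make_geometry(p=float(p)), opts=opts)
        F = force_displacement_curve(geo, w0_grid, Rb=spec.Rb, opts=opts)
        scale = spec.noise_rel_sd * F.max()
        noisy = F + rng.normal(0.0, scale, size=len(F))
        rows.append(pd.DataFrame({"w0_m": w0_grid, "F_N": noisy,
                                  "animal_id": i}))
        truths[str(i)] = float(p)
    df = pd.concat(rows, ignore_index=True)
    return df, _meta(spec, {"p_Pa_per_animal": truths})


def synth_current_traces(spec: FixtureSpec,
                         params: GatingParams = GatingParams(),
                         opts: SolverOptions = SolverOptions(n_s=56, n_phi=28,
                                                             gtol=1e-8),
                         n_realizations: int = 10, amplitude: float = 8e-6,
                         duration: float = 0.6, t_off: float = 0.4,
                         dt: float = 1e-3):
    """Current-trace dataset (columns t_s, I_pA, sweep_id) with stored
    ground-truth gating parameters; full mechanics+ensemble pipeline
    plus additive recording noise."""
    geo = calibrate_reference(spec.make_geometry(), opts=opts)
    stim = pr.make_stimulus("step", amplitude=amplitude, duration=duration,
                            t_off=t_off, dt=dt, Rb=spec.Rb, tau=params.tau)
    trace = pr.simulate_protocol(geo, stim, params=params,
                                 n_realizations=n_realizations,
                                 seed=spec.seed, opts=opts)
    rng = np.random.default_rng(spec.seed + 1)
    scale = spec.noise_rel_sd * np.max(np.abs(trace.mean))
    rows = []
    for k, tr in enumerate(trace.realizations):
        noisy = tr + rng.normal(0.0, scale, size=len(tr))
        rows.append(pd.DataFrame({"t_s": trace.t, "I_pA": noisy,
                                  "sweep_id": k}))
    df = pd.concat(rows, ignore_index=True)
    truth = {"g0": params.g0, "g1": params.g1, "a": params.a,
             "tau": params.tau, "r0": params.r0, "i_o": params.i_o,
             "i_s": params.i_s}
    return df, _meta(spec, truth), stim


def write_fixture(path, df: pd.DataFrame, meta: dict):
    """CSV with an embedded JSON header comment (regeneration metadata)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# wormtouch-fixture " + json.dumps(meta, default=float)
                 + "\n")
        df.to_csv(fh, index=False)


def read_fixture(path):
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    meta = {}
    tag = "# wormtouch-fixture "
    if header.startswith(tag):
        meta = json.loads(header[len(tag):])
    df = pd.read_csv(path, comment="#")
    return df, meta
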