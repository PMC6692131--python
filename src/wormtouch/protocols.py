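"""Stimulus protocols and in-silico experiments.

Stimuli command either the indentation depth (displacement clamp) or
the contact force (force clamp, inverted through the simulated
force-indentation relation).  The shell is solved quasi-statically at a
set of depth levels (the tissue is purely elastic; all time dependence
comes from channel dynamics), and channel ensembles are driven through
the interpolated deformation fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import population as pop
from .gating import GatingParams
from .geometry import BoundaryCondition, Indenter, ShellGeometry
from .solver import (SolverOptions, calibrate_reference, deformation_profile,
                     force_displacement_curve, solve_indentation)

__all__ = [
    "StimulusProtocol",
    "make_stimulus",
    "build_drive",
    "force_clamp_inverse",
    "simulate_protocol",
    "run_sweep",
    "pre_indentation_experiment",
]

DEFAULT_RISE = 2e-3     # actuator-like rise time for "instantaneous" steps


@dataclass
class StimulusProtocol:
    """Time-resolved stimulus: depth (or force) waveform plus bead."""

    t: np.ndarray
    values: np.ndarray              # w0 (m) or force (N) depending on clamp
    clamp: str = "displacement"     # or "force"
    kind: str = "step"
    Rb: float = 10e-6
    position: float = 0.0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("stimulus values must be non-negative")
        if self.clamp not in ("displacement", "force"):
            raise ValueError("clamp must be displacement or force")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def _ramp_between(t, t0, t1, v0, v1):
    return np.where(t < t0, v0,
                    np.where(t >= t1, v1,
                             v0 + (v1 - v0) * (t - t0) / max(t1 - t0, 1e-12)))


def make_stimulus(kind: str, *, amplitude: float = 8e-6,
                  duration: float = 1.0, dt: float = 1e-3,
                  t_on: float = 0.1, t_off: float = 0.6,
                  rise_time: float = DEFAULT_RISE,
                  ramp_time: float = 0.2,
                  frequency: float = 10.0, offset: float | None = None,
                  pre_depth: float = 5e-6, dwell: float | None = None,
                  step_amplitude: float = 3e-6,
                  clamp: str = "displacement", Rb: float = 10e-6,
                  position: float = 0.0, tau: float = 0.05) -> StimulusProtocol:
    """Build a step / ramp / sinusoid / pre-indented-step waveform.

    Pre-indented steps hold the pre-depth for ``dwell`` (default 10 tau,
    long enough for complete adaptation) before the test step.
    """
    if amplitude < 0 or (kind == "pre_indented_step" and pre_depth < 0):
        raise ValueError("depths must be non-negative")
    t = np.arange(0.0, duration + dt / 2, dt)
    params = dict(amplitude=amplitude, t_on=t_on, t_off=t_off,
                  rise_time=rise_time)
    if kind == "step":
        v = _ramp_between(t, t_on, t_on + rise_time, 0.0, amplitude)
        v = np.where(t >= t_off,
                     _ramp_between(t, t_off, t_off + rise_time, amplitude, 0.0),
                     v)
    elif kind == "ramp":
        params["ramp_time"] = ramp_time
        v = _ramp_between(t, t_on, t_on + ramp_time, 0.0, amplitude)
        v = np.where(t >= t_off,
                     _ramp_between(t, t_off, t_off + rise_time, amplitude, 0.0),
                     v)
    elif kind == "sinusoid":
        off = amplitude if offset is None else offset
        params.update(frequency=frequency, offset=off)
        v = np.where(t >= t_on,
                     off + amplitude * np.sin(2 * np.pi * frequency * (t - t_on)),
                     0.0)
        v = np.maximum(v, 0.0)
    elif kind == "pre_indented_step":
        if dwell is None:
            dwell = 10.0 * tau
        params.update(pre_depth=pre_depth, dwell=dwell,
                      step_amplitude=step_amplitude)
        if dwell < 10.0 * tau:
            raise ValueError("dwell must allow adaptation (>= 10 tau)")
        t_step = t_on + dwell
        total = pre_depth + step_amplitude
        v = _ramp_between(t, t_on, t_on + rise_time, 0.0, pre_depth)
        v = np.where(t >= t_step,
                     _ramp_between(t, t_step, t_step + rise_time,
                                   pre_depth, total), v)
        v = np.where(t >= t_off,
                     _ramp_between(t, t_off, t_off + rise_time, total,
                                   pre_depth), v)
        t_rel = t_off + dwell
        v = np.where(t >= t_rel,
                     _ramp_between(t, t_rel, t_rel + rise_time,
                                   pre_depth, 0.0), v)
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    return StimulusProtocol(t=t, values=v, clamp=clamp, kind=kind, Rb=Rb,
                            position=position, params=params)


_drive_cache: dict = {}


def build_drive(geometry: ShellGeometry, Rb: float, position: float,
                w0_max: float, n_levels: int = 6,
                bc: BoundaryCondition = BoundaryCondition(),
                opts: SolverOptions = SolverOptions(),
                theta_trn: float = 0.0):
    """Solve the indentation at a ladder of depths and tabulate the TRN
    line kinematics (cached); returns (drive, w0_levels, F_levels)."""
    key = (geometry.R, geometry.t, geometry.L, geometry.nu, geometry.E,
           geometry.p, Rb, round(position, 12), round(w0_max, 12), n_levels,
           bc.mode, opts.n_s, opts.n_phi, opts.grading, opts.phi_grading,
           theta_trn)
    if key in _drive_cache:
        return _drive_cache[key]
    if geometry.p > 0 and not geometry.calibrated:
        geometry = calibrate_reference(geometry, opts=opts)
    levels = np.linspace(0.0, w0_max, n_levels + 1)
    F, sols = force_displacement_curve(geometry, levels, Rb=Rb,
                                       position=position, bc=bc, opts=opts,
                                       return_solutions=True)
    drive = pop.MechanicsDrive.from_solutions(sols, theta_trn=theta_trn)
    out = (drive, levels, F)
    _drive_cache[key] = out
    return out


def force_clamp_inverse(geometry: ShellGeometry, F_t: np.ndarray,
                        Rb: float = 10e-6, position: float = 0.0,
                        w0_max: float = 12e-6, n_levels: int = 8,
                        bc: BoundaryCondition = BoundaryCondition(),
                        opts: SolverOptions = SolverOptions()):
    """Convert a commanded force history to depths via the simulated
    force-indentation curve (monotone interpolation with warm-started
    continuation).  Forces beyond the curve maximum are flagged."""
    _, levels, F_lev = build_drive(geometry, Rb, position, w0_max,
                                   n_levels=n_levels, bc=bc, opts=opts)
    F_t = np.asarray(F_t, dtype=float)
    if np.any(np.diff(F_lev) <= 0):
        raise RuntimeError("force-indentation curve is not monotone")
    saturated = F_t > F_lev[-1]
    w0_t = np.interp(F_t, F_lev, levels)
    return w0_t, bool(np.any(saturated))


def simulate_protocol(geometry: ShellGeometry, protocol: StimulusProtocol,
                      params: GatingParams = GatingParams(),
                      layout: pop.LayoutParams = pop.LayoutParams(),
                      model: str = "symmetric", n_realizations: int = 20,
                      seed: int = 0, n_levels: int = 6,
                      bc: BoundaryCondition = BoundaryCondition(),
                      opts: SolverOptions = SolverOptions(),
                      orientation_mode: str = "hemisphere") -> pop.CurrentTrace:
    """Full pipeline: mechanics ladder + channel ensemble for a stimulus."""
    if protocol.clamp == "force":
        w0_t, saturated = force_clamp_inverse(
            geometry, protocol.values, Rb=protocol.Rb,
            position=protocol.position, bc=bc, opts=opts)
        if saturated:
            import warnings
            warnings.warn("commanded force exceeds the simulated curve")
    else:
        w0_t = protocol.values
    w0_max = float(np.max(w0_t))
    if w0_max == 0.0:
        w0_max = 1e-6
    drive, _, _ = build_drive(geometry, protocol.Rb, protocol.position,
                              w0_max, n_levels=n_levels, bc=bc, opts=opts,
                              theta_trn=layout.theta_trn)
    t_on = protocol.params.get("t_on", 0.1)
    t_off = protocol.params.get("t_off", 0.6)
    if protocol.kind == "pre_indented_step":
        t_on = t_on + protocol.params["dwell"]
    windows = ((t_on, t_on + 0.15), (t_off, t_off + 0.15))
    return pop.simulate_response(drive, w0_t, protocol.dt, params,
                                 layout=layout, model=model,
                                 n_realizations=n_realizations, seed=seed,
                                 orientation_mode=orientation_mode,
                                 summary_windows=windows)


def run_sweep(axis: str, grid, protocol: StimulusProtocol,
              geometry: ShellGeometry, params: GatingParams = GatingParams(),
              layout: pop.LayoutParams = pop.LayoutParams(),
              model: str = "symmetric", n_realizations: int = 20,
              seed: int = 0, opts: SolverOptions = SolverOptions(),
              bc: BoundaryCondition = BoundaryCondition()) -> pd.DataFrame:
    """Sweep pressure, bead radius or bead position; one pipeline run per
    grid point.  Partial failures are recorded and the sweep continues."""
    if axis not in ("pressure", "bead_radius", "bead_position"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    rows = []
    for i, val in enumerate(np.asarray(grid, dtype=float)):
        row = {"axis": axis, "value": val}
        try:
            geo_i, proto_i = geometry, protocol
            if axis == "pressure":
                geo_i = ShellGeometry(R=geometry.R, t=geometry.t,
                                      L=geometry.L, nu=geometry.nu,
                                      E=geometry.E, p=val)
            elif axis == "bead_radius":
                proto_i = StimulusProtocol(t=protocol.t, values=protocol.values,
                                           clamp=protocol.clamp,
                                           kind=protocol.kind, Rb=val,
                                           position=protocol.position,
                                           params=protocol.params)
            else:
                proto_i = StimulusProtocol(t=protocol.t, values=protocol.values,
                                           clamp=protocol.clamp,
                                           kind=protocol.kind, Rb=protocol.Rb,
                                           position=val, params=protocol.params)
            trace = simulate_protocol(geo_i, proto_i, params=params,
                                      layout=layout, model=model,
                                      n_realizations=n_realizations,
                                      seed=seed + i, bc=bc, opts=opts)
            w0_pk = float(np.max(proto_i.values)) if proto_i.clamp == "displacement" else np.nan
            sol = solve_indentation(
                geo_i if geo_i.p == 0 or geo_i.calibrated
                else calibrate_reference(geo_i, opts=opts),
                Indenter(Rb=proto_i.Rb, position=proto_i.position,
                         w0=w0_pk if np.isfinite(w0_pk) else 8e-6),
                bc, opts=opts)
            prof = deformation_profile(sol)
            row.update(peak_on_pA=trace.summary["peak_on_pA"],
                       peak_off_pA=trace.summary["peak_off_pA"],
                       asymmetry_pA=trace.summary["asymmetry_pA"],
                       cv_on=trace.summary["cv_on"],
                       yh_m=prof.yh, F_N=sol.F, failed=False)
        except Exception as exc:   # noqa: BLE001 — record and continue
            row.update(failed=True, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def pre_indentation_experiment(geometry: ShellGeometry,
                               step_grid, pre_depth: float = 5e-6,
                               params: GatingParams = GatingParams(),
                               layout: pop.LayoutParams = pop.LayoutParams(),
                               model: str = "symmetric",
                               n_realizations: int = 20, seed: int = 0,
                               opts: SolverOptions = SolverOptions(),
                               bc: BoundaryCondition = BoundaryCondition(),
                               dt: float = 1e-3) -> pd.DataFrame:
    """Paired plain vs pre-indented steps of equal relative amplitude.

    For each step amplitude: peak on/off currents for both stimuli and
    the half-maximum width of the *incremental* deformation (profile
    difference between post- and pre-step equilibria).
    """
    rows = []
    if geometry.p > 0 and not geometry.calibrated:
        geometry = calibrate_reference(geometry, opts=opts)
    for i, step in enumerate(np.asarray(step_grid, dtype=float)):
        plain = make_stimulus("step", amplitude=step, dt=dt,
                              duration=1.0, tau=params.tau)
        pre = make_stimulus("pre_indented_step", pre_depth=pre_depth,
                            step_amplitude=step, dt=dt,
                            duration=1.4 + 10 * params.tau, t_off=0.9,
                            tau=params.tau)
        tr_plain = simulate_protocol(geometry, plain, params=params,
                                     layout=layout, model=model,
                                     n_realizations=n_realizations,
                                     seed=seed + i, bc=bc, opts=opts)
        tr_pre = simulate_protocol(geometry, pre, params=params,
                                   layout=layout, model=model,
                                   n_realizations=n_realizations,
                                   seed=seed + i, bc=bc, opts=opts)
        # incremental deformation width: profile(post) - profile(pre)
        sol_lo = solve_indentation(geometry, Indenter(w0=pre_depth), bc,
                                   opts=opts)
        sol_hi = solve_indentation(geometry, Indenter(w0=pre_depth + step),
                                   bc, warm_start=sol_lo.config, opts=opts)
        sol_plain = solve_indentation(geometry, Indenter(w0=step), bc,
                                      opts=opts)
        width_pre = _incremental_width(sol_lo, sol_hi)
        width_plain = deformation_profile(sol_plain).yh
        rows.append(dict(step_m=step, pre_depth_m=pre_depth,
                         on_plain_pA=tr_plain.summary["peak_on_pA"],
                         on_pre_pA=tr_pre.summary["peak_on_pA"],
                         off_plain_pA=tr_plain.summary["peak_off_pA"],
                         off_pre_pA=tr_pre.summary["peak_off_pA"],
                         incr_width_pre_m=width_pre,
                         incr_width_plain_m=width_plain))
    return pd.DataFrame(rows)


def _incremental_width(sol_lo, sol_hi) -> float:
    """Half-max half-width of the deformation increment between states."""
    from .solver import _line_values
    mesh = sol_lo.mesh
    z_lo = _line_values(mesh, sol_lo.config.positions[:, 2], 0.0)
    z_hi = _line_values(mesh, sol_hi.config.positions[:, 2], 0.0)
    dz = z_lo - z_hi
    imax = int(np.argmax(dz))
    half = dz[imax] / 2.0
    y = _line_values(mesh, sol_lo.config.positions[:, 1], 0.0)
    dists = []
    for side in (slice(imax, None, 1), slice(imax, None, -1)):
        d = dz[side]
        yy = y[side]
        below = np.nonzero(d <= half)[0]
        if len(below):
            k = below[0]
            dists.append(abs(np.interp(half, [d[k], d[k - 1]],
                                       [yy[k], yy[k - 1]]) - y[imax]))
    return float(np.mean(dists)) if dists else np.nan
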