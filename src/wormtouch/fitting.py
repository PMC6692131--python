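"""Parameter inference from deformation, force and current data.

Implements the estimation chain used to pin the model to experiments:
p/E from deformation profiles, the internal pressure p from
force-indentation curves, the coefficients of the factorized
force-indentation law from simulated curve families, and gating
parameters from mechanoreceptor current traces.  All searches are
deterministic given their seeds and record objective diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .geometry import Indenter, ShellGeometry
from .solver import (SolverOptions, calibrate_reference, deformation_profile,
                     force_displacement_curve, solve_indentation)

__all__ = [
    "FitResult",
    "fit_p_over_E",
    "fit_pressure",
    "fit_force_law",
    "fit_gating",
    "model_error_histogram",
]


@dataclass
class FitResult:
    params: dict
    sse: float
    r2: float
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.sse < 0 or self.r2 > 1.0 + 1e-12:
            raise ValueError("inconsistent goodness-of-fit values")


def _r2(y, yhat):
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)


# ---------------------------------------------------------------------------
# mechanics fits
# ---------------------------------------------------------------------------

def _profile_objective(pe: float, y_data, depth_data, base: ShellGeometry,
                       Rb: float, w0: float,
                       opts: SolverOptions) -> float:
    geo = ShellGeometry(R=base.R, t=base.t, L=base.L, nu=base.nu,
                        E=base.E, p=pe * base.E)
    geo = calibrate_reference(geo, opts=opts)
    sol = solve_indentation(geo, Indenter(Rb=Rb, w0=w0), opts=opts)
    prof = deformation_profile(sol)
    pred = np.interp(np.abs(y_data), prof.y - prof.center, -prof.uz)
    return float(np.sum((pred - depth_data) ** 2))


def fit_p_over_E(profiles: pd.DataFrame, geometry: ShellGeometry,
                 Rb: float = 10e-6, w0: float = 8e-6,
                 grid: np.ndarray | None = None,
                 opts: SolverOptions = SolverOptions(n_s=56, n_phi=28,
                                                     gtol=1e-8)) -> FitResult:
    """Least-squares p/E from measured deformation profiles.

    ``profiles`` columns: y_m (longitudinal offset from the bead) and
    depth_m (vertical deformation, positive into the body).  Logarithmic
    grid search with golden-section refinement around the minimum.
    """
    y = profiles["y_m"].to_numpy(float)
    d = profiles["depth_m"].to_numpy(float)
    if grid is None:
        grid = np.logspace(-4, -1, 10)
    obj = [_profile_objective(pe, y, d, geometry, Rb, w0, opts)
           for pe in grid]
    k = int(np.argmin(obj))
    if k == 0 or k == len(grid) - 1:
        diag = {"grid": grid, "objective": np.asarray(obj),
                "bracketed": False}
        pe_best, sse = grid[k], obj[k]
    else:
        res = minimize_scalar(
            lambda lp: _profile_objective(np.exp(lp), y, d, geometry, Rb,
                                          w0, opts),
            bracket=(np.log(grid[k - 1]), np.log(grid[k]),
                     np.log(grid[k + 1])),
            method="golden", options={"xtol": 3e-2})
        pe_best, sse = float(np.exp(res.x)), float(res.fun)
        diag = {"grid": grid, "objective": np.asarray(obj), "bracketed": True}
    # goodness relative to the data variance
    geo = ShellGeometry(R=geometry.R, t=geometry.t, L=geometry.L,
                        nu=geometry.nu, E=geometry.E, p=pe_best * geometry.E)
    geo = calibrate_reference(geo, opts=opts)
    sol = solve_indentation(geo, Indenter(Rb=Rb, w0=w0), opts=opts)
    prof = deformation_profile(sol)
    pred = np.interp(np.abs(y), prof.y - prof.center, -prof.uz)
    return FitResult(params={"p_over_E": pe_best}, sse=sse, r2=_r2(d, pred),
                     diagnostics=diag)


def fit_pressure(force_data: pd.DataFrame, geometry: ShellGeometry,
                 mode: str = "fixed_p_over_E", p_over_E: float = 0.01,
                 bounds: tuple[float, float] = (5e2, 3e5),
                 Rb: float = 10e-6, n_grid: int = 8,
                 opts: SolverOptions = SolverOptions(n_s=56, n_phi=28,
                                                     gtol=1e-8)) -> FitResult:
    """1D least squares for the internal pressure p.

    ``mode='fixed_p_over_E'`` (stiff worms): E co-varies so p/E stays at
    the given ratio.  ``mode='fixed_E'`` (soft worms): E and t stay at
    the geometry's values and only p varies.
    ``force_data`` columns: w0_m, F_N.
    """
    w0 = force_data["w0_m"].to_numpy(float)
    F = force_data["F_N"].to_numpy(float)
    order = np.argsort(w0)
    w0, F = w0[order], F[order]

    def curve(p):
        if mode == "fixed_p_over_E":
            E = p / p_over_E
        elif mode == "fixed_E":
            E = geometry.E
        else:
            raise ValueError(f"unknown mode {mode!r}")
        geo = ShellGeometry(R=geometry.R, t=geometry.t, L=geometry.L,
                            nu=geometry.nu, E=E, p=p)
        geo = calibrate_reference(geo, opts=opts)
        return force_displacement_curve(geo, w0, Rb=Rb, opts=opts)

    lo, hi = bounds
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
    obj = [float(np.sum((curve(p) - F) ** 2)) for p in grid]
    k = int(np.argmin(obj))
    if 0 < k < len(grid) - 1:
        res = minimize_scalar(
            lambda lp: float(np.sum((curve(np.exp(lp)) - F) ** 2)),
            bracket=(np.log(grid[k - 1]), np.log(grid[k]),
                     np.log(grid[k + 1])),
            method="golden", options={"xtol": 3e-2})
        p_best, sse = float(np.exp(res.x)), float(res.fun)
        bracketed = True
    else:
        p_best, sse, bracketed = float(grid[k]), obj[k], False
    pred = curve(p_best)
    return FitResult(params={"p": p_best}, sse=sse, r2=_r2(F, pred),
                     diagnostics={"grid": grid, "objective": np.asarray(obj),
                                  "bracketed": bracketed, "mode": mode})


def fit_force_law(curves: pd.DataFrame) -> FitResult:
    """Fit the factorized law F = a1 p R w0 (1 + a2 Rb/R)(1 + a3 w0/R).

    ``curves`` columns: R_m, Rb_m, w0_m, F_N, p_Pa.  Linear least
    squares in the monomial basis initializes a nonlinear refinement of
    (a1, a2, a3); the pooled R^2 is computed on the forces.
    """
    R = curves["R_m"].to_numpy(float)
    Rb = curves["Rb_m"].to_numpy(float)
    w0 = curves["w0_m"].to_numpy(float)
    F = curves["F_N"].to_numpy(float)
    p = curves["p_Pa"].to_numpy(float)
    if len(np.unique(R)) < 2 or len(np.unique(Rb)) < 2 \
            or len(np.unique(w0)) < 5:
        raise ValueError("need >= 2 radii, >= 2 bead sizes, >= 5 depths")
    y = F / (p * R * w0)
    X = np.stack([np.ones_like(y), Rb / R, w0 / R, (Rb / R) * (w0 / R)],
                 axis=1)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        raise np.linalg.LinAlgError("rank-deficient design for the fit")
    a1 = max(coef[0], 1e-12)
    a2 = coef[1] / a1
    a3 = coef[2] / a1

    def resid(a):
        return a[0] * p * R * w0 * (1 + a[1] * Rb / R) * (1 + a[2] * w0 / R) - F

    res = least_squares(resid, x0=[a1, a2, a3], method="lm")
    a1, a2, a3 = res.x
    pred = resid(res.x) + F
    return FitResult(params={"alpha1": float(a1), "alpha2": float(a2),
                             "alpha3": float(a3)},
                     sse=float(np.sum(resid(res.x) ** 2)),
                     r2=_r2(F, pred),
                     diagnostics={"linear_init": (float(coef[0]),
                                                  float(a2), float(a3)),
                                  "nfev": res.nfev})


# ---------------------------------------------------------------------------
# gating fit
# ---------------------------------------------------------------------------

def fit_gating(traces: pd.DataFrame, simulate, bounds: dict,
               n_starts: int = 4, seed: int = 0,
               model: str = "symmetric") -> FitResult:
    """Multi-start bounded least squares for gating parameters.

    ``traces`` columns: t_s, I_pA (ensemble-mean current).  ``simulate``
    maps a parameter dict to a predicted trace on the same grid (the
    caller wires in the mechanics/ensemble pipeline, typically with a
    frozen channel layout for speed).  ``bounds`` maps parameter names
    (subset of g0, g1, g2, a, tau, r0) to (lo, hi).
    """
    t = traces["t_s"].to_numpy(float)
    I = traces["I_pA"].to_numpy(float)
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    if np.std(I) == 0:
        return FitResult(params={k: np.nan for k in names}, sse=0.0, r2=1.0,
                         diagnostics={"unidentifiable": True,
                                      "reason": "flat trace"}, seed=seed)

    def resid(x):
        return simulate(dict(zip(names, x))) - I

    rng = np.random.default_rng(seed)
    best = None
    starts = [0.5 * (lo + hi)]
    for _ in range(n_starts - 1):
        starts.append(lo + (hi - lo) * rng.uniform(0.15, 0.85, len(names)))
    history = []
    for x0 in starts:
        res = least_squares(resid, x0=x0, bounds=(lo, hi), xtol=1e-6,
                            ftol=1e-6, max_nfev=60 * len(names))
        history.append((float(np.sum(res.fun**2)), res.x.copy()))
        if best is None or history[-1][0] < best[0]:
            best = history[-1]
    sse, x = best
    at_bounds = np.any(np.isclose(x, lo, rtol=1e-3)
                       | np.isclose(x, hi, rtol=1e-3))
    all_at_bounds = all(
        np.any(np.isclose(xx, lo, rtol=1e-3) | np.isclose(xx, hi, rtol=1e-3))
        for _, xx in history)
    pred = simulate(dict(zip(names, x)))
    return FitResult(params=dict(zip(names, map(float, x))), sse=sse,
                     r2=_r2(I, pred),
                     diagnostics={"n_starts": n_starts,
                                  "at_bounds": bool(at_bounds),
                                  "unidentifiable": bool(all_at_bounds),
                                  "sse_per_start": [h[0] for h in history],
                                  "model": model},
                     seed=seed)


def model_error_histogram(errors: np.ndarray, bins: int = 20) -> dict:
    """Normalized histogram plus summary statistics of per-realization
    model errors."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("no errors given")
    if np.ptp(errors) == 0:
        edges = np.array([errors[0] - 0.5, errors[0] + 0.5])
        dens = np.array([1.0])
    else:
        dens, edges = np.histogram(errors, bins=bins, density=True)
    return {"density": dens, "edges": edges,
            "mean": float(np.mean(errors)),
            "median": float(np.median(errors)),
            "q25": float(np.percentile(errors, 25)),
            "q75": float(np.percentile(errors, 75))}
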