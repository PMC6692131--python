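"""Shared fixtures: expensive shell solves are done once per session."""

import numpy as np
import pytest

from wormtouch import (BoundaryCondition, Indenter, ShellGeometry,
                       SolverOptions, calibrate_reference,
                       force_displacement_curve)
from wormtouch.population import MechanicsDrive


STD = dict(R=25e-6, t=1e-6, L=1e-3, nu=0.3, E=4e6)


@pytest.fixture(scope="session")
def opts_test():
    """Coarse-but-honest solver settings used throughout the suite."""
    return SolverOptions(n_s=56, n_phi=28, grading=4.5, phi_grading=0.5,
                         gtol=1e-8)


@pytest.fixture(scope="session")
def geo40(opts_test):
    """Calibrated standard worm at the fitted pressure p = 40 kPa."""
    return calibrate_reference(ShellGeometry(p=40e3, **STD), opts=opts_test)


@pytest.fixture(scope="session")
def geo0():
    return ShellGeometry(p=0.0, **STD)


@pytest.fixture(scope="session")
def curve40(geo40, opts_test):
    """Warm-started force-indentation ladder at the standard bead."""
    w0 = np.array([2e-6, 4e-6, 6e-6, 8e-6])
    F, sols = force_displacement_curve(geo40, w0, Rb=10e-6, opts=opts_test,
                                       return_solutions=True)
    return w0, F, sols


@pytest.fixture(scope="session")
def sol8(curve40):
    return curve40[2][-1]


@pytest.fixture(scope="session")
def rest40(curve40, geo40, opts_test):
    from wormtouch.solver import solve_indentation
    return solve_indentation(geo40, Indenter(Rb=10e-6, w0=0.0),
                             BoundaryCondition(), opts=opts_test)


@pytest.fixture(scope="session")
def drive40(curve40, rest40):
    """Deformation drive along the TRN line for the standard ladder."""
    _, _, sols = curve40
    return MechanicsDrive.from_solutions([rest40] + list(sols))


@pytest.fixture(scope="session")
def dense_curve40(geo40, opts_test):
    """Dense force ladder used for the work-energy balance check."""
    w0 = np.arange(2, 12) * 0.75e-6
    F, sols = force_displacement_curve(geo40, w0, Rb=10e-6, opts=opts_test,
                                       return_solutions=True)
    return w0, F, sols


@pytest.fixture(scope="session")
def yh_pair(opts_test):
    """Half-max widths for two shells with equal p/(E t) (tau >> 1)."""
    from wormtouch.solver import deformation_profile, solve_indentation
    out = []
    for t in (0.5e-6, 1e-6):
        geo = calibrate_reference(
            ShellGeometry(R=25e-6, t=t, L=1e-3, nu=0.3, E=4e6 * 1e-6 / t,
                          p=40e3), opts=opts_test)
        sol = solve_indentation(geo, Indenter(Rb=10e-6, w0=8e-6),
                                opts=opts_test)
        out.append((geo, deformation_profile(sol).yh))
    return out


@pytest.fixture(scope="session")
def sinusoid_trace(drive40):
    """Response to a sinusoidal indentation about a pre-indented offset."""
    from wormtouch.gating import GatingParams
    from wormtouch.population import simulate_response
    from wormtouch.protocols import make_stimulus
    f0 = 5.0
    stim = make_stimulus("sinusoid", amplitude=2e-6, offset=4e-6,
                         frequency=f0, dt=1e-3, duration=2.0, t_on=0.2)
    trace = simulate_response(drive40, stim.values, stim.dt, GatingParams(),
                              n_realizations=6, seed=4)
    return f0, stim, trace


@pytest.fixture(scope="session")
def preindent_result(geo40, opts_test):
    """Plain vs 5-um-pre-indented steps of equal relative amplitude."""
    from wormtouch.protocols import pre_indentation_experiment
    return pre_indentation_experiment(geo40, [3e-6], pre_depth=5e-6,
                                      n_realizations=8, seed=13,
                                      opts=opts_test)


@pytest.fixture(scope="session")
def clamp_pressure_result(opts_test):
    """Peak currents for displacement- vs force-clamped steps at two
    internal pressures (stiff vs softer worm)."""
    from wormtouch.protocols import make_stimulus, simulate_protocol
    out = {}
    for p in (1.6e3, 40e3):
        geo = calibrate_reference(ShellGeometry(p=p, **STD), opts=opts_test)
        disp = make_stimulus("step", amplitude=8e-6, dt=1e-3, duration=0.6,
                             t_off=0.4)
        tr_d = simulate_protocol(geo, disp, n_realizations=8, seed=9,
                                 opts=opts_test)
        F_cmd = 6e-6 * 40e3 * 25e-6 * 2.0        # ~ stiff-worm force scale
        force = make_stimulus("step", amplitude=F_cmd, dt=1e-3, duration=0.6,
                              t_off=0.4, clamp="force")
        tr_f = simulate_protocol(geo, force, n_realizations=8, seed=9,
                                 opts=opts_test)
        rest_d, rest_f = tr_d.mean[50], tr_f.mean[50]
        out[p] = {"disp": tr_d.summary["peak_on_pA"] - rest_d,
                  "force": tr_f.summary["peak_on_pA"] - rest_f}
    return out


@pytest.fixture(scope="session")
def force_law_mini(opts_test):
    """Scaled-down factorized-law family: R x Rb = {25, 40} x {3, 10} um.

    Returns (curve table, solution ladders) — the R = 25 um ladders also
    drive the bead-size current comparison.
    """
    import pandas as pd
    from wormtouch.solver import solve_indentation
    opts_small = SolverOptions(n_s=64, n_phi=36, grading=5.0,
                               phi_grading=0.7, gtol=1e-8)
    rows, drives = [], {}
    for R in (25e-6, 40e-6):
        # R/t fixed: thickness rescales out of the pressure-dominated law
        geo = calibrate_reference(
            ShellGeometry(R=R, t=R / 25.0, L=1e-3, nu=0.3, E=4e6, p=40e3))
        for Rb in (3e-6, 10e-6):
            opts = opts_small if Rb <= 3e-6 else opts_test
            w0s = (np.arange(1.5, 8.26, 1.5) * 1e-6 if Rb <= 3e-6
                   else np.arange(2.0, 8.1, 2.0) * 1e-6)
            F, sols = force_displacement_curve(geo, w0s, Rb=Rb, opts=opts,
                                               return_solutions=True)
            rest = solve_indentation(geo, Indenter(Rb=Rb, w0=0.0),
                                     opts=opts)
            drives[(R, Rb)] = [rest] + list(sols)
            for w, f in zip(w0s, F):
                rows.append(dict(R_m=R, Rb_m=Rb, w0_m=w, F_N=f, p_Pa=40e3))
    return pd.DataFrame(rows), drives


@pytest.fixture(scope="session")
def fit_opts():
    return SolverOptions(n_s=48, n_phi=24, gtol=1e-8)


@pytest.fixture(scope="session")
def pe_recovery(fit_opts):
    """Closed-loop p/E recovery from noisy synthetic profiles."""
    import wormtouch.fitting as ft
    import wormtouch.synthetic as sy
    spec = sy.FixtureSpec(seed=7, noise_rel_sd=0.01, w0=6e-6)
    df, meta = sy.synth_profiles(spec, opts=fit_opts)
    res = ft.fit_p_over_E(df, ShellGeometry(**STD), w0=6e-6,
                          grid=np.logspace(-3, -1.3, 5), opts=fit_opts)
    return res, meta


@pytest.fixture(scope="session")
def pressure_recovery(fit_opts):
    """Closed-loop internal-pressure recovery from noisy force curves."""
    import wormtouch.fitting as ft
    import wormtouch.synthetic as sy
    spec = sy.FixtureSpec(seed=11, noise_rel_sd=0.01)
    df, meta = sy.synth_force_curves(spec, opts=fit_opts,
                                     w0_grid=np.array([2e-6, 4e-6, 6e-6]))
    res = ft.fit_pressure(df, ShellGeometry(**STD), mode="fixed_p_over_E",
                          bounds=(5e3, 3e5), n_grid=5, opts=fit_opts)
    return res, meta


@pytest.fixture(scope="session")
def gating_recovery(drive40):
    """Closed-loop gating-parameter recovery from a noisy mean trace."""
    import pandas as pd
    import wormtouch.fitting as ft
    from wormtouch.gating import GatingParams
    from wormtouch.population import simulate_response
    from wormtouch.protocols import make_stimulus

    truth = GatingParams(g0=6.0, g1=150.0, tau=0.04)
    stim = make_stimulus("step", amplitude=8e-6, dt=2e-3, duration=0.55,
                         t_on=0.1, t_off=0.38, tau=truth.tau)

    def run(params):
        tr = simulate_response(drive40, stim.values, stim.dt, params,
                               n_realizations=3, seed=21)
        return tr.mean

    target = run(truth)
    rng = np.random.default_rng(5)
    noisy = target + 0.05 * np.max(np.abs(target)) \
        * rng.standard_normal(len(target))
    traces = pd.DataFrame({"t_s": stim.t, "I_pA": noisy})

    def simulate(pdict):
        return run(GatingParams(g0=pdict["g0"], g1=pdict["g1"],
                                tau=pdict["tau"]))

    res = ft.fit_gating(traces, simulate,
                        bounds={"g0": (3.0, 10.0), "g1": (40.0, 400.0),
                                "tau": (0.015, 0.12)},
                        n_starts=2, seed=1)
    return res, truth


@pytest.fixture(scope="session")
def step_trace(drive40):
    """Standard 8 um step-response ensemble (symmetric model)."""
    from wormtouch.gating import GatingParams
    from wormtouch.population import simulate_response
    from wormtouch.protocols import make_stimulus
    stim = make_stimulus("step", amplitude=8e-6, dt=1e-3, duration=0.8,
                         t_on=0.1, t_off=0.5)
    trace = simulate_response(drive40, stim.values, stim.dt, GatingParams(),
                              n_realizations=12, seed=11,
                              summary_windows=((0.1, 0.25), (0.5, 0.65)))
    return stim, trace
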