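"""Shell equilibrium solver: calibration, forces, profiles, moduli."""

import numpy as np
import pytest

from wormtouch import (BoundaryCondition, Indenter, ShellGeometry,
                       SolverOptions, bulk_modulus, calibrate_reference,
                       deformation_profile, enclosed_volume,
                       force_displacement_curve, solve_indentation, strain_at,
                       total_energy)
from wormtouch.geometry import ShellConfiguration, build_mesh
from wormtouch.solver import (indenter_force_by_energy_difference,
                              solve_rest_state)

STD = dict(R=25e-6, t=1e-6, L=1e-3, nu=0.3, E=4e6)


# ---------------------------------------------------------------------------
# calibration of the no-stress state
# ---------------------------------------------------------------------------

def test_calibration_identity_at_zero_pressure(geo0):
    assert calibrate_reference(geo0) is geo0


def test_calibration_small_pressure_matches_linear_membrane():
    # p/E = 1e-4: hoop strain ~ pR/(Et) = 2.5e-3; the calibrated
    # reference radius must sit below the target by that amount
    geo = calibrate_reference(ShellGeometry(p=400.0, **STD))
    rel = geo.R / geo.reference_R - 1.0
    assert rel == pytest.approx(400.0 * 25e-6 / (4e6 * 1e-6), rel=0.05)


def test_calibration_self_consistent_at_40kPa(geo40, opts_test):
    mesh, u_rest, _ = solve_rest_state(geo40, opts_test)
    pos = mesh.positions + u_rest
    mid = np.abs(mesh.positions[:, 1]) < geo40.reference_L / 4
    R_meas = np.mean(np.hypot(pos[mid, 0], pos[mid, 2]))
    assert R_meas == pytest.approx(geo40.R, rel=1e-3)


# ---------------------------------------------------------------------------
# indentation
# ---------------------------------------------------------------------------

def test_zero_indentation_is_rest_state(geo40, opts_test):
    sol = solve_indentation(geo40, Indenter(w0=0.0), opts=opts_test)
    assert sol.F == 0.0
    assert not sol.contact.any()


def test_profile_depth_matches_commanded_indentation(sol8):
    prof = deformation_profile(sol8)
    assert -prof.uz.min() == pytest.approx(8e-6, rel=0.01)
    # symmetric bead placement: symmetric profile
    left = np.interp(-15e-6, prof.y, prof.uz)
    right = np.interp(15e-6, prof.y, prof.uz)
    assert left == pytest.approx(right, rel=0.05)


def test_force_positive_and_strictly_increasing(curve40):
    w0, F, _ = curve40
    assert np.all(F > 0)
    assert np.all(np.diff(F) > 0)


def test_force_slope_increases_with_pressure(curve40, opts_test):
    # soft worm (p = 1.6 kPa): much shallower force-indentation relation
    w0, F40, _ = curve40
    geo_soft = calibrate_reference(ShellGeometry(p=1.6e3, **STD),
                                   opts=opts_test)
    F_soft = force_displacement_curve(geo_soft, w0, Rb=10e-6, opts=opts_test)
    assert np.all(F_soft < F40)
    assert F_soft[-1] / w0[-1] < 0.25 * F40[-1] / w0[-1]


def test_force_agrees_with_factorized_law(curve40, geo40):
    from wormtouch.oracles import factorized_force
    w0, F, _ = curve40
    pred = factorized_force(geo40.p, geo40.R, 10e-6, w0[-1])
    assert F[-1] == pytest.approx(pred, rel=0.2)


def test_energy_force_consistency(geo40, opts_test, curve40):
    # virtual-work force vs central-difference dE/dw0 across equilibria
    w0, F, sols = curve40
    dF = indenter_force_by_energy_difference(
        geo40, Indenter(Rb=10e-6, w0=6e-6), opts=opts_test, dw=0.1e-6)
    assert dF == pytest.approx(F[2], rel=0.01)


def test_indenter_work_balances_energy(dense_curve40):
    # cumulative int F dw0 = change of (elastic + pressure) energy,
    # compared between two states of the same continuation ladder with a
    # dense quadrature (the work between them dominates solver noise)
    w0, F, sols = dense_curve40
    work = np.trapezoid(F, w0)
    def energy(sol):
        return (sol.energies["stretching"] + sol.energies["bending"]
                + sol.energies["pressure"])
    delta = energy(sols[-1]) - energy(sols[0])
    assert work == pytest.approx(delta, rel=0.05)


def test_pressure_dominance_bending_subdominant(sol8):
    e = sol8.energies
    assert e["bending"] < 0.05 * abs(e["stretching"] + e["pressure"])


def test_volume_decreases_with_indentation(curve40, rest40):
    # the dimple displaces volume; below ~2 um the change is within
    # solver resolution, so monotonicity is asserted from there on
    _, _, sols = curve40
    V = np.array([s.V for s in sols])          # w0 = 2, 4, 6, 8 um
    assert V[-1] < rest40.V
    assert np.all(np.diff(V) < 0)


def test_contact_nodes_on_sphere(sol8):
    pen = sol8.energies["penetration"]
    tol = sol8.geometry.t / 100
    assert pen.max() <= tol
    d = np.linalg.norm(sol8.config.positions[sol8.contact]
                       - sol8.bead_center, axis=1)
    assert np.all(d <= sol8.indenter.Rb)


# ---------------------------------------------------------------------------
# profiles and strains
# ---------------------------------------------------------------------------

def test_yh_decreases_with_p_over_E(opts_test, sol8):
    geo_soft = calibrate_reference(ShellGeometry(p=4e3, **STD),
                                   opts=opts_test)   # p/E = 1e-3
    sol_soft = solve_indentation(geo_soft, Indenter(Rb=10e-6, w0=8e-6),
                                 opts=opts_test)
    yh_soft = deformation_profile(sol_soft).yh
    yh_stiff = deformation_profile(sol8).yh
    assert yh_stiff < yh_soft


def test_yh_collapse_in_p_over_Et(yh_pair):
    # same p/(E t), different t, both with tau >> 1: yh within 5%
    (geo_a, yh_a), (geo_b, yh_b) = yh_pair
    assert geo_a.shell_parameter > 5 and geo_b.shell_parameter > 5
    assert yh_a == pytest.approx(yh_b, rel=0.05)


def test_strain_zero_in_undeformed_state(geo0):
    mesh = build_mesh(geo0, n_s=32, n_phi=24)
    from wormtouch.solver import MechanicsSolution
    sol = MechanicsSolution(
        geometry=geo0, mesh=mesh, config=ShellConfiguration.undeformed(mesh),
        u_rest=np.zeros((mesh.n_nodes, 3)), bc=BoundaryCondition(),
        indenter=None, F=0.0, energies={}, V=0.0, V_rest=0.0,
        contact=np.zeros(mesh.n_nodes, bool), k_pen=0.0, bead_center=None)
    eps = strain_at(sol, 0.0, 0.3)
    assert np.allclose(eps, 0.0, atol=1e-12)


def test_strain_uniform_inflation_hoop(geo40, opts_test, rest40):
    # the resting state carries the finite hoop strain of the inflation
    eps = strain_at(rest40, 0.0, 0.0)
    lam_c = geo40.R / geo40.reference_R
    assert eps[0, 0] == pytest.approx((lam_c**2 - 1) / 2, rel=0.05)


def test_strain_nearly_diagonal_on_top_line(sol8):
    s_pts = np.linspace(-30e-6, 30e-6, 13)
    eps = strain_at(sol8, s_pts, 0.0)
    rest_eps = None
    shear = np.abs(eps[:, 0, 1])
    diag = np.maximum(np.abs(eps[:, 0, 0]), np.abs(eps[:, 1, 1]))
    assert np.all(shear <= 0.05 * diag)


def test_strain_outside_mesh_rejected(sol8):
    with pytest.raises(ValueError):
        strain_at(sol8, 1e-3, 0.0)


# ---------------------------------------------------------------------------
# volume / bulk modulus
# ---------------------------------------------------------------------------

def test_enclosed_volume_examples(geo0):
    mesh = build_mesh(geo0, n_s=48, n_phi=40)
    V = enclosed_volume(ShellConfiguration.undeformed(mesh))
    assert V == pytest.approx(np.pi * 25e-6**2 * 1e-3, rel=5e-3)


def test_bulk_modulus_linear_limit_free_lateral(geo0):
    kappa = bulk_modulus(geo0, 500.0, bc=None, load="lateral")
    pred = 4e6 * 1e-6 / ((2 - 0.3) * 25e-6)
    assert kappa == pytest.approx(pred, rel=0.03)


def test_bulk_modulus_linear_limit_capped(geo0):
    kappa = bulk_modulus(geo0, 500.0, bc=None, load="capped")
    pred = 4e6 * 1e-6 / ((2.5 - 2 * 0.3) * 25e-6)
    assert kappa == pytest.approx(pred, rel=0.03)


def test_bulk_modulus_linearity_in_dp(geo40):
    k1 = bulk_modulus(geo40, 1e3, bc=None)
    k4 = bulk_modulus(geo40, 4e3, bc=None)
    assert k1 == pytest.approx(k4, rel=0.02)


def test_bulk_modulus_pressurized_in_printed_band(geo40):
    kappa = bulk_modulus(geo40, 2e3, bc=None)
    assert 150e3 <= kappa <= 230e3


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def test_total_energy_zero_for_undeformed_unpressurized(geo0):
    mesh = build_mesh(geo0, n_s=32, n_phi=24)
    parts = total_energy(ShellConfiguration.undeformed(mesh), geo0)
    assert parts["stretching"] == pytest.approx(0.0, abs=1e-25)
    assert parts["bending"] == pytest.approx(0.0, abs=1e-25)


def test_plugged_ends_unimplemented():
    from wormtouch.geometry import EndCondition
    with pytest.raises(NotImplementedError):
        BoundaryCondition(ends=EndCondition.PLUGGED)
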