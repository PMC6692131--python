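"""Single-channel biophysics: frames, filament dynamics, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormtouch import gating as gt


AXIS = np.array([0.0, 1.0, 0.0])
NORMAL = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# local frames
# ---------------------------------------------------------------------------

def test_frame_theta_zero_is_primed_basis():
    f = gt.local_frame(0.0, AXIS, NORMAL)
    assert np.allclose(f.w1, [1, 0, 0])
    assert np.allclose(f.w2, [0, 1, 0])
    assert np.allclose(f.w3, [0, 0, 1])


def test_frame_quarter_turn():
    f = gt.local_frame(np.pi / 2, AXIS, NORMAL)
    assert np.allclose(f.w1, [0, 0, -1], atol=1e-12)
    assert np.allclose(f.w2, [0, 1, 0], atol=1e-12)
    assert np.allclose(f.w3, [1, 0, 0], atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.floats(-10, 10))
def test_frame_orthonormal_any_theta(theta):
    f = gt.local_frame(theta, AXIS, NORMAL)
    M = np.stack([f.w1, f.w2, f.w3])
    assert np.allclose(M @ M.T, np.eye(3), atol=1e-12)


def test_frame_rejects_degenerate_axis():
    with pytest.raises(ValueError):
        gt.local_frame(0.0, np.zeros(3), NORMAL)


# ---------------------------------------------------------------------------
# filament kinematics and relaxation
# ---------------------------------------------------------------------------

def test_filament_drive_uniaxial_stretching_relation():
    # eps_yy = 0.1 on an axial filament: |Gamma| = sqrt(1.2)
    grad_u = np.zeros((1, 3, 3))
    lam = np.sqrt(1.2)
    grad_u[0, 1, 1] = lam - 1.0
    Gam = gt.filament_drive(grad_u, AXIS)
    assert np.linalg.norm(Gam[0]) == pytest.approx(np.sqrt(1.2), rel=1e-12)


def test_filament_drive_zero_strain_identity():
    Gam = gt.filament_drive(np.zeros((5, 3, 3)), np.array([0.3, 0.5, 0.81]))
    assert np.allclose(Gam, [0.3, 0.5, 0.81])


def test_filament_step_decay_is_exponential():
    tau, dt = 0.05, 1e-3
    n = 301
    Gam = np.zeros((n, 3))
    Gam[1:, 0] = 0.1                           # tangential step
    x = gt.integrate_filament(Gam, tau, dt, w3_t=NORMAL)
    i_tau = 1 + int(tau / dt)
    assert x[i_tau, 0] / x[1, 0] == pytest.approx(np.exp(-1), rel=1e-6)


def test_filament_adaptation_under_constant_drive():
    tau, dt = 0.02, 1e-3
    n = 1 + int(15 * tau / dt)
    Gam = np.zeros((n, 3))
    Gam[1:, 0] = 0.2
    x = gt.integrate_filament(Gam, tau, dt, w3_t=NORMAL)
    assert np.linalg.norm(x[-1]) < 1e-3 * 0.2


def test_filament_sinusoid_frequency_response():
    tau = 0.05
    omega = 1.0 / tau
    dt = tau / 200
    t = np.arange(0, 60 * tau, dt)
    Gam = np.zeros((len(t), 3))
    Gam[:, 0] = 0.1 * np.sin(omega * t)
    x = gt.integrate_filament(Gam, tau, dt, w3_t=NORMAL)
    amp = np.abs(x[len(t) // 2:, 0]).max() / 0.1
    assert amp == pytest.approx(1 / np.sqrt(2), rel=0.01)


def test_filament_halfspace_constraint():
    tau, dt = 0.05, 1e-3
    Gam = np.zeros((50, 3))
    Gam[1:, 2] = -0.3                          # inward normal pull
    x = gt.integrate_filament(Gam, tau, dt, w3_t=NORMAL)
    assert np.all(x[:, 2] >= -1e-15)
    x_free = gt.integrate_filament(Gam, tau, dt)     # unconstrained
    assert x_free[1, 2] < 0


def test_tangential_force_projection():
    f = gt.local_frame(0.0, AXIS, NORMAL)
    F1, F2, F = gt.tangential_force(np.array([0.2, 0.0, 0.5]), f)
    assert F1 == pytest.approx(-0.2)
    assert F == pytest.approx(0.2)             # normal part excluded
    _, _, F0 = gt.tangential_force(np.zeros(3), f)
    assert F0 == 0.0
    _, _, Fn = gt.tangential_force(0.4 * NORMAL, f)
    assert Fn == 0.0                           # orthogonal filament


# ---------------------------------------------------------------------------
# free energies and rates
# ---------------------------------------------------------------------------

def test_free_energy_rest_and_split():
    p = gt.GatingParams(g0=2.0, a=0.5)
    dg, dgos, dgsc = gt.free_energies(0.0, 0.0, p)
    assert dg == 2.0 and dgos == 1.0 and dgsc == 1.0


def test_free_energy_symmetric_vs_directional_sign():
    p = gt.GatingParams(g0=2.0, g1=10.0, g2=10.0, v=np.array([1.0, 0.0]))
    sym_plus = gt.free_energies(0.3, 0.0, p, "symmetric")[0]
    sym_minus = gt.free_energies(-0.3, 0.0, p, "symmetric")[0]
    assert sym_plus == sym_minus               # isotropic in the plane
    dir_plus = gt.free_energies(0.3, 0.0, p, "directional")[0]
    dir_minus = gt.free_energies(-0.3, 0.0, p, "directional")[0]
    assert dir_plus != dir_minus
    assert dir_plus + dir_minus == pytest.approx(2 * p.g0)


def test_rates_at_zero_gap_equal_attempt_rate():
    rates = gt.transition_rates(0.0, 0.0, 500.0)
    assert np.allclose(rates, 500.0)


def test_stationary_distribution_boltzmann():
    P = gt.stationary_distribution(2.0, 0.5)
    w = np.array([1.0, np.exp(-1.0), np.exp(-2.0)])
    assert np.allclose(P, w / w.sum(), atol=1e-12)
    assert P == pytest.approx([0.6652, 0.2448, 0.0900], abs=1e-4)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.floats(-8, 8), st.floats(0.05, 0.95))
def test_master_equation_converges_to_boltzmann(dg, a):
    rates = gt.transition_rates(a * dg, (1 - a) * dg, 200.0)
    rt = tuple(np.full(400, r) for r in rates)
    P = gt.propagate_master([1.0, 0.0, 0.0], rt, 5e-4)
    assert np.allclose(P[-1], gt.stationary_distribution(dg, a), atol=1e-6)
    assert np.allclose(P.sum(axis=-1), 1.0, atol=1e-9)


def test_master_equation_frozen_without_rates():
    rt = tuple(np.zeros(10) for _ in range(4))
    P = gt.propagate_master([0.2, 0.3, 0.5], rt, 1e-3)
    assert np.allclose(P[-1], [0.2, 0.3, 0.5], atol=1e-12)


def test_master_matches_gillespie_ensemble():
    # time-varying rates: master-equation occupancy vs a stochastic
    # single-channel ensemble within 3 standard errors
    dt, n_t = 1e-3, 300
    t = np.arange(n_t) * dt
    dg = 4.0 - 6.0 * np.exp(-((t - 0.1) / 0.05) ** 2)   # transient opening
    rates = gt.transition_rates(0.5 * dg, 0.5 * dg, 300.0)
    rt = tuple(np.broadcast_to(r, (n_t,)).copy() for r in rates)
    P = gt.propagate_master(gt.stationary_distribution(4.0, 0.5), rt, dt)
    n_traj = 3000
    occ = np.zeros((n_t, 3))
    rng = np.random.default_rng(90000)
    for k in range(n_traj):
        s0 = rng.choice(3, p=gt.stationary_distribution(4.0, 0.5))
        traj = gt.gillespie_channel(rt, dt, t[-1], seed=90000 + k, state0=s0)
        occ[np.arange(n_t), traj] += 1
    occ /= n_traj
    # compare the open-state occupancy at a few pre-chosen instants
    for i in (60, 100, 150, 250):
        se = np.sqrt(max(P[i, 2] * (1 - P[i, 2]), 1e-6) / n_traj)
        assert abs(occ[i, 2] - P[i, 2]) <= 3 * se


def test_gillespie_reproducible_and_frozen():
    rt = tuple(np.zeros(5) for _ in range(4))
    tr = gt.gillespie_channel(rt, 1e-3, 4e-3, seed=3, state0=1)
    assert np.all(tr == 1)                     # no rates, no transitions
    rates = gt.transition_rates(0.5, 0.5, 400.0)
    rt = tuple(np.full(5, r) for r in rates)
    t1 = gt.gillespie_channel(rt, 1e-3, 200e-3, seed=7)
    t2 = gt.gillespie_channel(rt, 1e-3, 200e-3, seed=7)
    assert np.array_equal(t1, t2)


def test_params_validation():
    with pytest.raises(ValueError):
        gt.GatingParams(a=1.5)
    with pytest.raises(ValueError):
        gt.GatingParams(tau=-1.0)
    with pytest.raises(ValueError):
        gt.GatingParams(v=np.array([2.0, 0.0]))
    with pytest.raises(ValueError):
        gt.free_energies(0.1, 0.0, gt.GatingParams(v=None), "directional")
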