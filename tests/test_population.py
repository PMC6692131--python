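"""Channel placement, orientations and ensemble-current statistics."""

import numpy as np
import pytest

from wormtouch import gating as gt
from wormtouch import population as pop


def test_place_channels_degenerate_lognormal_equal_spacing():
    params = pop.LayoutParams(mu_ln=np.log(5e-6), sigma_ln=1e-12,
                              extent=(-50e-6, 50e-6))
    lay = pop.place_channels(params, seed=0)
    gaps = np.diff(lay.positions)
    assert np.allclose(gaps, 5e-6, rtol=1e-6)


def test_place_channels_reproducible():
    params = pop.LayoutParams()
    a = pop.place_channels(params, seed=42)
    b = pop.place_channels(params, seed=42)
    assert np.array_equal(a.positions, b.positions)
    c = pop.place_channels(params, seed=43)
    assert not np.array_equal(a.positions, c.positions)


def test_place_channels_lognormal_moments():
    params = pop.LayoutParams(extent=(-250e-6, 250e-6))
    gaps = []
    for seed in range(300):
        lay = pop.place_channels(params, seed)
        gaps.append(np.diff(lay.positions))
    gaps = np.concatenate(gaps)
    mu, sig = params.mu_ln, params.sigma_ln
    mean_th = np.exp(mu + sig**2 / 2)
    var_th = (np.exp(sig**2) - 1) * np.exp(2 * mu + sig**2)
    se_mean = np.sqrt(var_th / len(gaps))
    assert abs(gaps.mean() - mean_th) <= 3 * se_mean
    assert gaps.std() == pytest.approx(np.sqrt(var_th), rel=0.1)


def test_orientations_hemisphere_moment():
    v = pop.sample_orientations(100_000, seed=1, mode="hemisphere")
    assert np.all(v[:, 2] >= 0)
    assert np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)
    # uniform hemisphere: E[Gamma . w3] = 1/2, Var = 1/12
    se = np.sqrt(1 / 12 / len(v))
    assert abs(v[:, 2].mean() - 0.5) <= 3 * se


def test_orientations_tangential_modes():
    v = pop.sample_orientations(500, seed=2, mode="tangential_initial")
    assert np.allclose(v[:, 2], 0.0)
    assert np.allclose(np.linalg.norm(v, axis=1), 1.0)
    a = pop.sample_orientations(64, seed=3)
    b = pop.sample_orientations(64, seed=3)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        pop.sample_orientations(5, 0, mode="bogus")


def test_ensemble_current_closed_and_open():
    P = np.zeros((4, 10, 3))
    P[..., 0] = 1.0
    tr = pop.ensemble_current(P, i_o=-1.6, i_s=-0.8)
    assert np.allclose(tr.mean, 0.0) and np.allclose(tr.var, 0.0)
    P = np.zeros((2, 10, 3))
    P[..., 2] = 1.0
    tr = pop.ensemble_current(P, i_o=-1.6, i_s=-0.8)
    assert np.allclose(tr.mean, -16.0)
    assert np.allclose(tr.var, 0.0)


def test_ensemble_current_binomial_variance():
    # 20 half-open channels: Var = 20 * i_o^2 * 0.25 = 12.8 pA^2
    P = np.zeros((3, 20, 3))
    P[..., 2] = 0.5
    P[..., 0] = 0.5
    tr = pop.ensemble_current(P, i_o=-1.6, i_s=-0.8)
    assert np.allclose(tr.var, 12.8)
    assert np.allclose(tr.mean, -16.0)


def test_analytic_variance_matches_gillespie_population():
    # fixed constant drive: sum of independent-channel variances equals
    # the empirical variance of a simulated channel population
    dg, a, r0 = 1.0, 0.5, 300.0
    n_ch, n_rep = 20, 800
    P_eq = gt.stationary_distribution(dg, a)
    i_o, i_s = -1.6, -0.8
    mean_th = n_ch * (i_o * P_eq[2] + i_s * P_eq[1])
    var_th = n_ch * (i_o**2 * P_eq[2] + i_s**2 * P_eq[1]
                     - (i_o * P_eq[2] + i_s * P_eq[1])**2)
    rates = gt.transition_rates(a * dg, (1 - a) * dg, r0)
    rt = tuple(np.full(2, r) for r in rates)
    rng = np.random.default_rng(17)
    currents = np.empty(n_rep)
    for rep in range(n_rep):
        states = np.array([
            gt.gillespie_channel(rt, 1e-3, 50e-3,
                                 seed=int(rng.integers(2**31)),
                                 state0=int(rng.choice(3, p=P_eq)))[-1]
            for _ in range(n_ch)])
        currents[rep] = i_o * np.sum(states == 2) + i_s * np.sum(states == 1)
    assert currents.mean() == pytest.approx(
        mean_th, abs=3 * np.sqrt(var_th / n_rep))
    # variance of a variance estimate: SE ~ var * sqrt(2/(n-1))
    assert abs(currents.var(ddof=1) - var_th) \
        <= 3 * var_th * np.sqrt(2 / (n_rep - 1))


def test_mean_current_bounded_by_channel_count(step_trace):
    _, trace = step_trace
    n_max = 600    # generous bound on channels in the 500 um extent
    assert np.all(np.abs(trace.mean) <= 1.6 * n_max)


def test_unstimulated_far_half_silent(drive40):
    # channels confined far from the bead barely respond
    from wormtouch.gating import GatingParams
    from wormtouch.protocols import make_stimulus
    stim = make_stimulus("step", amplitude=8e-6, dt=1e-3, duration=0.4,
                         t_off=0.3)
    layout = pop.LayoutParams(extent=(150e-6, 250e-6))
    tr = pop.simulate_response(drive40, stim.values, stim.dt, GatingParams(),
                               layout=layout, n_realizations=4, seed=0)
    rest = tr.mean[50]
    n_ch = (250e-6 - 150e-6) / layout.mean_spacing
    assert np.max(np.abs(tr.mean - rest)) < 0.01 * 1.6 * n_ch


def test_step_response_shape(step_trace):
    stim, trace = step_trace
    rest = trace.mean[50]
    pk_on = trace.summary["peak_on_pA"]
    pk_off = trace.summary["peak_off_pA"]
    assert pk_on < rest - 5.0            # clear inward on-response
    assert pk_off < rest - 5.0           # and off-response
    # rapid adaptation: before stimulus release the current is back near rest
    assert abs(trace.mean[480] - rest) < 0.2 * abs(pk_on - rest)
    assert np.all(trace.var >= 0)
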