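"""Stimulus construction, clamp modes and in-silico experiments."""

import numpy as np
import pytest

from wormtouch import ShellGeometry, calibrate_reference
from wormtouch.gating import GatingParams
from wormtouch import population as pop
from wormtouch import protocols as pr

STD = dict(R=25e-6, t=1e-6, L=1e-3, nu=0.3, E=4e6)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def test_step_waveform_plateau():
    stim = pr.make_stimulus("step", amplitude=8e-6, dt=1e-3, duration=1.0)
    t = stim.t
    on = (t > 0.11) & (t < 0.59)
    assert np.allclose(stim.values[on], 8e-6)
    assert np.all(stim.values[t < 0.1] == 0.0)
    assert np.all(stim.values[t > 0.61] == 0.0)


def test_ramp_slope():
    stim = pr.make_stimulus("ramp", amplitude=8e-6, ramp_time=0.2, dt=1e-3)
    t = stim.t
    mid = (t > 0.12) & (t < 0.28)
    slopes = np.diff(stim.values[mid]) / 1e-3
    assert np.allclose(slopes, 8e-6 / 0.2, rtol=1e-6)


def test_pre_indented_step_plateau_sequence():
    stim = pr.make_stimulus("pre_indented_step", pre_depth=5e-6,
                            step_amplitude=3e-6, dt=1e-3, duration=2.2,
                            t_on=0.1, t_off=1.2, dwell=0.6, tau=0.05)
    t = stim.t
    def plateau(t0, t1):
        m = (t > t0) & (t < t1)
        vals = stim.values[m]
        assert np.ptp(vals) < 1e-12
        return vals[0]
    seq = [plateau(*w) for w in [(0.0, 0.09), (0.2, 0.69), (0.8, 1.19),
                                 (1.3, 1.79), (1.9, 2.15)]]
    assert np.allclose(seq, np.array([0, 5, 8, 5, 0]) * 1e-6)


def test_pre_indented_step_requires_adaptation_dwell():
    with pytest.raises(ValueError):
        pr.make_stimulus("pre_indented_step", dwell=0.1, tau=0.05)


def test_negative_amplitude_rejected():
    with pytest.raises(ValueError):
        pr.make_stimulus("step", amplitude=-1e-6)


def test_sinusoid_non_negative():
    stim = pr.make_stimulus("sinusoid", amplitude=3e-6, frequency=10.0,
                            dt=1e-3, duration=1.0)
    assert np.all(stim.values >= 0)


# ---------------------------------------------------------------------------
# force clamp
# ---------------------------------------------------------------------------

def test_force_clamp_round_trip(geo40, opts_test, curve40):
    # command the forces the solver produced at 2/4/6 um and recover
    # those depths (the 8 um point sits at the curve edge where the
    # saturation flag may trip on solver noise)
    w0_cmd, F, _ = curve40
    w0_rec, sat = pr.force_clamp_inverse(geo40, F[:3], Rb=10e-6, w0_max=8e-6,
                                         n_levels=8, opts=opts_test)
    assert not sat
    assert np.allclose(w0_rec, w0_cmd[:3], rtol=0.03)
    w0_zero, _ = pr.force_clamp_inverse(geo40, np.array([0.0]),
                                        Rb=10e-6, opts=opts_test)
    assert w0_zero[0] == 0.0


def test_force_clamp_saturation_flagged(geo40, opts_test):
    _, sat = pr.force_clamp_inverse(geo40, np.array([1.0]), Rb=10e-6,
                                    w0_max=8e-6, opts=opts_test)
    assert sat


def test_soft_worm_reaches_larger_depth_at_same_force(geo40, opts_test,
                                                      curve40):
    geo_soft = calibrate_reference(ShellGeometry(p=1.6e3, **STD),
                                   opts=opts_test)
    F_cmd = np.array([curve40[1][0]])          # force of 2 um on stiff worm
    w_stiff, _ = pr.force_clamp_inverse(geo40, F_cmd, opts=opts_test,
                                        w0_max=10e-6)
    w_soft, sat = pr.force_clamp_inverse(geo_soft, F_cmd, opts=opts_test,
                                         w0_max=10e-6)
    assert sat or w_soft[0] > 2.0 * w_stiff[0]


# ---------------------------------------------------------------------------
# responses through the full pipeline (coarse, few realizations)
# ---------------------------------------------------------------------------

def test_onset_offset_symmetry_symmetric_model(step_trace):
    _, trace = step_trace
    rest = trace.mean[50]
    on = trace.summary["peak_on_pA"] - rest
    off = trace.summary["peak_off_pA"] - rest
    assert abs(on - off) / max(abs(on), abs(off)) < 0.10


def test_sinusoid_doubles_frequency(sinusoid_trace):
    f0, stim, tr = sinusoid_trace
    sig = tr.mean[1200:]                      # steady state
    sig = sig - sig.mean()
    freqs = np.fft.rfftfreq(len(sig), 1e-3)
    amp = np.abs(np.fft.rfft(sig))
    amp[freqs < 2.0] = 0.0                    # drop slow drift
    peak_f = freqs[int(np.argmax(amp))]
    assert peak_f == pytest.approx(2 * f0, abs=0.5)


def test_ramp_slower_means_smaller_response(drive40):
    peaks = []
    for ramp_time in (0.01, 0.4):
        stim = pr.make_stimulus("ramp", amplitude=8e-6, ramp_time=ramp_time,
                                dt=1e-3, duration=1.0, t_on=0.1, t_off=0.7)
        tr = pop.simulate_response(drive40, stim.values, stim.dt,
                                   GatingParams(), n_realizations=6, seed=5,
                                   summary_windows=((0.1, 0.55),
                                                    (0.7, 0.85)))
        rest = tr.mean[50]
        peaks.append(tr.summary["peak_on_pA"] - rest)
    fast, slow = peaks
    assert abs(slow) < 0.7 * abs(fast)


def test_directional_single_channels_asymmetric_population_symmetric(drive40):
    stim = pr.make_stimulus("step", amplitude=8e-6, dt=1e-3, duration=0.8,
                            t_on=0.1, t_off=0.5)
    win = ((0.1, 0.25), (0.5, 0.65))
    par = GatingParams(g2=200.0)
    tr_dir = pop.simulate_response(drive40, stim.values, stim.dt, par,
                                   model="directional", n_realizations=16,
                                   seed=6, summary_windows=win)
    tr_sym = pop.simulate_response(drive40, stim.values, stim.dt,
                                   GatingParams(), model="symmetric",
                                   n_realizations=16, seed=6,
                                   summary_windows=win)
    # directional model at matched coupling: smaller mean response
    assert abs(tr_dir.summary["peak_on_pA"]) \
        < abs(tr_sym.summary["peak_on_pA"])
    # per-realization on/off asymmetry is larger for directional channels
    assert tr_dir.summary["asymmetry_pA"] > tr_sym.summary["asymmetry_pA"]


def test_run_sweep_records_partial_failures(geo40, opts_test):
    stim = pr.make_stimulus("step", amplitude=8e-6, dt=2e-3, duration=0.4,
                            t_off=0.3)
    df = pr.run_sweep("bead_radius", [-1e-6], stim, geo40,
                      n_realizations=2, opts=opts_test)
    assert bool(df["failed"].iloc[0])
    with pytest.raises(ValueError):
        pr.run_sweep("bogus_axis", [1.0], stim, geo40)
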