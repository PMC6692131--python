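"""Channel placement along the TRN and ensemble currents.

Channels sit in discrete puncta along the touch receptor neuron, one
channel per punctum, with log-normally distributed inter-punctum
spacings.  Each channel is driven by the local tissue deformation
computed by the shell solver; single-channel occupancies from the
master equation are summed into the total mechanoreceptor current
(mean and, for independent channels, variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gating as gt
from .solver import MechanicsSolution, _line_values

__all__ = [
    "LayoutParams",
    "TRNLayout",
    "CurrentTrace",
    "place_channels",
    "sample_orientations",
    "ensemble_current",
    "MechanicsDrive",
    "simulate_response",
    "asymmetry_statistic",
    "peak_current",
]


@dataclass(frozen=True)
class LayoutParams:
    """Puncta layout along the TRN.

    Defaults give a mean inter-punctum spacing of ~3 um with a broad
    log-normal spread, over a 500 um receptive extent centred on the
    stimulation site; values are configuration assumptions standing in
    for the fluorescence-puncta statistics.
    """

    mu_ln: float = float(np.log(3e-6) - 0.5 * 0.55**2)
    sigma_ln: float = 0.55
    extent: tuple[float, float] = (-250e-6, 250e-6)
    theta_trn: float = 0.0          # angular position of the TRN line

    @property
    def mean_spacing(self) -> float:
        return float(np.exp(self.mu_ln + 0.5 * self.sigma_ln**2))


@dataclass
class TRNLayout:
    positions: np.ndarray           # sorted channel stations (m)
    params: LayoutParams
    seed: int

    def __post_init__(self):
        lo, hi = self.params.extent
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("channel positions must be strictly increasing")
        if len(self.positions) and (self.positions[0] < lo
                                    or self.positions[-1] > hi):
            raise ValueError("channel outside the TRN extent")


@dataclass
class CurrentTrace:
    """Total-current statistics on a common time grid (pA, inward < 0).

    ``mean`` and ``var`` follow the independent-channel ensemble
    expressions; ``realizations`` holds per-realization mean traces and
    ``real_var`` the matching per-realization channel-noise variance.
    """

    t: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    realizations: np.ndarray | None = None
    real_var: np.ndarray | None = None
    summary: dict = field(default_factory=dict)

    def sd_band(self):
        sd = np.sqrt(self.var)
        return self.mean - sd, self.mean + sd


def place_channels(params: LayoutParams, seed: int) -> TRNLayout:
    """Cumulative-sum of i.i.d. log-normal spacings, truncated to extent."""
    rng = np.random.default_rng(seed)
    lo, hi = params.extent
    length = hi - lo
    if length <= 0:
        raise ValueError("empty TRN extent")
    n_guess = int(length / params.mean_spacing * 1.6) + 16
    gaps = rng.lognormal(params.mu_ln, params.sigma_ln, size=n_guess)
    pos = lo + np.cumsum(gaps)
    while pos[-1] < hi:
        gaps = rng.lognormal(params.mu_ln, params.sigma_ln, size=n_guess)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(gaps)])
    pos = pos[pos < hi]
    if len(pos) == 0:
        import warnings
        warnings.warn("TRN extent too small for a single channel")
    return TRNLayout(positions=pos, params=params, seed=seed)


def sample_orientations(n: int, seed: int,
                        mode: str = "hemisphere") -> np.ndarray:
    """Initial filament directions in the local (axial, circ, normal)
    frame: uniform on the outward hemisphere (Gamma0 . w3 >= 0), or
    confined to the tangent plane for the tangential variants."""
    rng = np.random.default_rng(seed)
    if mode == "hemisphere":
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[:, 2] = np.abs(v[:, 2])
        return v
    if mode in ("tangential_initial", "tangential_always"):
        ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.stack([np.cos(ang), np.sin(ang), np.zeros(n)], axis=1)
    raise ValueError(f"unknown orientation mode {mode!r}")


def ensemble_current(P_t: np.ndarray, i_o: float, i_s: float) -> CurrentTrace:
    """Mean and variance of the summed current of independent channels.

    ``P_t``: occupancies (n_t, n_channels, 3).  The mean is
    i_o sum_k Po^k + i_s sum_k Ps^k; the variance sums the single-channel
    current variances.
    """
    P_t = np.asarray(P_t, dtype=float)
    if P_t.ndim == 2:
        P_t = P_t[:, None, :]
    Ps, Po = P_t[..., 1], P_t[..., 2]
    mean_k = i_o * Po + i_s * Ps
    var_k = i_o**2 * Po + i_s**2 * Ps - mean_k**2
    return CurrentTrace(t=np.arange(P_t.shape[0], dtype=float),
                        mean=mean_k.sum(axis=1), var=var_k.sum(axis=1))


# ---------------------------------------------------------------------------
# coupling to the mechanics
# ---------------------------------------------------------------------------

class MechanicsDrive:
    """Deformation fields along the TRN line, tabulated per w0 level.

    Stores, for each solved indentation level, the mapping that carries
    a filament vector given in the resting local frame (axial,
    circumferential, normal components) to the lab frame, plus the local
    frame vectors, on the solver's axial stations.  Channel kinematics
    at arbitrary stations/depths are linear interpolations in s and w0.
    Quasi-static mechanics: time enters only through w0(t).
    """

    def __init__(self, w0_levels: np.ndarray, s: np.ndarray,
                 B: np.ndarray, normals: np.ndarray, axes: np.ndarray,
                 geometry=None):
        self.w0_levels = np.asarray(w0_levels, dtype=float)
        self.s = s
        self.B = B                  # (n_lev, n_s, 3, 3) lab <- rest frame
        self.normals = normals      # (n_lev, n_s, 3) deformed unit normal
        self.axes = axes            # (n_lev, n_s, 3) deformed unit axis
        self.geometry = geometry

    @classmethod
    def from_solutions(cls, solutions: list[MechanicsSolution],
                       theta_trn: float = 0.0) -> "MechanicsDrive":
        sols = sorted(solutions, key=lambda s: s.indenter.w0 if s.indenter else 0.0)
        mesh = sols[0].mesh
        nu = sols[0].geometry.nu
        dphi = 1e-3

        def line_tangents(u):
            pos = mesh.positions + u
            p0 = _line_values(mesh, pos, theta_trn)
            pp = _line_values(mesh, pos, theta_trn + dphi)
            pm = _line_values(mesh, pos, theta_trn - dphi)
            t_ax = np.gradient(p0, mesh.s, axis=0)
            t_c = (pp - pm) / 2.0
            return p0, t_ax, t_c

        _, r_ax, r_c = line_tangents(sols[0].u_rest)
        n_rest = np.cross(r_ax, r_c)
        n_rest /= np.linalg.norm(n_rest, axis=1, keepdims=True)
        nr1 = np.linalg.norm(r_ax, axis=1)
        nr2 = np.linalg.norm(r_c, axis=1)

        B, normals, axes, w0s = [], [], [], []
        for sol in sols:
            _, a1, a2 = line_tangents(sol.config.u)
            nrm = np.cross(a1, a2)
            nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
            e_ax = (a1.T / np.linalg.norm(a1, axis=1)).T
            # relative Green-Lagrange strain in the rest frame
            e11 = (np.sum(a1 * a1, 1) - nr1**2) / (2 * nr1**2)
            e22 = (np.sum(a2 * a2, 1) - nr2**2) / (2 * nr2**2)
            eps_n = -nu * (e11 + e22) / (1.0 - nu)
            Bl = np.empty((len(mesh.s), 3, 3))
            Bl[:, :, 0] = a1 / nr1[:, None]
            Bl[:, :, 1] = a2 / nr2[:, None]
            Bl[:, :, 2] = (1.0 + eps_n)[:, None] * nrm
            B.append(Bl)
            normals.append(nrm)
            axes.append(e_ax)
            w0s.append(sol.indenter.w0 if sol.indenter else 0.0)
        return cls(np.asarray(w0s), mesh.s.copy(), np.stack(B),
                   np.stack(normals), np.stack(axes),
                   geometry=sols[0].geometry)

    def at(self, positions: np.ndarray, w0_t: np.ndarray):
        """Interpolate (B, normal, axis) to channel stations and depths.

        Returns arrays of shape (n_t, n_chan, 3, 3) and (n_t, n_chan, 3).
        """
        positions = np.asarray(positions, dtype=float)
        w0_t = np.asarray(w0_t, dtype=float)
        # interpolate along s first (per level), then in w0 per time step
        def interp_s(arr):
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            out = np.empty((arr.shape[0], len(positions), flat.shape[2]))
            for c in range(flat.shape[2]):
                for l in range(arr.shape[0]):
                    out[l, :, c] = np.interp(positions, self.s, flat[l, :, c])
            return out.reshape((arr.shape[0], len(positions)) + arr.shape[2:])

        B_s = interp_s(self.B)
        n_s_ = interp_s(self.normals)
        a_s = interp_s(self.axes)
        lev = self.w0_levels
        idx = np.clip(np.searchsorted(lev, w0_t) - 1, 0, len(lev) - 2)
        wfrac = (w0_t - lev[idx]) / (lev[idx + 1] - lev[idx])
        wfrac = np.clip(wfrac, 0.0, 1.0)

        def interp_w(arr_s):
            lo = arr_s[idx]
            hi = arr_s[idx + 1]
            w = wfrac.reshape((-1,) + (1,) * (arr_s.ndim - 1))
            return lo * (1 - w) + hi * w

        B_t = interp_w(B_s)
        n_t_ = interp_w(n_s_)
        n_t_ /= np.linalg.norm(n_t_, axis=-1, keepdims=True)
        a_t = interp_w(a_s)
        a_t /= np.linalg.norm(a_t, axis=-1, keepdims=True)
        return B_t, n_t_, a_t


def _lab_frames(normals, axes, theta=0.0):
    """w1, w2, w3 for channels at angular offset theta around the TRN."""
    ey = axes
    ez = normals - ey * np.sum(normals * ey, axis=-1, keepdims=True)
    ez /= np.linalg.norm(ez, axis=-1, keepdims=True)
    ex = np.cross(ey, ez)
    w1 = np.cos(theta) * ex - np.sin(theta) * ez
    w2 = ey
    w3 = np.sin(theta) * ex + np.cos(theta) * ez
    return w1, w2, w3


class _PropagatorTable:
    """Tabulated one-step propagators M(dG_oc) on a dense grid.

    For fixed (a, r0, dt) the 3x3 propagator depends on the single
    scalar beta*dG_oc; entries are interpolated linearly in dG_oc.
    """

    def __init__(self, params: gt.GatingParams, dt: float,
                 g_lo: float = -60.0, g_hi: float = 60.0, n: int = 2401):
        self.grid = np.linspace(g_lo, g_hi, n)
        rates = gt.transition_rates(params.a * self.grid,
                                    (1.0 - params.a) * self.grid, params.r0)
        self.M = gt.propagator(rates, dt)       # (n, 3, 3)

    def __call__(self, dG: np.ndarray) -> np.ndarray:
        g = np.clip(dG, self.grid[0], self.grid[-1])
        x = (g - self.grid[0]) / (self.grid[1] - self.grid[0])
        i = np.clip(x.astype(int), 0, len(self.grid) - 2)
        f = (x - i)[..., None, None]
        return self.M[i] * (1 - f) + self.M[i + 1] * f


def simulate_response(drive: MechanicsDrive, w0_t: np.ndarray, dt: float,
                      params: gt.GatingParams,
                      layout: LayoutParams = LayoutParams(),
                      model: str = "symmetric",
                      n_realizations: int = 20, seed: int = 0,
                      orientation_mode: str = "hemisphere",
                      summary_windows=None) -> CurrentTrace:
    """Ensemble mechanoreceptor current for a displacement history w0(t).

    For each statistical realization, channel stations and filament
    orientations are drawn afresh; filaments are driven by the
    interpolated deformation, occupancies propagated with the tabulated
    master-equation propagator, and currents summed per the
    independent-channel expressions.  Averages and one-SD bands across
    realizations populate ``realizations`` and ``summary``.
    """
    w0_t = np.asarray(w0_t, dtype=float)
    n_t = len(w0_t)
    table = _PropagatorTable(params, dt)
    traces = np.empty((n_realizations, n_t))
    vars_ = np.empty((n_realizations, n_t))
    rng = np.random.default_rng(seed)
    always_tan = orientation_mode == "tangential_always"
    for r in range(n_realizations):
        s_lay = int(rng.integers(0, 2**31 - 1))
        s_ori = int(rng.integers(0, 2**31 - 1))
        lay = place_channels(layout, s_lay)
        nc = len(lay.positions)
        if nc == 0:
            traces[r] = 0.0
            vars_[r] = 0.0
            continue
        gam0 = sample_orientations(nc, s_ori, orientation_mode)
        B_t, nrm_t, ax_t = drive.at(lay.positions, w0_t)
        Gam = np.einsum("tcij,cj->tci", B_t, gam0)
        w1, w2, w3 = _lab_frames(nrm_t, ax_t, layout.theta_trn)
        x = gt.integrate_filament(Gam, params.tau, dt, w3_t=w3,
                                  always_tangential=always_tan)
        F1 = -np.sum(x * w1, axis=-1)
        F2 = -np.sum(x * w2, axis=-1)
        if model == "symmetric":
            dG = params.g0 - params.g1 * np.hypot(F1, F2)
        elif model == "directional":
            ang = np.random.default_rng(s_ori + 1).uniform(0, 2 * np.pi, nc)
            v1, v2 = np.cos(ang), np.sin(ang)
            dG = params.g0 - params.g2 * (F1 * v1 + F2 * v2)
        else:
            raise ValueError(f"unknown model {model!r}")
        # propagate occupancies
        P = np.tile(gt.stationary_distribution(params.g0, params.a), (nc, 1))
        mean_tr = np.empty(n_t)
        var_tr = np.empty(n_t)
        for i in range(n_t):
            if i > 0:
                M = table(dG[i - 1])
                P = np.einsum("cij,cj->ci", M, P)
            Ps, Po = P[:, 1], P[:, 2]
            mk = params.i_o * Po + params.i_s * Ps
            mean_tr[i] = mk.sum()
            var_tr[i] = (params.i_o**2 * Po + params.i_s**2 * Ps
                         - mk**2).sum()
        traces[r] = mean_tr
        vars_[r] = var_tr
    t = np.arange(n_t) * dt
    mean = traces.mean(axis=0)
    trace = CurrentTrace(t=t, mean=mean, var=vars_.mean(axis=0),
                         realizations=traces, real_var=vars_)
    if summary_windows is not None:
        trace.summary = asymmetry_statistic(trace, *summary_windows)
    return trace


def peak_current(trace_t: np.ndarray, mean: np.ndarray, t0: float,
                 t1: float) -> float:
    """Most-negative (inward) current within the window [t0, t1]."""
    m = (trace_t >= t0) & (trace_t <= t1)
    if not np.any(m):
        raise ValueError("peak window outside trace")
    return float(mean[m].min())


def asymmetry_statistic(trace: CurrentTrace, on_window: tuple[float, float],
                        off_window: tuple[float, float]) -> dict:
    """On/off peak statistics across realizations.

    Returns peak on/off currents of the ensemble mean, the
    root-mean-square on-off asymmetry <(I_on - I_off)^2>^{1/2} across
    realizations, and the coefficient of variation of the peak current
    (channel noise + placement variability).
    """
    if trace.realizations is None or len(trace.realizations) < 2:
        raise ValueError("need at least two realizations")
    t = trace.t
    on = np.array([peak_current(t, tr, *on_window)
                   for tr in trace.realizations])
    off = np.array([peak_current(t, tr, *off_window)
                    for tr in trace.realizations])
    peak_on = peak_current(t, trace.mean, *on_window)
    peak_off = peak_current(t, trace.mean, *off_window)
    asym = float(np.sqrt(np.mean((on - off) ** 2)))
    # CV of the on-peak: channel-noise variance at the mean-peak time
    # plus across-realization spread, relative to the mean peak
    i_pk = int(np.argmin(np.where((t >= on_window[0]) & (t <= on_window[1]),
                                  trace.mean, np.inf)))
    total_var = trace.var[i_pk] + on.var(ddof=1)
    cv = float(np.sqrt(total_var) / abs(trace.mean[i_pk])) \
        if trace.mean[i_pk] != 0 else np.inf
    return {"peak_on_pA": peak_on, "peak_off_pA": peak_off,
            "asymmetry_pA": asym, "cv_on": cv,
            "on_per_realization": on, "off_per_realization": off}
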