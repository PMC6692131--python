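"""Single MeT-channel biophysics.

Each mechano-electrical transduction channel sits in the TRN membrane
and is connected to an elastic filament embedded in the surrounding
tissue.  Tissue deformation displaces the filament tip relative to the
channel; the filament extension x relaxes with time constant tau
(adaptation) and its tangential elastic force tilts the free-energy
landscape of a three-state channel C <-> S <-> O (closed /
sub-conducting / open) whose occupancies follow a master equation with
detailed balance.

Conventions: filament lengths are rescaled to unity and the filament
stiffness k is absorbed into the gating constants, so forces here are
dimensionless extensions; free energies are in units of kB*T.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LocalFrame",
    "GatingParams",
    "local_frame",
    "filament_drive",
    "integrate_filament",
    "tangential_force",
    "free_energies",
    "transition_rates",
    "rate_matrix",
    "stationary_distribution",
    "propagate_master",
    "propagator",
    "gillespie_channel",
]

_EXP_CLIP = 50.0


@dataclass(frozen=True)
class LocalFrame:
    """Orthonormal channel frame on the TRN membrane.

    w1, w2 span the local tangent plane, w3 is the outward normal; theta
    is the angular offset of the channel around the TRN circumference.
    """

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    theta: float = 0.0

    def __post_init__(self):
        M = np.stack([self.w1, self.w2, self.w3])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-12):
            raise ValueError("frame is not orthonormal")
        if np.dot(np.cross(self.w1, self.w2), self.w3) < 0:
            raise ValueError("frame is not right-handed")


@dataclass(frozen=True)
class GatingParams:
    """Gating constants of the three-state channel.

    g0 sets the rest closed/open free-energy gap (kB*T); g1 (symmetric
    model) or g2 with preferred direction v (directional model) couples
    the tangential filament force to gating; a in [0, 1] splits the gap
    across the sub-conductance state; tau is the filament relaxation
    time (s); r0 the attempt rate (1/s); i_o and i_s the open and
    sub-state currents (pA, inward negative).
    """

    g0: float = 7.0
    g1: float = 200.0
    g2: float = 280.0
    v: np.ndarray | None = None
    a: float = 0.5
    tau: float = 0.05
    r0: float = 500.0
    i_o: float = -1.6
    i_s: float = -0.8

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("a must lie in [0, 1]")
        if self.r0 <= 0 or self.tau <= 0:
            raise ValueError("r0 and tau must be positive")
        if self.v is not None:
            v = np.asarray(self.v, dtype=float)
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-9):
                raise ValueError("preferred direction v must be a unit vector")
            object.__setattr__(self, "v", v)

    def with_(self, **kw) -> "GatingParams":
        return replace(self, **kw)


def local_frame(theta: float, axis_direction: np.ndarray,
                normal: np.ndarray) -> LocalFrame:
    """Channel frame at angular offset theta around the TRN.

    e'_y is the (deformed) axis direction, e'_z the outward normal at
    the top of the TRN, e'_x completes the right-handed triad; rotating
    by theta gives w1 = cos(theta) e'_x - sin(theta) e'_z, w2 = e'_y,
    w3 = sin(theta) e'_x + cos(theta) e'_z.
    """
    ey = np.asarray(axis_direction, dtype=float)
    ny = np.linalg.norm(ey)
    if ny < 1e-12:
        raise ValueError("degenerate axis direction")
    ey = ey / ny
    ez = np.asarray(normal, dtype=float)
    ez = ez - ey * (ez @ ey)
    nz = np.linalg.norm(ez)
    if nz < 1e-12:
        raise ValueError("normal parallel to axis")
    ez = ez / nz
    ex = np.cross(ey, ez)
    w1 = np.cos(theta) * ex - np.sin(theta) * ez
    w2 = ey
    w3 = np.sin(theta) * ex + np.cos(theta) * ez
    return LocalFrame(w1=w1, w2=w2, w3=w3, theta=theta)


def filament_drive(grad_u_t: np.ndarray, Gamma0: np.ndarray) -> np.ndarray:
    """Deformed filament vector Gamma(t) = (I + grad u(t)) . Gamma0.

    ``grad_u_t``: (n_t, 3, 3) displacement-gradient history at the
    channel (surface-consistent: in-plane columns from the membrane
    deformation, normal column from rotation plus the plane-stress
    normal strain).  To quadratic order the stretching obeys
    |Gamma|^2 - |Gamma0|^2 = 2 eps_ij Gamma0_i Gamma0_j.
    """
    grad_u_t = np.asarray(grad_u_t, dtype=float)
    if grad_u_t.ndim == 2:
        grad_u_t = grad_u_t[None]
    if grad_u_t.shape[-2:] != (3, 3):
        raise ValueError("displacement gradient must be (n_t, 3, 3)")
    G0 = np.asarray(Gamma0, dtype=float)
    return G0 + grad_u_t @ G0


def integrate_filament(Gamma_t: np.ndarray, tau: float, dt: float,
                       w3_t: np.ndarray | None = None,
                       x0: np.ndarray | None = None,
                       always_tangential: bool = False) -> np.ndarray:
    """Filament extension x(t) from dx/dt + x/tau = dGamma/dt.

    Exponential-integrator update per step (exact for piecewise-linear
    Gamma), followed by projection onto the admissible half-space
    x . w3 >= 0 imposed by the neural membrane.  ``w3_t`` may be a
    single vector or a per-sample array; ``always_tangential`` removes
    the normal component entirely instead.  Steps longer than tau/5 are
    sub-divided internally.

    Accepts a trailing batch axis: Gamma_t of shape (n_t, ..., 3).
    """
    Gamma_t = np.asarray(Gamma_t, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    n_t = Gamma_t.shape[0]
    x = np.zeros(Gamma_t.shape[1:]) if x0 is None else np.array(x0, dtype=float)
    out = np.empty_like(Gamma_t)
    out[0] = _project(x, _w3_at(w3_t, 0), always_tangential)
    n_sub = max(1, int(np.ceil(dt / (tau / 5.0))))
    h = dt / n_sub
    decay = np.exp(-h / tau)
    gain = tau * (1.0 - decay) / h
    x = out[0].copy()
    for i in range(1, n_t):
        dG = (Gamma_t[i] - Gamma_t[i - 1]) / n_sub
        for _ in range(n_sub):
            x = x * decay + dG * gain
        x = _project(x, _w3_at(w3_t, i), always_tangential)
        out[i] = x
    return out


def _w3_at(w3_t, i):
    if w3_t is None:
        return None
    w3_t = np.asarray(w3_t, dtype=float)
    if w3_t.ndim == 1:
        return w3_t
    return w3_t[i]


def _project(x, w3, always_tangential):
    if w3 is None:
        return x
    xn = np.einsum("...i,...i->...", x, w3)
    if always_tangential:
        return x - xn[..., None] * w3
    viol = np.minimum(xn, 0.0)
    return x - viol[..., None] * w3


def tangential_force(x: np.ndarray, frame: LocalFrame, k: float = 1.0):
    """(F1, F2, F): tangential components and amplitude of -k x."""
    Fel = -k * np.asarray(x, dtype=float)
    F1 = Fel @ frame.w1
    F2 = Fel @ frame.w2
    return F1, F2, np.hypot(F1, F2)


def free_energies(F1: np.ndarray, F2: np.ndarray, params: GatingParams,
                  model: str = "symmetric"):
    """(dG_oc, dG_os, dG_sc) in kB*T from the tangential force.

    Symmetric model: beta dG_oc = g0 - g1 * |F_tangential|; directional:
    beta dG_oc = g0 - g2 * F . v with v expressed in the (w1, w2) plane.
    """
    F1 = np.asarray(F1, dtype=float)
    F2 = np.asarray(F2, dtype=float)
    if model == "symmetric":
        dg_oc = params.g0 - params.g1 * np.hypot(F1, F2)
    elif model == "directional":
        if params.v is None:
            raise ValueError("directional model requires a preferred direction v")
        proj = F1 * params.v[0] + F2 * params.v[1]
        dg_oc = params.g0 - params.g2 * proj
    else:
        raise ValueError(f"unknown gating model {model!r}")
    return dg_oc, params.a * dg_oc, (1.0 - params.a) * dg_oc


def transition_rates(dG_os: np.ndarray, dG_sc: np.ndarray, r0: float):
    """(R_cs, R_sc, R_so, R_os) with detailed balance and a symmetric
    Arrhenius split R_ij = r0 exp(-beta dG_ij / 2); C<->O direct rates
    are zero."""
    dG_os = np.clip(np.asarray(dG_os, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    dG_sc = np.clip(np.asarray(dG_sc, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    R_cs = r0 * np.exp(-0.5 * dG_sc)
    R_sc = r0 * np.exp(+0.5 * dG_sc)
    R_so = r0 * np.exp(-0.5 * dG_os)
    R_os = r0 * np.exp(+0.5 * dG_os)
    return R_cs, R_sc, R_so, R_os


def rate_matrix(rates) -> np.ndarray:
    """Generator of the C <-> S <-> O chain, columns = source state.

    Accepts scalars or batched arrays; returns (..., 3, 3).
    """
    R_cs, R_sc, R_so, R_os = [np.asarray(r, dtype=float) for r in rates]
    shape = np.broadcast(R_cs, R_sc, R_so, R_os).shape
    A = np.zeros(shape + (3, 3))
    A[..., 0, 0] = -R_cs
    A[..., 0, 1] = R_sc
    A[..., 1, 0] = R_cs
    A[..., 1, 1] = -(R_sc + R_so)
    A[..., 1, 2] = R_os
    A[..., 2, 1] = R_so
    A[..., 2, 2] = -R_os
    return A


def stationary_distribution(dG_oc: float, a: float) -> np.ndarray:
    """Boltzmann weights (Pc, Ps, Po) ~ (1, e^{-(1-a) dG}, e^{-dG})."""
    dG_oc = np.clip(dG_oc, -_EXP_CLIP, _EXP_CLIP)
    w = np.array([0.0, -(1.0 - a) * dG_oc, -dG_oc])
    w = np.exp(w - w.max())
    return w / w.sum()


def propagator(rates, dt: float) -> np.ndarray:
    """exp(A dt) for the (possibly batched) generator, via symmetrized
    eigendecomposition (detailed balance makes A similar to a symmetric
    matrix, so the decomposition is real and stable)."""
    R_cs, R_sc, R_so, R_os = [np.atleast_1d(np.asarray(r, dtype=float))
                              for r in rates]
    A = rate_matrix((R_cs, R_sc, R_so, R_os))
    # stationary weights: pi ~ (1, Rcs/Rsc, (Rcs/Rsc)(Rso/Ros)); floor the
    # rates so vanishing transitions give a neutral (unit) weight ratio
    floor = 1e-300
    ln_pi = np.zeros(A.shape[:-2] + (3,))
    ln_pi[..., 1] = (np.log(np.maximum(R_cs, floor))
                     - np.log(np.maximum(R_sc, floor)))
    ln_pi[..., 2] = ln_pi[..., 1] + (np.log(np.maximum(R_so, floor))
                                     - np.log(np.maximum(R_os, floor)))
    ln_pi -= ln_pi.max(axis=-1, keepdims=True)
    sq = np.exp(0.5 * ln_pi)
    S = A * (sq[..., None, :] / sq[..., :, None])
    S = 0.5 * (S + np.swapaxes(S, -1, -2))      # clean round-off
    lam, Q = np.linalg.eigh(S)
    expl = np.exp(lam * dt)
    M = np.einsum("...ik,...k,...jk->...ij", Q, expl, Q)
    M = M * (sq[..., :, None] / sq[..., None, :])
    return M


def propagate_master(P0: np.ndarray, rates_t, dt: float) -> np.ndarray:
    """Occupancies P(t) under piecewise-constant rates.

    ``rates_t`` is a tuple of four arrays of shape (n_t,) (or (n_t, n)
    for n channels); each step uses the exact matrix exponential of the
    3x3 generator.  Probabilities are conserved to round-off; negative
    values beyond -1e-9 abort.
    """
    P = np.array(P0, dtype=float)
    if P.shape[-1] != 3:
        raise ValueError("P0 must have last dimension 3")
    if not np.allclose(P.sum(axis=-1), 1.0, atol=1e-9):
        raise ValueError("P0 must sum to 1")
    R = [np.atleast_1d(np.asarray(r, dtype=float)) for r in rates_t]
    n_t = R[0].shape[0]
    out = np.empty((n_t,) + P.shape)
    out[0] = P
    for i in range(1, n_t):
        M = propagator(tuple(r[i - 1] for r in R), dt)
        P = np.einsum("...ij,...j->...i", M, P)
        if np.any(P < -1e-9):
            raise FloatingPointError("negative occupancy in master equation")
        P = np.clip(P, 0.0, None)
        P = P / P.sum(axis=-1, keepdims=True)
        out[i] = P
    return out


def gillespie_channel(rates_t, dt: float, t_end: float, seed: int,
                      state0: int = 0) -> np.ndarray:
    """Exact-jump single-channel trajectory with thinning for
    time-dependent rates.

    ``rates_t`` is a tuple of four arrays sampled every ``dt`` (piecewise
    constant).  Returns the state (0=C, 1=S, 2=O) sampled on that grid.
    """
    rng = np.random.default_rng(seed)
    R = [np.asarray(r, dtype=float) for r in rates_t]
    n_t = int(round(t_end / dt)) + 1

    def rates_at(tt, st):
        i = min(int(tt / dt), R[0].shape[0] - 1)
        R_cs, R_sc, R_so, R_os = (r[i] for r in R)
        if st == 0:
            return [(1, R_cs)]
        if st == 1:
            return [(0, R_sc), (2, R_so)]
        return [(1, R_os)]

    r_max = max(float(np.max(r)) for r in R) * 2.0 + 1e-12
    traj = np.empty(n_t, dtype=np.int8)
    t, state, i_out = 0.0, state0, 0
    while i_out < n_t:
        # thinning: candidate jump from a homogeneous bound r_max
        t_next = t + rng.exponential(1.0 / r_max)
        while i_out < n_t and i_out * dt <= t_next:
            traj[i_out] = state
            i_out += 1
        if i_out >= n_t:
            break
        t = t_next
        chans = rates_at(t, state)
        tot = sum(r for _, r in chans)
        if rng.uniform() < tot / r_max:
            u = rng.uniform() * tot
            acc = 0.0
            for st, r in chans:
                acc += r
                if u <= acc:
                    state = st
                    break
    return traj
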