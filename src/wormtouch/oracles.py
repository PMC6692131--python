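"""Closed-form and simplified-equation shell benchmarks.

Independent references used to validate the full shell solver in limit
regimes:

* ``linear_cylinder_indentation`` — radial point load on a long,
  unpressurized thin cylindrical shell, evaluated by quadrature of the
  Donnell shallow-shell operator in Fourier space.  It carries the
  classical stiffness scaling  k ∝ E t^{5/2} R^{-3/2}.
* ``pressurized_sphere_indentation`` — point indentation of a
  pressurized spherical shell, from the axisymmetric shallow
  (Föppl–von Kármán) energy with pressure, solved by 1D minimization.
  In the pressure-dominated limit (tau = p R^2 / (E t^2) >> 1, depths
  beyond the bending crossover) the stiffness approaches pi * p * R.
* ``factorized_force`` — the factorized force-indentation law for pressurized
  cylinders, F = a1 p R w0 (1 + a2 Rb/R)(1 + a3 w0/R).

Every oracle is a pure function and validates its own regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "OracleResult",
    "linear_cylinder_indentation",
    "pressurized_sphere_indentation",
    "factorized_force",
    "ALPHA_DEFAULT",
]

#: factorized-law coefficients for the pressure-dominated cylinder
ALPHA_DEFAULT = (0.76, 2.1, 0.66)


@dataclass(frozen=True)
class OracleResult:
    quantity: str
    value: float
    validity: str


def linear_cylinder_indentation(R: float, t: float, E: float, nu: float,
                                F: float, pinch: bool = False) -> OracleResult:
    """Radial deflection under a radial point load on a long cylinder.

    Shallow-shell theory for a cylinder with Morley's low-harmonic
    correction (the bending operator (lap + 1/R^2)^2, which restores the
    exact inextensional ring-bending curvature (n^2-1) w / R^2 that
    plain Donnell theory misses at small n).  Expanding the point load
    in circumferential harmonics n (discrete on the closed cylinder) and
    an axial Fourier integral, the compliance per mode is

        w_k = q_k / [ D (k^2 - 1/R^2)^2 + (E t / R^2) kx^4 / k^4 ],
        k^2 = kx^2 + (n/R)^2.

    The sum/integral is evaluated numerically (no fitted constants) and
    its dimple part scales as F R^{3/2} / (E t^{5/2}): doubling t
    stiffens the shell by 2^{5/2}.  Valid for p = 0 and deflections
    small compared with t on a long cylinder.
    """
    if min(R, t, E) <= 0:
        raise ValueError("R, t, E must be positive")
    if t > R / 5:
        raise ValueError("outside thin-shell validity (t > R/5)")
    if F == 0.0:
        return OracleResult("deflection", 0.0, "p=0, w << t")
    D = E * t**3 / (12.0 * (1.0 - nu**2))
    c = E * t / R**2
    ell = (D / c) ** 0.25          # dimple length scale ~ sqrt(R t)
    kx = np.linspace(0.0, 40.0 / ell, 6001)
    kx[0] = 1e-12 / ell
    # harmonics n >= 2 carry the local dimple; n = 0 (axisymmetric) and
    # n = 1 (beam translation) are finite for discrete n and included.
    n_max = max(200, int(40.0 * R / ell))
    total = 0.0
    for n in range(0, n_max + 1):
        if pinch and n % 2 == 1:
            continue        # odd harmonics cancel for diametral loads
        if not pinch and n == 1:
            # rigid/beam translation of the axis: divergent for a point
            # load on an infinite free cylinder; the reported deflection
            # is the local dimple relative to the beam motion
            continue
        k2 = kx**2 + (n / R) ** 2
        integrand = 1.0 / (D * (k2 - 1.0 / R**2) ** 2 + c * kx**4 / k2**2)
        contrib = np.trapezoid(integrand, kx) / np.pi   # even in kx
        if n > 0:
            contrib *= 2.0
        if pinch:
            contrib *= 2.0  # second load adds cos(n pi) = +1 for even n
        total += contrib
    w0 = F / (2.0 * np.pi * R) * total
    return OracleResult("deflection", float(w0), "p=0, w << t")


def pressurized_sphere_indentation(R: float, p: float, E: float, t: float,
                                   w0: float, nu: float = 0.3,
                                   n_r: int = 260) -> OracleResult:
    """Force to indent a pressurized spherical shell by w0 at a point.

    Minimizes the axisymmetric shallow-shell (Föppl–von Kármán) energy
    of a spherical cap — membrane stretching + bending + pressure work —
    over radial and normal displacement profiles with the apex displaced
    by w0, and differentiates the relaxed energy with respect to w0.
    In the pressure-dominated regime (tau = p R^2/(E t^2) >> 1, depths
    beyond the bending crossover) the stiffness F/w0 tends to pi p R.
    """
    if min(R, p, E, t) <= 0:
        raise ValueError("R, p, E, t must be positive")
    if w0 == 0.0:
        return OracleResult("force", 0.0, "shallow cap, tau >> 1")
    tau = p * R**2 / (E * t**2)
    if tau < 1.0:
        raise ValueError("outside pressure-dominated validity (tau < 1)")
    D = E * t**3 / (12.0 * (1.0 - nu**2))
    T0 = p * R / 2.0                 # pre-tension of the pressurized sphere
    r_max = 4.0 * np.sqrt(2.0 * R * w0) + 10.0 * (D / (p * R))**0.5
    r = np.linspace(0.0, r_max, n_r)
    h = r[1] - r[0]
    rmid = 0.5 * (r[:-1] + r[1:])
    dz0 = np.diff(-r**2 / (2.0 * R)) / h
    C = E * t / (1.0 - nu**2)
    two_pi_rh = 2.0 * np.pi * rmid * h
    lscale = 1e-6
    escale = np.pi * p * R * lscale**2   # force scale pi p R x length^2

    # discrete laplacian operator for bending (n_r x n_r)
    L = np.zeros((n_r, n_r))
    for i in range(1, n_r - 1):
        L[i, i - 1] = 1.0 / h**2 - 1.0 / (2 * h * r[i])
        L[i, i] = -2.0 / h**2
        L[i, i + 1] = 1.0 / h**2 + 1.0 / (2 * h * r[i])
    L[0, 0], L[0, 1] = -4.0 / h**2, 4.0 / h**2
    W_b = D * 2.0 * np.pi * r * h
    QB = L.T @ (W_b[:, None] * L)           # grad_w of E_b = QB w
    gp = -p * np.concatenate([[np.pi * rmid[0] * h],
                              np.pi * (rmid[:-1] + rmid[1:]) * h,
                              [np.pi * rmid[-1] * h]])

    # perturbation energy about the pressurized sphere: the pre-tension
    # T0 (e_rr + e_tt) term makes the flat state an equilibrium; apex w
    # is clamped to -wc, the far edge (r = r_max) is pinned.
    def energy_grad(x, wc):
        u = np.concatenate([[0.0], x[:n_r - 2] * lscale, [0.0]])
        w = np.concatenate([[-wc], x[n_r - 2:] * lscale, [0.0]])
        du = np.diff(u) / h
        dw = np.diff(w) / h
        e_rr = du + dz0 * dw + 0.5 * dw * dw
        e_tt = 0.5 * (u[:-1] + u[1:]) / rmid
        S_rr = (T0 + C * (e_rr + nu * e_tt)) * two_pi_rh
        S_tt = (T0 + C * (e_tt + nu * e_rr)) * two_pi_rh
        E_m = float(np.sum((T0 * (e_rr + e_tt)
                            + 0.5 * C * (e_rr**2 + e_tt**2
                                         + 2 * nu * e_rr * e_tt)) * two_pi_rh))
        gu = np.zeros(n_r)
        gw = np.zeros(n_r)
        np.add.at(gu, np.arange(1, n_r), S_rr / h + S_tt / (2 * rmid))
        np.add.at(gu, np.arange(0, n_r - 1), -S_rr / h + S_tt / (2 * rmid))
        coef = S_rr * (dz0 + dw) / h
        np.add.at(gw, np.arange(1, n_r), coef)
        np.add.at(gw, np.arange(0, n_r - 1), -coef)
        E_b = 0.5 * float(w @ (QB @ w))
        gw += QB @ w
        E_p = float(gp @ w)
        gw += gp
        e = (E_m + E_b + E_p) / escale
        g = np.concatenate([gu[1:-1], gw[1:-1]]) * (lscale / escale)
        return e, g

    def relax(wc, x_start):
        res = minimize(lambda x: energy_grad(x, wc), x_start, jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": 6000, "maxfun": 60000,
                                "ftol": 1e-14, "gtol": 1e-9})
        return res.fun * escale, res.x

    x0 = np.zeros(2 * (n_r - 2))
    w_init = np.where(r < np.sqrt(R * w0), -w0 + r**2 / R, 0.0)
    x0[n_r - 2:] = w_init[1:-1] / lscale
    _, x_star = relax(w0, x0)
    dw0 = 0.01 * w0
    e_hi, _ = relax(w0 + dw0, x_star)
    e_lo, _ = relax(w0 - dw0, x_star)
    F = (e_hi - e_lo) / (2.0 * dw0)
    return OracleResult("force", float(F), "shallow cap, tau >> 1")


def factorized_force(p: float, R: float, Rb: float, w0: float,
               alpha: tuple[float, float, float] = ALPHA_DEFAULT) -> float:
    """Factorized force-indentation law of the pressure-dominated cylinder:
    F = a1 p R w0 (1 + a2 Rb / R)(1 + a3 w0 / R)."""
    if min(p, R, Rb) <= 0 or w0 < 0:
        raise ValueError("p, R, Rb must be positive and w0 >= 0")
    a1, a2, a3 = alpha
    return a1 * p * R * w0 * (1.0 + a2 * Rb / R) * (1.0 + a3 * w0 / R)
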