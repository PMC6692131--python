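"""Discrete shell energies and their analytic gradients.

The shell is modeled by its mid-surface only (thin-shell limit).  Total
energy of a configuration is

    E = E_stretch + E_bend - p (V - V0) + E_contact,

with a finite-strain membrane term (Green–Lagrange strain with a
plane-stress Hookean law, integrated over constant-strain triangles), an
optional Donnell-type bending term quadratic in the normal displacement,
the pressure potential through the enclosed volume, and a quadratic
penalty for penetration of the rigid spherical indenter.

Volume convention: the tube is closed by *virtual* caps fanned over the
deformed end rings (used both for volume measurements and the pressure
potential).  The potential alone would load the tube ends axially
(closed-tube case); the solver's default ``lateral`` load mode instead
pins the end rings axially at the zero-axial-stress homogeneous
equilibrium, so the virtual caps push against those pins and the shell
interior stays free of axial prestress — the traction-free-ends
condition of the glued-worm preparation.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import ShellMesh

__all__ = [
    "membrane_energy",
    "triangle_strains",
    "BendingOperator",
    "enclosed_volume_positions",
    "contact_energy",
    "contact_force",
]


# ---------------------------------------------------------------------------
# membrane
# ---------------------------------------------------------------------------

def _deformation_gradients(pos: np.ndarray, mesh: ShellMesh) -> np.ndarray:
    """Per-triangle 3x2 deformation gradient from developed reference coords."""
    tri = mesh.triangles
    d = np.stack([pos[tri[:, 1]] - pos[tri[:, 0]],
                  pos[tri[:, 2]] - pos[tri[:, 0]]], axis=2)  # (n_tri, 3, 2)
    return d @ mesh.tri_inv_ref


def triangle_strains(pos: np.ndarray, mesh: ShellMesh) -> np.ndarray:
    """Green–Lagrange membrane strain per triangle, (n_tri, 2, 2).

    Components are in the developed surface frame (axial, circumferential).
    """
    F = _deformation_gradients(pos, mesh)
    G = np.einsum("tia,tib->tab", F, F)
    eps = 0.5 * (G - np.eye(2))
    return eps


def membrane_energy(pos: np.ndarray, mesh: ShellMesh, E: float, nu: float,
                    t: float, grad: bool = True):
    """St. Venant–Kirchhoff membrane energy and nodal gradient."""
    F = _deformation_gradients(pos, mesh)
    G = np.einsum("tia,tib->tab", F, F)
    eps = 0.5 * (G - np.eye(2))
    c = E * t / (1.0 - nu**2)
    tr = eps[:, 0, 0] + eps[:, 1, 1]
    sig = c * ((1.0 - nu) * eps + nu * tr[:, None, None] * np.eye(2))
    w_dens = 0.5 * np.einsum("tab,tab->t", sig, eps)
    energy = float(np.dot(mesh.tri_area, w_dens))
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite membrane energy: mesh inversion?")
    if not grad:
        return energy, None
    # dW/dF = F sigma ; chain back to vertex positions
    dWdF = np.einsum("t,tia,tab->tib", mesh.tri_area, F, sig)
    dWdD = np.einsum("tib,tcb->tic", dWdF, mesh.tri_inv_ref)
    g = np.zeros_like(pos)
    tri = mesh.triangles
    np.add.at(g, tri[:, 1], dWdD[:, :, 0])
    np.add.at(g, tri[:, 2], dWdD[:, :, 1])
    np.add.at(g, tri[:, 0], -(dWdD[:, :, 0] + dWdD[:, :, 1]))
    return energy, g


# ---------------------------------------------------------------------------
# bending
# ---------------------------------------------------------------------------

class BendingOperator:
    """Quadratic Donnell-type bending energy in the normal displacement.

    Curvature changes on the cylinder (axial coordinate s, arc c = R phi):
        k_ss = w_,ss      k_cc = w_,cc + w / R^2      k_sc = w_,sc
    assembled with finite differences on the structured grid (free ends:
    curvature rows at the two end stations are dropped).  The energy is

        E_b = D/2 * sum_n A_n [k_ss^2 + k_cc^2 + 2 nu k_ss k_cc
                               + 2 (1 - nu) k_sc^2]

    which is precomputed as a sparse quadratic form  E_b = D/2 w^T Q w.
    """

    def __init__(self, mesh: ShellMesh, nu: float):
        n_s, n_phi, R = mesh.n_s, mesh.n_phi, mesh.R
        n = mesh.n_nodes
        s = mesh.s

        def nid(i, j):
            return i * n_phi + (j % n_phi)

        rows, cols, vals = [], [], []          # d2/ds2
        for i in range(1, n_s - 1):
            h1, h2 = s[i] - s[i - 1], s[i + 1] - s[i]
            a = 2.0 / (h1 * (h1 + h2))
            b = -2.0 / (h1 * h2)
            cc = 2.0 / (h2 * (h1 + h2))
            for j in range(n_phi):
                r = nid(i, j)
                rows += [r, r, r]
                cols += [nid(i - 1, j), r, nid(i + 1, j)]
                vals += [a, b, cc]
        K_ss = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

        # circumferential arc spacings (periodic, possibly graded)
        phi = mesh.phi
        dphi_f = (np.roll(phi, -1) - phi) % (2.0 * np.pi)   # j -> j+1
        dphi_b = (phi - np.roll(phi, 1)) % (2.0 * np.pi)    # j-1 -> j
        hc_f, hc_b = R * dphi_f, R * dphi_b

        rows, cols, vals = [], [], []          # d2/dc2 + 1/R^2
        for i in range(n_s):
            for j in range(n_phi):
                r = nid(i, j)
                h1, h2 = hc_b[j], hc_f[j]
                rows += [r, r, r]
                cols += [nid(i, j - 1), r, nid(i, j + 1)]
                vals += [2.0 / (h1 * (h1 + h2)),
                         -2.0 / (h1 * h2) + 1.0 / R**2,
                         2.0 / (h2 * (h1 + h2))]
        K_cc = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

        rows, cols, vals = [], [], []          # d/ds (non-uniform central)
        for i in range(1, n_s - 1):
            h1, h2 = s[i] - s[i - 1], s[i + 1] - s[i]
            # three-point first derivative, exact for quadratics
            a = -h2 / (h1 * (h1 + h2))
            b = (h2 - h1) / (h1 * h2)
            cc = h1 / (h2 * (h1 + h2))
            for j in range(n_phi):
                r = nid(i, j)
                rows += [r, r, r]
                cols += [nid(i - 1, j), r, nid(i + 1, j)]
                vals += [a, b, cc]
        D_s = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

        rows, cols, vals = [], [], []          # d/dc (periodic, non-uniform)
        for i in range(n_s):
            for j in range(n_phi):
                r = nid(i, j)
                h1, h2 = hc_b[j], hc_f[j]
                rows += [r, r, r]
                cols += [nid(i, j - 1), r, nid(i, j + 1)]
                vals += [-h2 / (h1 * (h1 + h2)),
                         (h2 - h1) / (h1 * h2),
                         h1 / (h2 * (h1 + h2))]
        D_c = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        K_sc = D_c @ D_s

        W = sp.diags(mesh.node_area)
        Q = (K_ss.T @ W @ K_ss + K_cc.T @ W @ K_cc
             + nu * (K_ss.T @ W @ K_cc + K_cc.T @ W @ K_ss)
             + 2.0 * (1.0 - nu) * (K_sc.T @ W @ K_sc))
        self.Q = Q.tocsr()
        self.normals = mesh.normals_reference()

    def energy(self, u: np.ndarray, D: float, grad: bool = True):
        w = np.einsum("ni,ni->n", u, self.normals)
        Qw = self.Q @ w
        energy = 0.5 * D * float(w @ Qw)
        if not grad:
            return energy, None
        return energy, D * Qw[:, None] * self.normals


# ---------------------------------------------------------------------------
# enclosed volume
# ---------------------------------------------------------------------------

def _signed_tet_volumes(v0, v1, v2):
    return np.einsum("ti,ti->t", v0, np.cross(v1, v2)) / 6.0


def enclosed_volume_positions(pos: np.ndarray, mesh: ShellMesh,
                              grad: bool = True):
    """Enclosed volume of the tube closed by fans over the deformed end
    rings, and its gradient with respect to nodal positions."""
    tri = mesh.triangles
    V = float(np.sum(_signed_tet_volumes(pos[tri[:, 0]], pos[tri[:, 1]],
                                         pos[tri[:, 2]])))
    g = np.zeros_like(pos) if grad else None
    if grad:
        np.add.at(g, tri[:, 0], np.cross(pos[tri[:, 1]], pos[tri[:, 2]]) / 6.0)
        np.add.at(g, tri[:, 1], np.cross(pos[tri[:, 2]], pos[tri[:, 0]]) / 6.0)
        np.add.at(g, tri[:, 2], np.cross(pos[tri[:, 0]], pos[tri[:, 1]]) / 6.0)

    n_phi = mesh.n_phi
    for end, sign in ((0, -1.0), (mesh.n_s - 1, +1.0)):
        ring = np.array([mesh.node_index(end, j) for j in range(n_phi)])
        ring_next = np.roll(ring, -1)
        d0, d1 = pos[ring], pos[ring_next]
        centroid = d0.mean(axis=0)
        cen = np.broadcast_to(centroid, d0.shape)
        # fan (centroid, r_j, r_{j+1}) oriented outward along +/- y
        b, c = (d0, d1) if sign > 0 else (d1, d0)
        ib, ic = (ring, ring_next) if sign > 0 else (ring_next, ring)
        V += float(_signed_tet_volumes(cen, b, c).sum())
        if grad:
            np.add.at(g, ib, np.cross(c, cen) / 6.0)
            np.add.at(g, ic, np.cross(cen, b) / 6.0)
            gc = np.cross(b, c).sum(axis=0) / (6.0 * n_phi)
            np.add.at(g, ring, np.broadcast_to(gc, d0.shape))
    return V, g


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------

def _bead_penetration(pos: np.ndarray, center: np.ndarray, Rb: float,
                      approach: float = 1.0):
    """Penetration into the bead plus the vertical shaft swept behind it.

    With ``approach = +1`` the bead descends from above along -z, so the
    impenetrable region is the union of the sphere and the cylinder of
    radius Rb above its centre (the swept volume / supporting shaft);
    ``approach = -1`` mirrors this for a bead pushed up from below.
    Returns (pen, dir) where ``dir`` is the unit push-out direction for
    penetrating nodes.
    """
    d = pos - center
    above = approach * d[:, 2] > 0
    rho = np.hypot(d[:, 0], d[:, 1])
    r3 = np.linalg.norm(d, axis=1)
    pen = np.where(above, Rb - rho, Rb - r3)
    pen = np.maximum(pen, 0.0)
    dirs = np.zeros_like(pos)
    act = pen > 0
    if np.any(act):
        da = d[act].copy()
        ab = above[act]
        da[ab, 2] = 0.0                      # shaft pushes out radially
        nrm = np.maximum(np.linalg.norm(da, axis=1), 1e-3 * Rb)
        dirs[act] = da / nrm[:, None]
    return pen, dirs


def contact_energy(pos: np.ndarray, mesh: ShellMesh, center: np.ndarray,
                   Rb: float, k_pen: float, grad: bool = True,
                   approach: float = 1.0):
    """Area-weighted quadratic penalty on penetration of the rigid bead
    (including its supporting shaft).  Returns (energy, gradient,
    penetration-per-node)."""
    pen, dirs = _bead_penetration(pos, center, Rb, approach)
    w = mesh.node_area * pen
    energy = 0.5 * k_pen * float(w @ pen)
    g = None
    if grad:
        g = -k_pen * w[:, None] * dirs
    return energy, g, pen


def contact_force(pos: np.ndarray, mesh: ShellMesh, center: np.ndarray,
                  Rb: float, k_pen: float, approach: float = 1.0) -> float:
    """Indenter force dE/dw0 (virtual work of the penalty at equilibrium).

    The bead center moves along -approach*z as w0 grows; only the
    spherical part contributes (the frictionless shaft exerts no
    traction along the travel direction):
    dE/dw0 = k sum_n A_n g_n (c - x_n)_z / |x_n - c| * approach.
    """
    d = pos - center
    above = approach * d[:, 2] > 0
    r = np.linalg.norm(d, axis=1)
    pen = np.maximum(Rb - r, 0.0)
    act = (pen > 0) & ~above
    if not np.any(act):
        return 0.0
    return float(k_pen * np.sum(mesh.node_area[act] * pen[act]
                                * (-approach * d[act, 2])
                                / np.maximum(r[act], 1e-3 * Rb)))
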