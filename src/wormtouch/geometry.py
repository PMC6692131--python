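"""Worm-body shell geometry and surface meshing.

The body is idealized as a thin cylindrical shell of mid-surface radius
``R``, wall thickness ``t`` and length ``L``, pressurized to ``p`` above
the surroundings.  The mesh discretizes the shell *mid-surface* with a
structured grid of axial stations ``s`` (optionally graded towards the
indenter) and uniformly spaced circumferential angles ``phi`` measured
from the top of the worm (the side touched by the bead).  All quantities
are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "ShellGeometry",
    "ShellMesh",
    "ShellConfiguration",
    "Indenter",
    "BCMode",
    "EndCondition",
    "BoundaryCondition",
    "build_mesh",
]


@dataclass(frozen=True)
class ShellGeometry:
    """Target (pressurized) shell geometry plus the no-stress reference.

    ``R``, ``t``, ``L`` are the values the pressurized body should have;
    ``reference_*`` describe the unloaded (no-stress) state that inflates
    to them.  When ``p == 0`` the two coincide.
    """

    R: float
    t: float
    L: float
    nu: float = 0.3
    E: float = 4.0e6
    p: float = 0.0
    reference_R: float | None = None
    reference_t: float | None = None
    reference_L: float | None = None

    def __post_init__(self):
        if min(self.R, self.t, self.L, self.E) <= 0:
            raise ValueError("R, t, L, E must be positive")
        if not (0.0 < self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.p < 0:
            raise ValueError("internal pressure must be non-negative")
        if self.t >= self.R / 10:
            raise ValueError("thin-shell model requires t < R/10")
        if self.p == 0.0:
            # no load: the reference state is the target state
            object.__setattr__(self, "reference_R", self.R)
            object.__setattr__(self, "reference_t", self.t)
            object.__setattr__(self, "reference_L", self.L)
        if self.reference_t is None:
            # wall-thickness change on inflation is O(p/E * t): negligible
            object.__setattr__(self, "reference_t", self.t)

    @property
    def calibrated(self) -> bool:
        return self.reference_R is not None and self.reference_L is not None

    @property
    def bending_rigidity(self) -> float:
        return self.E * self.t**3 / (12.0 * (1.0 - self.nu**2))

    @property
    def shell_parameter(self) -> float:
        """tau = p R^2 / (E t^2); bending is negligible for tau >> 1."""
        return self.p * self.R**2 / (self.E * self.t**2)

    def with_reference(self, reference_R: float, reference_L: float) -> "ShellGeometry":
        return replace(self, reference_R=reference_R, reference_L=reference_L)


class BCMode(str, Enum):
    FIXED_LOWER_HALF = "fixed_lower_half"
    VERTICALLY_RIGID_LOWER_HALF = "vertically_rigid_lower_half"


class EndCondition(str, Enum):
    FREE = "free"
    PLUGGED = "plugged"  # config stub only; not implemented


@dataclass(frozen=True)
class BoundaryCondition:
    """Glued-worm constraint on the lower half of the body.

    ``fixed_lower_half`` pins the lower half (phi in [pi/2, 3pi/2]) at its
    pressurized resting position; ``vertically_rigid_lower_half`` pins only
    its vertical (z) motion.  Ends are traction free.
    """

    mode: BCMode = BCMode.FIXED_LOWER_HALF
    ends: EndCondition = EndCondition.FREE

    def __post_init__(self):
        if self.ends is EndCondition.PLUGGED:
            raise NotImplementedError("plugged ends are a config stub only")


@dataclass(frozen=True)
class Indenter:
    """Rigid spherical bead pressed vertically into the top of the worm.

    ``w0`` is the travel of the bead's lowest point past the pressurized
    resting surface, ``position`` its axial station along the body.
    """

    Rb: float = 10e-6
    position: float = 0.0
    w0: float = 0.0

    def __post_init__(self):
        if self.Rb <= 0:
            raise ValueError("bead radius must be positive")
        if self.w0 < 0:
            raise ValueError("indentation depth must be non-negative")


def _graded_axial_nodes(L: float, n_s: int, center: float, grading: float) -> np.ndarray:
    """Axial stations on [-L/2, L/2] clustered near ``center`` by a sinh map."""
    half = L / 2.0
    center = float(np.clip(center, -0.45 * half, 0.45 * half))
    if grading <= 0:
        return np.linspace(-half, half, n_s)
    # split node budget proportionally between the two sides of the cluster
    n_left = max(4, int(round((n_s - 1) * (center + half) / L)))
    n_right = n_s - 1 - n_left
    if n_right < 4:
        n_right = 4
        n_left = n_s - 1 - n_right
    xi_l = np.linspace(1.0, 0.0, n_left + 1)
    xi_r = np.linspace(0.0, 1.0, n_right + 1)
    left = center - (center + half) * np.sinh(grading * xi_l) / np.sinh(grading)
    right = center + (half - center) * np.sinh(grading * xi_r) / np.sinh(grading)
    s = np.concatenate([left[:-1], [center], right[1:]])
    s[0], s[-1] = -half, half
    return s


@dataclass
class ShellMesh:
    """Structured triangulated mid-surface mesh of the reference cylinder."""

    s: np.ndarray          # (n_s,) axial stations
    phi: np.ndarray        # (n_phi,) angles, phi=0 at the top, periodic
    R: float               # reference mid-surface radius
    positions: np.ndarray = field(init=False)   # (n_nodes, 3)
    triangles: np.ndarray = field(init=False)   # (n_tri, 3) node indices
    tri_inv_ref: np.ndarray = field(init=False)  # (n_tri, 2, 2) inverse ref edge matrix
    tri_area: np.ndarray = field(init=False)    # (n_tri,)
    node_area: np.ndarray = field(init=False)   # (n_nodes,)

    def __post_init__(self):
        n_s, n_phi = len(self.s), len(self.phi)
        if n_s < 2 or n_phi < 3:
            raise ValueError("mesh too coarse")
        # lab frame: y axial, z vertical (top at phi=0), x completing
        ss, pp = np.meshgrid(self.s, self.phi, indexing="ij")
        x = self.R * np.sin(pp)
        y = ss
        z = self.R * np.cos(pp)
        self.positions = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)

        def nid(i, j):
            return i * n_phi + (j % n_phi)

        tris = []
        for i in range(n_s - 1):
            for j in range(n_phi):
                a, b = nid(i, j), nid(i + 1, j)
                c, d = nid(i + 1, j + 1), nid(i, j + 1)
                # ordered so cross(v1-v0, v2-v0) points outward
                tris.append((a, c, b))
                tris.append((a, d, c))
        self.triangles = np.asarray(tris, dtype=np.int64)

        # in-plane reference edge matrices from the actual 3D chords, in a
        # per-triangle orthonormal frame (e1 ~ axial, e2 ~ circumferential)
        # so the faceted reference mesh is exactly stress-free.
        v0 = self.positions[self.triangles[:, 0]]
        e1_3d = self.positions[self.triangles[:, 1]] - v0
        e2_3d = self.positions[self.triangles[:, 2]] - v0
        nrm = np.cross(e1_3d, e2_3d)
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        ax = np.array([0.0, 1.0, 0.0])
        t1 = ax - nrm * nrm[:, 1][:, None]
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(nrm, t1)
        e_all = np.empty((len(self.triangles), 2, 2))
        e_all[:, 0, 0] = np.einsum("ti,ti->t", e1_3d, t1)
        e_all[:, 0, 1] = np.einsum("ti,ti->t", e2_3d, t1)
        e_all[:, 1, 0] = np.einsum("ti,ti->t", e1_3d, t2)
        e_all[:, 1, 1] = np.einsum("ti,ti->t", e2_3d, t2)
        det = e_all[:, 0, 0] * e_all[:, 1, 1] - e_all[:, 0, 1] * e_all[:, 1, 0]
        self.tri_area = 0.5 * np.abs(det)
        inv = np.empty_like(e_all)
        inv[:, 0, 0] = e_all[:, 1, 1]
        inv[:, 0, 1] = -e_all[:, 0, 1]
        inv[:, 1, 0] = -e_all[:, 1, 0]
        inv[:, 1, 1] = e_all[:, 0, 0]
        self.tri_inv_ref = inv / det[:, None, None]

        area = np.zeros(len(self.positions))
        np.add.at(area, self.triangles.ravel(),
                  np.repeat(self.tri_area / 3.0, 3))
        self.node_area = area

    # ---- structured-grid helpers -------------------------------------
    @property
    def n_s(self) -> int:
        return len(self.s)

    @property
    def n_phi(self) -> int:
        return len(self.phi)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def node_index(self, i: int, j: int) -> int:
        return i * self.n_phi + (j % self.n_phi)

    def grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-node array to (n_s, n_phi, ...)."""
        return values.reshape(self.n_s, self.n_phi, *values.shape[1:])

    def lower_half_nodes(self) -> np.ndarray:
        """Indices of nodes on the glued lower half, phi in [pi/2, 3pi/2]."""
        lower = (np.cos(self.phi) <= 1e-12)
        mask = np.tile(lower, self.n_s)
        return np.nonzero(mask)[0]

    def normals_reference(self) -> np.ndarray:
        """Outward unit normals of the reference cylinder, per node."""
        pp = np.tile(self.phi, self.n_s)
        return np.stack([np.sin(pp), np.zeros_like(pp), np.cos(pp)], axis=1)

    def total_area(self) -> float:
        return float(self.tri_area.sum())


@dataclass
class ShellConfiguration:
    """A deformed state of the shell: mesh plus nodal displacements.

    Displacements are measured from the *reference* (no-stress) mesh; the
    pressurized resting state is itself a configuration.  Green–Lagrange
    strains are evaluated per triangle on demand by the energy module.
    """

    mesh: ShellMesh
    u: np.ndarray  # (n_nodes, 3)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (self.mesh.n_nodes, 3):
            raise ValueError("displacement field shape mismatch")

    @property
    def positions(self) -> np.ndarray:
        return self.mesh.positions + self.u

    @classmethod
    def undeformed(cls, mesh: ShellMesh) -> "ShellConfiguration":
        return cls(mesh, np.zeros((mesh.n_nodes, 3)))


def build_mesh(geometry: ShellGeometry, n_s: int = 72, n_phi: int = 40,
               cluster_at: float = 0.0, grading: float = 4.0,
               phi_grading: float = 0.0) -> ShellMesh:
    """Mesh the *reference* (no-stress) cylinder of a calibrated geometry.

    ``cluster_at`` concentrates axial resolution near the bead station;
    ``grading=0`` gives a uniform axial grid.  ``phi_grading`` in [0, 1)
    concentrates circumferential resolution at the top (contact side)
    through the smooth periodic map phi = xi - b sin(xi).
    """
    if n_s < 16 or n_phi < 16:
        raise ValueError("need n_s >= 16 and n_phi >= 16")
    R_ref = geometry.reference_R if geometry.reference_R is not None else geometry.R
    L_ref = geometry.reference_L if geometry.reference_L is not None else geometry.L
    if R_ref <= 0 or L_ref <= 0:
        raise ValueError("non-positive reference dimensions")
    if not (0.0 <= phi_grading < 1.0):
        raise ValueError("phi_grading must lie in [0, 1)")
    s = _graded_axial_nodes(L_ref, n_s, cluster_at, grading)
    xi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    phi = (xi - phi_grading * np.sin(xi)) % (2.0 * np.pi)
    return ShellMesh(s=s, phi=phi, R=R_ref)
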