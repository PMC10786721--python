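"""Triangulated spherical cell membrane and its spring-network force laws.

The cell is a closed icosphere mesh (642 vertices at the standard
resolution) whose shape is maintained by four nodal force families:

* a **link force** on every edge, resisting stretch of the edge relative to
  its reference length, with a persistence-length prefactor and a singular
  bracket that prevents strains beyond tau_l = 3;
* a **bending force** on every pair of adjacent triangles, resisting changes
  of the signed dihedral angle between their outward normals, singular at
  deviations of tau_b = pi/6;
* a **local area force** per triangle, resisting relative area changes,
  singular at tau_a = 0.3 (30% area change);
* a **global volume force** on all vertices, conserving the enclosed volume
  to within tau_v = 0.01 (note: this law's bracket has no "1 +" term).

Each modulus is dimensionless; forces scale with the thermal energy k_B*T.
All four laws are internal: at the reference configuration every force is
zero, and for any deformation the per-law net force over the mesh vanishes
(exactly for link/area/volume by construction, to rounding for bending via
the translation invariance of the dihedral angle).

Crossing a limiting factor raises :class:`MembraneLimitError` rather than
clamping: an out-of-range deviation signals a broken time step, and silent
clamping would corrupt parameter identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import trimesh

#: Spectrin-link persistence length, um (7.5 nm).
PERSISTENCE_LENGTH_UM = 7.5e-3

#: Limiting factors of the four force laws (fixed constants).
TAU_L = 3.0
TAU_B = math.pi / 6.0
TAU_A = 0.3
TAU_V = 0.01

#: Vertex counts reachable by icosahedron subdivision -> subdivision level.
ICOSPHERE_LEVELS = {12: 0, 42: 1, 162: 2, 642: 3, 2562: 4}

#: Parameter bounds used for identification (K's, then VR).
PARAM_BOUNDS = np.array([[0.0, 1e6]] * 4 + [[0.0, 40.0]])
PARAM_NAMES = ("K_l", "K_b", "K_a", "K_v", "VR")


class MembraneLimitError(RuntimeError):
    """A deformation crossed a limiting factor (singular force regime)."""


class MeshError(ValueError):
    pass


@dataclass
class CellModelParams:
    """Dimensionless moduli of the membrane force laws plus viscosity ratio."""

    K_l: float
    K_b: float
    K_a: float
    K_v: float
    VR: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip(PARAM_NAMES, PARAM_BOUNDS):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v!r} outside identification bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.K_l, self.K_b, self.K_a, self.K_v, self.VR])

    @classmethod
    def from_array(cls, arr) -> "CellModelParams":
        return cls(*map(float, arr))


@dataclass
class MembraneMesh:
    """Closed triangulated membrane with reference (stress-free) geometry.

    ``vertices`` hold the *current* configuration; the ``*_ref`` fields were
    captured at construction and define the zero-force state.  Lengths are
    in whatever unit the mesh was built with (um or lattice units).
    """

    vertices: np.ndarray      # (V, 3)
    faces: np.ndarray         # (F, 3) outward-wound
    edges: np.ndarray         # (E, 2)
    L0: np.ndarray            # (E,) reference edge lengths
    A0: np.ndarray            # (F,) reference triangle areas
    # hinge arrays, one per interior edge: shared edge (a, b) ordered along
    # face1's winding; c opposite in face1, d opposite in face2
    hinge_a: np.ndarray
    hinge_b: np.ndarray
    hinge_c: np.ndarray
    hinge_d: np.ndarray
    theta0: np.ndarray        # (E,) reference signed dihedral angles
    hinge_L0: np.ndarray      # (E,) reference length of the shared edge
    V0: float                 # reference enclosed volume
    L0_mean: float            # mean reference edge length
    persistence: float        # persistence length, same unit as vertices

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "MembraneMesh":
        return replace(self, vertices=self.vertices.copy())

    def translated(self, offset) -> "MembraneMesh":
        return replace(self, vertices=self.vertices + np.asarray(offset))

    def scaled(self, factor: float) -> "MembraneMesh":
        """Uniformly rescale the mesh *and* its reference state (unit change)."""
        return replace(
            self,
            vertices=self.vertices * factor,
            L0=self.L0 * factor,
            A0=self.A0 * factor**2,
            hinge_L0=self.hinge_L0 * factor,
            V0=self.V0 * factor**3,
            L0_mean=self.L0_mean * factor,
            persistence=self.persistence * factor,
        )

    def axial_extent(self, axis: int = 0) -> float:
        x = self.vertices[:, axis]
        return float(x.max() - x.min())


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed volume of a closed mesh via the divergence theorem.

    Positive when the faces are wound outward.
    """
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    return float(np.einsum('ij,ij->i', a, np.cross(b, c)).sum() / 6.0)


def _signed_dihedral(X, a, b, c, d):
    """Signed angle between outward normals across hinge (a,b).

    Positive/negative by convexity relative to the outward direction; the
    sign convention is fixed by ordering (a, b) along face1's winding.
    """
    e = X[b] - X[a]
    ehat = e / np.linalg.norm(e, axis=-1, keepdims=True)
    n1 = np.cross(X[b] - X[a], X[c] - X[a])
    n2 = np.cross(X[a] - X[b], X[d] - X[b])
    n1 = n1 / np.linalg.norm(n1, axis=-1, keepdims=True)
    n2 = n2 / np.linalg.norm(n2, axis=-1, keepdims=True)
    s = np.einsum('ij,ij->i', np.cross(n1, n2), ehat)
    cth = np.einsum('ij,ij->i', n1, n2)
    return np.arctan2(s, cth)


def make_cell_mesh(diameter: float, target_nodes: int = 642,
                   center=(0.0, 0.0, 0.0)) -> MembraneMesh:
    """Build an icosphere membrane of the given diameter.

    ``target_nodes`` must be an icosphere vertex count (12, 42, 162, 642,
    2562); 642 is the standard cell-model resolution (1280 triangles,
    1920 edges).  The reference state is the spherical configuration.
    """
    if diameter <= 0:
        raise MeshError("diameter must be positive")
    try:
        level = ICOSPHERE_LEVELS[target_nodes]
    except KeyError:
        raise MeshError(
            f"target_nodes={target_nodes} is not an icosphere count; "
            f"allowed: {sorted(ICOSPHERE_LEVELS)}") from None
    tm = trimesh.creation.icosphere(subdivisions=level, radius=diameter / 2.0)
    verts = np.asarray(tm.vertices, dtype=float) + np.asarray(center, float)
    faces = np.asarray(tm.faces, dtype=np.int64)

    edges = np.asarray(tm.edges_unique, dtype=np.int64)
    L0 = np.linalg.norm(verts[edges[:, 1]] - verts[edges[:, 0]], axis=1)

    # computed with the same expression used by area_forces so the reference
    # state is a bit-exact zero of the area law
    A0 = 0.5 * np.linalg.norm(
        np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                 verts[faces[:, 2]] - verts[faces[:, 0]]), axis=1)

    adj_faces = np.asarray(tm.face_adjacency, dtype=np.int64)      # (E, 2)
    adj_edges = np.asarray(tm.face_adjacency_edges, dtype=np.int64)
    unshared = np.asarray(tm.face_adjacency_unshared, dtype=np.int64)
    if len(adj_faces) != len(edges):
        raise MeshError("mesh is not a closed 2-manifold")

    # orient each hinge edge along face1's winding
    ha = np.empty(len(adj_faces), dtype=np.int64)
    hb = np.empty_like(ha)
    f1 = faces[adj_faces[:, 0]]
    for row in range(len(adj_faces)):
        u, v = adj_edges[row]
        tri = f1[row]
        # directed edge (u, v) or (v, u) as it appears in face1's cycle
        for t in range(3):
            if tri[t] == u and tri[(t + 1) % 3] == v:
                ha[row], hb[row] = u, v
                break
            if tri[t] == v and tri[(t + 1) % 3] == u:
                ha[row], hb[row] = v, u
                break
    hc = unshared[:, 0]
    hd = unshared[:, 1]
    theta0 = _signed_dihedral(verts, ha, hb, hc, hd)
    hinge_L0 = np.linalg.norm(verts[hb] - verts[ha], axis=1)

    return MembraneMesh(
        vertices=verts, faces=faces, edges=edges, L0=L0, A0=A0,
        hinge_a=ha, hinge_b=hb, hinge_c=hc, hinge_d=hd,
        theta0=theta0, hinge_L0=hinge_L0,
        V0=enclosed_volume(verts, faces),
        L0_mean=float(L0.mean()),
        persistence=PERSISTENCE_LENGTH_UM,
    )


# ---------------------------------------------------------------------------
# Bracket (singular amplification) factors of the four laws
# ---------------------------------------------------------------------------

def link_bracket(strain, tau: float = TAU_L):
    return 1.0 + 1.0 / (tau**2 - np.asarray(strain)**2)


def bending_bracket(dtheta, tau: float = TAU_B):
    return 1.0 + 1.0 / (tau**2 - np.asarray(dtheta)**2)


def area_bracket(rel_area, tau: float = TAU_A):
    return 1.0 + 1.0 / (tau**2 - np.asarray(rel_area)**2)


def volume_bracket(rel_vol, tau: float = TAU_V):
    # the volume law has no "1 +" term
    return 1.0 / (tau**2 - np.asarray(rel_vol)**2)


# ---------------------------------------------------------------------------
# Nodal forces
# ---------------------------------------------------------------------------

def link_forces(mesh: MembraneMesh, X: np.ndarray,
                params: CellModelParams, kBT: float) -> np.ndarray:
    """Stretch forces along every edge.

    Magnitude (K_l*kBT/P) * strain * [1 + 1/(tau_l^2 - strain^2)], applied
    equal and opposite to the edge endpoints, attractive when stretched.
    """
    a, b = mesh.edges[:, 0], mesh.edges[:, 1]
    dvec = X[b] - X[a]
    L = np.linalg.norm(dvec, axis=1)
    strain = (L - mesh.L0) / mesh.L0
    worst = np.argmax(np.abs(strain))
    if abs(strain[worst]) >= TAU_L:
        raise MembraneLimitError(
            f"edge {worst} (vertices {a[worst]}-{b[worst]}) strain "
            f"{strain[worst]:.3f} reached the limiting factor tau_l={TAU_L}")
    mag = (params.K_l * kBT / mesh.persistence) * strain * link_bracket(strain)
    fvec = (mag / L)[:, None] * dvec      # on endpoint a, toward b if stretched
    F = np.zeros_like(X)
    np.add.at(F, a, fvec)
    np.add.at(F, b, -fvec)
    return F


def bending_forces(mesh: MembraneMesh, X: np.ndarray,
                   params: CellModelParams, kBT: float) -> np.ndarray:
    """Dihedral restoring forces on every adjacent-triangle pair.

    The law magnitude (K_b*kBT/L0)*(theta-theta0)*[1 + 1/(tau_b^2 - d^2)]
    is distributed over the four hinge vertices along the (analytic)
    gradient of the dihedral angle, scaled by the hinge reference length so
    the characteristic nodal magnitude matches the law.  The gradient
    distribution exerts zero net force and zero net torque per hinge.
    """
    a, b, c, d = mesh.hinge_a, mesh.hinge_b, mesh.hinge_c, mesh.hinge_d
    theta = _signed_dihedral(X, a, b, c, d)
    dth = theta - mesh.theta0
    worst = np.argmax(np.abs(dth))
    if abs(dth[worst]) >= TAU_B:
        raise MembraneLimitError(
            f"hinge {worst} (edge {a[worst]}-{b[worst]}) dihedral deviation "
            f"{dth[worst]:.3f} rad reached tau_b={TAU_B:.4f}")
    mag = (params.K_b * kBT / mesh.hinge_L0) * dth * bending_bracket(dth)

    e = X[b] - X[a]
    l = np.linalg.norm(e, axis=1)
    N1 = np.cross(X[b] - X[a], X[c] - X[a])
    N2 = np.cross(X[a] - X[b], X[d] - X[b])
    n1 = N1 / np.einsum('ij,ij->i', N1, N1)[:, None]
    n2 = N2 / np.einsum('ij,ij->i', N2, N2)[:, None]
    pcb = np.einsum('ij,ij->i', X[c] - X[b], e) / l
    pdb = np.einsum('ij,ij->i', X[d] - X[b], e) / l
    pca = np.einsum('ij,ij->i', X[c] - X[a], e) / l
    pda = np.einsum('ij,ij->i', X[d] - X[a], e) / l
    ga = -pcb[:, None] * n1 - pdb[:, None] * n2
    gb = pca[:, None] * n1 + pda[:, None] * n2
    gc = -l[:, None] * n1
    gd = -l[:, None] * n2

    scale = (-mag * mesh.hinge_L0)[:, None]
    F = np.zeros_like(X)
    np.add.at(F, a, scale * ga)
    np.add.at(F, b, scale * gb)
    np.add.at(F, c, scale * gc)
    np.add.at(F, d, scale * gd)
    return F


def area_forces(mesh: MembraneMesh, X: np.ndarray,
                params: CellModelParams, kBT: float) -> np.ndarray:
    """Local area restoring forces per triangle.

    Magnitude (K_a*kBT/L0m)*(dA/A0)*[1 + 1/(tau_a^2 - (dA/A0)^2)] per
    triangle, applied to its three vertices along the centroid-radial
    directions (weighted by centroid distance so the per-triangle net force
    is exactly zero); vertices move toward the centroid when the triangle
    has grown.
    """
    va = X[mesh.faces[:, 0]]
    vb = X[mesh.faces[:, 1]]
    vc = X[mesh.faces[:, 2]]
    n = np.cross(vb - va, vc - va)
    A = 0.5 * np.linalg.norm(n, axis=1)
    s = (A - mesh.A0) / mesh.A0
    worst = np.argmax(np.abs(s))
    if abs(s[worst]) >= TAU_A:
        raise MembraneLimitError(
            f"triangle {worst} relative area change {s[worst]:.3f} reached "
            f"tau_a={TAU_A} (surface area change above 30%)")
    mag = (params.K_a * kBT / mesh.L0_mean) * s * area_bracket(s)
    centroid = (va + vb + vc) / 3.0
    dbar = (np.linalg.norm(centroid - va, axis=1)
            + np.linalg.norm(centroid - vb, axis=1)
            + np.linalg.norm(centroid - vc, axis=1)) / 3.0
    F = np.zeros_like(X)
    for col in range(3):
        rv = centroid - X[mesh.faces[:, col]]
        np.add.at(F, mesh.faces[:, col], (mag / dbar)[:, None] * rv)
    return F


def volume_force(mesh: MembraneMesh, X: np.ndarray,
                 params: CellModelParams, kBT: float) -> np.ndarray:
    """Global volume-conservation forces on all vertices.

    Magnitude (K_v*kBT/L0m)*(dV/V0)*[1/(tau_v^2 - (dV/V0)^2)] applied along
    area-weighted vertex normals, inward when the cell has swollen.  The
    area weighting makes the net force exactly zero on a closed mesh.
    """
    V = enclosed_volume(X, mesh.faces)
    rel = (V - mesh.V0) / mesh.V0
    if abs(rel) >= TAU_V:
        raise MembraneLimitError(
            f"relative volume change {rel:.4f} reached tau_v={TAU_V}")
    mag = (params.K_v * kBT / mesh.L0_mean) * rel * volume_bracket(rel)

    va = X[mesh.faces[:, 0]]
    vb = X[mesh.faces[:, 1]]
    vc = X[mesh.faces[:, 2]]
    nf = np.cross(vb - va, vc - va)  # outward, |nf| = 2*A_face
    Nv = np.zeros_like(X)
    for col in range(3):
        np.add.at(Nv, mesh.faces[:, col], nf / 6.0)  # area-weighted normals
    norm_mean = np.linalg.norm(Nv, axis=1).mean()
    return (-mag / norm_mean) * Nv


def total_forces(mesh: MembraneMesh, X: np.ndarray,
                 params: CellModelParams, kBT: float) -> np.ndarray:
    """Sum of the four constitutive force families per vertex."""
    return (link_forces(mesh, X, params, kBT)
            + bending_forces(mesh, X, params, kBT)
            + area_forces(mesh, X, params, kBT)
            + volume_force(mesh, X, params, kBT))


_LIMIT_MESSAGES = {
    1: "edge {i} strain {v:.3f} reached the limiting factor tau_l=" + str(TAU_L),
    2: "hinge {i} dihedral deviation {v:.3f} rad reached tau_b="
       + f"{TAU_B:.4f}",
    3: "triangle {i} relative area change {v:.3f} reached tau_a="
       + str(TAU_A) + " (surface area change above 30%)",
    4: "relative volume change {v:.4f} reached tau_v=" + str(TAU_V),
}


def total_forces_fast(mesh: MembraneMesh, X: np.ndarray,
                      params: CellModelParams, kBT: float,
                      out: np.ndarray | None = None) -> np.ndarray:
    """Compiled single-pass evaluation of :func:`total_forces`.

    Numerically identical (to rounding) to the sum of the four reference
    implementations; used in the time-stepping loop where the per-step
    cost matters.  ``out`` may supply a preallocated (V, 3) buffer.
    """
    from . import _kernels
    if out is None:
        out = np.empty_like(X)
    code, idx, val = _kernels.membrane_forces(
        X, mesh.edges, mesh.L0, mesh.faces, mesh.A0,
        mesh.hinge_a, mesh.hinge_b, mesh.hinge_c, mesh.hinge_d,
        mesh.theta0, mesh.hinge_L0, mesh.V0, mesh.L0_mean,
        mesh.persistence,
        params.K_l, params.K_b, params.K_a, params.K_v, kBT,
        TAU_L, TAU_B, TAU_A, TAU_V, out)
    if code:
        raise MembraneLimitError(_LIMIT_MESSAGES[code].format(i=idx, v=val))
    return out
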