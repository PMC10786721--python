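import math

import numpy as np
import pytest

from cellsqueeze import membrane as M
from cellsqueeze.membrane import (CellModelParams, MembraneLimitError,
                                  MeshError, area_bracket, area_forces,
                                  bending_bracket, bending_forces,
                                  enclosed_volume, link_bracket, link_forces,
                                  make_cell_mesh, total_forces, volume_bracket,
                                  volume_force)

KBT = 1.0  # unit thermal energy: force scales are arbitrary in these tests


@pytest.fixture(scope="module")
def params():
    return CellModelParams(K_l=2e4, K_b=4e4, K_a=2e4, K_v=9e4, VR=19.9)


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------

def test_icosphere_standard_resolution_counts(cell16):
    assert cell16.n_vertices == 642
    assert len(cell16.faces) == 1280
    assert len(cell16.edges) == 1920
    # Euler characteristic of a sphere
    assert cell16.n_vertices - len(cell16.edges) + len(cell16.faces) == 2


def test_icosphere_volume_close_to_sphere(cell16):
    exact = 4.0 / 3.0 * math.pi * 8.0**3  # 2144.66 um^3
    v = enclosed_volume(cell16.vertices, cell16.faces)
    assert v < exact                       # inscribed polyhedron
    assert v == pytest.approx(exact, rel=0.01)


def test_invalid_subdivision_count_rejected():
    with pytest.raises(MeshError, match="642"):
        make_cell_mesh(16.0, target_nodes=100)
    with pytest.raises(MeshError):
        make_cell_mesh(-1.0)


def test_tetrahedron_volume_and_orientation_sign():
    # unit-edge regular tetrahedron: V = sqrt(2)/12
    verts = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                      [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]) / math.sqrt(8)
    faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    v = enclosed_volume(verts, faces)
    assert v == pytest.approx(math.sqrt(2) / 12, rel=1e-12)
    assert enclosed_volume(verts, faces[:, ::-1]) == pytest.approx(-v)


# ---------------------------------------------------------------------------
# Bracket spot values (direct arithmetic on the constitutive laws)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bracket,dev,expected", [
    (link_bracket, 0.1, 1.0 + 1.0 / (9.0 - 0.01)),          # 1.1112347
    (bending_bracket, 0.1, 1.0 + 1.0 / ((math.pi / 6) ** 2 - 0.01)),
    (area_bracket, 0.1, 13.5),                               # 1 + 1/0.08
    (volume_bracket, 0.005, 1.0 / 7.5e-5),                   # 13333.33, no 1+
])
def test_bracket_spot_values(bracket, dev, expected):
    assert bracket(dev) == pytest.approx(expected, rel=1e-12)


def test_bracket_reference_numbers():
    assert link_bracket(0.1) == pytest.approx(1.11123, abs=1e-4)
    assert bending_bracket(0.1) == pytest.approx(4.78565, abs=1e-4)
    assert area_bracket(0.1) == pytest.approx(13.5, abs=1e-9)
    assert volume_bracket(0.005) == pytest.approx(13333.3, rel=1e-4)


@pytest.mark.parametrize("bracket,limit", [
    (link_bracket, M.TAU_L), (bending_bracket, M.TAU_B),
    (area_bracket, M.TAU_A), (volume_bracket, M.TAU_V)])
def test_bracket_increasing_and_divergent(bracket, limit):
    devs = np.linspace(0, limit * 0.999, 200)
    vals = np.asarray(bracket(devs))
    assert np.all(np.diff(vals) > 0)
    # divergence approaching the limiting factor
    assert bracket(limit * (1 - 1e-9)) > 1e6 * vals[0]


# ---------------------------------------------------------------------------
# Zero-force reference and internal-force properties
# ---------------------------------------------------------------------------

def test_reference_state_exactly_zero(cell16, params):
    F = total_forces(cell16, cell16.vertices, params, KBT)
    assert np.abs(F).max() == 0.0


def test_rigid_translation_leaves_forces_zero(cell16, params):
    X = cell16.vertices + np.array([3.0, -2.0, 7.0])
    F = total_forces(cell16, X, params, KBT)
    # forces depend only on shape; rounding of recomputed lengths allows
    # machine-epsilon leakage scaled by the (large) moduli
    scale = params.K_l * KBT / cell16.persistence
    assert np.abs(F).max() < 1e-10 * scale


def test_net_internal_force_vanishes_on_random_perturbations(cell16, params,
                                                             rng):
    for _ in range(100):
        X = cell16.vertices + 0.02 * rng.normal(size=cell16.vertices.shape)
        F = total_forces(cell16, X, params, KBT)
        assert np.abs(F.sum(axis=0)).max() < 1e-8 * np.abs(F).sum()


def test_each_force_family_has_zero_net_force(cell16, params, rng):
    X = cell16.vertices + 0.02 * rng.normal(size=cell16.vertices.shape)
    for fn in (link_forces, bending_forces, area_forces, volume_force):
        F = fn(cell16, X, params, KBT)
        assert np.abs(F.sum(axis=0)).max() < 1e-8 * (np.abs(F).sum() + 1e-30)


def test_link_force_pairwise_equal_opposite():
    mesh = make_cell_mesh(16.0, target_nodes=12)  # icosahedron: clean edges
    params = CellModelParams(K_l=1e4, K_b=0, K_a=0, K_v=0, VR=1)
    X = mesh.vertices.copy()
    X[0] *= 1.05  # stretch the edges at vertex 0
    F = link_forces(mesh, X, params, KBT)
    # net force of the whole edge set vanishes pairwise
    assert np.abs(F.sum(axis=0)).max() < 1e-12 * np.abs(F).sum()
    # vertex 0 pulled back toward the centre
    assert np.dot(F[0], X[0]) < 0


def test_stretched_sphere_link_forces_restore(cell16):
    params = CellModelParams(K_l=1e4, K_b=0, K_a=0, K_v=0, VR=1)
    X = cell16.vertices * 1.02  # uniform inflation stretches all edges
    F = link_forces(cell16, X, params, KBT)
    radial = np.einsum('ij,ij->i', F, X)
    assert np.all(radial < 0)   # all vertices pulled inward


def test_area_force_restoring_direction(cell16):
    params = CellModelParams(K_l=0, K_b=0, K_a=1e4, K_v=0, VR=1)
    X = cell16.vertices * 1.02  # all triangle areas grown
    F = area_forces(cell16, X, params, KBT)
    radial = np.einsum('ij,ij->i', F, X)
    assert np.all(radial < 0)   # toward centroids = inward on a sphere


def test_volume_force_inward_when_swollen(cell16):
    params = CellModelParams(K_l=0, K_b=0, K_a=0, K_v=1e4, VR=1)
    X = cell16.vertices * 1.001  # volume grown by ~0.3%
    F = volume_force(cell16, X, params, KBT)
    radial = np.einsum('ij,ij->i', F, X)
    assert np.all(radial < 0)
    X = cell16.vertices * 0.999  # shrunk: outward restoring
    F = volume_force(cell16, X, params, KBT)
    assert np.all(np.einsum('ij,ij->i', F, X) > 0)


def test_bending_forces_restore_dihedral(cell16):
    params = CellModelParams(K_l=0, K_b=1e4, K_a=0, K_v=0, VR=1)
    rng = np.random.default_rng(7)
    X = cell16.vertices + 0.01 * rng.normal(size=cell16.vertices.shape)
    F = bending_forces(cell16, X, params, KBT)
    # a small step along the force must reduce the dihedral deviation energy
    dev0 = M._signed_dihedral(X, cell16.hinge_a, cell16.hinge_b,
                              cell16.hinge_c, cell16.hinge_d) - cell16.theta0
    X2 = X + 1e-4 * F / (np.abs(F).max() + 1e-300)
    dev1 = M._signed_dihedral(X2, cell16.hinge_a, cell16.hinge_b,
                              cell16.hinge_c, cell16.hinge_d) - cell16.theta0
    assert (dev1**2).sum() < (dev0**2).sum()


def test_fast_path_matches_reference_implementation(cell16, params, rng):
    """The compiled single-pass force evaluation equals the sum of the four
    reference force functions to rounding precision."""
    from cellsqueeze.membrane import total_forces_fast
    for _ in range(5):
        X = cell16.vertices + 0.02 * rng.normal(size=cell16.vertices.shape)
        ref = total_forces(cell16, X, params, KBT)
        fast = total_forces_fast(cell16, X, params, KBT)
        assert np.abs(fast - ref).max() < 1e-10 * np.abs(ref).max()
    # limit handling identical
    X = cell16.vertices.copy()
    X[0] *= 5.0
    with pytest.raises(MembraneLimitError, match="edge"):
        total_forces_fast(cell16, X, params, KBT)


# ---------------------------------------------------------------------------
# Limiting factors abort with diagnostics
# ---------------------------------------------------------------------------

def test_limit_crossings_abort(cell16, params):
    X = cell16.vertices.copy()
    X[0] = X[0] * 5.0  # extreme local stretch
    with pytest.raises(MembraneLimitError, match="edge"):
        link_forces(cell16, X, params, KBT)
    with pytest.raises(MembraneLimitError, match="area"):
        area_forces(cell16, X, params, KBT)
    with pytest.raises(MembraneLimitError, match="volume"):
        volume_force(cell16, cell16.vertices * 1.01, params, KBT)
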