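import numpy as np
import pytest

from cellsqueeze import coupling, lbm, membrane
from cellsqueeze.coupling import (PESKIN_4PT, TENT_2PT, CouplingError,
                                  interpolate_velocity, spread_forces,
                                  tag_interior_sites, wall_repulsion,
                                  wall_surface_mask)


@pytest.mark.parametrize("kernel", [PESKIN_4PT, TENT_2PT])
def test_kernel_partition_of_unity(kernel, rng):
    """Sum of 1-D weights over the integer grid is 1 for any offset."""
    for _ in range(200):
        x = rng.uniform(-0.5, 0.5)
        offs = np.arange(-3, 4) - x
        w = kernel.weights_1d(offs)
        assert w.min() >= 0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_spread_conserves_total_force_random_offsets(rng):
    field = np.zeros((3, 12, 12, 12))
    X = 4.0 + rng.random((1000, 3)) * 3.0
    F = rng.normal(size=(1000, 3))
    spread_forces(F, X, field)
    total = field.sum(axis=(1, 2, 3))
    assert np.allclose(total, F.sum(axis=0), rtol=1e-12, atol=1e-12)


def test_spread_single_vertex_at_site_center():
    field = np.zeros((3, 9, 9, 9))
    spread_forces(np.array([[1.0, 0.0, 0.0]]),
                  np.array([[4.0, 4.0, 4.0]]), field)
    assert field[0].sum() == pytest.approx(1.0)
    assert field[1].sum() == pytest.approx(0.0)
    # compact support: nothing beyond the 4-point stencil
    assert field[0, :2].sum() == 0 and field[0, 7:].sum() == 0


def test_interpolate_uniform_field_exact(rng):
    u = np.zeros((3, 10, 10, 10))
    u[0], u[1], u[2] = 0.3, -0.1, 0.05
    X = 3.0 + rng.random((50, 3)) * 3.0
    U = interpolate_velocity(u, X)
    assert np.allclose(U, [0.3, -0.1, 0.05], atol=1e-13)


def test_interpolate_zero_field_zero():
    u = np.zeros((3, 8, 8, 8))
    assert np.all(interpolate_velocity(u, np.array([[4.2, 3.7, 4.9]])) == 0)


def test_vertex_outside_domain_rejected():
    field = np.zeros((3, 8, 8, 8))
    with pytest.raises(CouplingError, match="outside"):
        spread_forces(np.ones((1, 3)), np.array([[9.5, 4.0, 4.0]]), field)
    with pytest.raises(CouplingError):
        interpolate_velocity(field, np.array([[-2.0, 4.0, 4.0]]))


def test_repulsion_threshold_and_magnitude():
    """kappa*(d_cut/d): zero at d >= 0.8, 0.008 at d = 0.4 (study constants)."""
    wall = np.zeros((7, 7, 7), dtype=bool)
    wall[3, 3, 3] = True
    d_cut, kappa = 0.8, 0.004
    # beyond the activation distance: exactly zero
    F = wall_repulsion(np.array([[3.0, 3.0, 3.9]]), wall, d_cut, kappa)
    assert np.all(F == 0)
    # at d = 0.4: magnitude 0.004 * (0.8/0.4) = 0.008, direction wall->vertex
    F = wall_repulsion(np.array([[3.0, 3.0, 3.4]]), wall, d_cut, kappa)
    assert np.linalg.norm(F[0]) == pytest.approx(0.008, rel=1e-12)
    assert F[0, 2] > 0 and F[0, 0] == F[0, 1] == 0.0


def test_repulsion_penetration_aborts():
    wall = np.zeros((7, 7, 7), dtype=bool)
    wall[3, 3, 3] = True
    with pytest.raises(CouplingError, match="penetration"):
        wall_repulsion(np.array([[3.0, 3.0, 3.0]]), wall, 0.8, 0.004)


def test_interior_tagging_consistent_with_volume():
    mesh = membrane.make_cell_mesh(16.0)
    mesh = mesh.translated([12.0, 12.0, 12.0])
    inside = tag_interior_sites(mesh, (25, 25, 25))
    assert inside[12, 12, 12]            # centroid
    assert not inside[0, 0, 0]           # far outside
    assert not inside[12, 12, 21]        # just outside the surface
    tagged_volume = inside.sum() * 1.0
    v = membrane.enclosed_volume(mesh.vertices, mesh.faces)
    assert tagged_volume == pytest.approx(v, rel=0.05)


def test_momentum_bookkeeping_membrane_to_fluid(rng):
    """Force leaving the membrane equals force entering the fluid."""
    mesh = membrane.make_cell_mesh(6.0)
    mesh = mesh.translated([8.0, 8.0, 8.0])
    params = membrane.CellModelParams(1e4, 1e4, 1e4, 1e4, 5.0)
    X = mesh.vertices + 0.005 * rng.normal(size=mesh.vertices.shape)
    F = membrane.total_forces(mesh, X, params, 1.0)
    field = np.zeros((3, 17, 17, 17))
    spread_forces(F, X, field)
    # conservation relative to the total force magnitude (the nets are
    # near-zero residues of cancellation)
    assert np.allclose(field.sum(axis=(1, 2, 3)), F.sum(axis=0),
                       atol=1e-12 * np.abs(F).sum())


def test_rigid_reference_cell_advected_with_uniform_flow():
    """Neutrally buoyant cell in uniform flow drifts at fluid velocity.

    The membrane is at its reference state (zero force), so over 1000
    coupled steps the centroid must advance by u*t within 1%.
    """
    shape = (24, 16, 16)
    solid = np.zeros(shape, dtype=bool)
    u0 = 5e-3
    st = lbm.LatticeState.initialize(shape, tau=1.0)
    st.n[:] = lbm.equilibrium(np.ones(shape),
                              np.broadcast_to([u0, 0, 0], shape + (3,)))
    mesh = membrane.make_cell_mesh(6.0).translated([8.0, 7.5, 7.5])
    params = membrane.CellModelParams(1e4, 1e4, 1e4, 1e4, 1.0)
    X = mesh.vertices.copy()
    x0 = X[:, 0].mean()
    for step_i in range(1000):
        F = membrane.total_forces(mesh, X, params, 1e-9)
        st.force[:] = 0.0
        spread_forces(F, X, st.force)
        lbm.step(st, solid, periodic_x=True)
        U = interpolate_velocity(st.u, X)
        X = X + U
        if X[:, 0].max() > shape[0] - 2.5:   # wrap before leaving the box
            X[:, 0] -= shape[0] * 0.5
            x0 -= shape[0] * 0.5
            mesh = membrane.MembraneMesh(
                **{**mesh.__dict__, "vertices": X})
    drift = X[:, 0].mean() - x0
    assert drift == pytest.approx(1000 * u0, rel=0.01)


def test_wall_surface_mask_of_slab():
    solid = np.zeros((5, 5, 5), dtype=bool)
    solid[:, 0, :] = True
    mask = wall_surface_mask(solid)
    assert mask[:, 0, :].all()
    assert not mask[:, 1:, :].any()
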