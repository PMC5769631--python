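import numpy as np
import pytest

from valvemorph.rbc_membrane import (
    MembraneParams, MembraneState, make_ellipse, elastic_energy,
    elastic_forces, repulsion_forces, reparameterize, enclosed_area,
)


@pytest.fixture()
def perturbed_state():
    rng = np.random.default_rng(11)
    params = MembraneParams(k_stretch=1.3, k_bend=0.02)
    state = make_ellipse((0.0, 0.0), params)
    state.positions = state.positions + 0.02 * rng.standard_normal(
        state.positions.shape)
    return state, params


def test_circle_at_rest_radius_is_force_free():
    params = MembraneParams(k_stretch=1.0, k_bend=0.0, semi_axes=(0.3, 0.3))
    circle = make_ellipse((1.0, -0.5), params)
    assert np.abs(elastic_forces(circle, params)).max() == 0.0


def test_forces_carry_no_net_force_or_torque(perturbed_state):
    state, params = perturbed_state
    F = elastic_forces(state, params)
    scale = np.abs(F).max()
    assert np.abs(F.sum(axis=0)).max() < 1e-12 * scale
    r = state.positions
    torque = np.sum(r[:, 0] * F[:, 1] - r[:, 1] * F[:, 0])
    assert abs(torque) < 1e-12 * scale


def test_forces_equal_negative_energy_gradient(perturbed_state):
    state, params = perturbed_state
    F = elastic_forces(state, params)
    eps = 1e-6
    G = np.zeros_like(F)
    for i in range(len(state.positions)):
        for d in range(2):
            sp = state.copy(); sp.positions[i, d] += eps
            sm = state.copy(); sm.positions[i, d] -= eps
            G[i, d] = -(elastic_energy(sp, params)
                        - elastic_energy(sm, params)) / (2 * eps)
    np.testing.assert_allclose(F, G, atol=1e-6 * np.abs(F).max())


def test_relaxation_toward_rest_shape_decreases_energy():
    # quiescent fluid with identity mobility: explicit gradient descent
    rng = np.random.default_rng(3)
    params = MembraneParams(k_stretch=1.0, k_bend=0.002,
                            semi_axes=(0.25, 0.125))
    state = make_ellipse((0.0, 0.0), params)
    state.positions = state.positions + 0.01 * rng.standard_normal(
        state.positions.shape)
    energies = [elastic_energy(state, params)]
    # explicit gradient flow; step below the bending stability limit
    for _ in range(2000):
        state.positions = state.positions + 0.001 * elastic_forces(state, params)
        energies.append(elastic_energy(state, params))
    assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
    assert energies[-1] < 0.1 * energies[0]


def test_repulsion_vanishes_beyond_cutoff_and_balances_momentum():
    params = MembraneParams(repulsion_cutoff=0.05, repulsion_strength=1.0)
    far = [make_ellipse((0.0, 0.0), params), make_ellipse((2.0, 0.0), params)]
    forces = repulsion_forces(far, params)
    assert all(np.all(f == 0) for f in forces)

    a = max(params.semi_axes)
    near = [make_ellipse((0.0, 0.0), params),
            make_ellipse((2 * a + 0.03, 0.0), params)]  # gaps below cutoff
    f = repulsion_forces(near, params)
    total = f[0].sum(axis=0) + f[1].sum(axis=0)
    assert np.abs(total).max() < 1e-12
    assert f[0][:, 0].sum() < 0 < f[1][:, 0].sum()   # pushed apart along x


def test_wall_repulsion_pushes_away_from_walls():
    params = MembraneParams(repulsion_cutoff=0.1, repulsion_strength=1.0)
    cell = make_ellipse((0.0, 0.0), params)

    def gap(points):
        # upper wall just above the top nodes, lower wall far away
        return 0.17 - points[:, 1], points[:, 1] + 10.0

    f = repulsion_forces([cell], params, wall_gap=gap)[0]
    assert f[:, 1].sum() < 0          # net push downward, away from the wall


def test_reparameterize_uniform_spacing_and_exact_area():
    rng = np.random.default_rng(5)
    t = np.sort(rng.uniform(0, 2 * np.pi, 32))
    pts = np.column_stack([0.3 * np.cos(t), 0.2 * np.sin(t)])
    state = MembraneState(pts, np.full(32, 1.0), np.zeros(32))
    area0 = enclosed_area(pts)
    new = reparameterize(state)
    closed = np.vstack([new.positions, new.positions[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    assert (seg.max() - seg.min()) / seg.mean() < 0.01
    assert abs(enclosed_area(new.positions) - area0) < 1e-6 * area0


def test_reparameterize_rejects_self_intersection():
    pts = np.array([[0, 0], [1, 0], [0.2, 0.6], [1.2, 0.6]] * 8, dtype=float)
    pts += np.linspace(0, 0.01, 32)[:, None]  # figure-eight-ish garbage
    state = MembraneState.__new__(MembraneState)
    state.positions = pts
    state.ref_lengths = np.full(32, 1.0)
    state.ref_curvature = np.zeros(32)
    with pytest.raises(ValueError, match="self-intersect"):
        reparameterize(state)


def test_force_field_refines_second_order():
    """Doubling node count changes nodal force density by O(h^2)."""
    def max_force(n):
        params = MembraneParams(k_stretch=1.0, k_bend=0.005, n_nodes=n,
                                semi_axes=(0.3, 0.15))
        state = make_ellipse((0, 0), params)
        F = elastic_forces(state, params)
        ds = 2 * np.pi * 0.225 / n
        return np.abs(F).max() / ds          # force per unit length

    f32, f64, f128 = max_force(32), max_force(64), max_force(128)
    # density differences shrink by ~4x per refinement
    assert abs(f64 - f128) < 0.5 * abs(f32 - f64)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        MembraneParams(k_stretch=-1.0)
    with pytest.raises(ValueError):
        MembraneParams(n_nodes=8)
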