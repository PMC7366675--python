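import numpy as np
import pytest

from beatfield.errors import DegenerateSolveError, ValidationError
from beatfield.fem import (
    FieldDistribution,
    PotentialSolution,
    assemble_system,
    electrode_current,
    element_fields,
    scale_to_injection,
    solve_pair_potential,
    solve_scaled_pair_field,
)
from beatfield.mesh import HeadMesh, TissueLayer, attach_electrodes, build_layered_sphere_mesh


@pytest.fixture(scope="module")
def homog_setup():
    """Homogeneous sphere with two polar electrodes, assembled system."""
    mesh = build_layered_sphere_mesh([TissueLayer("brain", 92.0, 0.33)], 12.0, seed=3)
    aug, elecs = attach_electrodes(
        mesh, np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]), ["A", "B"]
    )
    return aug, elecs, assemble_system(aug)


def single_tet_mesh(verts):
    return HeadMesh(
        nodes=np.asarray(verts, dtype=float),
        tets=np.array([[0, 1, 2, 3]], dtype=np.int32),
        tissue=np.zeros(1, dtype=np.int16),
        sigma=np.ones(1),
        tissue_names=["brain"],
    )


class TestAssembly:
    def test_constants_in_null_space(self, homog_setup):
        _, _, system = homog_setup
        resid = system.matrix @ np.ones(system.matrix.shape[0])
        assert np.max(np.abs(resid)) < 1e-10 * np.max(np.abs(system.matrix.data))

    def test_linear_in_conductivity(self, homog_setup):
        aug, _, system = homog_setup
        double = aug.copy()
        double.sigma = 2.0 * double.sigma
        K2 = assemble_system(double).matrix
        diff = (K2 - 2.0 * system.matrix).tocoo()
        worst = np.max(np.abs(diff.data)) if diff.nnz else 0.0
        assert worst < 1e-12 * np.max(np.abs(system.matrix.data))

    def test_single_tet_matches_independent_derivation(self):
        # independent route: fit each P1 basis function by least squares,
        # read its gradient, integrate sigma*grad.grad over the volume
        rng = np.random.default_rng(11)
        verts = rng.normal(size=(4, 3)) * 10.0  # mm
        mesh = single_tet_mesh(verts)
        K = assemble_system(mesh).matrix.toarray()

        V_m = verts * 1e-3
        A = np.hstack([np.ones((4, 1)), V_m])
        grads = np.zeros((4, 3))
        for i in range(4):
            coef, *_ = np.linalg.lstsq(A, np.eye(4)[i], rcond=None)
            grads[i] = coef[1:]
        vol = abs(np.linalg.det(V_m[1:] - V_m[0])) / 6.0
        K_ref = vol * grads @ grads.T
        assert np.allclose(K, K_ref, rtol=1e-9, atol=1e-12 * np.abs(K_ref).max())

    def test_nonpositive_conductivity_rejected(self, homog_setup):
        aug, _, _ = homog_setup
        bad = aug.copy()
        bad.sigma = bad.sigma.copy()
        bad.sigma[0] = -1.0
        with pytest.raises(ValidationError, match="positive"):
            assemble_system(bad)


class TestSolve:
    def test_dirichlet_values_exact_and_maximum_principle(self, homog_setup):
        aug, elecs, system = homog_setup
        pot = solve_pair_potential(system, elecs[0], elecs[1])
        v = pot.potentials
        assert np.all(v[elecs[0].top_nodes] == 1.0)
        assert np.all(v[elecs[1].top_nodes] == -1.0)
        assert v.max() <= 1.0 + 1e-12 and v.min() >= -1.0 - 1e-12

    def test_swapping_electrodes_negates_solution(self, homog_setup):
        aug, elecs, system = homog_setup
        a = solve_pair_potential(system, elecs[0], elecs[1]).potentials
        b = solve_pair_potential(system, elecs[1], elecs[0]).potentials
        assert np.allclose(a, -b, atol=1e-9)

    def test_overlapping_electrode_nodes_rejected(self, homog_setup):
        aug, elecs, system = homog_setup
        with pytest.raises(ValidationError, match="share top nodes"):
            solve_pair_potential(system, elecs[0], elecs[0])


class TestFields:
    def test_linear_potential_gives_exact_constant_field(self, homog_setup):
        aug, _, _ = homog_setup
        pot = PotentialSolution(
            potentials=aug.nodes[:, 0] * 1e-3, active="x", reference="-", residual=0.0, method="manual"
        )
        f = element_fields(aug, pot)
        assert np.allclose(f.element_values, [-1.0, 0.0, 0.0], atol=1e-9)
        assert np.allclose(f.node_values, [-1.0, 0.0, 0.0], atol=1e-9)

    def test_constant_potential_gives_zero_field_and_current(self, homog_setup):
        aug, elecs, system = homog_setup
        pot = PotentialSolution(
            potentials=np.ones(aug.n_nodes), active="c", reference="-", residual=0.0, method="manual"
        )
        f = element_fields(aug, pot)
        assert np.max(np.abs(f.element_values)) < 1e-9  # rounding of ~100 1/m gradients
        assert abs(electrode_current(aug, pot, elecs[0], system=system)) < 1e-9

    def test_element_field_matches_edge_differences(self, homog_setup):
        aug, elecs, system = homog_setup
        pot = solve_pair_potential(system, elecs[0], elecs[1])
        f = element_fields(aug, pot, system)
        tets = aug.tets[::50]
        E = f.element_values[::50]
        p = aug.nodes[tets] * 1e-3
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            lhs = np.einsum("ek,ek->e", E, p[:, j] - p[:, i])
            rhs = -(pot.potentials[tets[:, j]] - pot.potentials[tets[:, i]])
            assert np.allclose(lhs, rhs, atol=1e-10)


class TestCurrentAndScaling:
    def test_charge_conservation_between_electrodes(self, homog_setup):
        aug, elecs, system = homog_setup
        pot = solve_pair_potential(system, elecs[0], elecs[1])
        ia = electrode_current(aug, pot, elecs[0], system=system)
        ib = electrode_current(aug, pot, elecs[1], system=system)
        assert ia > 0  # +1 V side pushes current into the head
        assert abs(ia + ib) < 0.01 * abs(ia)

    def test_scaling_examples(self):
        f = FieldDistribution(
            node_values=np.ones((3, 3)), element_values=np.ones((2, 3)), pair=("a", "b"), current_mA=2.0
        )
        half = scale_to_injection(f, computed_current_mA=2.0, target_current_mA=1.0)
        assert np.allclose(half.node_values, 0.5)
        same = scale_to_injection(f, computed_current_mA=1.0, target_current_mA=1.0)
        assert np.allclose(same.node_values, 1.0)

    def test_degenerate_current_rejected(self):
        f = FieldDistribution(np.ones((3, 3)), np.ones((2, 3)), ("a", "b"), 0.0)
        with pytest.raises(DegenerateSolveError):
            scale_to_injection(f, computed_current_mA=1e-12)

    def test_rescaled_solution_carries_unit_current(self, homog_setup):
        aug, elecs, system = homog_setup
        field, pot_scaled, raw = solve_scaled_pair_field(system, elecs[0], elecs[1])
        assert field.current_mA == 1.0
        i = electrode_current(aug, pot_scaled, elecs[0], system=system)
        assert abs(i - 1.0) < 1e-8

    def test_field_scales_linearly_with_current(self, homog_setup):
        aug, elecs, system = homog_setup
        f1, _, _ = solve_scaled_pair_field(system, elecs[0], elecs[1], target_current_mA=1.0)
        f2, _, _ = solve_scaled_pair_field(system, elecs[0], elecs[1], target_current_mA=2.0)
        assert np.allclose(f2.node_values, 2.0 * f1.node_values, rtol=1e-12)
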