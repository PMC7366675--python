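import numpy as np
import pytest

from beatfield.errors import PlacementError, ResolutionError, ValidationError
from beatfield.mesh import (
    DEFAULT_LAYERS,
    TissueLayer,
    build_layered_sphere_mesh,
    candidate_directions,
    define_rois,
    homogenize_conductivity,
    place_electrodes,
    validate_mesh,
)


def shell_volume(outer, inner):
    return 4.0 / 3.0 * np.pi * (outer**3 - inner**3)


class TestGenerator:
    def test_deterministic_for_fixed_seed(self):
        a = build_layered_sphere_mesh(target_edge_length=9.5, seed=5)
        b = build_layered_sphere_mesh(target_edge_length=9.5, seed=5)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.tets, b.tets)
        assert np.array_equal(a.tissue, b.tissue)

    def test_all_labels_present_and_centroids_contained(self, five_layer_mesh):
        m = five_layer_mesh
        radii = [la.outer_radius for la in DEFAULT_LAYERS] + [0.0]
        rc = np.linalg.norm(m.element_centroids(), axis=1)
        for code, name in enumerate(m.tissue_names):
            sel = m.tissue == code
            assert sel.any(), f"no elements labelled {name}"
            assert np.all(rc[sel] <= radii[code] + 1e-9)
            assert np.all(rc[sel] >= radii[code + 1] - 1e-9)

    def test_total_volume_within_2_percent(self, five_layer_mesh):
        total = five_layer_mesh.element_volumes().sum()
        analytic = shell_volume(DEFAULT_LAYERS[0].outer_radius, 0.0)
        assert abs(total - analytic) / analytic < 0.02

    def test_shell_volumes_within_5_percent(self, five_layer_mesh):
        m = five_layer_mesh
        vols = m.element_volumes()
        radii = [la.outer_radius for la in DEFAULT_LAYERS] + [0.0]
        for code, la in enumerate(DEFAULT_LAYERS):
            got = vols[m.tissue == code].sum()
            want = shell_volume(radii[code], radii[code + 1])
            assert abs(got - want) / want < 0.05, la.name

    def test_refinement_reduces_volume_gap_monotonically(self):
        analytic = shell_volume(92.0, 0.0)
        gaps = []
        for h in (20.0, 14.0, 10.0):
            m = build_layered_sphere_mesh([TissueLayer("brain", 92.0, 0.33)], h, seed=1)
            gaps.append(abs(m.element_volumes().sum() - analytic) / analytic)
        assert gaps[0] > gaps[1] > gaps[2]

    def test_single_layer_is_homogeneous(self):
        m = build_layered_sphere_mesh([TissueLayer("brain", 92.0, 0.33)], 16.0, seed=2)
        assert np.unique(m.sigma).tolist() == [0.33]

    def test_non_nested_radii_rejected(self):
        bad = [TissueLayer("a", 80.0, 1.0), TissueLayer("b", 85.0, 1.0)]
        with pytest.raises(ValidationError, match="strictly decreasing"):
            build_layered_sphere_mesh(bad, 10.0, seed=0)

    def test_too_coarse_for_thinnest_layer_names_it(self):
        with pytest.raises(ResolutionError, match="csf"):
            build_layered_sphere_mesh(DEFAULT_LAYERS, 16.0, seed=0)


class TestValidation:
    def test_generator_output_is_clean(self, five_layer_mesh):
        report = validate_mesh(five_layer_mesh)
        assert report.passed
        assert report.n_isolated_nodes == 0
        assert report.n_degenerate_elements == 0

    def test_appended_unreferenced_node_is_isolated(self, five_layer_mesh):
        m = five_layer_mesh.copy()
        m.nodes = np.vstack([m.nodes, [[0.0, 0.0, 0.123]]])
        assert validate_mesh(m).n_isolated_nodes == 1

    def test_repeated_vertex_makes_degenerate_element(self, five_layer_mesh):
        m = five_layer_mesh.copy()
        t = m.tets[0].copy()
        t[1] = t[0]
        m.tets = np.vstack([m.tets, t[None, :]])
        m.tissue = np.append(m.tissue, m.tissue[0])
        m.sigma = np.append(m.sigma, m.sigma[0])
        assert validate_mesh(m).n_degenerate_elements == 1

    def test_out_of_range_index_detected(self, five_layer_mesh):
        m = five_layer_mesh.copy()
        m.tets = m.tets.copy()
        m.tets[0, 0] = m.n_nodes + 10
        assert validate_mesh(m).n_out_of_range_indices == 1


class TestElectrodes:
    def test_sixty_one_candidates_plus_reference(self):
        # finer surface sampling so 61 footprints fit the 10-10-like layout
        mesh = build_layered_sphere_mesh(target_edge_length=6.0, seed=0)
        aug, eset = place_electrodes(mesh, 61)
        assert len(eset.candidates) == 61
        assert eset.reference.id == "REF"
        all_nodes = [set(e.top_nodes.tolist()) for e in eset.candidates + [eset.reference]]
        bottoms = [set(np.unique(e.bottom_faces).tolist()) for e in eset.candidates + [eset.reference]]
        for i in range(len(bottoms)):
            for j in range(i + 1, len(bottoms)):
                assert not (bottoms[i] & bottoms[j]), "scalp footprints must be disjoint"
                assert not (all_nodes[i] & all_nodes[j])

    def test_minimal_four_candidate_set(self, five_layer_mesh):
        aug, eset = place_electrodes(five_layer_mesh, 4)
        assert len(eset.candidates) == 4

    def test_bottom_faces_lie_on_scalp_surface(self, head_setup):
        aug, eset, _ = head_setup
        scalp_r = DEFAULT_LAYERS[0].outer_radius
        for e in eset.candidates + [eset.reference]:
            r = np.linalg.norm(aug.nodes[np.unique(e.bottom_faces)], axis=1)
            assert np.allclose(r, scalp_r, atol=1e-9)
            assert e.top_nodes.size > 0 and e.bottom_faces.size > 0

    def test_overlapping_footprints_rejected(self, five_layer_mesh):
        with pytest.raises(PlacementError, match="collides"):
            place_electrodes(five_layer_mesh, 61, diameter=40.0)

    def test_augmented_mesh_still_validates(self, head_setup):
        aug, _, _ = head_setup
        assert validate_mesh(aug).passed

    def test_candidate_directions_on_upper_cap(self):
        d = candidate_directions(61)
        assert d.shape == (61, 3)
        assert np.all(d[:, 2] >= -1e-12)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)


class TestRois:
    def test_target_and_cortex_nonempty_disjoint(self, head_setup):
        aug, _, roi = head_setup
        assert roi.target_nodes.size > 0
        assert roi.cortex_nodes.size > 0
        assert np.intersect1d(roi.target_nodes, roi.cortex_nodes).size == 0

    def test_zero_radius_target_is_an_error(self, head_setup):
        aug, _, _ = head_setup
        with pytest.raises(ValidationError, match="finer mesh or a larger"):
            define_rois(aug, (0.0, 0.0, 37.0), 0.0)

    def test_alternative_target_location_changes_only_target(self, head_setup):
        aug, _, roi = head_setup
        roi2 = define_rois(aug, (15.0, 10.0, 30.0), 6.0)
        assert set(roi2.target_nodes) != set(roi.target_nodes)
        # cortical membership rule unchanged: gray compartment minus the target
        gray = aug.tissue_nodes("gray")
        assert np.array_equal(roi2.cortex_nodes, np.setdiff1d(gray, roi2.target_nodes))


def test_homogenize_keeps_labels_and_electrode_sigma(head_setup):
    aug, _, _ = head_setup
    hom = homogenize_conductivity(aug, 0.3)
    assert hom.tissue_names == aug.tissue_names
    code = hom.tissue_code("electrode")
    assert np.all(hom.sigma[hom.tissue != code] == 0.3)
    assert np.all(hom.sigma[hom.tissue == code] == 1.0)
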