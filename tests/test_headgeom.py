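import numpy as np
import pytest
import trimesh

from _oracles import sphere_cpc
from tmstarget import headgeom as hg
from tmstarget.headgeom import CPCCoordinate, GeometryError


class TestCPCMapping:
    def test_fiducial_anchors(self, head):
        """CPC origin/endpoints of the sagittal axis land on NZ and IZ."""
        nz = hg.cpc_to_scalp(head, CPCCoordinate(0.0, 0.5)).position
        iz = hg.cpc_to_scalp(head, CPCCoordinate(1.0, 0.5)).position
        assert np.linalg.norm(nz - head.fiducials["NZ"]) < 0.3
        assert np.linalg.norm(iz - head.fiducials["IZ"]) < 0.3

    def test_vertex_by_symmetry(self, head):
        top = hg.cpc_to_scalp(head, CPCCoordinate(0.5, 0.5)).position
        assert np.linalg.norm(top - np.array([0.0, 0.0, 92.0])) < 0.3

    @pytest.mark.parametrize("p_nz,p_al", [
        (0.25, 0.5), (0.25, 0.25), (0.7, 0.33), (0.15, 0.27),
        (0.43, 0.43), (0.9, 0.9), (0.05, 0.1), (0.5, 0.73),
    ])
    def test_matches_closed_form_on_sphere(self, head, p_nz, p_al):
        """Plane-slice geodesics agree with the closed-form construction
        within 0.5 mm on a subdivision-4 icosphere."""
        site = hg.cpc_to_scalp(head, CPCCoordinate(p_nz, p_al))
        assert np.linalg.norm(site.position - sphere_cpc(p_nz, p_al)) < 0.5
        assert abs(np.linalg.norm(site.normal) - 1.0) < 1e-9
        # outward normal of a sphere is radial
        radial = site.position / np.linalg.norm(site.position)
        assert np.dot(site.normal, radial) > 0.99

    def test_round_trip_recovers_cpc(self, head):
        """Dense nearest-CPC inversion recovers the coordinate within step/2."""
        step = 0.01
        for target in (CPCCoordinate(0.3, 0.35), CPCCoordinate(0.22, 0.4)):
            pos = hg.cpc_to_scalp(head, target).position
            grid = [(p, a)
                    for p in np.arange(target.p_nz - 0.02, target.p_nz + 0.021, step / 4)
                    for a in np.arange(target.p_al - 0.02, target.p_al + 0.021, step / 4)]
            best = min(grid, key=lambda c: np.linalg.norm(
                hg.cpc_to_scalp(head, CPCCoordinate(*c)).position - pos))
            assert abs(best[0] - target.p_nz) <= step / 2
            assert abs(best[1] - target.p_al) <= step / 2

    def test_out_of_range_cpc_rejected(self):
        with pytest.raises(ValueError):
            CPCCoordinate(1.2, 0.5)


class TestSearchSpace:
    def test_printed_ranges_give_29x17_grids(self):
        for nz, al in [((0.15, 0.43), (0.27, 0.43)), ((0.52, 0.80), (0.10, 0.26))]:
            space = hg.build_search_space(nz, al, 0.01)
            assert space.shape == (29, 17)
            assert space.n_nodes == 493
            assert space.included.all()

    def test_degenerate_single_node(self):
        space = hg.build_search_space((0.3, 0.3), (0.4, 0.4), 0.01)
        assert space.n_nodes == 1

    def test_grid_values_match_index_arithmetic(self):
        space = hg.build_search_space((0.15, 0.43), (0.27, 0.43), 0.01)
        for i, j, cpc, _ in space.nodes():
            assert cpc.p_nz == pytest.approx(0.15 + 0.01 * i, abs=1e-9)
            assert cpc.p_al == pytest.approx(0.27 + 0.01 * j, abs=1e-9)

    def test_empty_range_rejected(self):
        with pytest.raises(GeometryError):
            hg.build_search_space((0.4, 0.3), (0.2, 0.3), 0.01)


@pytest.fixture(scope="module")
def tiny_space():
    return hg.build_search_space((0.2, 0.3), (0.3, 0.4), 0.05)


class TestMasking:
    def test_infinite_radius_keeps_all(self, head, tiny_space):
        masked = hg.mask_search_space(tiny_space, head, np.zeros((1, 3)), 1e9)
        assert masked.included.all()

    def test_own_projection_is_retained(self, head, tiny_space):
        site = hg.cpc_to_scalp(head, tiny_space.cpc(1, 1))
        center = hg.to_mni(head, hg.scalp_to_cortex(head, site))
        masked = hg.mask_search_space(tiny_space, head, center[None, :], 1.0)
        assert masked.included[1, 1]

    def test_matches_distance_oracle_and_is_idempotent(self, head, tiny_space, rng):
        site = hg.cpc_to_scalp(head, tiny_space.cpc(0, 0))
        anchor = hg.to_mni(head, hg.scalp_to_cortex(head, site))
        centers = np.vstack([anchor + rng.normal(scale=10.0, size=3),
                             rng.normal(scale=50.0, size=(2, 3))])
        masked = hg.mask_search_space(tiny_space, head, centers, 40.0)
        expected = np.zeros(tiny_space.shape, dtype=bool)
        for i, j, cpc, _ in tiny_space.nodes():
            site = hg.cpc_to_scalp(head, cpc)
            mni = hg.to_mni(head, hg.scalp_to_cortex(head, site))
            expected[i, j] = np.min(np.linalg.norm(centers - mni, axis=1)) <= 40.0
        assert (masked.included == expected).all()
        again = hg.mask_search_space(masked, head, centers, 40.0)
        assert (again.included == masked.included).all()
        shuffled = hg.mask_search_space(tiny_space, head, centers[::-1], 40.0)
        assert (shuffled.included == masked.included).all()

    def test_all_excluded_raises(self, head, tiny_space):
        with pytest.raises(GeometryError):
            hg.mask_search_space(tiny_space, head, np.array([[500.0, 0, 0]]), 1.0)


class TestCortexProjection:
    def test_concentric_depth_and_radiality(self, head):
        site = hg.cpc_to_scalp(head, CPCCoordinate(0.3, 0.4))
        cortex, fallback = hg.project_to_cortex(head, site)
        assert not fallback
        depth = np.linalg.norm(site.position - cortex)
        assert depth == pytest.approx(14.0, abs=0.2)
        angle = np.arccos(np.clip(
            np.dot(cortex / np.linalg.norm(cortex),
                   site.position / np.linalg.norm(site.position)), -1, 1))
        assert angle < 1e-3  # radial on concentric spheres (mesh-limited)

    def test_translated_cortex_matches_ray_sphere_quadratic(self, head):
        shift = np.array([5.0, 0.0, 0.0])
        moved = hg.HeadModel(
            scalp=head.scalp,
            cortex=trimesh.Trimesh(head.cortex.vertices + shift,
                                   head.cortex.faces, process=False),
            fiducials=head.fiducials, mni_affine=head.mni_affine)
        site = hg.cpc_to_scalp(moved, CPCCoordinate(0.35, 0.45))
        cortex, fallback = hg.project_to_cortex(moved, site)
        assert not fallback
        # closed-form first intersection of the inward ray with |x - shift| = 78
        o, d = site.position - shift, -site.normal
        b = o @ d
        t = -b - np.sqrt(b**2 - (o @ o - 78.0**2))
        expected = site.position + t * (-site.normal)
        assert np.linalg.norm(cortex - expected) < 0.2

    def test_missed_ray_uses_flagged_nearest_vertex(self, head):
        # cortical cap on the far side only: rays from the top miss it
        verts = head.cortex.vertices
        keep = verts[:, 2] < -40.0
        idx = np.flatnonzero(keep)
        remap = -np.ones(len(verts), dtype=int)
        remap[idx] = np.arange(len(idx))
        faces = head.cortex.faces
        faces = faces[keep[faces].all(axis=1)]
        cap = trimesh.Trimesh(verts[idx], remap[faces], process=False)
        capped = hg.HeadModel(scalp=head.scalp, cortex=cap,
                              fiducials=head.fiducials, mni_affine=head.mni_affine)
        site = hg.cpc_to_scalp(capped, CPCCoordinate(0.5, 0.5))  # vertex
        cortex, fallback = hg.project_to_cortex(capped, site)
        assert fallback
        assert cortex in cap.vertices


class TestMNITransform:
    def test_identity_and_translation(self, head):
        p = np.array([1.0, -2.0, 3.0])
        assert np.allclose(hg.to_mni(head, p), p)
        shifted = hg.HeadModel(scalp=head.scalp, cortex=head.cortex,
                               fiducials=head.fiducials,
                               mni_affine=np.array([[1, 0, 0, 10],
                                                    [0, 1, 0, 0],
                                                    [0, 0, 1, 0],
                                                    [0, 0, 0, 1.0]]))
        assert np.allclose(hg.to_mni(shifted, p), p + [10, 0, 0])

    def test_random_affine_matches_matrix_vector_oracle(self, head, rng):
        A = np.eye(4)
        A[:3] = rng.normal(size=(3, 4))
        model = hg.HeadModel(scalp=head.scalp, cortex=head.cortex,
                             fiducials=head.fiducials, mni_affine=A)
        p = rng.normal(size=3)
        expected = (A @ np.append(p, 1.0))[:3]
        assert np.allclose(hg.to_mni(model, p), expected, atol=1e-9)


class TestAdjacentSpacing:
    def test_default_grid_spacing_near_2_8_mm(self, head, mdd_space):
        spacing = hg.mean_adjacent_spacing(head, mdd_space)
        assert 2.0 <= spacing <= 3.6

    def test_spacing_scales_with_step(self, head):
        fine = hg.build_search_space((0.2, 0.3), (0.3, 0.4), 0.02)
        coarse = hg.build_search_space((0.2, 0.3), (0.3, 0.4), 0.04)
        ratio = hg.mean_adjacent_spacing(head, coarse) / hg.mean_adjacent_spacing(head, fine)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_single_pair_equals_pair_distance(self, head):
        space = hg.build_search_space((0.3, 0.31), (0.4, 0.4), 0.01)
        a = hg.cpc_to_scalp(head, space.cpc(0, 0)).position
        b = hg.cpc_to_scalp(head, space.cpc(1, 0)).position
        assert hg.mean_adjacent_spacing(head, space) == pytest.approx(
            np.linalg.norm(a - b), abs=1e-9)


def test_head_model_io_round_trip(tmp_path, head):
    hg.save_head_model(head, tmp_path)
    loaded = hg.load_head_model(tmp_path)
    assert np.allclose(loaded.scalp.vertices, head.scalp.vertices, atol=1e-4)
    assert np.allclose(loaded.mni_affine, head.mni_affine)
    loaded.validate()
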