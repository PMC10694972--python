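import numpy as np
import pytest
from scipy.spatial import Delaunay

from ecgikit.errors import GeometryError, InvalidParameterError
from ecgikit.geometry import (
    ElectrodeSet,
    PairedSites,
    SurfaceMesh,
    _star_triangulate,
    closest_point_on_mesh,
    exclude_valve_plane,
    match_paired_sites,
    node_neighbours,
    reconstruct_virtual_vest,
    resample_and_smooth,
    rigid_icp_align,
)
from ecgikit.synthgen import generate_heart_mesh, generate_torso_and_vest


def _tetrahedron():
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    t = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return SurfaceMesh(v, t)


class TestSurfaceMesh:
    def test_euler_characteristic_closed_surface(self, heart_small):
        assert heart_small.euler_characteristic() == 2

    def test_watertight(self, heart_small):
        assert heart_small.is_watertight()

    def test_tetrahedron_areas(self):
        m = _tetrahedron()
        # each face is an equilateral triangle of side 2*sqrt(2)
        side = 2.0 * np.sqrt(2.0)
        area = np.sqrt(3.0) / 4.0 * side**2
        assert np.allclose(m.triangle_areas, area)
        # vertex areas: each vertex touches 3 of the 4 faces, lumped 1/3 each
        assert np.allclose(m.vertex_area, area)
        assert np.isclose(m.vertex_area.sum(), 4 * area)

    def test_enclosed_volume_tetrahedron(self):
        # regular tetrahedron with side 2*sqrt(2): V = side^3 / (6*sqrt(2)) = 8/3
        assert np.isclose(abs(_tetrahedron().enclosed_volume()), 8.0 / 3.0)

    def test_rejects_bad_triangle_index(self):
        with pytest.raises(GeometryError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))


class TestClosestPoint:
    def test_closest_point_at_most_vertex_distance(self, sphere_mesh):
        rng = np.random.default_rng(1)
        pts = rng.normal(scale=60.0, size=(100, 3))
        _, d, _ = closest_point_on_mesh(pts, sphere_mesh)
        vd = np.linalg.norm(
            pts[:, None] - sphere_mesh.vertices[None], axis=2
        ).min(axis=1)
        assert np.all(d <= vd + 1e-9)

    def test_on_surface_points_have_zero_distance(self, sphere_mesh):
        # triangle centroids lie exactly on the surface
        tri = sphere_mesh.vertices[sphere_mesh.triangles[:25]]
        centroids = tri.mean(axis=1)
        cp, d, _ = closest_point_on_mesh(centroids, sphere_mesh)
        assert np.allclose(d, 0.0, atol=1e-9)
        assert np.allclose(cp, centroids, atol=1e-9)

    def test_matches_dense_sampling_oracle(self, sphere_mesh):
        rng = np.random.default_rng(2)
        pts = rng.normal(scale=60.0, size=(3, 3))
        _, d, _ = closest_point_on_mesh(pts, sphere_mesh)
        u = np.linspace(0, 1, 60)
        uu, vv = np.meshgrid(u, u)
        keep = (uu + vv) <= 1
        for p, dist in zip(pts, d):
            best = np.inf
            for t in sphere_mesh.triangles:
                a, b, c = sphere_mesh.vertices[t]
                q = a + uu[keep][:, None] * (b - a) + vv[keep][:, None] * (c - a)
                best = min(best, np.linalg.norm(q - p, axis=1).min())
            assert dist <= best + 1e-9
            assert abs(dist - best) < 0.5  # dense sampling is itself approximate

    def test_single_point_input(self, sphere_mesh):
        cp, d, tid = closest_point_on_mesh(np.array([0.0, 0.0, 100.0]), sphere_mesh)
        assert cp.shape == (1, 3)
        assert np.isclose(d[0], 60.0, atol=1.0)  # 100 - radius 40, coarse mesh


class TestElectrodeSet:
    def test_four_corners_per_panel_enforced(self):
        pos = np.zeros((4, 3)) + np.arange(4)[:, None]
        gid = [("anterior", r, 0) for r in range(4)]
        with pytest.raises(GeometryError):
            ElectrodeSet(pos, gid, 25.0, np.array([True, True, True, False]))

    def test_duplicate_grid_ids_rejected(self):
        pos = np.zeros((4, 3)) + np.arange(4)[:, None]
        gid = [("anterior", 0, 0)] * 4
        with pytest.raises(GeometryError):
            ElectrodeSet(pos, gid, 25.0, np.ones(4, bool))

    def test_corner_positions_ordered_row_major(self):
        pos = np.arange(12.0).reshape(4, 3)
        gid = [("a", 0, 0), ("a", 0, 3), ("a", 2, 0), ("a", 2, 3)]
        es = ElectrodeSet(pos, gid, 25.0, np.ones(4, bool))
        assert np.array_equal(es.corner_positions("a"), pos)


class TestPairingAndValve:
    def test_match_paired_sites_identity(self, heart_small):
        pairs = match_paired_sites(heart_small, heart_small)
        assert np.array_equal(pairs.pairs[:, 0], pairs.pairs[:, 1])
        assert np.allclose(pairs.pair_distance, 0.0)

    def test_match_excludes_valve_nodes(self, heart_small):
        valve = heart_small.labels["valve_plane"]
        pairs = match_paired_sites(heart_small, heart_small)
        assert not np.isin(pairs.pairs, valve).any()
        assert pairs.n_pairs == heart_small.n_vertices - len(valve)

    def test_exclude_valve_plane_flags_reason(self, heart_small, processed):
        m = exclude_valve_plane(processed["markers"], heart_small)
        valve = heart_small.labels["valve_plane"]
        assert m.excluded[valve].all()
        # untouched values at retained nodes
        keep = ~np.isin(np.arange(m.n_nodes), valve)
        assert np.array_equal(m.at[keep], processed["markers"].at[keep])

    def test_exclude_requires_label(self, processed):
        bare = _tetrahedron()
        with pytest.raises(GeometryError):
            exclude_valve_plane(processed["markers"], bare)

    def test_paired_sites_rejects_negative_distance(self):
        with pytest.raises(GeometryError):
            PairedSites(pairs=np.array([[0, 0]]), pair_distance=np.array([-1.0]))


class TestNodeNeighbours:
    def test_adjacency_is_symmetric_with_edge_lengths(self, heart_small):
        adj = node_neighbours(heart_small)
        assert (adj != adj.T).nnz == 0
        coo = adj.tocoo()
        d = np.linalg.norm(
            heart_small.vertices[coo.row] - heart_small.vertices[coo.col], axis=1
        )
        assert np.allclose(coo.data, d)


class TestVirtualVest:
    def test_exact_on_planar_panel(self):
        verts = np.array(
            [[x, y, 0.0] for x in np.linspace(-300, 300, 7)
             for y in np.linspace(-300, 300, 7)]
        )
        flat = SurfaceMesh(verts, Delaunay(verts[:, :2]).simplices)
        corners = {
            "anterior": np.array(
                [[0, 0, 0], [150, 0, 0], [0, 87.5, 0], [150, 87.5, 0]], float
            )
        }
        vv = reconstruct_virtual_vest(corners, flat, (8, 13), spacing=12.5)
        for (panel, r, c), pos in zip(vv.grid_id, vv.positions):
            expected = np.array([150.0 * c / 12, 87.5 * r / 7, 0.0])
            assert np.allclose(pos, expected, atol=1e-9)

    def test_rms_error_below_half_spacing_on_cylinder(self, heart_small):
        torso, el = generate_torso_and_vest(
            heart=heart_small, anterior_drop=(), posterior_extra=0, n_electrodes=256
        )
        corners = {p: el.corner_positions(p) for p in el.panels}
        vv = reconstruct_virtual_vest(corners, torso, (8, 16), spacing=25.0)
        pos = {g: p for g, p in zip(vv.grid_id, vv.positions)}
        err = np.array(
            [np.linalg.norm(pos[g] - p) for g, p in zip(el.grid_id, el.positions)]
        )
        assert np.sqrt((err**2).mean()) < 12.5

    def test_duplicate_corner_rejected(self, heart_small):
        torso, _ = generate_torso_and_vest(heart=heart_small)
        c = np.zeros((4, 3))
        with pytest.raises(GeometryError):
            reconstruct_virtual_vest({"anterior": c}, torso, (8, 16), 25.0)

    def test_far_corner_rejected(self, heart_small):
        torso, el = generate_torso_and_vest(heart=heart_small)
        c = el.corner_positions("anterior").copy()
        c[0] += 500.0
        with pytest.raises(GeometryError):
            reconstruct_virtual_vest({"anterior": c}, torso, (8, 16), 25.0)


class TestResampleAndIcp:
    def test_downsample_to_target(self, heart_small):
        out = resample_and_smooth(heart_small, target_nodes=120)
        assert out.n_vertices == 120
        assert out.is_watertight()

    def test_upsample_to_target(self, heart_small):
        out = resample_and_smooth(heart_small, target_nodes=260)
        assert out.n_vertices == 260
        assert out.is_watertight()

    def test_icp_recovers_small_rigid_motion(self, sphere_mesh):
        ang = 0.05
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0],
             [np.sin(ang), np.cos(ang), 0],
             [0, 0, 1]]
        )
        moved = SurfaceMesh(
            sphere_mesh.vertices @ rot.T + np.array([2.0, -1.0, 0.5]),
            sphere_mesh.triangles.copy(),
        )
        aligned = rigid_icp_align(moved, sphere_mesh, iterations=30)
        # a sphere is rotation-symmetric, so judge residual surface distance
        # rather than per-vertex identity
        _, before, _ = closest_point_on_mesh(moved.vertices, sphere_mesh)
        _, after, _ = closest_point_on_mesh(aligned.vertices, sphere_mesh)
        assert after.mean() < 0.2 * before.mean()


def test_star_triangulation_watertight_random_blob():
    rng = np.random.default_rng(7)
    d = rng.normal(size=(150, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    pts = d * (30.0 + 3.0 * rng.random(150))[:, None]
    m = SurfaceMesh(pts, _star_triangulate(pts))
    assert m.euler_characteristic() == 2
    assert m.is_watertight()


def test_resample_requires_valid_target(heart_small):
    with pytest.raises(InvalidParameterError):
        resample_and_smooth(heart_small, target_nodes=10)
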