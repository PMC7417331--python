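"""Mesh construction, point location and dihedral-angle geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amlfp.mesh import (
    BoundingBox,
    MeshError,
    OutsideMeshError,
    TetMesh,
    build_hex_mesh,
    dihedral_angle,
    generate_tet_mesh,
    kuhn_tetrahedralize,
    locate_hex_voxel,
    locate_tet,
    mesh_stats,
    nearest_node,
    opposite_edge,
    read_mesh,
    scaled_bounding_box,
    write_mesh,
)


class TestScaledBoundingBox:
    def test_identity_scale(self):
        box = scaled_bounding_box([(0, 0, 0), (1, 1, 1)], 1.0)
        assert np.allclose(box.min_corner, [0, 0, 0])
        assert np.allclose(box.max_corner, [1, 1, 1])

    def test_expansion_preserves_centroid(self):
        box = scaled_bounding_box([(0, 0, 0), (1, 1, 1)], 1.42)
        assert np.allclose(box.min_corner, [-0.21] * 3)
        assert np.allclose(box.max_corner, [1.21] * 3)
        assert np.allclose(box.center, [0.5] * 3)

    def test_degenerate_axes_named(self):
        with pytest.raises(MeshError, match="y, z"):
            scaled_bounding_box([(0, 0, 0), (2, 0, 0)])

    def test_too_few_points(self):
        with pytest.raises(MeshError):
            scaled_bounding_box([(0, 0, 0)])

    def test_shrinking_rejected(self):
        with pytest.raises(MeshError):
            scaled_bounding_box([(0, 0, 0), (1, 1, 1)], 0.9)


class TestBuildHexMesh:
    @pytest.mark.parametrize(
        "sides, L, dims",
        [
            ((100, 100, 100), 50.0, (3, 3, 3)),
            ((100, 50, 50), 50.0, (3, 2, 2)),
        ],
    )
    def test_node_counts(self, sides, L, dims):
        box = BoundingBox([0, 0, 0], list(sides))
        mesh = build_hex_mesh(box, L)
        assert mesh.dims == dims
        assert mesh.n_nodes == np.prod(dims)
        assert mesh.n_elements == np.prod(np.array(dims) - 1)

    def test_lattice_extends_outward(self):
        box = BoundingBox([0, 0, 0], [100, 100, 100])
        mesh = build_hex_mesh(box, 40.0)
        assert all(d >= 4 for d in mesh.dims)  # ceil(100/40)+1
        assert np.all(mesh.origin <= box.min_corner + 1e-9)
        assert np.all(mesh.max_corner >= box.max_corner - 1e-9)

    def test_edge_too_large(self):
        box = BoundingBox([0, 0, 0], [100, 50, 100])
        with pytest.raises(MeshError):
            build_hex_mesh(box, 60.0)


class TestGenerateTetMesh:
    def test_deterministic_per_seed(self, unit_box):
        a = generate_tet_mesh(unit_box, 80.0, seed=3)
        b = generate_tet_mesh(unit_box, 80.0, seed=3)
        assert np.array_equal(a.tets, b.tets)
        assert np.allclose(a.nodes, b.nodes)

    def test_positive_volumes_and_edge_bound(self, small_tet):
        assert np.all(small_tet.signed_volumes() > 0)
        e = small_tet.edges()
        elen = np.linalg.norm(small_tet.nodes[e[:, 0]] - small_tet.nodes[e[:, 1]], axis=1)
        assert elen.max() <= 80.0 * (1 + 1e-9)

    def test_minimum_tet_count_for_cube(self, unit_box):
        mesh = generate_tet_mesh(unit_box, 300.0, seed=0)
        assert mesh.n_elements >= 5

    def test_volumes_tile_the_meshed_box(self, small_tet):
        # the convex lattice volume is exactly tiled by the tets
        lo = small_tet.nodes.min(axis=0)
        hi = small_tet.nodes.max(axis=0)
        assert np.isclose(small_tet.volumes().sum(), np.prod(hi - lo), rtol=1e-6)
        # and it covers the requested box
        assert np.all(lo <= 1e-9) and np.all(hi >= 100 - 1e-9)


class TestPointLocation:
    def test_hex_lattice_node_maps_to_lower_voxel(self, small_hex):
        nodes, local = locate_hex_voxel(small_hex, [50.0, 50.0, 50.0])
        assert np.allclose(local, 0.0)
        assert nodes[0] == small_hex.node_index(1, 1, 1)

    def test_hex_voxel_center(self, small_hex):
        nodes, local = locate_hex_voxel(small_hex, [25.0, 25.0, 25.0])
        assert np.allclose(local, 0.5)
        assert nodes[0] == small_hex.node_index(0, 0, 0)

    def test_hex_outside_errors(self, small_hex):
        with pytest.raises(OutsideMeshError):
            locate_hex_voxel(small_hex, [101.0, 50.0, 50.0])

    def test_hex_random_points_bounded_by_corners(self, small_hex):
        rng = np.random.default_rng(0)
        pos = small_hex.node_positions()
        for p in rng.uniform(0, 100, size=(1000, 3)):
            nodes, local = locate_hex_voxel(small_hex, p)
            corners = pos[nodes]
            assert np.all(corners.min(axis=0) <= p + 1e-9)
            assert np.all(corners.max(axis=0) >= p - 1e-9)
            assert np.all((local >= 0) & (local <= 1))

    def test_tet_centroid_and_vertex(self, small_tet):
        k = 5
        centroid = small_tet.nodes[small_tet.tets[k]].mean(axis=0)
        t, lam = locate_tet(small_tet, centroid)
        assert np.allclose(lam, 0.25)
        assert np.allclose(
            small_tet.nodes[small_tet.tets[t]].mean(axis=0), centroid
        )
        vert = small_tet.nodes[small_tet.tets[k][0]]
        t2, lam2 = locate_tet(small_tet, vert)
        assert np.isclose(lam2.max(), 1.0)

    def test_tet_outside_errors(self, small_tet):
        with pytest.raises(OutsideMeshError):
            locate_tet(small_tet, [500.0, 500.0, 500.0])

    def test_nearest_node_and_ties(self, small_hex):
        assert nearest_node(small_hex, [1.0, 1.0, 1.0]) == small_hex.node_index(0, 0, 0)
        # equidistant between (0,0,0) and (50,0,0): lower index wins
        assert nearest_node(small_hex, [25.0, 0.0, 0.0]) == small_hex.node_index(0, 0, 0)
        assert nearest_node(small_hex, [50.0, 0.0, 0.0]) == small_hex.node_index(1, 0, 0)


def _dihedral_oracle(verts, edge):
    """Independent oracle: angle between in-plane vectors orthogonal to the edge."""
    i, j = edge
    r, s = opposite_edge(edge)
    u = verts[j] - verts[i]
    u = u / np.linalg.norm(u)
    a = verts[r] - verts[i]
    b = verts[s] - verts[i]
    a = a - (a @ u) * u
    b = b - (b @ u) * u
    return np.arccos(np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1, 1))


class TestDihedralAngle:
    def test_regular_tet_all_edges(self, regular_tet):
        for edge in TetMesh._EDGE_LOCAL:
            assert np.isclose(dihedral_angle(regular_tet, edge), np.arccos(1 / 3.0))

    def test_trirectangular_values(self, trirect_tet):
        # edge CD: the slanted edge of the right-angle corner tet
        assert np.isclose(dihedral_angle(trirect_tet, (2, 3)), np.arctan(np.sqrt(2)))
        # edge AD between the two coordinate-plane faces
        assert np.isclose(dihedral_angle(trirect_tet, (0, 3)), np.pi / 2)

    def test_degenerate_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(MeshError):
            dihedral_angle(flat, (0, 1))

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from(list(TetMesh._EDGE_LOCAL)))
    def test_matches_face_normal_oracle(self, seed, edge):
        rng = np.random.default_rng(seed)
        verts = rng.normal(size=(4, 3)) * 50
        if abs(np.linalg.det(verts[1:] - verts[0])) < 1e-3:
            return
        assert np.isclose(
            dihedral_angle(verts, edge), _dihedral_oracle(verts, edge), atol=1e-9
        )


class TestMeshStats:
    def test_hex_counts(self, small_hex):
        st_ = mesh_stats(small_hex)
        assert (st_.n_nodes, st_.n_elements) == (27, 8)
        assert np.isclose(st_.elements_per_node, 8 / 27)

    def test_elements_per_node_approaches_one(self):
        box = BoundingBox([0, 0, 0], [1900.0] * 3)
        mesh = build_hex_mesh(box, 100.0)  # 20³ nodes
        assert mesh.dims == (20, 20, 20)
        assert mesh_stats(mesh).elements_per_node >= 0.85

    def test_kuhn_subdivision_counts(self, small_hex):
        tet = kuhn_tetrahedralize(small_hex)
        assert tet.n_nodes == small_hex.n_nodes
        assert tet.n_elements == 6 * small_hex.n_elements
        assert np.isclose(tet.volumes().sum(), 8 * 50.0 ** 3)


class TestMeshIO:
    def test_msh_roundtrip(self, small_tet, tmp_path):
        path = tmp_path / "m.msh"
        write_mesh(small_tet, path)
        back = read_mesh(path)
        assert np.array_equal(back.tets, small_tet.tets)
        assert np.allclose(back.nodes, small_tet.nodes)

    def test_tetgen_roundtrip(self, small_tet, tmp_path):
        path = tmp_path / "m.node"
        write_mesh(small_tet, path)
        back = read_mesh(path)
        assert np.array_equal(back.tets, small_tet.tets)
        assert np.allclose(back.nodes, small_tet.nodes)

    def test_tetgen_one_based_normalized(self, tmp_path):
        (tmp_path / "t.node").write_text(
            "4 3 0 0\n1 0 0 0\n2 1 0 0\n3 0 1 0\n4 0 0 1\n"
        )
        (tmp_path / "t.ele").write_text("1 4 0\n1 1 2 3 4\n")
        mesh = read_mesh(tmp_path / "t.ele")
        assert mesh.tets.min() == 0 and mesh.tets.max() == 3

    def test_msh_triangles_only_rejected(self, tmp_path):
        path = tmp_path / "tri.msh"
        path.write_text(
            "$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
            "$Nodes\n3\n1 0 0 0\n2 1 0 0\n3 0 1 0\n$EndNodes\n"
            "$Elements\n1\n1 2 2 0 1 1 2 3\n$EndElements\n"
        )
        with pytest.raises(MeshError, match="tet4"):
            read_mesh(path)

    def test_msh41_reader(self, tmp_path):
        path = tmp_path / "v4.msh"
        path.write_text(
            "$MeshFormat\n4.1 0 8\n$EndMeshFormat\n"
            "$Nodes\n1 4 1 4\n3 1 0 4\n1\n2\n3\n4\n"
            "0 0 0\n1 0 0\n0 1 0\n0 0 1\n$EndNodes\n"
            "$Elements\n1 1 1 1\n3 1 4 1\n1 1 2 3 4\n$EndElements\n"
        )
        mesh = read_mesh(path)
        assert mesh.n_nodes == 4 and mesh.n_elements == 1

    def test_unsupported_version(self, tmp_path):
        path = tmp_path / "v9.msh"
        path.write_text("$MeshFormat\n9.0 0 8\n$EndMeshFormat\n")
        with pytest.raises(MeshError, match="9.0"):
            read_mesh(path)
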