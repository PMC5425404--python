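"""Vessel-network data model, file I/O, preprocessing, characterization."""

import numpy as np
import pytest

from vascusim.geometry import make_cylinder
from vascusim.grid import RegularGrid, build_grid_from_bounding_box
from vascusim.network import (NetworkFormatError, VesselNetwork,
                              clip_to_geometry, density_map,
                              make_hexagonal_network, map_occupancy,
                              preprocess, read_network_csv, read_network_vtk,
                              write_network_csv, write_network_vtk)


def two_node_net():
    net = VesselNetwork()
    net.add_node((0, 0, 0))
    net.add_node((0, 0, 100), boundary_role="outlet", boundary_pressure=2000.0)
    net.add_segment(0, 1, 10.0)
    return net


class TestCsvIO:
    def test_two_node_roundtrip(self, tmp_path):
        net = two_node_net()
        write_network_csv(net, tmp_path / "n.csv", tmp_path / "s.csv")
        back = read_network_csv(tmp_path / "n.csv", tmp_path / "s.csv")
        assert len(back.segments) == 1
        assert back.segment_length(0) == pytest.approx(100.0)
        assert back.nodes[1].boundary_role == "outlet"
        assert back.nodes[1].boundary_pressure == 2000.0

    def test_roundtrip_preserves_positions_and_radii_exactly(self, tmp_path, rng):
        net = VesselNetwork()
        pos = rng.uniform(-500, 500, size=(20, 3))
        for p in pos:
            net.add_node(p)
        for i in range(19):
            net.add_segment(i, i + 1, float(rng.uniform(2, 20)))
        write_network_csv(net, tmp_path / "n.csv", tmp_path / "s.csv")
        back = read_network_csv(tmp_path / "n.csv", tmp_path / "s.csv")
        for nid in net.nodes:
            np.testing.assert_allclose(back.nodes[nid].position,
                                       net.nodes[nid].position, atol=1e-9)
        for sid in net.segments:
            assert back.segments[sid].radius == net.segments[sid].radius

    def test_dangling_reference_rejected(self, tmp_path):
        (tmp_path / "n.csv").write_text(
            "id,x_um,y_um,z_um,boundary_role,boundary_pressure_pa\n"
            "0,0,0,0,none,\n")
        (tmp_path / "s.csv").write_text("id,node0,node1,radius_um\n0,0,99,10\n")
        with pytest.raises(NetworkFormatError, match="99"):
            read_network_csv(tmp_path / "n.csv", tmp_path / "s.csv")

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "n.csv").write_text("id,x_um,y_um\n0,0,0\n")
        (tmp_path / "s.csv").write_text("id,node0,node1,radius_um\n")
        with pytest.raises(NetworkFormatError, match="z_um"):
            read_network_csv(tmp_path / "n.csv", tmp_path / "s.csv")

    def test_nonpositive_radius_rejected(self, tmp_path):
        (tmp_path / "n.csv").write_text(
            "id,x_um,y_um,z_um,boundary_role,boundary_pressure_pa\n"
            "0,0,0,0,none,\n1,0,0,10,none,\n")
        (tmp_path / "s.csv").write_text("id,node0,node1,radius_um\n0,0,1,-1\n")
        with pytest.raises(NetworkFormatError, match="radius"):
            read_network_csv(tmp_path / "n.csv", tmp_path / "s.csv")


VTK_POLYLINE = """# vtk DataFile Version 3.0
skeleton
ASCII
DATASET POLYDATA
POINTS 3 float
0 0 0
0 0 50
0 0 100
LINES 1 4
3 0 1 2
POINT_DATA 3
SCALARS Radius float 1
LOOKUP_TABLE default
8
10
12
"""


class TestVtkIO:
    def test_polyline_decomposed_with_endpoint_mean_radii(self, tmp_path):
        (tmp_path / "net.vtk").write_text(VTK_POLYLINE)
        net = read_network_vtk(tmp_path / "net.vtk")
        assert len(net.segments) == 2
        radii = sorted(s.radius for s in net.segments.values())
        assert radii == [9.0, 11.0]

    def test_repeated_point_rejected(self, tmp_path):
        bad = VTK_POLYLINE.replace("3 0 1 2", "3 0 1 1")
        (tmp_path / "net.vtk").write_text(bad)
        with pytest.raises(NetworkFormatError, match="zero-length"):
            read_network_vtk(tmp_path / "net.vtk")

    def test_missing_radius_rejected(self, tmp_path):
        bad = VTK_POLYLINE.replace("Radius", "Thickness")
        (tmp_path / "net.vtk").write_text(bad)
        with pytest.raises(NetworkFormatError, match="Radius"):
            read_network_vtk(tmp_path / "net.vtk")

    def test_write_then_read_roundtrip(self, tmp_path):
        net = two_node_net()
        net.segments[0].flow_rate = 123.0
        write_network_vtk(net, tmp_path / "o.vtk")
        back = read_network_vtk(tmp_path / "o.vtk")
        assert len(back.segments) == 1
        np.testing.assert_allclose(back.nodes[1].position, (0, 0, 100),
                                   atol=1e-6)


class TestPreprocess:
    def test_coincident_nodes_merged(self):
        net = VesselNetwork()
        net.add_node((0, 0, 0))
        net.add_node((0.1, 0, 0))
        net.add_node((100, 0, 0))
        net.add_segment(0, 2, 10)
        net.add_segment(1, 2, 10)
        out = preprocess(net, merge_tolerance=1.0)
        assert len(out.nodes) == 2
        assert len(out.segments) == 1  # duplicate pair removed

    def test_zero_tolerance_is_identity_up_to_repairs(self):
        net = two_node_net()
        out = preprocess(net, merge_tolerance=0.0)
        assert len(out.nodes) == 2 and len(out.segments) == 1

    def test_broken_chain_reconnected(self):
        # A-B and B'-C with |B - B'| = 0.5 um must become A-B''-C
        net = VesselNetwork()
        a = net.add_node((0, 0, 0))
        b = net.add_node((100, 0, 0))
        b2 = net.add_node((100.5, 0, 0))
        c = net.add_node((200, 0, 0))
        net.add_segment(a.id, b.id, 10)
        net.add_segment(b2.id, c.id, 10)
        out = preprocess(net, merge_tolerance=1.0)
        assert len(out.nodes) == 3
        assert len(out.segments) == 2
        merged = [n for n in out.nodes.values()
                  if 99 < n.position[0] < 101]
        assert len(merged) == 1
        np.testing.assert_allclose(merged[0].position, (100.25, 0, 0))

    def test_no_close_pairs_remain(self, rng):
        net = VesselNetwork()
        pts = rng.uniform(0, 50, size=(40, 3))
        for p in pts:
            net.add_node(p)
        for i in range(39):
            net.add_segment(i, i + 1, 5)
        out = preprocess(net, merge_tolerance=5.0)
        pos = out.node_positions()
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 5.0
        for sid in out.segments:
            assert out.segment_length(sid) > 0

    def test_small_components_dropped(self):
        net = two_node_net()
        net.add_node((500, 500, 500))  # isolated node
        out = preprocess(net, merge_tolerance=0.0, min_component_nodes=2)
        assert len(out.nodes) == 2


class TestClip:
    def test_interior_segment_kept(self, roi_cylinder):
        net = two_node_net()
        out = clip_to_geometry(net, roi_cylinder)
        assert len(out.segments) == 1
        assert out.total_length() == pytest.approx(100.0)

    def test_crossing_segment_truncated_at_cylinder_wall(self, roi_cylinder):
        net = VesselNetwork()
        net.add_node((0, 0, 100))
        net.add_node((2000, 0, 100))
        net.add_segment(0, 1, 10)
        out = clip_to_geometry(net, roi_cylinder)
        assert len(out.segments) == 1
        xs = sorted(n.position[0] for n in out.nodes.values())
        assert xs[0] == pytest.approx(0.0)
        assert xs[1] == pytest.approx(600.0, abs=1e-3)

    def test_fully_outside_network_is_emptied(self, roi_cylinder):
        net = VesselNetwork()
        net.add_node((5000, 0, 0))
        net.add_node((5000, 0, 100))
        net.add_segment(0, 1, 10)
        out = clip_to_geometry(net, roi_cylinder)
        assert len(out.segments) == 0

    def test_clip_never_increases_length(self, roi_cylinder, rng):
        net = VesselNetwork()
        pts = rng.uniform(-900, 900, size=(30, 3))
        for p in pts:
            net.add_node(p)
        for i in range(29):
            net.add_segment(i, i + 1, 8)
        out = clip_to_geometry(net, roi_cylinder)
        assert out.total_length() <= net.total_length() + 1e-6


class TestHexagonal:
    def test_single_hexagon(self):
        L = 40.0
        net = make_hexagonal_network(2 * L, np.sqrt(3) * L, L, 10.0)
        assert len(net.nodes) == 6
        assert len(net.segments) == 6
        assert all(net.degree(n) == 2 for n in net.nodes)

    def test_interior_nodes_have_degree_three(self):
        net = make_hexagonal_network(1000.0, 1000.0, 40.0, 10.0)
        degs = [net.degree(n) for n in net.nodes]
        assert max(degs) == 3
        # interior nodes (all incident hexagon edges present) dominate
        assert sum(d == 3 for d in degs) > len(degs) / 2

    def test_uniform_edge_lengths(self):
        L = 40.0
        net = make_hexagonal_network(500.0, 500.0, L, 10.0)
        for sid in net.segments:
            assert net.segment_length(sid) == pytest.approx(L, rel=1e-9)
        assert net.total_length() == pytest.approx(len(net.segments) * L)

    def test_too_small_rectangle_rejected(self):
        with pytest.raises(ValueError):
            make_hexagonal_network(30.0, 30.0, 40.0, 10.0)

    def test_inlet_outlet_flagged_at_opposite_corners(self):
        net = make_hexagonal_network(500.0, 500.0, 40.0, 10.0)
        assert len(net.boundary_nodes("inlet")) == 1
        assert len(net.boundary_nodes("outlet")) == 1


class TestMaps:
    def test_density_conserves_total_length(self, rng):
        net = VesselNetwork()
        pts = rng.uniform(10, 190, size=(15, 3))
        for p in pts:
            net.add_node(p)
        for i in range(14):
            net.add_segment(i, i + 1, 5)
        grid = build_grid_from_bounding_box(((0, 0, 0), (200, 200, 200)), 25.0)
        field = density_map(net, grid)
        total = field.values.sum() * grid.spacing**3
        assert total == pytest.approx(net.total_length(), rel=1e-6)

    def test_empty_network_gives_zero_density(self):
        grid = RegularGrid((0, 0, 0), 10.0, (4, 4, 4))
        field = density_map(VesselNetwork(), grid)
        assert not field.values.any()

    def test_single_voxel_segment(self):
        # axis-aligned segment of length h centred in one voxel
        h = 20.0
        grid = RegularGrid((0, 0, 0), h, (3, 3, 3))
        net = VesselNetwork()
        net.add_node((20, 20, 10))
        net.add_node((20, 20, 30))
        net.add_segment(0, 1, 5)
        field = density_map(net, grid)
        # segment spans site (1,1,0)'s and (1,1,1)'s voxels equally? no:
        # z from 10 to 30 crosses the face at z=10+... voxel of site (1,1,1)
        # spans z in [10, 30] exactly, so all length lands there
        assert field.values[1, 1, 1] == pytest.approx(h / h**3)
        vals = field.values.copy()
        vals[1, 1, 1] = 0.0
        assert not vals.any()

    def test_occupancy_examples(self):
        h = 20.0
        grid = RegularGrid((0, 0, 0), h, (3, 3, 3))
        assert not map_occupancy(VesselNetwork(), grid).values.any()
        net = VesselNetwork()
        net.add_node((20, 20, 10))
        net.add_node((20, 20, 30))
        net.add_segment(0, 1, 5)
        occ = map_occupancy(net, grid)
        assert occ.values[1, 1, 1] == 1.0

    def test_occupancy_support_includes_density_support(self, rng):
        net = VesselNetwork()
        pts = rng.uniform(10, 190, size=(10, 3))
        for p in pts:
            net.add_node(p)
        for i in range(9):
            net.add_segment(i, i + 1, 5)
        grid = build_grid_from_bounding_box(((0, 0, 0), (200, 200, 200)), 25.0)
        dens = density_map(net, grid).values > 0
        occ = map_occupancy(net, grid).values > 0
        # any voxel with centreline length has its centre within h/2 of the
        # centreline only if the piece passes near the centre; the guaranteed
        # inclusion is the reverse: occupied sites carry nonzero density or
        # neighbour a voxel that does.  Check the subdivision-invariant core:
        # sites whose centre the centreline crosses are occupied.
        assert occ.sum() >= 1
        # occupancy is a subset of voxels within one cell of the support
        from scipy import ndimage

        dilated = ndimage.binary_dilation(dens, iterations=1)
        assert not (occ & ~dilated).any()


class TestValidation:
    def test_dangling_segment_detected(self):
        net = two_node_net()
        net.segments[0] = net.segments[0].__class__(
            id=0, node_ids=(0, 5), radius=10.0)
        with pytest.raises(NetworkFormatError):
            net.validate()

    def test_duplicate_pair_detected(self):
        net = two_node_net()
        net.add_segment(1, 0, 5.0)
        with pytest.raises(NetworkFormatError):
            net.validate()

    def test_self_loop_rejected_on_construction(self):
        net = two_node_net()
        with pytest.raises(NetworkFormatError):
            net.add_segment(0, 0, 5.0)
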