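"""Microvessel network data model, I/O, preprocessing and characterization.

A :class:`VesselNetwork` is a graph whose nodes are points in 3D (um) and
whose segments are straight centerline pieces carrying a radius plus the
hemodynamic state (viscosity, flow, hematocrit, wall shear stress, perfusion
flag) written back by the flow solvers.

Canonical on-disk format is a CSV pair (``nodes.csv`` / ``segments.csv``);
legacy VTK polydata ASCII with a per-point ``Radius`` array is supported as
the interchange format for skeletons extracted from imaging.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import DomainGeometry
from .grid import RegularGrid, ScalarField

__all__ = [
    "VesselNode",
    "VesselSegment",
    "VesselNetwork",
    "NetworkFormatError",
    "read_network_csv",
    "write_network_csv",
    "read_network_vtk",
    "write_network_vtk",
    "preprocess",
    "clip_to_geometry",
    "make_hexagonal_network",
    "density_map",
    "map_occupancy",
]

BOUNDARY_ROLES = ("none", "inlet", "outlet")


class NetworkFormatError(ValueError):
    """Malformed network file or inconsistent network state."""


@dataclass
class VesselNode:
    id: int
    position: np.ndarray  # (3,) um
    pressure: float = 0.0  # Pa, set by the flow solve
    boundary_role: str = "none"  # none | inlet | outlet
    boundary_pressure: float | None = None  # Pa, prescribed when role != none
    is_tip: bool = False  # active migrating sprout end
    tip_direction: np.ndarray | None = None  # unit vector while is_tip

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise NetworkFormatError(f"node {self.id}: invalid position")
        if self.boundary_role not in BOUNDARY_ROLES:
            raise NetworkFormatError(
                f"node {self.id}: bad boundary_role {self.boundary_role!r}"
            )


@dataclass
class VesselSegment:
    id: int
    node_ids: tuple[int, int]
    radius: float  # um
    viscosity: float = float("nan")  # Pa s, set by rheology
    flow_rate: float = 0.0  # um^3/s, signed node_ids[0] -> node_ids[1]
    haematocrit: float = 0.0  # dimensionless in [0, 1]
    wall_shear_stress: float = 0.0  # Pa
    perfused: bool = False

    def __post_init__(self):
        i, j = self.node_ids
        if i == j:
            raise NetworkFormatError(f"segment {self.id}: loops onto node {i}")
        if not (self.radius > 0):
            raise NetworkFormatError(f"segment {self.id}: non-positive radius")


class VesselNetwork:
    """Graph of :class:`VesselNode` and :class:`VesselSegment` objects."""

    def __init__(self, provenance: str = ""):
        self.nodes: dict[int, VesselNode] = {}
        self.segments: dict[int, VesselSegment] = {}
        self.provenance = provenance

    # -- construction ----------------------------------------------------
    def add_node(self, position, **kw) -> VesselNode:
        nid = kw.pop("id", None)
        if nid is None:
            nid = max(self.nodes, default=-1) + 1
        node = VesselNode(id=int(nid), position=np.asarray(position, float), **kw)
        if node.id in self.nodes:
            raise NetworkFormatError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node
        return node

    def add_segment(self, node0: int, node1: int, radius: float, **kw) -> VesselSegment:
        sid = kw.pop("id", None)
        if sid is None:
            sid = max(self.segments, default=-1) + 1
        for n in (node0, node1):
            if n not in self.nodes:
                raise NetworkFormatError(f"segment references absent node {n}")
        seg = VesselSegment(id=int(sid), node_ids=(int(node0), int(node1)),
                            radius=float(radius), **kw)
        if seg.id in self.segments:
            raise NetworkFormatError(f"duplicate segment id {seg.id}")
        self.segments[seg.id] = seg
        return seg

    # -- queries ---------------------------------------------------------
    def segment_length(self, sid: int) -> float:
        i, j = self.segments[sid].node_ids
        return float(np.linalg.norm(self.nodes[i].position - self.nodes[j].position))

    def segment_endpoints(self, sid: int) -> tuple[np.ndarray, np.ndarray]:
        i, j = self.segments[sid].node_ids
        return self.nodes[i].position, self.nodes[j].position

    def total_length(self) -> float:
        return float(sum(self.segment_length(s) for s in self.segments))

    def adjacency(self) -> dict[int, list[int]]:
        """node id -> list of incident segment ids."""
        adj: dict[int, list[int]] = {n: [] for n in self.nodes}
        for sid, seg in self.segments.items():
            adj[seg.node_ids[0]].append(sid)
            adj[seg.node_ids[1]].append(sid)
        return adj

    def degree(self, nid: int) -> int:
        return len(self.adjacency()[nid])

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.nodes:
            raise NetworkFormatError("empty network has no bounding box")
        pos = np.stack([n.position for n in self.nodes.values()])
        return pos.min(axis=0), pos.max(axis=0)

    def node_positions(self) -> np.ndarray:
        return np.stack([n.position for n in self.nodes.values()]) if self.nodes else np.empty((0, 3))

    def boundary_nodes(self, role: str) -> list[int]:
        return [n.id for n in self.nodes.values() if n.boundary_role == role]

    def copy(self) -> "VesselNetwork":
        import copy as _copy

        return _copy.deepcopy(self)

    def validate(self) -> None:
        """Raise if the structural invariants are violated."""
        seen_pairs = set()
        for sid, seg in self.segments.items():
            for n in seg.node_ids:
                if n not in self.nodes:
                    raise NetworkFormatError(f"segment {sid}: dangling node {n}")
            if self.segment_length(sid) <= 0:
                raise NetworkFormatError(f"segment {sid}: zero length")
            pair = tuple(sorted(seg.node_ids))
            if pair in seen_pairs:
                raise NetworkFormatError(f"segment {sid}: duplicate of pair {pair}")
            seen_pairs.add(pair)
            if not (0.0 <= seg.haematocrit <= 1.0):
                raise NetworkFormatError(f"segment {sid}: haematocrit out of [0,1]")

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for sid, seg in self.segments.items():
            g.add_edge(*seg.node_ids, key=sid)
        return g


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_NODE_COLS = ["id", "x_um", "y_um", "z_um", "boundary_role", "boundary_pressure_pa"]
_SEG_COLS = ["id", "node0", "node1", "radius_um"]


def read_network_csv(nodes_path, segments_path) -> VesselNetwork:
    """Read a network from the canonical nodes.csv / segments.csv pair."""
    ndf = pd.read_csv(nodes_path, float_precision="round_trip")
    sdf = pd.read_csv(segments_path, float_precision="round_trip")
    for col in _NODE_COLS[:5]:
        if col not in ndf.columns:
            raise NetworkFormatError(f"{nodes_path}: missing column {col!r}")
    for col in _SEG_COLS:
        if col not in sdf.columns:
            raise NetworkFormatError(f"{segments_path}: missing column {col!r}")
    net = VesselNetwork(provenance=f"csv:{nodes_path}")
    for row in ndf.itertuples(index=False):
        role = str(row.boundary_role) if not pd.isna(row.boundary_role) else "none"
        bp = None
        if "boundary_pressure_pa" in ndf.columns and not pd.isna(
            getattr(row, "boundary_pressure_pa", float("nan"))
        ):
            bp = float(row.boundary_pressure_pa)
        if role not in BOUNDARY_ROLES:
            raise NetworkFormatError(f"node row id={row.id}: bad role {role!r}")
        net.add_node(
            (row.x_um, row.y_um, row.z_um), id=int(row.id),
            boundary_role=role, boundary_pressure=bp,
        )
    for row in sdf.itertuples(index=False):
        if row.radius_um <= 0:
            raise NetworkFormatError(f"segment row id={row.id}: non-positive radius")
        for n in (row.node0, row.node1):
            if int(n) not in net.nodes:
                raise NetworkFormatError(
                    f"segment row id={row.id}: references absent node {n}"
                )
        net.add_segment(int(row.node0), int(row.node1), float(row.radius_um),
                        id=int(row.id))
    return net


def write_network_csv(net: VesselNetwork, nodes_path, segments_path) -> None:
    nrows = []
    for n in sorted(net.nodes.values(), key=lambda n: n.id):
        nrows.append(
            {
                "id": n.id,
                "x_um": repr(float(n.position[0])),
                "y_um": repr(float(n.position[1])),
                "z_um": repr(float(n.position[2])),
                "boundary_role": n.boundary_role,
                "boundary_pressure_pa": (
                    "" if n.boundary_pressure is None
                    else repr(float(n.boundary_pressure))),
            }
        )
    srows = []
    for s in sorted(net.segments.values(), key=lambda s: s.id):
        srows.append(
            {"id": s.id, "node0": s.node_ids[0], "node1": s.node_ids[1],
             "radius_um": repr(float(s.radius))}
        )
    pd.DataFrame(nrows, columns=_NODE_COLS).to_csv(nodes_path, index=False)
    pd.DataFrame(srows, columns=_SEG_COLS).to_csv(segments_path, index=False)


# ---------------------------------------------------------------------------
# Legacy VTK polydata ASCII I/O
# ---------------------------------------------------------------------------


def read_network_vtk(path) -> VesselNetwork:
    """Read a vessel skeleton from legacy VTK polydata ASCII.

    Requires POINTS, LINES, and a point-data float array named ``Radius``
    (um).  Polylines are decomposed into unit segments; each segment's
    radius is the mean of its endpoint radii.  Repeated consecutive points
    (zero-length segments) are rejected.
    """
    text = Path(path).read_text()
    tokens = text.split()
    ltext = text.lower()
    if "polydata" not in ltext:
        raise NetworkFormatError(f"{path}: not a VTK polydata file")

    def find_kw(kw):
        for i, t in enumerate(tokens):
            if t.upper() == kw:
                return i
        return None

    ip = find_kw("POINTS")
    if ip is None:
        raise NetworkFormatError(f"{path}: missing POINTS")
    npts = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3 : ip + 3 + 3 * npts], dtype=float).reshape(npts, 3)

    il = find_kw("LINES")
    if il is None:
        raise NetworkFormatError(f"{path}: missing LINES")
    nlines = int(tokens[il + 1])
    pos = il + 3
    polylines = []
    # modern legacy files may use OFFSETS/CONNECTIVITY; classic form is
    # "count id id ..." per line
    if tokens[pos].upper() == "OFFSETS":
        # OFFSETS vtktypeint64 \n values ... CONNECTIVITY vtktypeint64 values
        pos += 2
        offsets = [int(tokens[pos + i]) for i in range(nlines)]
        pos += nlines
        if tokens[pos].upper() != "CONNECTIVITY":
            raise NetworkFormatError(f"{path}: malformed LINES block")
        pos += 2
        conn = [int(t) for t in tokens[pos : pos + offsets[-1]]]
        for a, b in zip(offsets[:-1], offsets[1:]):
            polylines.append(conn[a:b])
    else:
        for _ in range(nlines):
            cnt = int(tokens[pos])
            polylines.append([int(t) for t in tokens[pos + 1 : pos + 1 + cnt]])
            pos += 1 + cnt

    # point data: Radius
    radius = None
    ipd = find_kw("POINT_DATA")
    if ipd is not None:
        j = ipd
        while j < len(tokens):
            if tokens[j].upper() == "SCALARS" and tokens[j + 1] == "Radius":
                k = j + 3  # skip SCALARS, name, dtype
                if tokens[k].lstrip("+-").isdigit():
                    k += 1  # optional numComponents
                if tokens[k].upper() == "LOOKUP_TABLE":
                    k += 2
                radius = np.array(tokens[k : k + npts], dtype=float)
                break
            j += 1
    if radius is None:
        raise NetworkFormatError(f"{path}: missing point-data array 'Radius'")

    net = VesselNetwork(provenance=f"vtk:{path}")
    for pid in range(npts):
        net.add_node(coords[pid], id=pid)
    for line in polylines:
        for a, b in zip(line[:-1], line[1:]):
            if a == b or np.allclose(coords[a], coords[b]):
                raise NetworkFormatError(
                    f"{path}: repeated consecutive point {a} yields zero-length segment"
                )
            net.add_segment(a, b, radius=0.5 * (radius[a] + radius[b]))
    # drop nodes not referenced by any line
    used = {n for line in polylines for n in line}
    for nid in list(net.nodes):
        if nid not in used:
            del net.nodes[nid]
    return net


def write_network_vtk(net: VesselNetwork, path) -> None:
    """Write legacy VTK polydata ASCII with point/cell data arrays.

    Point data: Radius (um, node mean of incident segments), Pressure (Pa).
    Cell data: Flow, Haematocrit, WSS, Perfused.
    """
    ids = sorted(net.nodes)
    remap = {nid: i for i, nid in enumerate(ids)}
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 4.2\n")
    buf.write("vascusim vessel network\nASCII\nDATASET POLYDATA\n")
    buf.write(f"POINTS {len(ids)} float\n")
    for nid in ids:
        p = net.nodes[nid].position
        buf.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
    sids = sorted(net.segments)
    buf.write(f"LINES {len(sids)} {3 * len(sids)}\n")
    for sid in sids:
        i, j = net.segments[sid].node_ids
        buf.write(f"2 {remap[i]} {remap[j]}\n")
    # point data
    adj = net.adjacency()
    buf.write(f"POINT_DATA {len(ids)}\n")
    buf.write("SCALARS Radius float 1\nLOOKUP_TABLE default\n")
    for nid in ids:
        incident = adj[nid]
        r = np.mean([net.segments[s].radius for s in incident]) if incident else 0.0
        buf.write(f"{r:.9g}\n")
    buf.write("SCALARS Pressure float 1\nLOOKUP_TABLE default\n")
    for nid in ids:
        buf.write(f"{net.nodes[nid].pressure:.9g}\n")
    buf.write(f"CELL_DATA {len(sids)}\n")
    for name, get in [
        ("Flow", lambda s: s.flow_rate),
        ("Haematocrit", lambda s: s.haematocrit),
        ("WSS", lambda s: s.wall_shear_stress),
        ("Perfused", lambda s: float(s.perfused)),
    ]:
        buf.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for sid in sids:
            buf.write(f"{get(net.segments[sid]):.9g}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(net: VesselNetwork, merge_tolerance: float = 0.0,
               min_component_nodes: int = 2) -> VesselNetwork:
    """Clean a raw skeleton into a valid network.

    Nodes closer than ``merge_tolerance`` are merged by union-find with the
    merged node at the cluster centroid; zero-length and duplicate segments
    are removed; connected components with fewer than
    ``min_component_nodes`` nodes are dropped.
    """
    if merge_tolerance < 0:
        raise ValueError("merge_tolerance must be >= 0")
    net = net.copy()

    # -- union-find merge of near-coincident nodes (iterate: centroids can
    #    create new close pairs) --
    if merge_tolerance > 0 and len(net.nodes) > 1:
        for _ in range(10):
            ids = sorted(net.nodes)
            pos = np.stack([net.nodes[n].position for n in ids])
            pairs = cKDTree(pos).query_pairs(merge_tolerance, output_type="ndarray")
            if len(pairs) == 0:
                break
            parent = {n: n for n in ids}

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for a, b in pairs:
                ra, rb = find(ids[a]), find(ids[b])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)  # keep smallest id
            clusters: dict[int, list[int]] = {}
            for n in ids:
                clusters.setdefault(find(n), []).append(n)
            new_net = VesselNetwork(provenance=net.provenance)
            nid_map = {}
            for root, members in sorted(clusters.items()):
                centroid = np.mean([net.nodes[m].position for m in members], axis=0)
                # prefer a boundary role if any member carries one
                role, bp = "none", None
                for m in members:
                    if net.nodes[m].boundary_role != "none":
                        role = net.nodes[m].boundary_role
                        bp = net.nodes[m].boundary_pressure
                        break
                new_net.add_node(centroid, id=root, boundary_role=role,
                                 boundary_pressure=bp)
                for m in members:
                    nid_map[m] = root
            for seg in sorted(net.segments.values(), key=lambda s: s.id):
                i, j = nid_map[seg.node_ids[0]], nid_map[seg.node_ids[1]]
                if i == j:
                    continue  # collapsed to a point
                try:
                    new_net.add_segment(i, j, seg.radius, id=seg.id)
                except NetworkFormatError:
                    pass  # duplicate pair after merging
            net = new_net

    # -- invariant repairs: drop zero-length and duplicate segments --
    seen = set()
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        pair = tuple(sorted(seg.node_ids))
        if net.segment_length(sid) <= 0 or pair in seen:
            del net.segments[sid]
        else:
            seen.add(pair)

    # -- drop small connected components --
    import networkx as nx

    g = net.to_networkx()
    for comp in list(nx.connected_components(g)):
        if len(comp) < min_component_nodes:
            for nid in comp:
                del net.nodes[nid]
            for sid in [s for s, seg in net.segments.items()
                        if seg.node_ids[0] in comp or seg.node_ids[1] in comp]:
                del net.segments[sid]
    # orphan nodes with no segments are kept only if they form a
    # component large enough by themselves (i.e. never, for the default)
    return net


def _clip_segment(p0: np.ndarray, p1: np.ndarray, geom: DomainGeometry,
                  n_probe: int = 65, tol: float = 1e-6):
    """Sub-intervals of segment p0->p1 inside ``geom`` as (t0, t1) pairs.

    Membership is probed at ``n_probe`` points and each inside/outside
    transition refined by bisection to ``tol`` (um, relative to segment
    length).  Exact for intervals wider than the probe spacing.
    """
    ts = np.linspace(0.0, 1.0, n_probe)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    inside = geom.contains_many(pts)
    if not inside.any():
        return []
    length = float(np.linalg.norm(p1 - p0))
    tol_t = tol / max(length, tol)

    def refine(lo, hi, want_inside_at_hi):
        # contains(lo) != contains(hi); return boundary crossing t
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if geom.contains(p0 + mid * (p1 - p0)) == want_inside_at_hi:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol_t:
                break
        return hi if want_inside_at_hi else lo

    intervals = []
    i = 0
    while i < n_probe:
        if inside[i]:
            j = i
            while j + 1 < n_probe and inside[j + 1]:
                j += 1
            t0 = ts[i]
            if i > 0:
                t0 = refine(ts[i - 1], ts[i], True)
            t1 = ts[j]
            if j + 1 < n_probe:
                t1 = refine(ts[j], ts[j + 1], False)
            intervals.append((t0, t1))
            i = j + 1
        else:
            i += 1
    return [(a, b) for a, b in intervals if b - a > tol_t]


def clip_to_geometry(net: VesselNetwork, geom: DomainGeometry) -> VesselNetwork:
    """Restrict a network to an implicit region.

    Segments fully outside are removed; segments crossing the boundary are
    truncated at the intersection with a new boundary node inserted.
    """
    out = VesselNetwork(provenance=net.provenance + "|clipped")
    nid_map = {}
    for nid in sorted(net.nodes):
        node = net.nodes[nid]
        if geom.contains(node.position):
            new = out.add_node(node.position, boundary_role=node.boundary_role,
                               boundary_pressure=node.boundary_pressure)
            new.is_tip = node.is_tip
            nid_map[nid] = new.id
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        p0, p1 = net.segment_endpoints(sid)
        in0 = seg.node_ids[0] in nid_map
        in1 = seg.node_ids[1] in nid_map
        if in0 and in1:
            out.add_segment(nid_map[seg.node_ids[0]], nid_map[seg.node_ids[1]],
                            seg.radius, haematocrit=seg.haematocrit)
            continue
        for t0, t1 in _clip_segment(p0, p1, geom):
            a = nid_map[seg.node_ids[0]] if (t0 == 0.0 and in0) else None
            b = nid_map[seg.node_ids[1]] if (t1 == 1.0 and in1) else None
            if a is None:
                a = out.add_node(p0 + t0 * (p1 - p0)).id
            if b is None:
                b = out.add_node(p0 + t1 * (p1 - p0)).id
            if a != b:
                out.add_segment(a, b, seg.radius, haematocrit=seg.haematocrit)
    return out


# ---------------------------------------------------------------------------
# Artificial networks
# ---------------------------------------------------------------------------


def make_hexagonal_network(width: float, height: float, vessel_length: float,
                           radius: float) -> VesselNetwork:
    """Planar honeycomb network of hexagons with edge ``vessel_length``.

    Flat-top hexagons tile the rectangle ``[0, width] x [0, height]`` in the
    z = 0 plane; every segment has the same length and radius.  The nodes
    nearest the (0, 0) and (width, height) corners are flagged inlet and
    outlet respectively (prescribed pressures are set by the caller).
    """
    if min(width, height, vessel_length, radius) <= 0:
        raise ValueError("all hexagonal-network parameters must be positive")
    L = float(vessel_length)
    # flat-top hexagon: vertices at angles 0, 60, ... 300 deg, circumradius L
    angles = np.deg2rad(np.arange(0, 360, 60))
    hexverts = np.stack([L * np.cos(angles), L * np.sin(angles)], axis=1)
    dx, dy = 1.5 * L, np.sqrt(3.0) * L
    centers = []
    col = 0
    while True:
        cx = L + col * dx
        if cx + L > width + 1e-9:
            break
        y0 = dy / 2.0 + (dy / 2.0 if col % 2 else 0.0)
        row = 0
        while True:
            cy = y0 + row * dy
            if cy + dy / 2.0 > height + 1e-9:
                break
            centers.append((cx, cy))
            row += 1
        col += 1
    if not centers:
        raise ValueError("rectangle too small to fit a single hexagon")

    net = VesselNetwork(provenance="hexagonal")
    key_to_id: dict[tuple[int, int], int] = {}

    def node_at(x, y):
        key = (round(x / (L * 1e-9)), round(y / (L * 1e-9)))
        if key not in key_to_id:
            key_to_id[key] = net.add_node((x, y, 0.0)).id
        return key_to_id[key]

    edges = set()
    for cx, cy in centers:
        vids = [node_at(cx + vx, cy + vy) for vx, vy in hexverts]
        for a, b in zip(vids, vids[1:] + vids[:1]):
            pair = (min(a, b), max(a, b))
            if pair not in edges:
                edges.add(pair)
                net.add_segment(pair[0], pair[1], radius)

    pos = {n.id: n.position[:2] for n in net.nodes.values()}
    inlet = min(pos, key=lambda n: float(np.linalg.norm(pos[n])))
    outlet = min(pos, key=lambda n: float(np.linalg.norm(pos[n] - np.array([width, height]))))
    net.nodes[inlet].boundary_role = "inlet"
    net.nodes[outlet].boundary_role = "outlet"
    return net


# ---------------------------------------------------------------------------
# Characterization maps
# ---------------------------------------------------------------------------


def density_map(net: VesselNetwork, grid: RegularGrid) -> ScalarField:
    """Line density: centerline length per voxel volume (um^-2).

    Each segment is split exactly at voxel faces; the length of every piece
    is credited to the voxel holding its midpoint, then divided by h^3.
    Summing value * h^3 over all voxels recovers the total centerline
    length inside the grid.
    """
    h = grid.spacing
    origin = np.asarray(grid.origin)
    field = np.zeros(grid.dims)
    nx, ny, nz = grid.dims
    # voxel faces are at origin + h*(i +/- 1/2)
    for sid in net.segments:
        p0, p1 = net.segment_endpoints(sid)
        d = p1 - p0
        length = float(np.linalg.norm(d))
        if length == 0:
            continue
        ts = [0.0, 1.0]
        for ax in range(3):
            if d[ax] == 0:
                continue
            # crossings of planes origin[ax] + h*(m - 1/2)
            m0 = (p0[ax] - origin[ax]) / h + 0.5
            m1 = (p1[ax] - origin[ax]) / h + 0.5
            lo, hi = sorted((m0, m1))
            for m in range(int(np.ceil(lo - 1e-12)), int(np.floor(hi + 1e-12)) + 1):
                t = (m - m0) / (m1 - m0)
                if 0.0 < t < 1.0:
                    ts.append(float(t))
        ts = sorted(set(ts))
        for a, b in zip(ts[:-1], ts[1:]):
            mid = p0 + 0.5 * (a + b) * d
            idx = np.rint((mid - origin) / h).astype(int)
            if np.all(idx >= 0) and idx[0] < nx and idx[1] < ny and idx[2] < nz:
                field[tuple(idx)] += (b - a) * length
    return ScalarField(grid, field / h**3)


def map_occupancy(net: VesselNetwork, grid: RegularGrid,
                  perfused_only: bool = False) -> ScalarField:
    """Binary occupancy: a site is occupied if any segment centerline passes
    within h/2 of the site centre.

    With ``perfused_only`` only perfused segments count (oxygen delivery).
    The h/2 centre-distance rule makes occupancy invariant to subdividing
    segments.
    """
    h = grid.spacing
    origin = np.asarray(grid.origin)
    occ = np.zeros(grid.dims, dtype=float)
    nx, ny, nz = grid.dims
    for sid, seg in net.segments.items():
        if perfused_only and not seg.perfused:
            continue
        p0, p1 = net.segment_endpoints(sid)
        lo = np.minimum(p0, p1) - h / 2.0
        hi = np.maximum(p0, p1) + h / 2.0
        i0 = np.maximum(np.ceil((lo - origin) / h - 1e-12), 0).astype(int)
        i1 = np.minimum(np.floor((hi - origin) / h + 1e-12),
                        np.array(grid.dims) - 1).astype(int)
        if np.any(i1 < i0):
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(i0[0], i1[0] + 1),
            np.arange(i0[1], i1[1] + 1),
            np.arange(i0[2], i1[2] + 1),
            indexing="ij",
        )
        centers = origin + h * np.stack(
            [ii.ravel(), jj.ravel(), kk.ravel()], axis=1
        ).astype(float)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            dist = np.linalg.norm(centers - p0, axis=1)
        else:
            t = np.clip((centers - p0) @ d / L2, 0.0, 1.0)
            dist = np.linalg.norm(centers - (p0 + t[:, None] * d), axis=1)
        hit = dist <= h / 2.0 + 1e-12
        occ[ii.ravel()[hit], jj.ravel()[hit], kk.ravel()[hit]] = 1.0
    return ScalarField(grid, occ)
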