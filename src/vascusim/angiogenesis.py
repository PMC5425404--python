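"""VEGF-driven sprouting and off-lattice tip-cell migration.

Sprouts nucleate on existing vessel nodes with a saturating VEGF-dependent
hazard, converted to a per-step probability ``1 - exp(-dt P_max c/(c+c50))``
so the rate is robust to the step size.  Active tips then perform a
persistent random walk, once per global step: the new heading is the
normalized blend of the previous heading (persistence, weight alpha), the
unit VEGF gradient (chemotaxis, beta), the direction to the nearest point
of a non-adjacent vessel inside an attraction radius (gamma), and an
isotropic random unit vector (sigma).  A tip that lands within the
anastomosis radius of a non-adjacent segment fuses with it (the segment is
split and the tip deactivated); a confining geometry, when given, projects
escaping tips back to its nearest point.

Geometry queries run against a per-call snapshot of the network, so
segments created while processing a batch of tips become targets only from
the next global step on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DomainGeometry
from .grid import ScalarField
from .network import VesselNetwork

__all__ = ["AngiogenesisParameters", "select_sprouts", "migrate_tips",
           "limbal_initialization"]


@dataclass
class AngiogenesisParameters:
    p_max: float = 1e-5  # 1/s, maximal sprout hazard per eligible node
    c_50: float = 0.5  # nM, VEGF half-saturation for sprouting
    tip_speed: float = 20.0 / 3600.0  # um/s (~20 um/h)
    persistence_weight: float = 0.5  # alpha
    chemotaxis_weight: float = 0.3  # beta
    vessel_attraction_weight: float = 0.1  # gamma
    noise_weight: float = 0.1  # sigma
    attraction_radius: float = 50.0  # um
    anastomosis_radius: float = 5.0  # um
    sprout_exclusion_distance: float = 40.0  # um, d_min
    sprout_radius: float = 5.0  # um, radius of new sprout segments

    def __post_init__(self):
        w = np.array([self.persistence_weight, self.chemotaxis_weight,
                      self.vessel_attraction_weight, self.noise_weight])
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("migration weights must be non-negative, not all zero")
        w = w / w.sum()  # single-knob semantics: weights renormalized to 1
        (self.persistence_weight, self.chemotaxis_weight,
         self.vessel_attraction_weight, self.noise_weight) = map(float, w)


# ---------------------------------------------------------------------------
# Field sampling helpers (batch, tolerant of out-of-grid points)
# ---------------------------------------------------------------------------


class _FieldProbe:
    """Batch trilinear sampler of a field and its central-difference
    gradient; points outside the grid read as zero."""

    def __init__(self, field: ScalarField):
        from scipy.interpolate import RegularGridInterpolator

        axes = field.grid.axes()
        h = field.grid.spacing

        def interp(vals):
            return RegularGridInterpolator(axes, vals, method="linear",
                                           bounds_error=False, fill_value=0.0)

        self._c = interp(field.values)
        comps = []
        for axis in range(3):
            if field.grid.dims[axis] == 1:
                comps.append(interp(np.zeros(field.grid.dims)))
            else:
                comps.append(interp(np.gradient(field.values, h, axis=axis)))
        self._g = comps

    def concentration(self, pts: np.ndarray) -> np.ndarray:
        return self._c(np.atleast_2d(pts))

    def gradient(self, p: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(p)
        return np.array([float(g(q)[0]) for g in self._g])


class _SegmentSnapshot:
    """Frozen arrays of segment endpoints for vectorized nearest queries."""

    def __init__(self, net: VesselNetwork):
        self.sids = np.array(sorted(net.segments), dtype=int)
        if len(self.sids):
            self.a = np.stack([net.segment_endpoints(s)[0] for s in self.sids])
            self.b = np.stack([net.segment_endpoints(s)[1] for s in self.sids])
            self.node0 = np.array([net.segments[s].node_ids[0] for s in self.sids])
            self.node1 = np.array([net.segments[s].node_ids[1] for s in self.sids])
        else:
            self.a = self.b = np.empty((0, 3))
            self.node0 = self.node1 = np.empty(0, dtype=int)

    def nearest(self, p: np.ndarray, exclude_node: int | None = None):
        """(sid, point, t, distance) of the nearest non-adjacent segment."""
        if len(self.sids) == 0:
            return None
        keep = np.ones(len(self.sids), dtype=bool)
        if exclude_node is not None:
            keep &= (self.node0 != exclude_node) & (self.node1 != exclude_node)
        if not keep.any():
            return None
        a, b = self.a[keep], self.b[keep]
        d = b - a
        L2 = np.einsum("ij,ij->i", d, d)
        t = np.clip(np.einsum("ij,ij->i", p - a, d) / np.maximum(L2, 1e-300),
                    0.0, 1.0)
        q = a + t[:, None] * d
        dist = np.linalg.norm(p - q, axis=1)
        i = int(np.argmin(dist))
        idx = np.nonzero(keep)[0][i]
        return int(self.sids[idx]), q[i], float(t[i]), float(dist[i])


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = float(np.linalg.norm(v))
    return v / n if n > 1e-14 else None


# ---------------------------------------------------------------------------
# Sprouting
# ---------------------------------------------------------------------------


def _initial_direction(net: VesselNetwork, adj: dict, nid: int,
                       grad: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sprout direction: perpendicular to the parent vessel, in the plane of
    the vessel and the VEGF gradient, on the gradient-facing side; a random
    perpendicular when the gradient is zero."""
    incident = adj.get(nid, [])
    if incident:
        a, b = net.segment_endpoints(incident[0])
        axis = _unit(b - a)
    else:
        axis = None
    if axis is None:
        g = _unit(grad)
        return g if g is not None else _random_unit_vector(rng)
    g = _unit(grad - float(grad @ axis) * axis)  # gradient normal to vessel
    if g is not None:
        return g
    perp = None
    while perp is None:
        r = _random_unit_vector(rng)
        perp = _unit(r - float(r @ axis) * axis)
    return perp


def select_sprouts(net: VesselNetwork, vegf: ScalarField, dt: float,
                   params: AngiogenesisParameters,
                   rng: np.random.Generator,
                   geom: DomainGeometry | None = None) -> list[int]:
    """Stochastically nucleate sprouts; return the new tip node ids.

    Eligible nodes are non-tip, non-boundary nodes farther than the
    exclusion distance from every existing tip and from every sprout base
    formed earlier in the same call.  Each sprouting node gains a one-step
    segment toward the local VEGF gradient (perpendicular to its vessel)
    ending in a new active tip node; with a confining ``geom`` the new
    tip is projected inside it.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    probe = _FieldProbe(vegf)
    adj = net.adjacency()
    candidates = [nid for nid in sorted(net.nodes)
                  if not net.nodes[nid].is_tip
                  and net.nodes[nid].boundary_role == "none"]
    guard = [net.nodes[n].position for n in net.nodes if net.nodes[n].is_tip]
    if not candidates:
        return []
    pos = np.stack([net.nodes[n].position for n in candidates])
    c = np.maximum(probe.concentration(pos), 0.0)
    p = 1.0 - np.exp(-dt * params.p_max * c / np.where(c > 0, c + params.c_50, 1.0))
    draws = rng.random(len(candidates))
    d_min = params.sprout_exclusion_distance
    new_tips: list[int] = []
    for i, nid in enumerate(candidates):
        if c[i] <= 0.0 or draws[i] >= p[i]:
            continue
        x = net.nodes[nid].position
        if guard and d_min > 0:
            if float(np.min(np.linalg.norm(np.stack(guard) - x, axis=1))) < d_min:
                continue
        grad = probe.gradient(x)
        direction = _initial_direction(net, adj, nid, grad, rng)
        tip_pos = x + params.tip_speed * dt * direction
        if geom is not None:
            tip_pos = geom.project_inside(tip_pos)
        tip = net.add_node(tip_pos)
        tip.is_tip = True
        tip.tip_direction = direction
        sid = net.add_segment(nid, tip.id, params.sprout_radius).id
        adj.setdefault(nid, []).append(sid)
        adj[tip.id] = [sid]
        guard.append(x)
        guard.append(tip.position)
        new_tips.append(tip.id)
    return new_tips


# ---------------------------------------------------------------------------
# Tip migration
# ---------------------------------------------------------------------------


def migrate_tips(net: VesselNetwork, vegf: ScalarField,
                 geom: DomainGeometry | None, dt: float,
                 params: AngiogenesisParameters,
                 rng: np.random.Generator) -> VesselNetwork:
    """Advance every active tip by one persistent-random-walk step.

    Tips move ``tip_speed * dt`` along the blended heading, are projected
    back inside ``geom`` when given, and fuse (anastomose) when the new
    position falls within the anastomosis radius of a segment not adjacent
    to the tip; a fused tip is deactivated and never moves again.
    """
    probe = _FieldProbe(vegf)
    snap = _SegmentSnapshot(net)
    adj = net.adjacency()
    tip_ids = sorted(n for n in net.nodes if net.nodes[n].is_tip)
    for nid in tip_ids:
        tip = net.nodes[nid]
        d_old = tip.tip_direction if tip.tip_direction is not None else np.zeros(3)
        parts = params.persistence_weight * d_old
        g = _unit(probe.gradient(tip.position))
        if g is not None:
            parts = parts + params.chemotaxis_weight * g
        near = snap.nearest(tip.position, exclude_node=nid)
        if near is not None:
            _, q, _, dist = near
            # sharp attraction kernel; attraction suppressed within one step
            # length of the tip (its own recent trail) to avoid refusion
            step = params.tip_speed * dt
            if step < dist <= params.attraction_radius:
                v = _unit(q - tip.position)
                if v is not None:
                    parts = parts + params.vessel_attraction_weight * v
        parts = parts + params.noise_weight * _random_unit_vector(rng)
        d_new = _unit(parts)
        if d_new is None:
            d_new = d_old if np.linalg.norm(d_old) > 0 else _random_unit_vector(rng)
        new_pos = tip.position + params.tip_speed * dt * d_new
        if geom is not None:
            new_pos = geom.project_inside(new_pos)
        radius = (net.segments[adj[nid][0]].radius if adj.get(nid)
                  else params.sprout_radius)
        tip.is_tip = False
        tip.tip_direction = None
        hit = snap.nearest(new_pos, exclude_node=nid)
        if hit is not None and hit[3] <= params.anastomosis_radius:
            sid, q, t, _ = hit
            if sid in net.segments:  # not already split by an earlier tip
                target = _split_segment_at(net, sid, q, t, adj)
                if target != nid and not _connected(net, adj, nid, target):
                    s = net.add_segment(nid, target, radius)
                    adj.setdefault(nid, []).append(s.id)
                    adj.setdefault(target, []).append(s.id)
                continue
        new = net.add_node(new_pos)
        new.is_tip = True
        new.tip_direction = d_new
        s = net.add_segment(nid, new.id, radius)
        adj.setdefault(nid, []).append(s.id)
        adj[new.id] = [s.id]
    return net


def _connected(net, adj, a, b):
    return any(b in net.segments[s].node_ids for s in adj.get(a, []))


def _split_segment_at(net, sid, q, t, adj):
    """Insert a node at parameter t on segment sid; return its node id."""
    seg = net.segments[sid]
    i, j = seg.node_ids
    if t <= 1e-9:
        return i
    if t >= 1.0 - 1e-9:
        return j
    mid = net.add_node(q)
    radius, h = seg.radius, seg.haematocrit
    del net.segments[sid]
    adj[i] = [s for s in adj.get(i, []) if s != sid]
    adj[j] = [s for s in adj.get(j, []) if s != sid]
    s1 = net.add_segment(i, mid.id, radius, haematocrit=h)
    s2 = net.add_segment(mid.id, j, radius, haematocrit=h)
    adj[i].append(s1.id)
    adj[j].append(s2.id)
    adj[mid.id] = [s1.id, s2.id]
    return mid.id


# ---------------------------------------------------------------------------
# Limbal seed vessel
# ---------------------------------------------------------------------------


def limbal_initialization(geom: DomainGeometry, n_nodes: int = 64,
                          radius: float = 10.0) -> VesselNetwork:
    """Closed circular limbal vessel at the equatorial rim of a shell.

    The loop sits at z = 0 (relative to the shell centre) at the mid-shell
    radius, discretized into ``n_nodes`` equal segments; every node is
    sprout-eligible.
    """
    if geom.kind != "hemisphere_shell":
        raise ValueError("limbal initialization requires a hemisphere_shell")
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes to close the loop")
    c = geom.params["center"]
    r_mid = geom.params["outer_radius"] - geom.params["thickness"] / 2.0
    net = VesselNetwork(provenance="limbus")
    theta = 2.0 * np.pi * np.arange(n_nodes) / n_nodes
    for th in theta:
        net.add_node(c + r_mid * np.array([np.cos(th), np.sin(th), 0.0]))
    for i in range(n_nodes):
        net.add_segment(i, (i + 1) % n_nodes, radius)
    return net
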