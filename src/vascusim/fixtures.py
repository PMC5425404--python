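"""Deterministic generators of test inputs.

Provides small closed-form networks (single tube, Y-bifurcation, honeycomb)
and a synthetic "intravital-like" tumor skeleton: tortuous backbone vessels
traversing a cylindrical region depth-wise with dangling side branches and
lognormal radii.  The synthetic skeleton is a plausibility construct — its
statistics are *not* fitted to any real microvessel dataset — but it is
connected inlet-face to outlet-face, passes network validation, and is
bit-reproducible from its seed, so the full tumor scenario runs with no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import make_hemisphere_shell
from .network import VesselNetwork, make_hexagonal_network

__all__ = ["SyntheticNetworkSpec", "synthetic_tumor_network", "fixture_catalog",
           "single_tube", "y_bifurcation", "hexagon_grid"]


@dataclass
class SyntheticNetworkSpec:
    """Parameters of the synthetic tumor-like skeleton."""

    cylinder_diameter: float = 1200.0  # um
    cylinder_depth: float = 200.0  # um
    n_backbone_vessels: int = 12
    tortuosity_amplitude: float = 15.0  # um lateral jitter per axial step
    branch_probability: float = 0.1  # per interior backbone node
    radius_log_mean: float = 10.0  # um, lognormal median
    radius_log_sigma: float = 0.25
    axial_step: float = 40.0  # um
    seed: int = 42

    def __post_init__(self):
        for name in ("cylinder_diameter", "cylinder_depth", "axial_step",
                     "radius_log_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_backbone_vessels < 1:
            raise ValueError("need at least one backbone vessel")


def single_tube(length: float = 100.0, radius: float = 10.0,
                inlet_pressure: float = 3330.0,
                outlet_pressure: float = 2000.0) -> VesselNetwork:
    """One straight segment along z with prescribed end pressures."""
    net = VesselNetwork(provenance="fixture:single-tube")
    net.add_node((0, 0, 0), boundary_role="inlet", boundary_pressure=inlet_pressure)
    net.add_node((0, 0, length), boundary_role="outlet",
                 boundary_pressure=outlet_pressure)
    net.add_segment(0, 1, radius)
    return net


def y_bifurcation(radius_parent: float = 10.0, radius_daughter: float = 10.0,
                  inlet_pressure: float = 3330.0,
                  outlet_pressure: float = 2000.0) -> VesselNetwork:
    """Symmetric Y: one parent splitting into two mirror-image daughters."""
    net = VesselNetwork(provenance="fixture:y-bifurcation")
    net.add_node((0, 0, 0), boundary_role="inlet", boundary_pressure=inlet_pressure)
    net.add_node((0, 0, 100))
    net.add_node((50, 0, 200), boundary_role="outlet",
                 boundary_pressure=outlet_pressure)
    net.add_node((-50, 0, 200), boundary_role="outlet",
                 boundary_pressure=outlet_pressure)
    net.add_segment(0, 1, radius_parent)
    net.add_segment(1, 2, radius_daughter)
    net.add_segment(1, 3, radius_daughter)
    return net


def hexagon_grid(n_cols: int = 10, n_rows: int = 10, vessel_length: float = 40.0,
                 radius: float = 10.0, inlet_pressure: float = 3330.0,
                 outlet_pressure: float = 2000.0) -> VesselNetwork:
    """Honeycomb of roughly n_cols x n_rows hexagons with corner BCs."""
    L = vessel_length
    width = (1.5 * n_cols + 0.5) * L
    height = (n_rows + 0.5) * np.sqrt(3.0) * L
    net = make_hexagonal_network(width, height, L, radius)
    for nid in net.boundary_nodes("inlet"):
        net.nodes[nid].boundary_pressure = inlet_pressure
    for nid in net.boundary_nodes("outlet"):
        net.nodes[nid].boundary_pressure = outlet_pressure
    return net


def synthetic_tumor_network(spec: SyntheticNetworkSpec | None = None) -> VesselNetwork:
    """Generate the synthetic tumor-like skeleton from its embedded seed.

    Backbone vessels run depth-wise through the cylinder as laterally
    perturbed polylines (inlet node at z = 0, outlet node at z = depth);
    side branches attach with the given per-node probability and dangle
    (they receive no flow, exercising the perfusion logic).  Regenerates
    internally (up to 10 attempts) if validation fails.
    """
    if spec is None:
        spec = SyntheticNetworkSpec()
    last_err: Exception | None = None
    for attempt in range(10):
        rng = np.random.default_rng(spec.seed + attempt)
        net = _generate(spec, rng)
        try:
            net.validate()
            if _face_connected(net):
                return net
            last_err = RuntimeError("no inlet-to-outlet path")
        except Exception as e:  # pragma: no cover - regeneration guard
            last_err = e
    raise RuntimeError(f"could not generate a valid synthetic network: {last_err}")


def _generate(spec: SyntheticNetworkSpec, rng: np.random.Generator) -> VesselNetwork:
    net = VesselNetwork(provenance=f"fixture:synthetic-tumor(seed={spec.seed})")
    R = spec.cylinder_diameter / 2.0
    depth = spec.cylinder_depth
    n_steps = max(int(round(depth / spec.axial_step)), 1)
    dz = depth / n_steps

    def draw_radius():
        r = float(rng.lognormal(np.log(spec.radius_log_mean),
                                spec.radius_log_sigma))
        return float(np.clip(r, 2.0, 30.0))

    for _ in range(spec.n_backbone_vessels):
        # start uniformly in the disk (area-uniform), stay inside 0.9 R
        r0 = 0.9 * R * np.sqrt(rng.random())
        th0 = 2 * np.pi * rng.random()
        xy = np.array([r0 * np.cos(th0), r0 * np.sin(th0)])
        prev = net.add_node((xy[0], xy[1], 0.0), boundary_role="inlet")
        interior_nodes = []
        for k in range(1, n_steps + 1):
            xy = xy + rng.normal(scale=spec.tortuosity_amplitude, size=2)
            rr = float(np.linalg.norm(xy))
            if rr > 0.95 * R:
                xy = xy * (0.95 * R / rr)
            z = k * dz
            role = "outlet" if k == n_steps else "none"
            node = net.add_node((xy[0], xy[1], z), boundary_role=role)
            net.add_segment(prev.id, node.id, draw_radius())
            if role == "none":
                interior_nodes.append(node)
            prev = node
        # dangling side branches
        for node in interior_nodes:
            if rng.random() >= spec.branch_probability:
                continue
            direction = rng.normal(size=3)
            direction[2] *= 0.3  # branches mostly lateral
            direction /= np.linalg.norm(direction)
            p = node.position.copy()
            tail = node
            for _ in range(int(rng.integers(1, 4))):
                p = p + spec.axial_step * direction \
                    + rng.normal(scale=spec.tortuosity_amplitude / 2.0, size=3)
                p[2] = float(np.clip(p[2], 0.5 * dz, depth - 0.5 * dz))
                rr = float(np.linalg.norm(p[:2]))
                if rr > 0.95 * R:
                    p[:2] *= 0.95 * R / rr
                nxt = net.add_node(p)
                net.add_segment(tail.id, nxt.id, draw_radius())
                tail = nxt
    return net


def _face_connected(net: VesselNetwork) -> bool:
    import networkx as nx

    g = net.to_networkx()
    inlets = net.boundary_nodes("inlet")
    outlets = set(net.boundary_nodes("outlet"))
    if not inlets or not outlets:
        return False
    for comp in nx.connected_components(g):
        if any(i in comp for i in inlets) and comp & outlets:
            return True
    return False


def fixture_catalog() -> dict:
    """Named zero-argument builders of every standard fixture network."""
    from .angiogenesis import limbal_initialization

    small_spec = SyntheticNetworkSpec()

    return {
        "single-tube": single_tube,
        "Y-bifurcation": y_bifurcation,
        "hexagon-10x10": hexagon_grid,
        "synthetic-tumor-small": lambda: synthetic_tumor_network(small_spec),
        "cornea-default": lambda: limbal_initialization(
            make_hemisphere_shell((0, 0, 0), 1400.0, 100.0), 64, 10.0),
    }
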