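"""Blood flow in vessel networks: 1D Poiseuille flow, nonlinear rheology,
hematocrit phase separation, perfusion flags, wall shear stress and
structural radius adaptation.

The network is treated as a resistor graph: each segment carries a
conductance ``G = pi R^4 / (8 mu L)`` and nodal pressures solve the linear
conservation system with pressures prescribed at inlet/outlet nodes.  The
apparent viscosity follows the empirical in-vitro law of Pries and
co-workers (diameter- and hematocrit-dependent, reproducing the
Fahraeus-Lindqvist minimum at capillary diameters), and red-cell flux is
partitioned at diverging bifurcations by the empirical logit plasma-skimming
law.  Internal units: um, s, Pa — conductances are um^3/(Pa s) and flows
um^3/s without further conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import VesselNetwork

__all__ = [
    "FlowBoundaryConditions",
    "RheologyParameters",
    "AdaptationParameters",
    "assign_viscosity",
    "solve_flow",
    "propagate_haematocrit",
    "update_perfusion",
    "compute_wall_shear",
    "adapt_radii",
    "relative_viscosity",
]


class HemodynamicsError(RuntimeError):
    pass


@dataclass
class FlowBoundaryConditions:
    """Prescribed nodal pressures (Pa), keyed by node id."""

    pressures: dict[int, float] = field(default_factory=dict)

    @classmethod
    def from_network(cls, net: VesselNetwork) -> "FlowBoundaryConditions":
        """Collect prescribed pressures from inlet/outlet node roles."""
        p = {}
        for n in net.nodes.values():
            if n.boundary_role != "none":
                if n.boundary_pressure is None:
                    raise HemodynamicsError(
                        f"boundary node {n.id} has role {n.boundary_role} but no pressure"
                    )
                p[n.id] = float(n.boundary_pressure)
        return cls(p)

    def validate(self, net: VesselNetwork) -> None:
        roles = {net.nodes[n].boundary_role for n in self.pressures if n in net.nodes}
        if not self.pressures or not all(np.isfinite(list(self.pressures.values()))):
            raise HemodynamicsError("boundary conditions empty or non-finite")
        if "inlet" not in roles or "outlet" not in roles:
            warnings.warn("boundary conditions lack an inlet or an outlet role")


@dataclass
class RheologyParameters:
    plasma_viscosity: float = 1.2e-3  # Pa s
    law: str = "diameter_haematocrit"  # or "constant"


@dataclass
class AdaptationParameters:
    k_growth: float = 1e-6  # 1/s
    shrink_tendency: float = 1.0  # k_s, dimensionless
    tau_ref: float = 1.0  # Pa
    r_min: float = 1.0  # um
    r_max: float = 50.0  # um


# ---------------------------------------------------------------------------
# Rheology
# ---------------------------------------------------------------------------


def relative_viscosity(d_um, H) -> np.ndarray:
    """In-vitro relative apparent viscosity mu_rel(d, H).

    ``d_um`` is the luminal diameter in um, ``H`` the tube hematocrit.
    Empirical fit constants follow the standard in-vitro formulation; the
    law is 1 at H = 0 and exhibits the Fahraeus-Lindqvist viscosity minimum
    near capillary diameters at physiological H.  H is evaluated at most at
    0.99: the fit diverges at H = 1, which plasma skimming can produce
    transiently in a starved branch.
    """
    d = np.asarray(d_um, dtype=float)
    H = np.minimum(np.asarray(H, dtype=float), 0.99)
    mu45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    frac = 1.0 / (1.0 + 1e-11 * d**12)
    C = (0.8 + np.exp(-0.075 * d)) * (-1.0 + frac) + frac
    num = (1.0 - H) ** C - 1.0
    den = (1.0 - 0.45) ** C - 1.0
    return 1.0 + (mu45 - 1.0) * num / den


def assign_viscosity(net: VesselNetwork, params: RheologyParameters) -> VesselNetwork:
    """Set per-segment apparent viscosity (Pa s) in place."""
    for seg in net.segments.values():
        if not (0.0 <= seg.haematocrit <= 1.0):
            raise HemodynamicsError(
                f"segment {seg.id}: haematocrit {seg.haematocrit} outside [0, 1]"
            )
        if params.law == "constant":
            seg.viscosity = params.plasma_viscosity
        elif params.law == "diameter_haematocrit":
            seg.viscosity = params.plasma_viscosity * float(
                relative_viscosity(2.0 * seg.radius, seg.haematocrit)
            )
        else:
            raise ValueError(f"unknown rheology law {params.law!r}")
    return net


# ---------------------------------------------------------------------------
# Flow solve
# ---------------------------------------------------------------------------


def _conductance(net: VesselNetwork, sid: int) -> float:
    seg = net.segments[sid]
    L = net.segment_length(sid)
    if not np.isfinite(seg.viscosity) or seg.viscosity <= 0:
        raise HemodynamicsError(f"segment {sid}: viscosity not set")
    return np.pi * seg.radius**4 / (8.0 * seg.viscosity * L)


def solve_flow(net: VesselNetwork, bcs: FlowBoundaryConditions) -> VesselNetwork:
    """Solve nodal pressures and signed segment flows in place.

    Pressures at prescribed nodes are imposed; at every other node the net
    Poiseuille flow sums to zero.  Connected components containing no
    prescribed node are flagged and assigned the mean prescribed pressure
    with zero flow.
    """
    bcs.validate(net)
    ids = sorted(net.nodes)
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    G = np.array([_conductance(net, s) for s in sorted(net.segments)])
    if len(G) and not np.all(np.isfinite(G)):
        raise HemodynamicsError("non-finite conductance")
    sids = sorted(net.segments)

    rows, cols, vals = [], [], []
    for g, sid in zip(G, sids):
        i, j = (index[x] for x in net.segments[sid].node_ids)
        rows += [i, j, i, j]
        cols += [i, j, j, i]
        vals += [g, g, -g, -g]
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    prescribed = {index[nid]: p for nid, p in bcs.pressures.items() if nid in index}
    # connected components without a prescribed node -> mean-pressure fallback
    ncomp, labels = sp.csgraph.connected_components(
        (abs(lap) > 0).astype(int), directed=False
    )
    mean_p = float(np.mean(list(prescribed.values())))
    dead_components = set(range(ncomp)) - {labels[i] for i in prescribed}
    for i in range(n):
        if labels[i] in dead_components:
            prescribed.setdefault(i, mean_p)
    if dead_components:
        warnings.warn(
            f"{len(dead_components)} component(s) lack prescribed pressures; "
            "set to mean prescribed pressure with zero flow"
        )

    free = np.array([i for i in range(n) if i not in prescribed], dtype=int)
    p = np.zeros(n)
    for i, v in prescribed.items():
        p[i] = v
    if free.size:
        A = lap[free][:, free].tocsc()
        fixed = np.array(sorted(prescribed), dtype=int)
        b = -lap[free][:, fixed] @ p[fixed]
        p[free] = spla.spsolve(A, b)
    for nid in ids:
        net.nodes[nid].pressure = float(p[index[nid]])
    for g, sid in zip(G, sids):
        i, j = net.segments[sid].node_ids
        net.segments[sid].flow_rate = float(g * (p[index[i]] - p[index[j]]))
    return net


# ---------------------------------------------------------------------------
# Hematocrit propagation / plasma skimming
# ---------------------------------------------------------------------------


def _logit(x):
    return np.log(x / (1.0 - x))


def phase_separation_split(psi_a: float, H_F: float, d_parent: float,
                           d_a: float, d_b: float, law: str = "logit") -> float:
    """Fraction of parent red-cell flux entering daughter ``a``.

    ``psi_a`` is the fractional *blood* flow into daughter a.  With the
    empirical ``logit`` law, daughters receiving less than the plasma-
    skimming threshold X0 of the blood flow get no red cells at all;
    ``proportional`` splits red cells like plasma (for testing).
    """
    if law == "proportional":
        return float(np.clip(psi_a, 0.0, 1.0))
    if law != "logit":
        raise ValueError(f"unknown phase-separation law {law!r}")
    if H_F <= 0.0:
        return float(np.clip(psi_a, 0.0, 1.0))
    x0 = 0.964 * (1.0 - H_F) / d_parent
    if psi_a <= x0:
        return 0.0
    if psi_a >= 1.0 - x0:
        return 1.0
    B = 1.0 + 6.98 * (1.0 - H_F) / d_parent
    ratio = (d_a / d_b) ** 2
    A = -13.29 * ((ratio - 1.0) / (ratio + 1.0)) * (1.0 - H_F) / d_parent
    arg = (psi_a - x0) / (1.0 - 2.0 * x0)
    logitF = A + B * _logit(arg)
    return float(1.0 / (1.0 + np.exp(-logitF)))


def _split_outflows(Q_parent, H_parent, d_parent, outs, law):
    """Distribute parent RBC flux among outflow segments.

    ``outs``: list of (segment, |Q|) sorted externally.  Returns hematocrits
    in the same order; conserves flux exactly, clamps H to [0, 1] with the
    excess returned to the sibling(s).
    """
    flux = Q_parent * H_parent
    if len(outs) == 1:
        seg, q = outs[0]
        return [min(flux / q, 1.0) if q > 0 else 0.0]
    if len(outs) == 2:
        (sa, qa), (sb, qb) = outs
        qt = qa + qb
        psi_a = qa / qt if qt > 0 else 0.5
        Fa = phase_separation_split(psi_a, H_parent, d_parent,
                                    2 * sa.radius, 2 * sb.radius, law)
        fa, fb = Fa * flux, (1.0 - Fa) * flux
        Ha = fa / qa if qa > 0 else 0.0
        Hb = fb / qb if qb > 0 else 0.0
        if Ha > 1.0:  # clamp, push excess cells to the sibling
            fb += (Ha - 1.0) * qa
            Ha, Hb = 1.0, min(fb / qb, 1.0) if qb > 0 else 0.0
        elif Hb > 1.0:
            fa += (Hb - 1.0) * qb
            Hb, Ha = 1.0, min(fa / qa, 1.0) if qa > 0 else 0.0
        return [Ha, Hb]
    # trifurcation or higher: recursive pairwise split in descending flow
    # order — first branch vs the aggregate of the rest
    (s0, q0) = outs[0]
    rest = outs[1:]
    q_rest = sum(q for _, q in rest)
    d_rest = max(2 * s.radius for s, _ in rest)
    psi0 = q0 / (q0 + q_rest)
    F0 = phase_separation_split(psi0, H_parent, d_parent, 2 * s0.radius, d_rest, law)
    f0 = F0 * flux
    H0 = f0 / q0 if q0 > 0 else 0.0
    if H0 > 1.0:
        f0 = q0
        H0 = 1.0
    H_rest_parent = (flux - f0) / q_rest if q_rest > 0 else 0.0
    sub = _split_outflows(q_rest, min(H_rest_parent, 1.0), d_parent, rest, law)
    return [H0] + sub


def propagate_haematocrit(net: VesselNetwork, inlet_H: float = 0.45,
                          law: str = "logit", max_sweeps: int = 1000,
                          tol: float = 1e-8) -> VesselNetwork:
    """Propagate hematocrit downstream from the inlets in place.

    Segments are processed in topological order of the flow digraph;
    converging nodes mix by flux weighting, diverging bifurcations apply the
    phase-separation ``law``.  Red-cell flux Q*H is conserved at every node.
    If the flow digraph is cyclic the same update is relaxed iteratively.
    Zero-flow segments receive H = 0.
    """
    import networkx as nx

    if not (0.0 <= inlet_H <= 1.0):
        raise HemodynamicsError("inlet hematocrit must lie in [0, 1]")
    qeps = 1e-30
    dg = nx.DiGraph()
    dg.add_nodes_from(net.nodes)
    for sid, seg in net.segments.items():
        if abs(seg.flow_rate) <= qeps:
            seg.haematocrit = 0.0
            continue
        i, j = seg.node_ids
        up, dn = (i, j) if seg.flow_rate > 0 else (j, i)
        dg.add_edge(up, dn, sid=sid)

    def sweep(order) -> float:
        delta = 0.0
        for nid in order:
            ins = [net.segments[dg.edges[e]["sid"]] for e in dg.in_edges(nid)]
            outs = [net.segments[dg.edges[e]["sid"]] for e in dg.out_edges(nid)]
            if not outs:
                continue
            node = net.nodes[nid]
            if node.boundary_role == "inlet" or not ins:
                # source node: every outflow leaves at the inlet hematocrit
                for s in outs:
                    delta = max(delta, abs(s.haematocrit - inlet_H))
                    s.haematocrit = inlet_H
                continue
            q_in = sum(abs(s.flow_rate) for s in ins)
            flux_in = sum(abs(s.flow_rate) * s.haematocrit for s in ins)
            H_mix = flux_in / q_in if q_in > 0 else 0.0
            d_parent = max(2 * s.radius for s in ins)
            pairs = sorted(((s, abs(s.flow_rate)) for s in outs),
                           key=lambda p: -p[1])
            Hs = _split_outflows(q_in, H_mix, d_parent, pairs, law)
            for (s, _), H in zip(pairs, Hs):
                H = float(np.clip(H, 0.0, 1.0))
                delta = max(delta, abs(s.haematocrit - H))
                s.haematocrit = H
        return delta

    try:
        order = list(nx.topological_sort(dg))
        sweep(order)
        sweep(order)  # second pass settles inlets feeding inlets
    except nx.NetworkXUnfeasible:
        order = list(dg.nodes)
        for _ in range(max_sweeps):
            if sweep(order) < tol:
                break
        else:
            raise HemodynamicsError(
                f"hematocrit relaxation failed to converge in {max_sweeps} sweeps"
            )
    return net


# ---------------------------------------------------------------------------
# Perfusion, wall shear, adaptation
# ---------------------------------------------------------------------------


def update_perfusion(net: VesselNetwork, q_threshold: float = 0.0) -> VesselNetwork:
    """Flag segments with |Q| above threshold (um^3/s) as perfused."""
    for seg in net.segments.values():
        seg.perfused = bool(abs(seg.flow_rate) > q_threshold)
    return net


def compute_wall_shear(net: VesselNetwork) -> VesselNetwork:
    """Poiseuille wall shear stress tau_w = 4 mu |Q| / (pi R^3), in Pa."""
    for seg in net.segments.values():
        seg.wall_shear_stress = float(
            4.0 * seg.viscosity * abs(seg.flow_rate) / (np.pi * seg.radius**3)
        )
    return net


def adapt_radii(net: VesselNetwork, params: AdaptationParameters, dt: float) -> VesselNetwork:
    """Structural adaptation: one explicit step of radius remodelling.

    ``R <- clamp(R * exp(dt * k_growth * (log(tau_w / tau_ref + eps) - k_s)))``
    with eps = 1e-12 Pa guarding the logarithm.  Unperfused segments take
    the tau_w = 0 branch and shrink toward ``r_min``.
    """
    eps = 1e-12
    for seg in net.segments.values():
        tau = seg.wall_shear_stress if seg.perfused else 0.0
        stim = np.log(tau / params.tau_ref + eps) - params.shrink_tendency
        r = seg.radius * np.exp(dt * params.k_growth * stim)
        seg.radius = float(np.clip(r, params.r_min, params.r_max))
    return net
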