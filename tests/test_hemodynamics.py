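"""Network blood flow: Poiseuille solve, rheology, plasma skimming,
perfusion, wall shear, structural adaptation."""

import numpy as np
import pytest

from vascusim import fixtures
from vascusim.hemodynamics import (AdaptationParameters,
                                   FlowBoundaryConditions, HemodynamicsError,
                                   RheologyParameters, adapt_radii,
                                   assign_viscosity, compute_wall_shear,
                                   phase_separation_split,
                                   propagate_haematocrit, relative_viscosity,
                                   solve_flow, update_perfusion)
from vascusim.network import VesselNetwork


def solved_single_tube(mu=1e-3, radius=10.0, length=100.0, dp=1330.0):
    net = fixtures.single_tube(length=length, radius=radius,
                               inlet_pressure=2000.0 + dp,
                               outlet_pressure=2000.0)
    assign_viscosity(net, RheologyParameters(plasma_viscosity=mu, law="constant"))
    solve_flow(net, FlowBoundaryConditions.from_network(net))
    return net


class TestRheology:
    def test_cell_free_blood_has_plasma_viscosity(self):
        d = np.array([3.0, 10.0, 50.0, 300.0, 1000.0])
        np.testing.assert_allclose(relative_viscosity(d, 0.0), 1.0, atol=1e-12)

    def test_viscosity_increases_with_haematocrit(self):
        ds = np.linspace(4.0, 300.0, 20)
        hs = np.linspace(0.0, 0.8, 20)
        for d in ds:
            mu = relative_viscosity(d, hs)
            assert np.all(np.diff(mu) > 0), f"non-monotone at d={d}"

    def test_fahraeus_lindqvist_minimum_at_capillary_diameter(self):
        d = np.linspace(3.0, 1000.0, 5000)
        mu = relative_viscosity(d, 0.45)
        d_min = d[np.argmin(mu)]
        assert 5.0 <= d_min <= 15.0

    def test_invalid_haematocrit_rejected(self):
        net = fixtures.single_tube()
        net.segments[0].haematocrit = 1.5
        with pytest.raises(HemodynamicsError):
            assign_viscosity(net, RheologyParameters())


class TestFlowSolve:
    def test_single_tube_matches_poiseuille_closed_form(self):
        # independent one-line oracle: Q = pi R^4 dP / (8 mu L)
        R, L, mu, dp = 10.0, 100.0, 1e-3, 1330.0
        net = solved_single_tube(mu=mu, radius=R, length=L, dp=dp)
        q_oracle = np.pi * R**4 * dp / (8.0 * mu * L)
        assert net.segments[0].flow_rate == pytest.approx(q_oracle, rel=1e-10)

    def test_zero_pressure_drop_gives_zero_flow(self):
        net = solved_single_tube(dp=0.0)
        assert net.segments[0].flow_rate == 0.0

    def test_symmetric_bifurcation_splits_flow_equally(self):
        net = fixtures.y_bifurcation()
        assign_viscosity(net, RheologyParameters(law="constant"))
        solve_flow(net, FlowBoundaryConditions.from_network(net))
        q1 = net.segments[1].flow_rate
        q2 = net.segments[2].flow_rate
        assert q1 == pytest.approx(q2, rel=1e-12)
        assert q1 + q2 == pytest.approx(net.segments[0].flow_rate, rel=1e-12)

    def test_flow_conserved_at_interior_nodes_of_honeycomb(self):
        net = fixtures.hexagon_grid()
        assign_viscosity(net, RheologyParameters(law="constant"))
        solve_flow(net, FlowBoundaryConditions.from_network(net))
        adj = net.adjacency()
        max_q = max(abs(s.flow_rate) for s in net.segments.values())
        for nid, sids in adj.items():
            if net.nodes[nid].boundary_role != "none":
                continue
            net_flow = sum(
                s.flow_rate if s.node_ids[1] == nid else -s.flow_rate
                for s in (net.segments[x] for x in sids))
            assert abs(net_flow) <= 1e-8 * max_q

    def test_pressures_bounded_by_prescribed_values(self):
        net = fixtures.hexagon_grid()
        assign_viscosity(net, RheologyParameters(law="constant"))
        solve_flow(net, FlowBoundaryConditions.from_network(net))
        ps = [n.pressure for n in net.nodes.values()]
        assert min(ps) >= 2000.0 - 1e-9
        assert max(ps) <= 3330.0 + 1e-9

    def test_component_without_bc_gets_mean_pressure_and_no_flow(self):
        net = fixtures.single_tube()
        net.add_node((500, 0, 0))
        net.add_node((500, 0, 100))
        net.add_segment(2, 3, 10.0)
        assign_viscosity(net, RheologyParameters(law="constant"))
        with pytest.warns(UserWarning, match="component"):
            solve_flow(net, FlowBoundaryConditions.from_network(net))
        assert net.segments[1].flow_rate == 0.0
        assert net.nodes[2].pressure == pytest.approx(0.5 * (3330 + 2000))


class TestHaematocrit:
    def test_straight_chain_carries_inlet_haematocrit(self):
        net = VesselNetwork()
        net.add_node((0, 0, 0), boundary_role="inlet", boundary_pressure=3000.0)
        for i in range(1, 5):
            net.add_node((0, 0, 100.0 * i))
        net.nodes[4].boundary_role = "outlet"
        net.nodes[4].boundary_pressure = 2000.0
        for i in range(4):
            net.add_segment(i, i + 1, 10.0)
        assign_viscosity(net, RheologyParameters(law="constant"))
        solve_flow(net, FlowBoundaryConditions.from_network(net))
        propagate_haematocrit(net, inlet_H=0.45)
        for s in net.segments.values():
            assert s.haematocrit == pytest.approx(0.45, abs=1e-12)

    @pytest.mark.parametrize("law", ["logit", "proportional"])
    def test_symmetric_bifurcation_splits_cells_equally(self, law):
        net = fixtures.y_bifurcation()
        assign_viscosity(net, RheologyParameters(law="constant"))
        solve_flow(net, FlowBoundaryConditions.from_network(net))
        propagate_haematocrit(net, inlet_H=0.45, law=law)
        h1 = net.segments[1].haematocrit
        h2 = net.segments[2].haematocrit
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert h1 == pytest.approx(0.45, abs=1e-9)

    def test_phase_separation_favors_high_flow_branch(self):
        # the empirical law sends a disproportionate red-cell share to the
        # faster daughter and starves branches below the skimming threshold
        F = phase_separation_split(0.7, 0.45, 10.0, 10.0, 10.0)
        assert F > 0.7
        assert phase_separation_split(0.01, 0.45, 10.0, 10.0, 10.0) == 0.0
        assert phase_separation_split(0.99, 0.45, 10.0, 10.0, 10.0) == 1.0

    def test_red_cell_flux_conserved_at_divergent_nodes(self, rng):
        """Conservation oracle on random perturbed honeycombs (seed 1234)."""
        for trial in range(3):
            net = fixtures.hexagon_grid(n_cols=4, n_rows=3)
            for s in net.segments.values():
                s.radius = float(rng.uniform(4.0, 15.0))
            assign_viscosity(net, RheologyParameters(law="constant"))
            solve_flow(net, FlowBoundaryConditions.from_network(net))
            propagate_haematocrit(net, inlet_H=0.45)
            adj = net.adjacency()
            for nid, sids in adj.items():
                segs = [net.segments[x] for x in sids]
                ins = [s for s in segs
                       if (s.node_ids[1] == nid) == (s.flow_rate > 0)
                       and abs(s.flow_rate) > 1e-30]
                outs = [s for s in segs
                        if (s.node_ids[0] == nid) == (s.flow_rate > 0)
                        and abs(s.flow_rate) > 1e-30]
                if len(outs) < 2 or not ins:
                    continue
                if net.nodes[nid].boundary_role != "none":
                    continue
                flux_in = sum(abs(s.flow_rate) * s.haematocrit for s in ins)
                flux_out = sum(abs(s.flow_rate) * s.haematocrit for s in outs)
                assert flux_out == pytest.approx(flux_in, rel=1e-10, abs=1e-10)
            for s in net.segments.values():
                assert 0.0 <= s.haematocrit <= 1.0

    def test_invalid_inlet_haematocrit_rejected(self):
        net = solved_single_tube()
        with pytest.raises(HemodynamicsError):
            propagate_haematocrit(net, inlet_H=1.2)


class TestPerfusion:
    def test_flowing_segment_perfused_at_zero_threshold(self):
        net = solved_single_tube()
        update_perfusion(net, 0.0)
        assert net.segments[0].perfused

    def test_dead_end_branch_is_unperfused(self):
        # T-network: flow passes A-B-C; side branch B-D carries none
        net = VesselNetwork()
        net.add_node((0, 0, 0), boundary_role="inlet", boundary_pressure=3330.0)
        net.add_node((0, 0, 100))
        net.add_node((0, 0, 200), boundary_role="outlet", boundary_pressure=2000.0)
        net.add_node((100, 0, 100))
        net.add_segment(0, 1, 10)
        net.add_segment(1, 2, 10)
        net.add_segment(1, 3, 10)
        assign_viscosity(net, RheologyParameters(law="constant"))
        solve_flow(net, FlowBoundaryConditions.from_network(net))
        update_perfusion(net, 1.0)
        assert net.segments[0].perfused and net.segments[1].perfused
        assert not net.segments[2].perfused

    def test_high_threshold_unperfuses_everything(self):
        net = solved_single_tube()
        update_perfusion(net, 1e30)
        assert not any(s.perfused for s in net.segments.values())


class TestWallShear:
    def test_no_flow_no_shear(self):
        net = solved_single_tube(dp=0.0)
        compute_wall_shear(net)
        assert net.segments[0].wall_shear_stress == 0.0

    def test_shear_is_linear_in_flow(self):
        net = solved_single_tube()
        compute_wall_shear(net)
        tau1 = net.segments[0].wall_shear_stress
        net.segments[0].flow_rate *= 2
        compute_wall_shear(net)
        assert net.segments[0].wall_shear_stress == pytest.approx(2 * tau1)

    def test_single_tube_shear_equals_pressure_identity(self):
        # Poiseuille identity: tau_w = dP R / (2 L)
        R, L, dp = 10.0, 100.0, 1330.0
        net = solved_single_tube(radius=R, length=L, dp=dp)
        compute_wall_shear(net)
        assert net.segments[0].wall_shear_stress == pytest.approx(
            dp * R / (2 * L), rel=1e-10)


class TestAdaptation:
    def params(self, **kw):
        base = dict(k_growth=1e-4, shrink_tendency=1.0, tau_ref=1.0,
                    r_min=1.0, r_max=50.0)
        base.update(kw)
        return AdaptationParameters(**base)

    def test_fixed_point_at_reference_stimulus(self):
        p = self.params()
        net = fixtures.single_tube(radius=10.0)
        net.segments[0].perfused = True
        net.segments[0].wall_shear_stress = p.tau_ref * np.e**p.shrink_tendency
        adapt_radii(net, p, dt=1800.0)
        assert net.segments[0].radius == pytest.approx(10.0, rel=1e-12)

    def test_zero_shear_shrinks_to_lower_clamp(self):
        p = self.params()
        net = fixtures.single_tube(radius=10.0)
        net.segments[0].perfused = True
        net.segments[0].wall_shear_stress = 0.0
        adapt_radii(net, p, dt=1e9)
        assert net.segments[0].radius == p.r_min

    def test_single_growth_step_matches_formula(self):
        # k_s = 0, tau = e tau_ref, dt k = 0.1  ->  R *= e^0.1
        p = self.params(shrink_tendency=0.0, k_growth=0.1)
        net = fixtures.single_tube(radius=10.0)
        net.segments[0].perfused = True
        net.segments[0].wall_shear_stress = np.e * p.tau_ref
        adapt_radii(net, p, dt=1.0)
        assert net.segments[0].radius == pytest.approx(10.0 * np.e**0.1,
                                                       rel=1e-9)

    def test_unperfused_segment_shrinks_monotonically(self):
        p = self.params()
        net = fixtures.single_tube(radius=10.0)
        net.segments[0].perfused = False
        net.segments[0].wall_shear_stress = 100.0  # ignored when unperfused
        radii = []
        for _ in range(20):
            adapt_radii(net, p, dt=1800.0)
            radii.append(net.segments[0].radius)
        assert all(b <= a for a, b in zip(radii, radii[1:]))
        assert radii[-1] >= p.r_min

    def test_adaptation_monotone_in_shear(self):
        p = self.params()
        out = []
        for tau in (0.1, 1.0, 10.0, 100.0):
            net = fixtures.single_tube(radius=10.0)
            net.segments[0].perfused = True
            net.segments[0].wall_shear_stress = tau
            adapt_radii(net, p, dt=1800.0)
            out.append(net.segments[0].radius)
        assert all(b > a for a, b in zip(out, out[1:]))
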