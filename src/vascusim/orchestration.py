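"""Coupled multiscale simulations: vascularized tumor growth and corneal
micropocket angiogenesis.

``TumorSimulation`` advances, once per global time step (default 30 min):

1. map vessel occupancy and perfusion onto the lattice;
2. hemodynamics: viscosity -> flow -> hematocrit -> perfusion -> wall shear;
3. steady oxygen solve (perfused vessels source, cells consume);
4. cell cycling in 5-min ODE substeps, daughter placement, hypoxia/death;
5. steady VEGF solve (hypoxic cells release, vessels sink, decay);
6. sprout selection and one tip-migration move;
7. structural radius adaptation.

``CorneaSimulation`` solves the VEGF field once on the masked hemispherical
shell (pellet held at a fixed concentration), seeds a limbal vessel loop,
and then only sprouts and migrates tips against the frozen field with
geometric confinement.

Both are deterministic per seed: all randomness flows through one
``numpy.random.Generator``, so calling ``step()`` incrementally and
``run()`` to the same end time produce identical trajectories.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import hemodynamics as hemo
from .angiogenesis import limbal_initialization, migrate_tips, select_sprouts
from .cells import TUMOR, NORMAL, initialize_population
from .config import SimulationConfig, save_config
from .geometry import make_cuboid, make_cylinder, make_hemisphere_shell
from .grid import build_grid_from_bounding_box, write_field_vtk
from .network import (VesselNetwork, write_network_csv, write_network_vtk)
from .transport import (make_cornea_vegf_problem, make_oxygen_problem,
                        make_vegf_problem, solve_steady_state)

log = logging.getLogger("vascusim")

__all__ = ["TumorSimulation", "CorneaSimulation", "run_tumor", "run_cornea",
           "assign_axial_pressure_bcs"]


def assign_axial_pressure_bcs(net: VesselNetwork, axis: int,
                              inlet_pressure: float, outlet_pressure: float,
                              tol: float = 1.0) -> None:
    """Flag nodes on the low/high face along ``axis`` as inlet/outlet.

    A pressure drop applied across the domain depth: nodes within ``tol``
    (um) of the minimal coordinate become inlets at ``inlet_pressure``,
    of the maximal coordinate outlets at ``outlet_pressure``.
    """
    lo, hi = net.bounding_box()
    for node in net.nodes.values():
        x = node.position[axis]
        if x <= lo[axis] + tol:
            node.boundary_role = "inlet"
            node.boundary_pressure = float(inlet_pressure)
        elif x >= hi[axis] - tol:
            node.boundary_role = "outlet"
            node.boundary_pressure = float(outlet_pressure)


class _SimulationBase:
    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.step_index = 0
        self.n_pde_solves = 0
        self.summary_rows: list[dict] = []
        self._outdir: Path | None = None

    # -- output ----------------------------------------------------------
    def attach_output(self, outdir) -> None:
        self._outdir = Path(outdir)
        self._outdir.mkdir(parents=True, exist_ok=True)
        save_config(self.config, self._outdir / "config_resolved.yaml")

    def _maybe_snapshot(self) -> None:
        cad = self.config.output_cadence
        if self._outdir is None or cad <= 0 or self.step_index % cad != 0:
            return
        self.write_snapshot(self._outdir, f"step{self.step_index:04d}")

    def finalize(self):
        df = pd.DataFrame(self.summary_rows)
        if self._outdir is not None:
            df.to_csv(self._outdir / "summary.csv", index=False)
            self.write_snapshot(self._outdir, "final")
        return df

    def run(self, n_steps: int | None = None):
        if n_steps is None:
            n_steps = self.config.n_global_steps - self.step_index
        for _ in range(n_steps):
            t0 = time.perf_counter()
            self.step()
            log.info("step %d done in %.2f s", self.step_index,
                     time.perf_counter() - t0)
        return self.finalize()


class TumorSimulation(_SimulationBase):
    """Hybrid tumor growth on a (preprocessed) vessel network."""

    def __init__(self, config: SimulationConfig, network: VesselNetwork):
        super().__init__(config)
        self.network = network
        if not network.boundary_nodes("inlet") or not network.boundary_nodes("outlet"):
            assign_axial_pressure_bcs(network, axis=2,
                                      inlet_pressure=config.inlet_pressure,
                                      outlet_pressure=config.outlet_pressure)
        for nid in network.boundary_nodes("inlet"):
            if network.nodes[nid].boundary_pressure is None:
                network.nodes[nid].boundary_pressure = config.inlet_pressure
        for nid in network.boundary_nodes("outlet"):
            if network.nodes[nid].boundary_pressure is None:
                network.nodes[nid].boundary_pressure = config.outlet_pressure
        self.grid = build_grid_from_bounding_box(network, config.grid_spacing)
        lo, hi = network.bounding_box()
        center = 0.5 * (lo + hi)
        seed_region = make_cylinder(
            center=(center[0], center[1], lo[2]),
            radius=config.tumor_seed_diameter / 2.0,
            depth=max(hi[2] - lo[2], config.grid_spacing),
            axis=(0, 0, 1),
        )
        self.cells = initialize_population(self.grid, seed_region,
                                           config.cell_types, self.rng)
        self.oxygen = None
        self.vegf = None
        self.angio_params = config.angiogenesis.build()

    def step(self) -> None:
        cfg = self.config
        net = self.network
        # (1-2) hemodynamics on the current network
        hemo.assign_viscosity(net, cfg.rheology)
        bcs = hemo.FlowBoundaryConditions.from_network(net)
        hemo.solve_flow(net, bcs)
        hemo.propagate_haematocrit(net, cfg.inlet_haematocrit,
                                   law=cfg.phase_separation_law)
        hemo.update_perfusion(net, cfg.perfusion_threshold)
        hemo.compute_wall_shear(net)
        # (3) oxygen
        self.oxygen = solve_steady_state(
            make_oxygen_problem(self.grid, net, self.cells, cfg.oxygen))
        self.n_pde_solves += 1
        # (4) cells
        events = self.cells.advance_cycles(self.oxygen, cfg.dt_ode,
                                           cfg.n_substeps)
        self.cells.place_daughters(events, self.rng)
        self.cells.update_hypoxia_and_death(self.oxygen, cfg.dt_global)
        # (5) VEGF
        self.vegf = solve_steady_state(
            make_vegf_problem(self.grid, net, self.cells, cfg.vegf))
        self.n_pde_solves += 1
        # (6) angiogenesis, one move per global increment
        select_sprouts(net, self.vegf, cfg.dt_global, self.angio_params, self.rng)
        migrate_tips(net, self.vegf, None, cfg.dt_global, self.angio_params,
                     self.rng)
        # (7) structural adaptation
        if cfg.adaptation_enabled:
            hemo.adapt_radii(net, cfg.adaptation, cfg.dt_global)
        self.step_index += 1
        self._record()
        self._maybe_snapshot()

    def _record(self) -> None:
        net = self.network
        nseg = len(net.segments)
        nperf = sum(1 for s in net.segments.values() if s.perfused)
        self.summary_rows.append({
            "step": self.step_index,
            "time_s": self.step_index * self.config.dt_global,
            "n_tumor": self.cells.count(TUMOR),
            "n_normal": self.cells.count(NORMAL),
            "n_hypoxic": int(np.sum(self.cells.hypoxic)),
            "n_divisions": self.cells.n_divisions,
            "n_deaths": self.cells.n_deaths,
            "n_nodes": len(net.nodes),
            "n_segments": nseg,
            "perfused_fraction": nperf / nseg if nseg else 0.0,
            "total_length_um": net.total_length(),
            "n_tips": sum(1 for n in net.nodes.values() if n.is_tip),
            "mean_oxygen_nM": float(np.mean(self.oxygen.values)),
            "mean_vegf_nM": float(np.mean(self.vegf.values)),
        })

    def write_snapshot(self, outdir, tag: str) -> None:
        outdir = Path(outdir)
        write_network_csv(self.network, outdir / f"network_{tag}_nodes.csv",
                          outdir / f"network_{tag}_segments.csv")
        write_network_vtk(self.network, outdir / f"network_{tag}.vtk")
        self.cells.to_dataframe(step=self.step_index).to_csv(
            outdir / f"cells_{tag}.csv", index=False)
        if self.oxygen is not None:
            write_field_vtk(self.oxygen, outdir / f"oxygen_{tag}.vtk", "Oxygen")
        if self.vegf is not None:
            write_field_vtk(self.vegf, outdir / f"vegf_{tag}.vtk", "VEGF")


class CorneaSimulation(_SimulationBase):
    """Corneal micropocket assay: frozen pellet-driven VEGF field, sprouting
    from a limbal loop, confined tip migration."""

    def __init__(self, config: SimulationConfig):
        super().__init__(config)
        R, t = config.shell_outer_radius, config.shell_thickness
        self.shell = make_hemisphere_shell((0, 0, 0), R, t)
        side, depth = config.pellet_side, config.pellet_depth
        # pellet implanted at the dome pole, spanning the shell thickness
        self.pellet = make_cuboid((-side / 2.0, -side / 2.0, R - depth),
                                  (side, side, depth))
        self.grid = build_grid_from_bounding_box(self.shell, config.grid_spacing)
        self.vegf = solve_steady_state(make_cornea_vegf_problem(
            self.grid, self.shell, self.pellet, config.pellet_concentration,
            config.vegf.diffusivity, config.vegf.decay))
        self.n_pde_solves = 1  # solved once, frozen thereafter
        self.network = limbal_initialization(self.shell, config.limbus_nodes,
                                             config.limbus_radius)
        self.angio_params = config.angiogenesis.build()

    def step(self) -> None:
        cfg = self.config
        select_sprouts(self.network, self.vegf, cfg.dt_global,
                       self.angio_params, self.rng, geom=self.shell)
        migrate_tips(self.network, self.vegf, self.shell, cfg.dt_global,
                     self.angio_params, self.rng)
        self.step_index += 1
        self._record()
        self._maybe_snapshot()

    def containment_fraction(self) -> float:
        pos = self.network.node_positions()
        return float(np.mean(self.shell.contains_many(pos)))

    def _record(self) -> None:
        net = self.network
        self.summary_rows.append({
            "step": self.step_index,
            "time_s": self.step_index * self.config.dt_global,
            "n_nodes": len(net.nodes),
            "n_segments": len(net.segments),
            "n_tips": sum(1 for n in net.nodes.values() if n.is_tip),
            "total_length_um": net.total_length(),
            "containment_fraction": self.containment_fraction(),
        })

    def write_snapshot(self, outdir, tag: str) -> None:
        outdir = Path(outdir)
        write_network_csv(self.network, outdir / f"network_{tag}_nodes.csv",
                          outdir / f"network_{tag}_segments.csv")
        write_network_vtk(self.network, outdir / f"network_{tag}.vtk")
        if self.step_index == 0 or tag == "final":
            write_field_vtk(self.vegf, outdir / f"vegf_{tag}.vtk", "VEGF")


def run_tumor(config: SimulationConfig, network: VesselNetwork,
              outdir=None) -> tuple[TumorSimulation, pd.DataFrame]:
    """Run the tumor scenario to its configured end time."""
    sim = TumorSimulation(config, network)
    if outdir is not None:
        sim.attach_output(outdir)
    summary = sim.run()
    return sim, summary


def run_cornea(config: SimulationConfig, outdir=None):
    """Run the cornea scenario to its configured end time."""
    sim = CorneaSimulation(config)
    if outdir is not None:
        sim.attach_output(outdir)
    summary = sim.run()
    return sim, summary
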