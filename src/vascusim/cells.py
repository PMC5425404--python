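"""On-lattice cellular automaton for oxygen-dependent tissue growth.

Every lattice site holds at most one cell (cells and vessels may co-occupy
a site; only cell-cell exclusion is enforced).  Each cell carries a cycle
phase ``phi`` in [0, 1) advanced by the minimal oxygen-limited phase model

    d(phi)/dt = c / (T_min (c + c_phi))

so the division interval at constant oxygen c is ``T_min (c + c_phi) / c``:
``T_min`` at saturating oxygen, unbounded as c -> 0.  Cells whose local
oxygen falls below a hypoxia threshold release VEGF at a constant rate;
sustained exposure below a (lower) death threshold for longer than
``t_death`` removes the cell.  Tumor cells invade by replacing a Normal
neighbour when dividing with no empty site available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DomainGeometry
from .grid import RegularGrid, ScalarField

__all__ = ["CellTypeParameters", "CellLattice", "initialize_population",
           "EMPTY", "TUMOR", "NORMAL"]

EMPTY, TUMOR, NORMAL = 0, 1, 2
_TYPE_NAMES = {EMPTY: "Empty", TUMOR: "Tumor", NORMAL: "Normal"}

# von Neumann neighbourhood in 3D
_NEIGHBOR_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


@dataclass
class CellTypeParameters:
    """Per-type cycle/viability parameters.

    t_min: minimal cycle time (s) at saturating oxygen.
    c_phi: oxygen half-saturation for cycling (nM).
    c_hypoxia: oxygen below which the cell is hypoxic and releases VEGF (nM).
    c_death: oxygen below which the death clock accumulates (nM);
        must be < c_hypoxia.
    t_death: sustained time below c_death before apoptosis (s).
    k_vegf_release: constant VEGF release rate while hypoxic (nM/s).
    k_o2_consumption: linear oxygen consumption rate (1/s, positive).
    """

    t_min: float
    c_phi: float
    c_hypoxia: float
    c_death: float
    t_death: float
    k_vegf_release: float
    k_o2_consumption: float

    def __post_init__(self):
        if not self.c_death < self.c_hypoxia:
            raise ValueError("c_death must be below c_hypoxia")
        for name in ("t_min", "c_phi", "c_hypoxia", "c_death", "t_death"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class CellLattice:
    """Automaton state co-registered with a :class:`RegularGrid`.

    Arrays over sites: ``cell_type`` (EMPTY/TUMOR/NORMAL), ``phase``,
    ``hypoxia_clock`` (s below the death threshold), ``hypoxic`` flags.
    """

    def __init__(self, grid: RegularGrid,
                 params: dict[int, CellTypeParameters]):
        self.grid = grid
        self.params = params
        self.cell_type = np.full(grid.dims, EMPTY, dtype=np.int8)
        self.phase = np.zeros(grid.dims)
        self.hypoxia_clock = np.zeros(grid.dims)
        self.hypoxic = np.zeros(grid.dims, dtype=bool)
        self.n_divisions = 0
        self.n_deaths = 0

    # -- queries ---------------------------------------------------------
    def count(self, cell_type: int) -> int:
        return int(np.sum(self.cell_type == cell_type))

    def living_mask(self) -> np.ndarray:
        return self.cell_type != EMPTY

    def _per_type(self, attr: str) -> np.ndarray:
        out = np.zeros(self.grid.dims)
        for t, p in self.params.items():
            out[self.cell_type == t] = getattr(p, attr)
        return out

    # -- dynamics --------------------------------------------------------
    def advance_cycles(self, oxygen: ScalarField, dt_ode: float,
                       n_substeps: int) -> list[tuple[int, int, int]]:
        """Advance phases by explicit Euler; return division-event sites.

        The phase rate is re-evaluated each substep against the (frozen)
        oxygen field.  At most one division per cell per call: on crossing
        phi >= 1 the phase wraps and the site is recorded.
        """
        alive = self.living_mask()
        t_min = self._per_type("t_min")
        c_phi = self._per_type("c_phi")
        c = np.maximum(oxygen.values, 0.0)
        divided = np.zeros(self.grid.dims, dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(alive, c / (t_min * (c + c_phi)), 0.0)
        rate = np.nan_to_num(rate, nan=0.0)
        for _ in range(n_substeps):
            self.phase[alive] += dt_ode * rate[alive]
            wrap = alive & (self.phase >= 1.0) & ~divided
            self.phase[wrap] -= 1.0
            divided |= wrap
        self.phase = np.clip(self.phase, 0.0, np.nextafter(1.0, 0.0))
        return [tuple(int(v) for v in idx) for idx in np.argwhere(divided)]

    def place_daughters(self, events, rng: np.random.Generator) -> int:
        """Place daughters of division events; return placements made.

        Daughters go to a uniformly chosen empty von Neumann neighbour; a
        Tumor parent with no empty neighbour replaces a uniformly chosen
        Normal neighbour (invasion); otherwise the division aborts.
        """
        events = list(events)
        rng.shuffle(events)
        dims = np.array(self.grid.dims)
        placed = 0
        for site in events:
            parent_type = int(self.cell_type[site])
            if parent_type == EMPTY:
                continue  # parent died earlier this step
            nbrs = np.asarray(site) + _NEIGHBOR_OFFSETS
            ok = np.all((nbrs >= 0) & (nbrs < dims), axis=1)
            nbrs = nbrs[ok]
            types = self.cell_type[tuple(nbrs.T)]
            empty = nbrs[types == EMPTY]
            if len(empty):
                target = empty[rng.integers(len(empty))]
            elif parent_type == TUMOR:
                normals = nbrs[types == NORMAL]
                if len(normals) == 0:
                    continue
                target = normals[rng.integers(len(normals))]
            else:
                continue
            t = tuple(int(v) for v in target)
            self.cell_type[t] = parent_type
            self.phase[t] = 0.0
            self.hypoxia_clock[t] = 0.0
            self.hypoxic[t] = False
            placed += 1
            self.n_divisions += 1
        return placed

    def update_hypoxia_and_death(self, oxygen: ScalarField,
                                 dt_global: float) -> int:
        """Update hypoxia flags and death clocks; remove dead cells."""
        alive = self.living_mask()
        c = oxygen.values
        c_hyp = self._per_type("c_hypoxia")
        c_death = self._per_type("c_death")
        t_death = self._per_type("t_death")
        self.hypoxic = alive & (c < c_hyp)
        below = alive & (c < c_death)
        self.hypoxia_clock[below] += dt_global
        self.hypoxia_clock[alive & ~below] = 0.0
        dead = alive & (self.hypoxia_clock > t_death)
        n = int(np.sum(dead))
        self.cell_type[dead] = EMPTY
        self.phase[dead] = 0.0
        self.hypoxia_clock[dead] = 0.0
        self.hypoxic[dead] = False
        self.n_deaths += n
        return n

    # -- coupling maps ---------------------------------------------------
    def vegf_release_map(self) -> ScalarField:
        """Zeroth-order VEGF source: release rate at hypoxic-cell sites."""
        out = np.where(self.hypoxic, self._per_type("k_vegf_release"), 0.0)
        return ScalarField(self.grid, out)

    def oxygen_consumption_map(self) -> ScalarField:
        """Signed linear oxygen rate: -k_O2(type) at living-cell sites."""
        out = np.where(self.living_mask(), -self._per_type("k_o2_consumption"), 0.0)
        return ScalarField(self.grid, out)

    # -- export ----------------------------------------------------------
    def to_dataframe(self, step: int | None = None):
        import pandas as pd

        idx = np.argwhere(self.living_mask())
        rows = {
            "site_i": idx[:, 0], "site_j": idx[:, 1], "site_k": idx[:, 2],
            "type": [_TYPE_NAMES[int(self.cell_type[tuple(s)])] for s in idx],
            "phase": [float(self.phase[tuple(s)]) for s in idx],
            "state": [
                "hypoxic" if self.hypoxic[tuple(s)] else "cycling" for s in idx
            ],
        }
        df = pd.DataFrame(rows)
        if step is not None:
            df.insert(0, "step", step)
        return df


def initialize_population(grid: RegularGrid, tumor_region: DomainGeometry | None,
                          params: dict[int, CellTypeParameters],
                          rng: np.random.Generator) -> CellLattice:
    """Fill every lattice site with a cell; Tumor inside the seed region.

    Initial phases are uniform on [0, 1) so divisions stagger rather than
    synchronize across the population.
    """
    lat = CellLattice(grid, params)
    lat.cell_type[...] = NORMAL
    if tumor_region is not None:
        pts = grid.site_positions()
        inside = tumor_region.contains_many(pts).reshape(grid.dims)
        lat.cell_type[inside] = TUMOR
    lat.phase = rng.random(grid.dims)
    return lat
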