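"""Steady-state reaction-diffusion transport on a regular grid.

Oxygen and VEGF in the extravascular space obey

    D lap(c) + rho (c_b - c) + k_lin c + k_const - lambda c = 0

where ``rho`` is an effective vascular permeability, nonzero only on
lattice sites occupied by (perfused, for oxygen) vessels; ``c_b`` is the
vascular concentration; ``k_lin`` is a signed per-site linear rate
(consumption negative); ``k_const`` is a zeroth-order per-site source used
for constant hypoxic VEGF release; and ``lambda`` is a natural decay rate,
relevant for VEGF.  The equation is discretized with the 7-point stencil,
zero-flux (reflected-ghost) conditions at grid faces and at inactive
neighbours of a masked domain, and optional Dirichlet sites (the cornea
pellet).  A steady solve is performed once per coupling step; all time
dependence enters through the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DomainGeometry
from .grid import RegularGrid, ScalarField, build_grid_from_bounding_box
from .network import VesselNetwork, map_occupancy

__all__ = [
    "TransportProblem",
    "solve_steady_state",
    "make_oxygen_problem",
    "make_vegf_problem",
    "make_cornea_vegf_problem",
    "sample_field",
    "field_gradient",
    "build_grid_from_bounding_box",
]


class TransportError(RuntimeError):
    pass


@dataclass
class TransportProblem:
    """Coefficients of one steady reaction-diffusion solve.

    Per-site arrays have the grid's (nx, ny, nz) shape.  ``dirichlet_mask``
    marks sites whose value is imposed from ``dirichlet_values``.
    """

    grid: RegularGrid
    diffusivity: float  # um^2/s
    rho: np.ndarray  # 1/s, exchange coefficient, >= 0
    c_b: np.ndarray  # nM, vascular concentration per occupied site
    k_lin: np.ndarray  # 1/s, signed linear rate (consumption < 0)
    k_const: np.ndarray  # nM/s, zeroth-order source
    decay: float = 0.0  # lambda, 1/s
    mask: np.ndarray | None = None  # active-site flags; None = all active
    dirichlet_mask: np.ndarray | None = None
    dirichlet_values: np.ndarray | None = None

    @classmethod
    def homogeneous(cls, grid: RegularGrid, diffusivity: float, decay: float = 0.0):
        z = np.zeros(grid.dims)
        return cls(grid, diffusivity, z.copy(), z.copy(), z.copy(), z.copy(), decay)

    def validate(self) -> None:
        if self.diffusivity <= 0:
            raise TransportError("diffusivity must be positive")
        if self.decay < 0:
            raise TransportError("decay rate must be non-negative")
        if np.any(self.rho < 0):
            raise TransportError("exchange coefficient rho must be non-negative")
        for name in ("rho", "c_b", "k_lin", "k_const"):
            a = getattr(self, name)
            if a.shape != self.grid.dims:
                raise TransportError(f"{name} shape {a.shape} != grid dims")
        if self.dirichlet_mask is not None and self.mask is not None:
            if np.any(self.dirichlet_mask & ~self.mask):
                raise TransportError("Dirichlet sites must be active sites")


def _assemble(problem: TransportProblem):
    """Assemble (A, b) for the 7-point discretization.

    Rows follow the full grid in C order; inactive sites get identity rows
    with zero value, Dirichlet sites identity rows with their value.
    Zero-flux closure uses a reflected (mirror) ghost: where a neighbour is
    missing along an axis and the opposite one exists, the coupling to the
    existing neighbour is doubled.  This even-reflection closure keeps the
    scheme second-order accurate at Neumann boundaries (at the cost of a
    mildly nonsymmetric matrix).
    """
    grid = problem.grid
    n = grid.n_sites
    h2 = grid.spacing**2
    D = problem.diffusivity

    active = (problem.mask if problem.mask is not None
              else np.ones(grid.dims, bool)).astype(bool)
    diri = (problem.dirichlet_mask if problem.dirichlet_mask is not None
            else np.zeros(grid.dims, bool)).astype(bool)
    dval = (problem.dirichlet_values if problem.dirichlet_values is not None
            else np.zeros(grid.dims))

    react = problem.rho + problem.decay - problem.k_lin
    if np.any(react[active] < -1e-15):
        import warnings

        warnings.warn("rho + lambda - k_lin < 0 at active sites; "
                      "the discrete operator may lose definiteness")

    lin = np.arange(n).reshape(grid.dims)
    interior = active & ~diri
    rows, cols, vals = [], [], []

    def neighbour_ids(axis, sign):
        """For every site, linear id of its (axis, sign) neighbour or -1."""
        ids = np.full(grid.dims, -1, dtype=int)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if sign > 0:
            dst[axis] = slice(0, grid.dims[axis] - 1)
            src[axis] = slice(1, grid.dims[axis])
        else:
            dst[axis] = slice(1, grid.dims[axis])
            src[axis] = slice(0, grid.dims[axis] - 1)
        ids[tuple(dst)] = lin[tuple(src)]
        # a neighbour outside the active mask counts as missing
        flat = ids.ravel()
        exists = flat >= 0
        exists[exists] &= active.ravel()[flat[exists]]
        flat[~exists] = -1
        return flat

    for axis in range(3):
        plus = neighbour_ids(axis, +1)
        minus = neighbour_ids(axis, -1)
        here = interior.ravel()
        for nbr, opp in ((plus, minus), (minus, plus)):
            ok = here & (nbr >= 0)
            f = np.nonzero(ok)[0]
            t = nbr[f]
            w = np.where(opp[f] >= 0, 1.0, 2.0)  # mirror ghost doubles
            rows.append(f)
            cols.append(t)
            vals.append(-w * D / h2)
            rows.append(f)
            cols.append(f)
            vals.append(w * D / h2)

    idx = np.arange(n)
    rows.append(idx)
    cols.append(idx)
    vals.append(np.where(interior.ravel(), react.ravel(), 1.0))

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    b = np.where(
        interior.ravel(),
        (problem.rho * problem.c_b + problem.k_const).ravel(),
        np.where(diri.ravel(), dval.ravel(), 0.0),
    )
    # eliminate couplings into Dirichlet columns: move to RHS
    if diri.any():
        dvec = np.where(diri.ravel(), dval.ravel(), 0.0)
        contrib = A @ dvec
        contrib[~interior.ravel()] = 0.0
        b = b - contrib
        A = A.tocoo()
        keep = ~(interior.ravel()[A.row] & diri.ravel()[A.col])
        A = sp.csr_matrix((A.data[keep], (A.row[keep], A.col[keep])), shape=(n, n))
    return A, b


def solve_steady_state(problem: TransportProblem, rtol: float = 1e-10,
                       direct_max: int = 400_000) -> ScalarField:
    """Solve the steady reaction-diffusion problem.

    Direct sparse factorization up to ``direct_max`` unknowns, BiCGSTAB
    (Jacobi preconditioned, relative tolerance ``rtol``, at most 10 N
    iterations) beyond.  Raises on non-convergence and on solutions more
    negative than round-off allows — the continuous problem obeys a
    maximum principle, so a materially negative concentration indicates a
    defective coefficient set, not something to clip.
    """
    problem.validate()
    A, b = _assemble(problem)
    n = A.shape[0]
    if n <= direct_max:
        c = spla.spsolve(A.tocsc(), b)
    else:
        M = sp.diags(1.0 / A.diagonal())
        c, info = spla.bicgstab(A, b, rtol=rtol, maxiter=10 * n, M=M)
        if info != 0:
            res = float(np.linalg.norm(A @ c - b) / max(np.linalg.norm(b), 1e-300))
            raise TransportError(f"BiCGSTAB failed (info={info}, residual={res:.3e})")
    cmax = float(np.max(np.abs(c))) if n else 0.0
    if cmax > 0 and float(np.min(c)) < -1e-9 * cmax:
        raise TransportError(f"negative concentration {np.min(c):.3e} beyond tolerance")
    return ScalarField(problem.grid, c.reshape(problem.grid.dims))


# ---------------------------------------------------------------------------
# Problem factories
# ---------------------------------------------------------------------------


def make_oxygen_problem(grid: RegularGrid, net: VesselNetwork, cell_lattice,
                        params) -> TransportProblem:
    """Oxygen: perfused vessels source at c_b, living cells consume linearly.

    ``params`` needs: diffusivity, rho (permeability 1/s), c_b (nM);
    per-type consumption comes from the cell lattice's consumption map.
    """
    p = TransportProblem.homogeneous(grid, params.diffusivity, decay=0.0)
    occ = map_occupancy(net, grid, perfused_only=True).values
    p.rho = params.vessel_permeability * occ
    p.c_b = params.vascular_concentration * occ
    if cell_lattice is not None:
        p.k_lin = cell_lattice.oxygen_consumption_map().values
    return p


def make_vegf_problem(grid: RegularGrid, net: VesselNetwork, cell_lattice,
                      params) -> TransportProblem:
    """VEGF: hypoxic cells release at constant rate, vessels act as sinks
    (exchange toward a vascular concentration of zero), field decays."""
    p = TransportProblem.homogeneous(grid, params.diffusivity, decay=params.decay)
    occ = map_occupancy(net, grid, perfused_only=False).values
    p.rho = params.vessel_permeability * occ
    p.c_b = np.zeros(grid.dims)
    if cell_lattice is not None:
        p.k_const = cell_lattice.vegf_release_map().values
    return p


def make_cornea_vegf_problem(grid: RegularGrid, shell: DomainGeometry,
                             pellet: DomainGeometry, c_pellet: float,
                             diffusivity: float, decay: float) -> TransportProblem:
    """Cornea: diffusion-decay on the masked shell with the pellet held at a
    fixed concentration (Dirichlet); no vessel or cell terms."""
    p = TransportProblem.homogeneous(grid, diffusivity, decay=decay)
    pts = grid.site_positions()
    in_shell = shell.contains_many(pts).reshape(grid.dims)
    in_pellet = pellet.contains_many(pts).reshape(grid.dims) & in_shell
    if not in_shell.any():
        raise TransportError("grid does not intersect the shell")
    if not in_pellet.any():
        raise TransportError("no grid site falls inside the pellet")
    # stair-stepping a thin curved shell can strand face-disconnected site
    # islands; keep only the components reachable from the pellet so the
    # decay-free problem stays well posed
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(in_shell, structure=struct)
    keep = np.unique(labels[in_pellet])
    in_shell = in_shell & np.isin(labels, keep[keep > 0])
    in_pellet = in_pellet & in_shell
    p.mask = in_shell
    p.dirichlet_mask = in_pellet
    p.dirichlet_values = np.where(in_pellet, float(c_pellet), 0.0)
    return p


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _interpolator(field: ScalarField, values: np.ndarray):
    from scipy.interpolate import RegularGridInterpolator

    return RegularGridInterpolator(field.grid.axes(), values, method="linear",
                                   bounds_error=True)


def sample_field(field: ScalarField, p) -> float:
    """Trilinear interpolation of the field at an arbitrary point (um).

    Points outside the grid raise ``ValueError``.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    return float(_interpolator(field, field.values)(p)[0])


def field_gradient(field: ScalarField, p) -> np.ndarray:
    """Field gradient (nM/um) at a point: central differences on the grid
    (one-sided at faces) interpolated trilinearly."""
    h = field.grid.spacing
    comps = []
    for axis in range(3):
        if field.grid.dims[axis] == 1:
            comps.append(np.zeros(field.grid.dims))
        else:
            comps.append(np.gradient(field.values, h, axis=axis))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    return np.array([float(_interpolator(field, g)(p)[0]) for g in comps])
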