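"""Regular lattices and per-site scalar fields.

The same axis-aligned lattice carries the cellular automaton, the
finite-difference transport solves, and network characterization maps.
Site ``(i, j, k)`` sits at ``origin + h * (i, j, k)`` (0-based indices);
its voxel is the cube of side ``h`` centred on the site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegularGrid", "ScalarField", "build_grid_from_bounding_box"]


@dataclass(frozen=True)
class RegularGrid:
    """Axis-aligned lattice: origin (um), spacing h (um), dims (nx, ny, nz)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(int(n) < 1 for n in self.dims):
            raise ValueError("grid dims must each be >= 1")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(n) for n in self.dims))

    @property
    def n_sites(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def site_position(self, i: int, j: int, k: int) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.array([i, j, k], float)

    def site_positions(self) -> np.ndarray:
        """(n_sites, 3) array of site centres in C (i-major) order."""
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
        return np.asarray(self.origin) + self.spacing * idx

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        h = self.spacing
        return tuple(o[a] + h * np.arange(self.dims[a]) for a in range(3))

    def upper_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.array(self.dims) - 1)


@dataclass
class ScalarField:
    """One scalar per lattice site, stored as an (nx, ny, nz) array."""

    grid: RegularGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            self.values = self.values.reshape(self.grid.dims)

    @classmethod
    def zeros(cls, grid: RegularGrid) -> "ScalarField":
        return cls(grid, np.zeros(grid.dims))

    @classmethod
    def full(cls, grid: RegularGrid, value: float) -> "ScalarField":
        return cls(grid, np.full(grid.dims, float(value)))

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())


def write_field_vtk(field: ScalarField, path, name: str = "value") -> None:
    """Write a field as legacy VTK structured-points ASCII."""
    from pathlib import Path

    g = field.grid
    lines = [
        "# vtk DataFile Version 4.2",
        "vascusim scalar field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {g.dims[0]} {g.dims[1]} {g.dims[2]}",
        f"ORIGIN {g.origin[0]:.9g} {g.origin[1]:.9g} {g.origin[2]:.9g}",
        f"SPACING {g.spacing:.9g} {g.spacing:.9g} {g.spacing:.9g}",
        f"POINT_DATA {g.n_sites}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    # VTK structured points run x fastest: transpose from (i, j, k) C order
    vals = field.values.transpose(2, 1, 0).ravel()
    lines.extend(f"{v:.9g}" for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_csv(field: ScalarField, path) -> None:
    """Write a field as flat CSV ``i,j,k,value`` with a grid-metadata header."""
    from pathlib import Path

    g = field.grid
    out = [
        f"# origin_um={g.origin[0]},{g.origin[1]},{g.origin[2]} "
        f"spacing_um={g.spacing} dims={g.dims[0]}x{g.dims[1]}x{g.dims[2]}",
        "i,j,k,value",
    ]
    nx, ny, nz = g.dims
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out.append(f"{i},{j},{k},{field.values[i, j, k]!r}")
    Path(path).write_text("\n".join(out) + "\n")


def build_grid_from_bounding_box(obj, h: float) -> RegularGrid:
    """Grid covering the bounding box of a network or geometry.

    Sites per axis follow ``ceil(extent / h) + 1`` so the lattice always
    covers the box (the last site may lie beyond the upper bound).
    """
    if h <= 0:
        raise ValueError("grid spacing must be positive")
    if hasattr(obj, "bounding_box"):
        lo, hi = obj.bounding_box()
    else:
        lo, hi = obj
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if lo.shape != (3,) or hi.shape != (3,) or np.any(hi < lo):
        raise ValueError("invalid bounding box")
    extent = hi - lo
    # tiny epsilon so exact multiples of h do not gain a spurious site
    dims = tuple(int(np.ceil(e / h - 1e-12)) + 1 for e in extent)
    return RegularGrid(tuple(lo), float(h), dims)
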