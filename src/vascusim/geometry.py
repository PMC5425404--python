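"""Implicit 3D region primitives.

Regions are *closed* point sets in a right-handed Cartesian frame with
lengths in micrometres.  They are used to extract regions of interest from
vessel networks, to mask finite-difference grids, and to confine migrating
vessel tips: :meth:`DomainGeometry.project_inside` returns the nearest point
of the region, so a tip that steps outside is placed back on the surface.

Three kinds are supported:

``cylinder``
    Finite solid cylinder given by a base-centre point, a unit axis, a
    radius, and a depth.  The region is ``0 <= (p-center)·axis <= depth``
    and radial distance ``<= radius``.
``hemisphere_shell``
    The upper half (``z >= 0`` relative to the centre) of a spherical shell
    of outer radius ``R`` and thickness ``t``:
    ``R - t <= |p - center| <= R``.  Models a cornea-like curved tissue.
``cuboid``
    Axis-aligned box given by a corner and side lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "DomainGeometry",
    "make_cylinder",
    "make_hemisphere_shell",
    "make_cuboid",
]

GeometryKind = Literal["cylinder", "hemisphere_shell", "cuboid"]


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point has non-finite coordinates: {a}")
    return a


@dataclass(frozen=True)
class DomainGeometry:
    """An implicit closed 3D region (cylinder, hemispherical shell, cuboid)."""

    kind: GeometryKind
    params: dict = field(default_factory=dict)

    # -- membership ------------------------------------------------------
    def contains(self, p) -> bool:
        """Closed-region membership test; boundary points are inside."""
        x = _as_point(p)
        tol = 1e-9
        if self.kind == "cylinder":
            c, axis = self.params["center"], self.params["axis"]
            r, depth = self.params["radius"], self.params["depth"]
            d = x - c
            t = float(d @ axis)
            if t < -tol or t > depth + tol:
                return False
            radial = d - t * axis
            return float(np.linalg.norm(radial)) <= r + tol
        if self.kind == "hemisphere_shell":
            c = self.params["center"]
            R, t = self.params["outer_radius"], self.params["thickness"]
            d = x - c
            if d[2] < -tol:
                return False
            rr = float(np.linalg.norm(d))
            return R - t - tol <= rr <= R + tol
        if self.kind == "cuboid":
            corner, sides = self.params["corner"], self.params["sides"]
            rel = x - corner
            return bool(np.all(rel >= -tol) and np.all(rel <= sides + tol))
        raise ValueError(f"unsupported geometry kind {self.kind!r}")

    def contains_many(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized membership for an (n, 3) array of points."""
        pts = np.asarray(pts, dtype=float)
        tol = 1e-9
        if self.kind == "cylinder":
            c, axis = self.params["center"], self.params["axis"]
            r, depth = self.params["radius"], self.params["depth"]
            d = pts - c
            t = d @ axis
            radial = d - t[:, None] * axis
            return (
                (t >= -tol)
                & (t <= depth + tol)
                & (np.linalg.norm(radial, axis=1) <= r + tol)
            )
        if self.kind == "hemisphere_shell":
            c = self.params["center"]
            R, th = self.params["outer_radius"], self.params["thickness"]
            d = pts - c
            rr = np.linalg.norm(d, axis=1)
            return (d[:, 2] >= -tol) & (rr >= R - th - tol) & (rr <= R + tol)
        if self.kind == "cuboid":
            corner, sides = self.params["corner"], self.params["sides"]
            rel = pts - corner
            return np.all(rel >= -tol, axis=1) & np.all(rel <= sides + tol, axis=1)
        raise ValueError(f"unsupported geometry kind {self.kind!r}")

    # -- projection ------------------------------------------------------
    def project_inside(self, p) -> np.ndarray:
        """Nearest point of the region (identity on interior points)."""
        x = _as_point(p)
        if self.kind == "cylinder":
            c, axis = self.params["center"], self.params["axis"]
            r, depth = self.params["radius"], self.params["depth"]
            d = x - c
            t = float(np.clip(d @ axis, 0.0, depth))
            radial = d - float(d @ axis) * axis
            rn = float(np.linalg.norm(radial))
            if rn > r:
                radial = radial * (r / rn)
            return c + t * axis + radial
        if self.kind == "hemisphere_shell":
            c = self.params["center"]
            R, th = self.params["outer_radius"], self.params["thickness"]
            d = x - c
            if d[2] >= 0.0:
                rr = float(np.linalg.norm(d))
                if rr == 0.0:
                    return c + np.array([0.0, 0.0, R - th])
                return c + d * (np.clip(rr, R - th, R) / rr)
            # below the equatorial plane: nearest point lies on the flat
            # equatorial annulus z = 0, R-t <= rho <= R
            h = d.copy()
            h[2] = 0.0
            rho = float(np.linalg.norm(h))
            if rho == 0.0:
                return c + np.array([R - th, 0.0, 0.0])
            return c + h * (np.clip(rho, R - th, R) / rho)
        if self.kind == "cuboid":
            corner, sides = self.params["corner"], self.params["sides"]
            return corner + np.clip(x - corner, 0.0, sides)
        raise ValueError(f"unsupported geometry kind {self.kind!r}")

    # -- misc ------------------------------------------------------------
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lower corner, upper corner)."""
        if self.kind == "cylinder":
            c, axis = self.params["center"], self.params["axis"]
            r, depth = self.params["radius"], self.params["depth"]
            # extent of a cylinder along each coordinate axis
            e = r * np.sqrt(np.clip(1.0 - axis**2, 0.0, 1.0))
            ends = np.stack([c, c + depth * axis])
            lo = ends.min(axis=0) - e
            hi = ends.max(axis=0) + e
            return lo, hi
        if self.kind == "hemisphere_shell":
            c = self.params["center"]
            R = self.params["outer_radius"]
            return (
                c + np.array([-R, -R, 0.0]),
                c + np.array([R, R, R]),
            )
        if self.kind == "cuboid":
            corner, sides = self.params["corner"], self.params["sides"]
            return corner.copy(), corner + sides
        raise ValueError(f"unsupported geometry kind {self.kind!r}")


def make_cylinder(center, radius: float, depth: float, axis=(0.0, 0.0, 1.0)) -> DomainGeometry:
    """Finite closed cylinder from its base centre along ``axis``."""
    if radius <= 0 or depth <= 0:
        raise ValueError("cylinder radius and depth must be positive")
    a = np.asarray(axis, dtype=float)
    n = float(np.linalg.norm(a))
    if n == 0.0:
        raise ValueError("cylinder axis must be a nonzero vector")
    return DomainGeometry(
        "cylinder",
        {
            "center": _as_point(center),
            "axis": a / n,
            "radius": float(radius),
            "depth": float(depth),
        },
    )


def make_hemisphere_shell(center, outer_radius: float, thickness: float) -> DomainGeometry:
    """Upper-half spherical shell (dome in z >= 0 through ``center``)."""
    if outer_radius <= 0 or thickness <= 0:
        raise ValueError("outer_radius and thickness must be positive")
    if thickness >= outer_radius:
        raise ValueError("shell thickness must be smaller than the outer radius")
    return DomainGeometry(
        "hemisphere_shell",
        {
            "center": _as_point(center),
            "outer_radius": float(outer_radius),
            "thickness": float(thickness),
        },
    )


def make_cuboid(corner, sides) -> DomainGeometry:
    """Axis-aligned box from its low corner and (sx, sy, sz) side lengths."""
    s = np.asarray(sides, dtype=float)
    if s.shape != (3,) or np.any(s <= 0):
        raise ValueError("cuboid sides must be three positive lengths")
    return DomainGeometry("cuboid", {"corner": _as_point(corner), "sides": s})
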