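"""Parametric aortic-root geometry.

The aortic root is described by the scalar parameters echo measures at peak
T-wave (maximum opening): annulus base radius Rb, commissure radius Rc,
sinus height Hs, the sinus-of-Valsalva bulge (maximum radius Ds at axial
location Zs) and the leaflet dimensions. Tri-leaflet symmetry means one
sixth of the root (a 60 degree wedge, half a leaflet) defines the whole.

Only one scalar feeds the downstream flow model: the annulus area pi Rb^2,
used as the valve's maximum effective orifice area. The revolved sinus wall
can additionally be meshed and exported for inspection; leaflet surfaces are
deliberately not reconstructed (no printed free-edge curve exists), and the
leaflet dimensions are validated metadata only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, ValidationError

WEDGE_ANGLE_DEG = 60.0


@dataclass(frozen=True)
class ValveGeometryParams:
    """Scalar aortic-root geometry, all lengths in millimetres."""

    base_radius: float  # Rb
    commissure_radius: float  # Rc
    valve_height: float  # H
    sinus_height: float  # Hs
    leaflet_height: float  # Lh
    leaflet_free_edge: float  # Lf
    sinus_max_radius: float  # Ds
    sinus_max_location: float  # Zs
    leaflet_thickness: float = 0.6

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not self.sinus_max_location < self.sinus_height:
            raise ValidationError("sinus maximum must lie below the sinus top (Zs < Hs)")
        if self.sinus_max_radius < max(self.base_radius, self.commissure_radius):
            raise ValidationError("sinus must bulge outward (Ds >= Rb and Ds >= Rc)")
        limit = 2.0 * self.sinus_max_radius
        if self.leaflet_height >= limit or self.leaflet_free_edge >= limit:
            raise ValidationError("leaflet dimensions exceed the root diameter")


@dataclass(frozen=True)
class ValveMesh:
    """Triangulated surface wedge of the revolved sinus wall.

    Vertices are in millimetres; replicating the wedge ``360 / wedge_angle``
    times about the z-axis tiles the full root.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    wedge_angle: float  # degrees

    @property
    def radial_coordinates(self) -> np.ndarray:
        return np.hypot(self.vertices[:, 0], self.vertices[:, 1])

    def replicate(self, copies: int) -> "ValveMesh":
        """Rotate-copy the wedge ``copies`` times about the z-axis."""
        if copies < 1:
            raise DomainError("need at least one copy")
        verts, faces = [], []
        n = len(self.vertices)
        for k in range(copies):
            a = math.radians(k * self.wedge_angle)
            rot = np.array(
                [
                    [math.cos(a), -math.sin(a), 0.0],
                    [math.sin(a), math.cos(a), 0.0],
                    [0.0, 0.0, 1.0],
                ]
            )
            verts.append(self.vertices @ rot.T)
            faces.append(self.faces + k * n)
        return ValveMesh(
            np.vstack(verts), np.vstack(faces), wedge_angle=self.wedge_angle * copies
        )


def annulus_area(params: ValveGeometryParams) -> float:
    """Annulus area pi Rb^2 in m^2; the flow model's maximum orifice area."""
    radius_m = params.base_radius * 1e-3
    return math.pi * radius_m**2


def _profile_interpolator(params: ValveGeometryParams) -> PchipInterpolator:
    z = np.array([0.0, params.sinus_max_location, params.sinus_height])
    r = np.array(
        [params.base_radius, params.sinus_max_radius, params.commissure_radius]
    )
    # Monotone piecewise-cubic: C1, no overshoot, zero slope at the interior
    # maximum, so the bulge peaks exactly at Zs.
    return PchipInterpolator(z, r)


def sinus_profile(params: ValveGeometryParams, z) -> np.ndarray | float:
    """Sinus-wall radius (mm) at axial position ``z`` (mm), 0 <= z <= Hs.

    A monotone cubic through the three measured anchors: Rb at the annulus,
    Ds at the bulge (z = Zs), Rc at the commissures (z = Hs).
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0) or np.any(z_arr > params.sinus_height):
        raise DomainError(f"z must lie in [0, {params.sinus_height}] mm")
    out = _profile_interpolator(params)(z_arr)
    return float(out) if np.isscalar(z) else out


def build_wedge_mesh(params: ValveGeometryParams, resolution: int = 32) -> ValveMesh:
    """Surface mesh of the 60-degree sinus-wall wedge.

    ``resolution`` is the number of segments along each edge (axial and
    circumferential); the mesh is a structured grid of the revolved profile
    split into triangles, deterministic for fixed inputs.
    """
    if resolution < 4:
        raise DomainError("resolution must be at least 4 segments per edge")
    z = np.linspace(0.0, params.sinus_height, resolution + 1)
    r = _profile_interpolator(params)(z)
    theta = np.radians(np.linspace(0.0, WEDGE_ANGLE_DEG, resolution + 1))
    zz, tt = np.meshgrid(z, theta, indexing="ij")
    rr = np.broadcast_to(r[:, None], zz.shape)
    vertices = np.column_stack(
        [(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel(), zz.ravel()]
    )
    ncol = resolution + 1
    faces = []
    for i in range(resolution):
        for j in range(resolution):
            a = i * ncol + j
            b = a + 1
            c = a + ncol
            d = c + 1
            faces.append((a, b, d))  # consistent outward orientation
            faces.append((a, d, c))
    return ValveMesh(vertices, np.asarray(faces, dtype=int), WEDGE_ANGLE_DEG)


def export_mesh(
    mesh: ValveMesh, path: Union[str, Path], file_format: str | None = None
) -> None:
    """Export a mesh as STL (binary) or OFF, by extension or explicit format."""
    import trimesh

    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in {"stl", "off"}:
        raise DomainError(f"unsupported mesh format {fmt!r} (use stl or off)")
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, process=False
    )
    tm.export(path, file_type=fmt)
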