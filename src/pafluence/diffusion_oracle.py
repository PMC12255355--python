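"""Closed-form diffusion-theory fluence fields.

Infinite-medium Green's functions for an isotropic point source and a
collimated plane source, used as analytic oracles for the Monte Carlo
engine, plus a finite-aperture approximation by linear superposition of
point kernels over the aperture area.

Point:  phi(r) = phi0 * exp(-mueff*r) / (4*pi*D*r)     (b = 1)
Plane:  phi(z) = phi0 * mueff/(2*mua) * exp(-mueff*z)  (b = 0)

with D = 1/(3*(mua + (1-g)*mus)). These forms carry no boundary
corrections (no extrapolated-boundary image sources); they describe the
diffuse regime beyond about one transport mean free path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry_param import FluenceProfile
from .optics_core import OpticalProperties, SourceSpec, effective_attenuation

__all__ = [
    "GreensFunctionSpec",
    "fluence_point",
    "fluence_plane",
    "fluence_aperture_superposition",
    "aperture_profile",
]


@dataclass(frozen=True)
class GreensFunctionSpec:
    """Geometry + medium + source scale for a closed-form fluence field."""

    geometry: str  # "point_3d" or "plane_1d"
    props: OpticalProperties
    phi0: float = 1.0

    def __post_init__(self) -> None:
        if self.geometry not in ("point_3d", "plane_1d"):
            raise ValidationError(f"unknown geometry {self.geometry!r}")
        if self.phi0 <= 0:
            raise ValidationError("phi0 must be > 0")

    def __call__(self, r):
        if self.geometry == "point_3d":
            return fluence_point(self.props, r, self.phi0)
        return fluence_plane(self.props, r, self.phi0)


def fluence_point(props: OpticalProperties, r, phi0: float = 1.0):
    """Isotropic point source fluence phi0 * exp(-mueff*r) / (4*pi*D*r).

    ``r`` is the radial distance in mm, strictly positive (scalar or array).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("r must be > 0 for the point Green's function")
    mueff = effective_attenuation(props)
    d = props.diffusion_constant
    out = phi0 * np.exp(-mueff * r) / (4.0 * math.pi * d * r)
    return float(out) if out.ndim == 0 else out


def fluence_plane(props: OpticalProperties, r, phi0: float = 1.0):
    """Collimated plane source fluence phi0 * mueff/(2*mua) * exp(-mueff*r).

    ``r`` is depth below the illuminated surface in mm, >= 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValidationError("depth must be >= 0 for the plane Green's function")
    mueff = effective_attenuation(props)
    out = phi0 * (mueff / (2.0 * props.mua)) * np.exp(-mueff * r)
    return float(out) if out.ndim == 0 else out


def fluence_aperture_superposition(
    props: OpticalProperties,
    aperture: SourceSpec,
    field_points: np.ndarray,
    phi0: float = 1.0,
    quad_pitch_mm: float = 0.25,
) -> np.ndarray:
    """Fluence of a rectangular aperture by superposing point kernels.

    The aperture lies in the z = 0 plane centered at the origin (width
    along x, height along y); ``field_points`` is an (N, 3) array of
    positions with z > 0. The integral over the aperture area uses a
    tensor-product midpoint rule at ``quad_pitch_mm`` node pitch (the
    actual pitch divides the aperture side exactly). Linear in phi0 and
    additive over disjoint aperture partitions by construction.

    A fast, smooth stand-in for Monte Carlo beyond ~1 transport mean free
    path; it shares the kernels' lack of boundary corrections.
    """
    if aperture.kind != "rect_aperture":
        raise ValidationError("superposition requires a rect_aperture source")
    pts = np.atleast_2d(np.asarray(field_points, dtype=float))
    if pts.shape[1] != 3:
        raise ValidationError("field_points must be (N, 3)")
    if np.any(pts[:, 2] <= 0):
        raise ValidationError("field points must lie strictly inside the medium (z > 0)")

    nx = max(1, int(round(aperture.width / quad_pitch_mm)))
    ny = max(1, int(round(aperture.height / quad_pitch_mm)))
    xs = (np.arange(nx) + 0.5) * (aperture.width / nx) - aperture.width / 2.0
    ys = (np.arange(ny) + 0.5) * (aperture.height / ny) - aperture.height / 2.0
    da = (aperture.width / nx) * (aperture.height / ny)

    mueff = effective_attenuation(props)
    dconst = props.diffusion_constant
    qx, qy = np.meshgrid(xs, ys, indexing="ij")
    qx = qx.ravel()
    qy = qy.ravel()

    out = np.empty(pts.shape[0])
    # chunk over field points; node count is bounded by the aperture size
    for i, (px, py, pz) in enumerate(pts):
        d = np.sqrt((px - qx) ** 2 + (py - qy) ** 2 + pz**2)
        out[i] = np.sum(np.exp(-mueff * d) / d)
    out *= phi0 * da / (4.0 * math.pi * dconst)
    return out


def aperture_profile(
    props: OpticalProperties,
    aperture: SourceSpec,
    depths_mm: np.ndarray,
    phi0: float = 1.0,
    quad_pitch_mm: float = 0.25,
    lateral_offset_mm: float = 0.0,
) -> FluenceProfile:
    """On-axis (or laterally offset) depth profile of the aperture field."""
    depths = np.asarray(depths_mm, dtype=float)
    pts = np.column_stack(
        [np.full_like(depths, lateral_offset_mm), np.zeros_like(depths), depths]
    )
    phi = fluence_aperture_superposition(props, aperture, pts, phi0, quad_pitch_mm)
    return FluenceProfile(
        r=depths,
        phi=phi,
        source_meta={"kind": "rect_aperture_superposition", "quad_pitch_mm": quad_pitch_mm},
    )
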