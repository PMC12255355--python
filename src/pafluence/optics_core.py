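"""Domain types for tissue optics: optical properties, media, and light sources.

All lengths are millimeters and all attenuation coefficients mm**-1.
The bundled tissue table (skin, fat, muscle at 700/800/900/1064 nm, plus
reference media with defined scattering-to-absorption ratios) is loaded
from packaged YAML via :func:`tissue_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "OpticalProperties",
    "SourceSpec",
    "MediumVolume",
    "effective_attenuation",
    "scattering_ratio",
    "ballistic_attenuation",
    "dominant_attenuation",
    "build_layered_volume",
    "homogeneous_volume",
    "tissue_table",
    "tissue_properties",
    "reference_medium",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of a homogeneous medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm**-1. Must be positive.
    mus : float
        Scattering coefficient, mm**-1. Must be non-negative.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection angle), in [0, 1). Soft tissue is strongly forward
        scattering with g ~ 0.9.
    n : float
        Refractive index, >= 1.
    """

    mua: float
    mus: float
    g: float = 0.9
    n: float = 1.4

    def __post_init__(self) -> None:
        for name in ("mua", "mus", "g", "n"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
        if self.mua <= 0:
            raise ValidationError(f"mua must be > 0, got {self.mua}")
        if self.mus < 0:
            raise ValidationError(f"mus must be >= 0, got {self.mus}")
        if not (0 <= self.g < 1):
            raise ValidationError(f"g must be in [0, 1), got {self.g}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")

    @property
    def mus_reduced(self) -> float:
        """Reduced scattering coefficient mus' = (1 - g) * mus, mm**-1."""
        return (1.0 - self.g) * self.mus

    @property
    def mut(self) -> float:
        """Total interaction coefficient mua + mus, mm**-1."""
        return self.mua + self.mus

    @property
    def mueff(self) -> float:
        return effective_attenuation(self)

    @property
    def diffusion_constant(self) -> float:
        """Diffusion constant D = 1 / (3 * (mua + mus')), mm."""
        return 1.0 / (3.0 * (self.mua + self.mus_reduced))

    @property
    def transport_mfp(self) -> float:
        """Transport mean free path 1 / (mua + mus'), mm."""
        return 1.0 / (self.mua + self.mus_reduced)

    def to_dict(self) -> dict:
        return {"mua": self.mua, "mus": self.mus, "g": self.g, "n": self.n}


def effective_attenuation(props: OpticalProperties) -> float:
    """Effective attenuation coefficient mueff = sqrt(3*mua*(mua + (1-g)*mus)).

    This is the asymptotic exponential decay rate of diffuse fluence with
    depth in a scattering-dominant medium. Strictly increasing in mua and
    in mus. Returns mm**-1.
    """
    return math.sqrt(3.0 * props.mua * (props.mua + props.mus_reduced))


def scattering_ratio(props: OpticalProperties) -> float:
    """Scattering-to-absorption ratio mus / mua (dimensionless).

    Biological soft tissues have ratios above ~100:1, which is the
    regime where one aperture-intrinsic geometry parameter applies
    regardless of tissue identity.
    """
    if props.mua == 0:
        raise ValidationError("scattering_ratio undefined for mua = 0")
    return props.mus / props.mua


def ballistic_attenuation(props: OpticalProperties) -> float:
    """Beer-Lambert attenuation rate mua + mus, mm**-1.

    The exponential decay rate of fluence when scattering is negligible
    (collimated/ballistic transport).
    """
    return props.mut


def dominant_attenuation(props: OpticalProperties) -> float:
    """Exponential decay rate of the fluence tail for this medium, mm**-1.

    In the diffusive regime (mus' > mua) the tail decays at the diffusion
    rate ``effective_attenuation``. When absorption dominates the reduced
    scattering, transport stays ballistic and the decay rate is the
    Beer-Lambert total attenuation mua + mus. Windowed power-law fits of
    the geometry parameter need the decay rate that actually governs the
    profile, which is what this helper selects.
    """
    if props.mus_reduced > props.mua:
        return effective_attenuation(props)
    return ballistic_attenuation(props)


_SOURCE_KINDS = ("isotropic_point", "infinite_plane", "rect_aperture")


@dataclass(frozen=True)
class SourceSpec:
    """Light source description.

    kind is one of ``isotropic_point`` (emits uniformly over 4*pi),
    ``infinite_plane`` (collimated, covers one full face of the volume) or
    ``rect_aperture`` (collimated rectangular output of ``width`` x
    ``height`` mm centered on one face; the default 30 x 2 mm matches a
    typical fiber-bundle output used for photoacoustic imaging).
    ``numerical_aperture`` is the half-angle sine of the launch cone in
    air; 0 means perfectly collimated.
    """

    kind: str
    center: Optional[tuple] = None
    width: float = 30.0
    height: float = 2.0
    numerical_aperture: float = 0.0
    photon_count: int = 100_000

    def __post_init__(self) -> None:
        if self.kind not in _SOURCE_KINDS:
            raise ValidationError(
                f"source kind must be one of {_SOURCE_KINDS}, got {self.kind!r}"
            )
        if self.kind == "rect_aperture" and (self.width <= 0 or self.height <= 0):
            raise ValidationError("rect_aperture requires width, height > 0")
        if not (0 <= self.numerical_aperture < 1):
            raise ValidationError("numerical_aperture must be in [0, 1)")
        if self.photon_count <= 0:
            raise ValidationError("photon_count must be positive")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center": None if self.center is None else list(self.center),
            "width": self.width,
            "height": self.height,
            "numerical_aperture": self.numerical_aperture,
            "photon_count": self.photon_count,
        }


@dataclass
class MediumVolume:
    """Labeled voxel grid binding integer labels to optical properties.

    ``labels`` maps each voxel to an integer id; ``palette`` maps label
    names to :class:`OpticalProperties` and ``label_ids`` maps names to the
    integer ids used in the grid. Voxels are cubic with edge ``voxel_size``
    mm; a voxel's property is constant over its half-open cube
    [i*voxel_size, (i+1)*voxel_size). Layered media are stacked along the
    z axis (the source axis).
    """

    shape: tuple
    voxel_size: float
    labels: np.ndarray
    palette: dict
    label_ids: dict
    layers: Optional[list] = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValidationError(f"shape must be 3 positive ints, got {self.shape}")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be > 0")
        if self.labels.shape != self.shape:
            raise ValidationError("labels array does not match shape")
        used = set(np.unique(self.labels).tolist())
        known = set(self.label_ids.values())
        if not used <= known:
            raise ValidationError(f"grid labels {used - known} missing from palette")
        for name in self.label_ids:
            if name not in self.palette:
                raise ValidationError(f"label {name!r} has no palette entry")

    @property
    def extent_mm(self) -> tuple:
        return tuple(s * self.voxel_size for s in self.shape)

    @property
    def center_mm(self) -> tuple:
        return tuple(0.5 * e for e in self.extent_mm)

    def property_arrays(self) -> tuple:
        """Per-label-id arrays (mua, mus, g, n) indexable by the grid labels."""
        n_ids = max(self.label_ids.values()) + 1
        mua = np.zeros(n_ids)
        mus = np.zeros(n_ids)
        g = np.zeros(n_ids)
        n = np.ones(n_ids)
        for name, lid in self.label_ids.items():
            p = self.palette[name]
            mua[lid], mus[lid], g[lid], n[lid] = p.mua, p.mus, p.g, p.n
        return mua, mus, g, n

    def props_at_entry(self) -> OpticalProperties:
        """Properties of the first voxel on the source axis (z=0 face center)."""
        lid = int(self.labels[self.shape[0] // 2, self.shape[1] // 2, 0])
        for name, i in self.label_ids.items():
            if i == lid:
                return self.palette[name]
        raise ValidationError("entry voxel label not found in palette")

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size": self.voxel_size,
            "palette": {k: v.to_dict() for k, v in self.palette.items()},
            "layers": self.layers,
        }


def build_layered_volume(
    shape: Sequence[int],
    voxel_size: float,
    layers: Sequence[tuple],
    palette: dict,
) -> MediumVolume:
    """Build a volume from a stack of (thickness_mm, label) layers along z.

    The final layer may use thickness ``None`` meaning "rest of the
    volume". Thicknesses must be positive multiples of ``voxel_size``.
    A single layer with thickness None gives a homogeneous volume.
    """
    shape = tuple(int(s) for s in shape)
    if len(layers) == 0:
        raise ValidationError("at least one layer is required")
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be > 0")
    label_ids = {name: i for i, name in enumerate(palette)}
    for _, name in layers:
        if name not in palette:
            raise ValidationError(f"layer label {name!r} not in palette")

    nz = shape[2]
    labels = np.zeros(shape, dtype=np.int16)
    z0 = 0
    for k, (thickness, name) in enumerate(layers):
        if thickness is None:
            if k != len(layers) - 1:
                raise ValidationError("only the final layer may have thickness None")
            nvox = nz - z0
        else:
            if thickness <= 0:
                raise ValidationError("layer thickness must be positive")
            ratio = thickness / voxel_size
            nvox = int(round(ratio))
            if abs(ratio - nvox) > 1e-9 * max(1.0, ratio) or nvox == 0:
                raise ValidationError(
                    f"layer thickness {thickness} mm is not a positive multiple "
                    f"of voxel_size {voxel_size} mm"
                )
        if nvox <= 0 or z0 + nvox > nz:
            raise ValidationError("layer stack exceeds the volume extent")
        labels[:, :, z0 : z0 + nvox] = label_ids[name]
        z0 += nvox
    if z0 != nz:
        raise ValidationError(
            "layers do not cover the full source-axis extent "
            "(use thickness None for the final layer)"
        )
    return MediumVolume(
        shape=shape,
        voxel_size=voxel_size,
        labels=labels,
        palette=dict(palette),
        label_ids=label_ids,
        layers=[[t, n] for t, n in layers],
    )


def homogeneous_volume(
    extent_mm: Sequence[float] | float,
    voxel_size: float,
    props: OpticalProperties,
    name: str = "medium",
) -> MediumVolume:
    """Homogeneous volume of the given physical extent (mm, scalar = cube)."""
    if np.isscalar(extent_mm):
        extent_mm = (extent_mm, extent_mm, extent_mm)
    shape = tuple(int(round(e / voxel_size)) for e in extent_mm)
    return build_layered_volume(shape, voxel_size, [(None, name)], {name: props})


@lru_cache(maxsize=1)
def _load_table() -> dict:
    text = resources.files("pafluence.data").joinpath("tissue_optics.yaml").read_text()
    return yaml.safe_load(text)


def tissue_table() -> dict:
    """All bundled tissue rows as {(tissue, wavelength_nm): OpticalProperties}."""
    raw = _load_table()["tissues"]
    out = {}
    for tissue, rows in raw.items():
        for wl, p in rows.items():
            out[(tissue, int(wl))] = OpticalProperties(**p)
    return out


def tissue_properties(tissue: str, wavelength_nm: int) -> OpticalProperties:
    """Bundled optical properties for a tissue at one of 700/800/900/1064 nm."""
    table = tissue_table()
    key = (tissue.lower(), int(wavelength_nm))
    if key not in table:
        raise ValidationError(f"no bundled properties for {key}")
    return table[key]


def reference_medium(name: str) -> OpticalProperties:
    """Bundled defined-ratio reference media.

    Names: ``mus_mua_0.001`` (absorption dominant), ``mus_mua_100``,
    ``mus_mua_500`` (scattering dominant); all share mueff ~= 0.50 mm**-1
    by construction when evaluated with the diffusion formula.
    """
    media = _load_table()["reference_media"]
    if name not in media:
        raise ValidationError(f"unknown reference medium {name!r}; have {list(media)}")
    return OpticalProperties(**media[name])
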