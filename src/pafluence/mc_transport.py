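"""Voxel Monte Carlo photon transport.

Standard hop-drop-spin random walk on a labeled voxel grid: step lengths
are sampled from the local total interaction coefficient with exact ray
traversal across voxel boundaries, a fraction mua/mut of the photon
weight is deposited at each interaction, directions are resampled from
the Henyey-Greenstein phase function, and low-weight photons undergo
Russian roulette. Deposited weight is converted to fluence per launched
photon by dividing by mua * voxel volume (absorbed-weight estimator).

The outer boundary applies unpolarized Fresnel reflection against an
exterior index (air, n=1) by default, including total internal
reflection; transmitted photons are tallied as escaped. An index-matched
mode (every photon at the boundary escapes) is available as a config
switch. Collimated sources may be given a numerical aperture; the launch
direction is then tilted by a polar angle drawn uniformly in solid angle
up to asin(NA / n_medium).

The engine is single threaded and deterministic given an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ConfigurationError, ValidationError
from .geometry_param import FluenceProfile
from .optics_core import MediumVolume, SourceSpec

__all__ = [
    "FluenceVolume",
    "TransportLedger",
    "run_mc",
    "extract_profile",
    "hg_samples",
]

MIN_PHOTONS = 1_000
ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1

_KIND_CODE = {"isotropic_point": 0, "infinite_plane": 1, "rect_aperture": 2}


@dataclass
class TransportLedger:
    """Energy audit of a transport run (weights, in launched-photon units)."""

    launched_weight: float
    absorbed_weight: float
    escaped_weight: float
    roulette_killed_weight: float
    roulette_added_weight: float

    @property
    def rouletted_weight_bias(self) -> float:
        """Net weight injected (+) or removed (-) by roulette; zero in expectation."""
        return self.roulette_added_weight - self.roulette_killed_weight

    @property
    def relative_imbalance(self) -> float:
        """(absorbed + escaped - launched) / launched; bounded by roulette noise."""
        return (
            self.absorbed_weight + self.escaped_weight - self.launched_weight
        ) / self.launched_weight

    def to_dict(self) -> dict:
        return {
            "launched_weight": self.launched_weight,
            "absorbed_weight": self.absorbed_weight,
            "escaped_weight": self.escaped_weight,
            "roulette_killed_weight": self.roulette_killed_weight,
            "roulette_added_weight": self.roulette_added_weight,
            "relative_imbalance": self.relative_imbalance,
        }


@dataclass
class FluenceVolume:
    """Per-voxel fluence (a.u. per launched photon) plus run metadata."""

    grid: np.ndarray
    voxel_size: float
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.grid.shape


@njit(cache=True, fastmath=True)
def _hg_cos(g):
    u = np.random.random()
    if g < 1e-6:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - t * t) / (2.0 * g)


@njit(cache=True, fastmath=True)
def _hg_samples(g, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _hg_cos(g)
    return out


def hg_samples(g: float, n: int, seed: int) -> np.ndarray:
    """Draw n Henyey-Greenstein deflection cosines (validation helper).

    The first moment of the distribution is the anisotropy g itself.
    """
    return _hg_samples(float(g), int(n), int(seed))


@njit(cache=True, fastmath=True)
def _spin(ux, uy, uz, g):
    ct = _hg_cos(g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    st = math.sqrt(1.0 - ct * ct)
    phi = 2.0 * math.pi * np.random.random()
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz > 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -den * st * cp + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True)
def _fresnel_reflectance(ci, n1, n2):
    """Unpolarized Fresnel reflectance for incidence cosine ci, n1 -> n2."""
    if ci > 1.0:
        ci = 1.0
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    ct = math.sqrt(1.0 - sin_t2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _transport(
    labels,
    mua,
    mus,
    g,
    n_arr,
    dx,
    kind,
    sx,
    sy,
    sz,
    half_w,
    half_h,
    cos_min,
    nphot,
    seed,
    w_threshold,
    p_survive,
    fresnel,
    n_out,
):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    lx = nx * dx
    ly = ny * dx
    lz = nz * dx
    absorb = np.zeros((nx, ny, nz))
    absorbed = 0.0
    escaped = 0.0
    killed = 0.0
    added = 0.0
    # boundary-crossing overshoot: large enough that the position always
    # advances by more than one float ulp (direction components smaller
    # than the parallel threshold below are treated as in-plane), small
    # enough to be photometrically negligible (~2e-6 mm per crossing)
    nudge = 1e-5 * dx
    for _ in range(nphot):
        # --- launch ---
        if kind == 0:  # isotropic point
            x, y, z = sx, sy, sz
            ct = 2.0 * np.random.random() - 1.0
            st = math.sqrt(1.0 - ct * ct)
            ph = 2.0 * math.pi * np.random.random()
            ux = st * math.cos(ph)
            uy = st * math.sin(ph)
            uz = ct
        else:
            if kind == 1:  # full-face collimated plane at z=0
                x = np.random.random() * lx
                y = np.random.random() * ly
            else:  # rectangular aperture centered on the z=0 face
                x = sx + (np.random.random() - 0.5) * 2.0 * half_w
                y = sy + (np.random.random() - 0.5) * 2.0 * half_h
            z = nudge
            if cos_min < 1.0:
                ct = 1.0 - np.random.random() * (1.0 - cos_min)
                st = math.sqrt(1.0 - ct * ct)
                ph = 2.0 * math.pi * np.random.random()
                ux = st * math.cos(ph)
                uy = st * math.sin(ph)
                uz = ct
            else:
                ux = 0.0
                uy = 0.0
                uz = 1.0
        w = 1.0
        tau = -math.log(1.0 - np.random.random())
        while True:
            if x < 0.0 or x >= lx or y < 0.0 or y >= ly or z < 0.0 or z >= lz:
                if fresnel == 0:
                    escaped += w
                    break
                # Fresnel reflection at the outer boundary (exterior n_out):
                # reflect each exceeded axis with probability R, else escape
                li = labels[
                    min(max(int(x / dx), 0), nx - 1),
                    min(max(int(y / dx), 0), ny - 1),
                    min(max(int(z / dx), 0), nz - 1),
                ]
                n_med = n_arr[li]
                dead = False
                if x < 0.0 or x >= lx:
                    if np.random.random() < _fresnel_reflectance(abs(ux), n_med, n_out):
                        ux = -ux
                        x = -x if x < 0.0 else 2.0 * lx - x
                    else:
                        dead = True
                if not dead and (y < 0.0 or y >= ly):
                    if np.random.random() < _fresnel_reflectance(abs(uy), n_med, n_out):
                        uy = -uy
                        y = -y if y < 0.0 else 2.0 * ly - y
                    else:
                        dead = True
                if not dead and (z < 0.0 or z >= lz):
                    if np.random.random() < _fresnel_reflectance(abs(uz), n_med, n_out):
                        uz = -uz
                        z = -z if z < 0.0 else 2.0 * lz - z
                    else:
                        dead = True
                if dead:
                    escaped += w
                    break
                if x < 0.0 or x >= lx or y < 0.0 or y >= ly or z < 0.0 or z >= lz:
                    # mirrored position still outside (deep overshoot); drop it
                    escaped += w
                    break
            ix = int(x / dx)
            iy = int(y / dx)
            iz = int(z / dx)
            lab = labels[ix, iy, iz]
            mt = mua[lab] + mus[lab]
            # distance to the nearest voxel face along the direction;
            # near-parallel components never cross their faces
            if ux > 1e-8:
                tx = ((ix + 1) * dx - x) / ux
            elif ux < -1e-8:
                tx = (ix * dx - x) / ux
            else:
                tx = 1e30
            if uy > 1e-8:
                ty = ((iy + 1) * dx - y) / uy
            elif uy < -1e-8:
                ty = (iy * dx - y) / uy
            else:
                ty = 1e30
            if uz > 1e-8:
                tz = ((iz + 1) * dx - z) / uz
            elif uz < -1e-8:
                tz = (iz * dx - z) / uz
            else:
                tz = 1e30
            sb = tx
            if ty < sb:
                sb = ty
            if tz < sb:
                sb = tz
            if sb < 0.0:  # float jitter can place the position past a face
                sb = 0.0
            s_need = tau / mt
            if s_need < sb:
                # hop to the interaction site inside this voxel
                x += ux * s_need
                y += uy * s_need
                z += uz * s_need
                # drop
                dep = w * mua[lab] / mt
                absorb[ix, iy, iz] += dep
                absorbed += dep
                w -= dep
                if w < w_threshold:
                    if np.random.random() < p_survive:
                        added += w * (1.0 / p_survive - 1.0)
                        w /= p_survive
                    else:
                        killed += w
                        break
                # spin
                ux, uy, uz = _spin(ux, uy, uz, g[lab])
                tau = -math.log(1.0 - np.random.random())
            else:
                # cross into the next voxel
                s = sb + nudge
                x += ux * s
                y += uy * s
                z += uz * s
                tau -= s * mt
                if tau < 0.0:
                    tau = 0.0
    return absorb, absorbed, escaped, killed, added


def _source_position(volume: MediumVolume, source: SourceSpec) -> tuple:
    ex, ey, ez = volume.extent_mm
    if source.kind == "isotropic_point":
        if source.center is not None:
            return tuple(float(c) for c in source.center)
        return (ex / 2.0, ey / 2.0, ez / 2.0)
    # face sources: centered laterally on the z=0 face
    return (ex / 2.0, ey / 2.0, 0.0)


def run_mc(
    volume: MediumVolume,
    source: SourceSpec,
    photons: int | None = None,
    seed: int | None = None,
    roulette_threshold: float = ROULETTE_THRESHOLD,
    roulette_survival: float = ROULETTE_SURVIVAL,
    boundary: str = "fresnel",
    exterior_n: float = 1.0,
) -> tuple:
    """Run the voxel Monte Carlo engine.

    Returns ``(FluenceVolume, TransportLedger)``. ``photons`` defaults to
    ``source.photon_count`` and must be at least 1000 (below that the
    profile statistics are unusable). ``seed`` is required; it is recorded
    in the output metadata along with the source and normalization mode.

    ``boundary`` selects the outer boundary condition: ``"fresnel"``
    (default) applies unpolarized Fresnel reflection against an exterior
    medium of index ``exterior_n`` (air), including total internal
    reflection — the condition under which the aperture geometry
    parameter of a tissue-air interface is defined; ``"matched"`` treats
    the boundary as index matched (every photon reaching it escapes).
    """
    if photons is None:
        photons = source.photon_count
    photons = int(photons)
    if photons < MIN_PHOTONS:
        raise ConfigurationError(
            f"photons must be >= {MIN_PHOTONS} for usable statistics, got {photons}"
        )
    if seed is None:
        raise ConfigurationError("an explicit RNG seed is required")
    seed = int(seed)
    if not (0 <= seed < 2**31):
        raise ConfigurationError("seed must fit in a signed 32-bit integer")

    if boundary not in ("fresnel", "matched"):
        raise ConfigurationError(f"unknown boundary condition {boundary!r}")
    mua, mus, g, n_idx = volume.property_arrays()
    used = np.unique(volume.labels)
    if np.any((mua[used] + mus[used]) <= 0):
        raise ConfigurationError("every voxel must have a positive total attenuation")

    sx, sy, sz = _source_position(volume, source)
    ex, ey, ez = volume.extent_mm
    if source.kind == "isotropic_point" and not (
        0 < sx < ex and 0 < sy < ey and 0 < sz < ez
    ):
        raise ConfigurationError("point source must lie inside the volume")
    if source.kind == "rect_aperture" and (
        source.width > ex or source.height > ey
    ):
        raise ConfigurationError("rect aperture exceeds the volume face")

    cos_min = 1.0
    if source.numerical_aperture > 0 and source.kind != "isotropic_point":
        n_medium = volume.props_at_entry().n
        cos_min = math.cos(math.asin(source.numerical_aperture / n_medium))

    absorb, absorbed, escaped, killed, added = _transport(
        volume.labels,
        mua,
        mus,
        g,
        n_idx,
        float(volume.voxel_size),
        _KIND_CODE[source.kind],
        sx,
        sy,
        sz,
        source.width / 2.0,
        source.height / 2.0,
        cos_min,
        photons,
        seed,
        float(roulette_threshold),
        float(roulette_survival),
        1 if boundary == "fresnel" else 0,
        float(exterior_n),
    )

    ledger = TransportLedger(
        launched_weight=float(photons),
        absorbed_weight=float(absorbed),
        escaped_weight=float(escaped),
        roulette_killed_weight=float(killed),
        roulette_added_weight=float(added),
    )
    # absorbed-weight estimator: fluence = deposited / (mua * voxel volume),
    # normalized per launched photon
    vvox = volume.voxel_size**3
    mua_grid = mua[volume.labels]
    fluence = absorb / (mua_grid * vvox * photons)
    fv = FluenceVolume(
        grid=fluence,
        voxel_size=volume.voxel_size,
        meta={
            "photon_count": photons,
            "seed": seed,
            "source": source.to_dict(),
            "source_position_mm": [sx, sy, sz],
            "normalization": "fluence_per_launched_photon",
            "roulette_threshold": roulette_threshold,
            "roulette_survival": roulette_survival,
            "boundary": boundary,
            "exterior_n": exterior_n,
        },
    )
    return fv, ledger


def extract_profile(
    fluence: FluenceVolume,
    source: SourceSpec,
    mode: str = "axial",
    lateral_halfwidth_mm: float | tuple | None = None,
    lateral_offset_mm: float = 0.0,
    max_r_mm: float | None = None,
) -> FluenceProfile:
    """Extract a fluence-versus-distance profile from a volume.

    Modes
    -----
    ``axial``
        Samples along the source normal (+z; for a point source the +z ray
        from the source), one voxel column, at voxel centers. Matches the
        raw-trace convention; noisy for small photon counts.
    ``radial``
        Point sources only: spherical-shell average around the source,
        exploiting the source symmetry for variance reduction.
    ``lateral_mean``
        Face sources: per-depth average over a lateral patch of half-width
        ``lateral_halfwidth_mm`` (scalar or (x, y) pair; defaults to a
        quarter of the face for the plane source and (3.0, 0.4) mm for the
        rectangular aperture, inside the laterally-consistent central
        region of the aperture field).

    ``lateral_offset_mm`` shifts the sampled column/patch along x for
    off-axis consistency studies.
    """
    grid = fluence.grid
    nx, ny, nz = grid.shape
    dx = fluence.voxel_size
    sx, sy, sz = fluence.meta.get(
        "source_position_mm", [nx * dx / 2, ny * dx / 2, 0.0]
    )
    kind = source.kind
    off_vox = int(round(lateral_offset_mm / dx))

    if mode == "radial":
        if kind != "isotropic_point":
            raise ValidationError("radial profiles require an isotropic point source")
        xs = (np.arange(nx) + 0.5) * dx - sx
        ys = (np.arange(ny) + 0.5) * dx - sy
        zs = (np.arange(nz) + 0.5) * dx - sz
        r = np.sqrt(
            xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
        ).ravel()
        idx = (r / dx).astype(np.int64)
        nbin = int(idx.max()) + 1
        cnt = np.bincount(idx, minlength=nbin)
        phi_sum = np.bincount(idx, weights=grid.ravel(), minlength=nbin)
        r_sum = np.bincount(idx, weights=r, minlength=nbin)
        keep = cnt > 0
        r_mean = r_sum[keep] / cnt[keep]
        phi_mean = phi_sum[keep] / cnt[keep]
        order = np.argsort(r_mean)
        r_mean, phi_mean = r_mean[order], phi_mean[order]
        if max_r_mm is not None:
            m = r_mean <= max_r_mm
            r_mean, phi_mean = r_mean[m], phi_mean[m]
        return FluenceProfile(
            r=r_mean, phi=phi_mean, source_meta={**fluence.meta, "profile_mode": "radial"}
        )

    cx = nx // 2 + off_vox
    cy = ny // 2
    if not (0 <= cx < nx):
        raise ValidationError("lateral offset places the profile outside the grid")

    if kind == "isotropic_point":
        iz0 = int(sz / dx)
        if iz0 >= nz - 1:
            raise ValidationError("ray from the source exits the grid immediately")
        zc = (np.arange(nz) + 0.5) * dx
        m = zc > sz
        r = zc[m] - sz
        phi = grid[cx, cy, m]
    else:
        zc = (np.arange(nz) + 0.5) * dx
        r = zc
        if mode == "axial":
            phi = grid[cx, cy, :]
        elif mode == "lateral_mean":
            if lateral_halfwidth_mm is None:
                if kind == "infinite_plane":
                    hw = (nx * dx / 4.0, ny * dx / 4.0)
                else:
                    hw = (3.0, 0.4)
            elif np.isscalar(lateral_halfwidth_mm):
                hw = (float(lateral_halfwidth_mm), float(lateral_halfwidth_mm))
            else:
                hw = tuple(float(h) for h in lateral_halfwidth_mm)
            hx = max(0, int(round(hw[0] / dx)))
            hy = max(0, int(round(hw[1] / dx)))
            x0, x1 = max(0, cx - hx), min(nx, cx + hx + 1)
            y0, y1 = max(0, cy - hy), min(ny, cy + hy + 1)
            phi = grid[x0:x1, y0:y1, :].mean(axis=(0, 1))
        else:
            raise ValidationError(f"unknown profile mode {mode!r}")
    if max_r_mm is not None:
        m = r <= max_r_mm
        r, phi = r[m], phi[m]
    if r.size == 0:
        raise ValidationError("profile is empty")
    return FluenceProfile(
        r=r, phi=np.ascontiguousarray(phi), source_meta={**fluence.meta, "profile_mode": mode}
    )
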