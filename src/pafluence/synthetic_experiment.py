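"""Synthetic amplitude-versus-path traces emulating the two bench protocols.

``translation``: a target/transducer assembly in a liquid scattering bath
(milk/water) is translated away from a fixed 30 x 2 mm fiber output at
0.25 mm/s while imaging at 10 Hz, sweeping the optical path from 5 to
30 mm. ``displacement``: the fiber tip is pressed into a solid tissue slab
at 0.10 mm/s, shortening the path to an embedded target by up to a few mm
(quantified as strain of the slab).

The forward model is the generalized fluence law
p = P0 * (1/r)**b * exp(-mueff*r), with multiplicative Gaussian noise
(sigma, default 0.05) and a rectified additive noise floor (default 1% of
the clean trace peak). An optional near-field "ballistic bump" adds excess
attenuation above the diffusive model within a configurable onset depth,
reproducing the near-source overestimate seen before photons become fully
diffuse; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .mueff_estimator import AmplitudeTrace

__all__ = [
    "ExperimentConfig",
    "generate_trace",
    "milk_ladder",
    "MILK_PRESET_CONCENTRATIONS",
    "MILK_BASE_MUEFF",
    "MILK_MUEFF_PER_PERCENT",
]

#: Milk-ladder preset: eight fat-free milk dilutions, % v/v.
MILK_PRESET_CONCENTRATIONS = (2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0)

#: Ground-truth model for the ladder at 1064 nm: water absorption
#: (~0.014 mm**-1) sets the baseline mueff and each % v/v of fat-free milk
#: adds reduced scattering, raising mueff roughly linearly over this
#: dilution range.
MILK_BASE_MUEFF = 0.025
MILK_MUEFF_PER_PERCENT = 0.0016


@dataclass
class ExperimentConfig:
    """Configuration of one synthetic acquisition."""

    mode: str = "translation"
    mueff_true: float = 0.1
    b_true: float = 0.5
    r_start: float = 5.0
    r_end: float = 30.0
    speed: float = 0.25
    frame_rate: float = 10.0
    noise_sigma: float = 0.05
    noise_floor: Optional[float] = None  # None -> 1% of the clean peak
    p0: float = 1.0
    seed: int = 0
    ballistic_onset_mm: Optional[float] = None
    ballistic_excess: Optional[float] = None  # extra decay rate; default mueff_true

    def __post_init__(self) -> None:
        if self.mode not in ("translation", "displacement"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.r_start == self.r_end:
            raise ConfigurationError("r_start and r_end must differ")
        if min(self.r_start, self.r_end) <= 0:
            raise ConfigurationError("optical path must stay positive")
        if self.frame_rate <= 0 or self.speed <= 0:
            raise ConfigurationError("frame_rate and speed must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.mueff_true <= 0:
            raise ConfigurationError("mueff_true must be positive")

    @property
    def dr_per_frame(self) -> float:
        step = self.speed / self.frame_rate
        return step if self.r_end > self.r_start else -step

    @property
    def n_frames(self) -> int:
        return int(round(abs(self.r_end - self.r_start) / abs(self.dr_per_frame)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


def _clean_amplitude(cfg: ExperimentConfig, r: np.ndarray) -> np.ndarray:
    p = cfg.p0 * (1.0 / r) ** cfg.b_true * np.exp(-cfg.mueff_true * r)
    if cfg.ballistic_onset_mm is not None:
        excess = (
            cfg.ballistic_excess if cfg.ballistic_excess is not None else cfg.mueff_true
        )
        # within the onset depth photons are not yet diffuse: the profile
        # decays faster than the diffusive model, so compensation there
        # overestimates mueff
        p = p * np.exp(excess * np.clip(cfg.ballistic_onset_mm - r, 0.0, None))
    return p


def generate_trace(cfg: ExperimentConfig) -> AmplitudeTrace:
    """Generate one seeded, reproducible amplitude trace.

    r advances by speed/frame_rate per frame from r_start toward r_end;
    p = clean(r) * (1 + eps) + eta with eps ~ N(0, sigma**2) and
    eta ~ |N(0, floor**2)|. Negative draws are floored at zero (the
    estimator excludes, not clips, non-positive samples).
    """
    n = cfg.n_frames
    if n < 2:
        raise ConfigurationError("configuration yields fewer than 2 frames")
    i = np.arange(n)
    r = cfg.r_start + i * cfg.dr_per_frame
    if np.any(r <= 0):
        raise ConfigurationError("configuration yields non-positive optical path")
    clean = _clean_amplitude(cfg, r)

    rng = np.random.default_rng(cfg.seed)
    eps = rng.normal(0.0, cfg.noise_sigma, size=n) if cfg.noise_sigma > 0 else 0.0
    floor = cfg.noise_floor if cfg.noise_floor is not None else 0.01 * clean.max()
    eta = np.abs(rng.normal(0.0, floor, size=n)) if floor > 0 else 0.0
    p = np.clip(clean * (1.0 + eps) + eta, 0.0, None)

    return AmplitudeTrace(
        frame=i,
        r=r,
        p=p,
        t=i / cfg.frame_rate,
        meta={"config": cfg.to_dict(), "mueff_true": cfg.mueff_true, "b_true": cfg.b_true},
    )


def milk_ladder(
    concentrations: Sequence[float],
    mueff_per_unit: float = MILK_MUEFF_PER_PERCENT,
    base_mueff: float = MILK_BASE_MUEFF,
    cfg: Optional[ExperimentConfig] = None,
) -> list:
    """One translation trace per milk concentration (% v/v).

    Each trace uses mueff_true = base_mueff + mueff_per_unit *
    concentration (linear-in-concentration ground truth) and a seed offset
    by the rung index so the set is reproducible yet independent. Returns
    a list of :class:`AmplitudeTrace` whose metadata records the
    concentration.
    """
    if any(c <= 0 for c in concentrations):
        raise ConfigurationError("concentrations must be positive")
    template = cfg if cfg is not None else ExperimentConfig()
    traces = []
    for k, conc in enumerate(concentrations):
        d = template.to_dict()
        d["mode"] = "translation"
        d["mueff_true"] = base_mueff + mueff_per_unit * conc
        d["seed"] = int(template.seed) + k
        trace = generate_trace(ExperimentConfig.from_dict(d))
        trace.meta["milk_concentration_pct"] = float(conc)
        traces.append(trace)
    return traces
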