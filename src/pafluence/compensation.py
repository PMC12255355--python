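"""Depth-dependent fluence compensation with an estimated (b, mueff) pair.

Once the aperture geometry parameter b and the bulk effective attenuation
mueff are known, photoacoustic amplitudes at different optical path
lengths can be equalized by the multiplicative gain

    gain(r) = (r / r_ref)**b * exp(+mueff * (r - r_ref))

which is exactly the inverse of the amplitude-ratio model, is 1 at the
reference depth, and chains multiplicatively across depths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .mueff_estimator import AmplitudeTrace

__all__ = ["CompensationModel", "gain", "compensate_trace"]


@dataclass(frozen=True)
class CompensationModel:
    """Geometry + attenuation pair used to equalize amplitudes over depth."""

    b: float
    mueff: float
    reference_r: float
    valid_range: tuple = (1.0, 15.0)

    def __post_init__(self) -> None:
        if self.reference_r <= 0:
            raise ValidationError("reference_r must be > 0")
        lo, hi = self.valid_range
        if not (lo <= self.reference_r <= hi):
            raise ValidationError("reference_r must lie inside valid_range")
        if not np.isfinite(self.b) or not np.isfinite(self.mueff):
            raise ValidationError("b and mueff must be finite")

    def inverse(self) -> "CompensationModel":
        """Model whose gain exactly undoes this one (same reference depth)."""
        return CompensationModel(
            b=-self.b,
            mueff=-self.mueff,
            reference_r=self.reference_r,
            valid_range=self.valid_range,
        )

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "mueff_per_mm": self.mueff,
            "reference_r_mm": self.reference_r,
            "valid_range_mm": list(self.valid_range),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def gain(model: CompensationModel, r, warn_outside: bool = True):
    """Multiplicative compensation factor at optical path r (mm).

    gain(reference_r) = 1. Values outside the model's valid range are
    still returned but trigger a warning, since the (b, mueff) pair was
    only validated there.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValidationError("r must be > 0")
    lo, hi = model.valid_range
    if warn_outside and np.any((r_arr < lo) | (r_arr > hi)):
        warnings.warn(
            f"compensation applied outside the validated range [{lo}, {hi}] mm",
            stacklevel=2,
        )
    out = (r_arr / model.reference_r) ** model.b * np.exp(
        model.mueff * (r_arr - model.reference_r)
    )
    return float(out) if out.ndim == 0 else out


def compensate_trace(trace: AmplitudeTrace, model: CompensationModel) -> AmplitudeTrace:
    """Apply the depth gain to every frame of a trace.

    The returned trace records the model in its metadata for provenance.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = gain(model, trace.r, warn_outside=False)
    return AmplitudeTrace(
        frame=trace.frame.copy(),
        r=trace.r.copy(),
        p=trace.p * g,
        t=None if trace.t is None else trace.t.copy(),
        meta={**trace.meta, "compensation": model.to_dict()},
    )
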