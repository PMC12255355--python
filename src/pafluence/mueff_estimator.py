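"""Effective attenuation from photoacoustic amplitude versus optical path.

The target amplitude follows P(r) ~ (c/r)**b * P0 * exp(-mueff*r), so with
the aperture's geometry parameter b known (one Monte Carlo run per
aperture, reusable across tissues), multiplying by r**b removes the
geometric spread and the remaining exponential is linear in log space:

    ln(P * r**b) = const - mueff * r

A stride-1 moving-window OLS of that line gives a local mueff per window;
the per-depth (or per-strain) values are averaged over the converged range
to a single bulk estimate. For two samples the windowed fit reduces
exactly to the two-position ratio formula

    mueff = [b * ln(r2/r1) - ln(P1/P2)] / (r1 - r2).

Assuming b too large attributes real attenuation to geometric spread and
underestimates mueff; b too small overestimates it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._windows import sliding_ols, window_centers
from .errors import EstimationError, ValidationError

__all__ = [
    "AmplitudeTrace",
    "MuEffEstimate",
    "smooth_trace",
    "estimate_mueff_windowed",
    "estimate_mueff_pair",
    "aggregate_mueff",
    "strain_axis",
    "DEFAULT_WINDOW_SAMPLES",
    "DEFAULT_SMOOTHING_FRAMES",
]

#: 20 samples ~ 2 mm at the 0.1 mm frame pitch of the translation protocol.
DEFAULT_WINDOW_SAMPLES = 20
DEFAULT_SMOOTHING_FRAMES = 30


@dataclass
class AmplitudeTrace:
    """Per-frame maximum photoacoustic amplitude at a target.

    ``r`` is the optical path length from the source output to the target
    in mm; ``p`` the maximum PA amplitude (a.u.); ``t`` optional time in
    seconds. ``meta`` carries acquisition context (frame rate, speed,
    generator settings).
    """

    frame: np.ndarray
    r: np.ndarray
    p: np.ndarray
    t: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame)
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if not (self.frame.shape == self.r.shape == self.p.shape):
            raise ValidationError("frame, r and p must have equal length")
        if np.any(self.r <= 0):
            raise ValidationError("optical path lengths must be positive")
        if np.any(self.p < 0):
            raise ValidationError("amplitudes must be non-negative")
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)
            if self.t.shape != self.r.shape:
                raise ValidationError("t must match the trace length")
            if self.t.size >= 2 and np.any(np.diff(self.t) < 0):
                raise ValidationError("frames must be ordered in time")

    def __len__(self) -> int:
        return self.r.size

    def to_frame(self) -> pd.DataFrame:
        t = self.t if self.t is not None else np.full(len(self), np.nan)
        return pd.DataFrame(
            {"frame": self.frame, "t_s": t, "r_mm": self.r, "p_au": self.p}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "AmplitudeTrace":
        df = pd.read_csv(path)
        for col in ("frame", "r_mm", "p_au"):
            if col not in df.columns:
                raise ValidationError(f"trace CSV missing column {col!r}")
        t = df["t_s"].to_numpy() if "t_s" in df.columns else None
        if t is not None and np.all(np.isnan(t)):
            t = None
        return cls(
            frame=df["frame"].to_numpy(),
            r=df["r_mm"].to_numpy(),
            p=df["p_au"].to_numpy(),
            t=t,
        )


@dataclass
class MuEffEstimate:
    """Windowed local mueff values plus the aggregated bulk estimate."""

    window_centers: np.ndarray
    mueff_local: np.ndarray
    fit_r2: np.ndarray
    b_used: float
    window_samples: int
    smoothing_frames: int = 0
    mueff_aggregate: float = math.nan
    aggregate_range: Optional[tuple] = None
    aggregate_axis: str = "depth_mm"
    n_skipped: int = 0
    aux_centers: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_mm": self.window_centers,
                "mueff_local_per_mm": self.mueff_local,
                "r2": self.fit_r2,
            }
        )

    def write(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            summary = {
                "mueff_aggregate_per_mm": self.mueff_aggregate,
                "aggregate_range": None
                if self.aggregate_range is None
                else list(self.aggregate_range),
                "aggregate_axis": self.aggregate_axis,
                "b_used": self.b_used,
                "window_samples": self.window_samples,
                "smoothing_frames": self.smoothing_frames,
                "n_windows": int(self.window_centers.size),
                "n_skipped": self.n_skipped,
            }
            with open(json_path, "w") as fh:
                json.dump(summary, fh, indent=2)


def smooth_trace(trace: AmplitudeTrace, frames: int = DEFAULT_SMOOTHING_FRAMES) -> AmplitudeTrace:
    """Centered moving-average of the amplitude over ``frames`` frames.

    Distances are left untouched; the endpoint windows shrink so the
    output has the same length as the input.
    """
    if frames < 1:
        raise ValidationError("smoothing window must be >= 1 frame")
    if len(trace) < frames:
        raise EstimationError(
            f"trace has {len(trace)} frames, shorter than smoothing window {frames}"
        )
    p = (
        pd.Series(trace.p)
        .rolling(window=frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return AmplitudeTrace(
        frame=trace.frame.copy(),
        r=trace.r.copy(),
        p=p,
        t=None if trace.t is None else trace.t.copy(),
        meta={**trace.meta, "smoothing_frames": frames},
    )


def estimate_mueff_windowed(
    trace: AmplitudeTrace,
    b: float,
    window: int = DEFAULT_WINDOW_SAMPLES,
    aux_axis: Optional[np.ndarray] = None,
) -> MuEffEstimate:
    """Moving-window log-linear fit of mueff with geometry compensation b.

    Per window, y = ln(p * r**b) is regressed on r and the local mueff is
    minus the slope. Windows containing any non-positive amplitude are
    skipped and flagged (excluding rather than clipping noise-floor
    samples, which would bias the log fit). Raises
    :class:`EstimationError` if no window survives.

    ``aux_axis`` is an optional per-frame axis (e.g. strain); its
    per-window means for the surviving windows are stored on the estimate
    as ``aux_centers`` for aggregation on that axis.
    """
    if not np.isfinite(b):
        raise ValidationError("b must be finite")
    if len(trace) < window:
        raise EstimationError(
            f"trace has {len(trace)} samples, need >= {window} for one window"
        )
    with np.errstate(divide="ignore"):
        y = np.where(trace.p > 0, np.log(trace.p), np.nan) + b * np.log(trace.r)
    slope, r2, _, valid = sliding_ols(trace.r, y, window)
    if not valid.any():
        raise EstimationError("no window with strictly positive amplitudes")
    centers = window_centers(trace.r, window)
    aux = None
    if aux_axis is not None:
        aux_axis = np.asarray(aux_axis, dtype=float)
        if aux_axis.shape != trace.r.shape:
            raise ValidationError("aux_axis must have one value per frame")
        aux = window_centers(aux_axis, window)[valid]
    return MuEffEstimate(
        window_centers=centers[valid],
        mueff_local=-slope[valid],
        fit_r2=r2[valid],
        b_used=float(b),
        window_samples=window,
        smoothing_frames=int(trace.meta.get("smoothing_frames", 0)),
        n_skipped=int((~valid).sum()),
        aux_centers=aux,
    )


def estimate_mueff_pair(p1: float, p2: float, r1: float, r2: float, b: float) -> float:
    """Two-position ratio estimate of mueff.

    mueff = [b * ln(r2/r1) - ln(p1/p2)] / (r1 - r2); the closed-form
    inversion of the amplitude ratio P(r1)/P(r2) = (r2/r1)**b *
    exp(-mueff*(r1 - r2)).
    """
    if p1 <= 0 or p2 <= 0:
        raise ValidationError("amplitudes must be positive")
    if r1 <= 0 or r2 <= 0:
        raise ValidationError("distances must be positive")
    if r1 == r2:
        raise ValidationError("r1 and r2 must differ")
    return (b * math.log(r2 / r1) - math.log(p1 / p2)) / (r1 - r2)


def aggregate_mueff(
    est: MuEffEstimate,
    rng: Sequence[float],
    centers: Optional[np.ndarray] = None,
    axis: str = "depth_mm",
) -> float:
    """Arithmetic mean of the local mueff over windows inside ``rng``.

    ``centers`` defaults to the window depth centers; pass per-window
    strain values (same length/order as ``est.mueff_local``) to aggregate
    the displacement protocol over a strain interval instead. The result
    and range are recorded on the estimate.
    """
    lo, hi = rng
    if hi <= lo:
        raise ValidationError(f"invalid aggregation range ({lo}, {hi})")
    c = est.window_centers if centers is None else np.asarray(centers, dtype=float)
    if c.shape != est.mueff_local.shape:
        raise ValidationError("centers must align with the windowed estimates")
    mask = (c >= lo) & (c <= hi)
    if not mask.any():
        raise EstimationError(f"no windows inside the aggregation range [{lo}, {hi}]")
    value = float(np.mean(est.mueff_local[mask]))
    est.mueff_aggregate = value
    est.aggregate_range = (float(lo), float(hi))
    est.aggregate_axis = axis
    return value


def strain_axis(trace: AmplitudeTrace, initial_length: float) -> np.ndarray:
    """Engineering strain (DeltaL / L) per frame for the displacement protocol.

    Compression toward the target shortens the optical path, so
    strain[i] = (r[0] - r[i]) / initial_length.
    """
    if initial_length <= 0:
        raise ValidationError("initial_length must be > 0")
    return (trace.r[0] - trace.r) / float(initial_length)
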