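"""Temporal-resolution handling: analysis time bases and signal interpolation.

Four analysis approaches are supported; they differ in the time vector the
quantifier sees and in the sampling-interval divisor applied to the raw
per-sample IRF amplitude afterwards:

==============  ======================  ==========================
approach        time vector             amplitude normalization
==============  ======================  ==========================
none            sample index 0,1,2,...  none (assumed dt = 1 s)
input_time      index 0,1,2,...         none
scaling         index 0,1,2,...         divide by the input dt
interpolation   interpolated seconds    divide by the interpolated dt
==============  ======================  ==========================

For ``input_time`` the quantifier is handed the true acquisition times
(e.g. t = 0, 2, 4, ... s at 30 bpm) but the amplitude stays per-sample, so
the estimated flow matches the uncorrected analysis — correcting the IRF
width but not its height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator, make_smoothing_spline

from .curves import SampledCurve

__all__ = [
    "APPROACHES",
    "INTERP_ALGORITHMS",
    "TimeBase",
    "prepare_timebase",
    "interpolate_curve",
    "median_dt",
]

APPROACHES = ("none", "input_time", "scaling", "interpolation")
INTERP_ALGORITHMS = ("linear", "pchip", "cubic_spline", "smoothing_spline")


@dataclass(frozen=True)
class TimeBase:
    """The time vector a quantifier works on, plus normalization metadata.

    ``vector`` is in seconds for input_time/interpolated modes and in
    sample-index units for index mode; ``dt_norm`` is the divisor applied
    to the raw per-sample amplitude when converting to flow (1 when no
    normalization is requested).
    """

    vector: np.ndarray
    dt_nominal: float
    mode: str  # index | input_time | interpolated
    dt_norm: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if np.any(np.diff(v) <= 0):
            raise ValueError("time base must be strictly increasing")
        object.__setattr__(self, "vector", v)
        if self.mode == "index" and v.size >= 2:
            if abs((v[1] - v[0]) - 1.0) > 1e-12:
                raise ValueError("index mode implies unit spacing")


def median_dt(times: np.ndarray) -> float:
    """Median of successive time differences.

    Used to derive a representative sampling interval when the heart rate
    varies during a scan; the median is insensitive to occasional ECG
    mistriggers that double or halve one interval.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 time stamps")
    d = np.diff(t)
    if np.any(d <= 0):
        raise ValueError("time stamps must be strictly increasing")
    return float(np.median(d))


def prepare_timebase(curve: SampledCurve, approach: str) -> TimeBase:
    """Build the quantification time base for one analysis approach.

    The curve must already be on its final sampling grid (after any
    interpolation).  For a non-uniform grid the scaling approach falls
    back to the median sampling interval.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")
    n = len(curve)
    t = np.asarray(curve.times, dtype=float)
    dt_nom = median_dt(t)
    if approach == "none":
        return TimeBase(np.arange(n, dtype=float), dt_nom, "index", dt_norm=1.0)
    if approach == "input_time":
        return TimeBase(t - t[0], dt_nom, "input_time", dt_norm=1.0)
    if approach == "scaling":
        return TimeBase(np.arange(n, dtype=float), dt_nom, "index", dt_norm=dt_nom)
    # interpolation: the caller interpolated already; normalize by its dt
    return TimeBase(t - t[0], dt_nom, "interpolated", dt_norm=dt_nom)


def interpolate_curve(
    curve: SampledCurve,
    target_hr: float,
    algorithm: str = "cubic_spline",
    smoothing_p: float = 0.9,
) -> SampledCurve:
    """Resample a curve to a fixed heart rate ``target_hr`` (bpm).

    The target grid is ``t0 + k * 60/target_hr`` truncated to the source
    range (no extrapolation).  ``linear``, ``pchip`` and ``cubic_spline``
    pass through the source samples; ``smoothing_spline`` minimizes
    ``p * sum(residual^2) + (1 - p) * integral(f'')^2`` with
    ``p = smoothing_p`` (p -> 1 recovers interpolation) and evaluates the
    smoother on the target grid.
    """
    if target_hr <= 0:
        raise ValueError("target_hr must be positive")
    if algorithm not in INTERP_ALGORITHMS:
        raise ValueError(
            f"unknown interpolation algorithm {algorithm!r}; "
            f"expected one of {INTERP_ALGORITHMS}"
        )
    if len(curve) < 4:
        raise ValueError("interpolation needs at least 4 samples")
    t = curve.times
    dt_t = 60.0 / target_hr
    n_out = int(np.floor((t[-1] - t[0]) / dt_t + 1e-9)) + 1
    new_t = t[0] + dt_t * np.arange(n_out)
    if n_out < 2:
        raise ValueError("target grid has fewer than 2 samples")

    if algorithm == "linear":
        new_v = np.interp(new_t, t, curve.values)
    elif algorithm == "pchip":
        new_v = PchipInterpolator(t, curve.values)(new_t)
    elif algorithm == "cubic_spline":
        new_v = CubicSpline(t, curve.values)(new_t)
    else:  # smoothing_spline
        if not (0 < smoothing_p <= 1):
            raise ValueError("smoothing_p must be in (0, 1]")
        if smoothing_p == 1.0:
            lam = 0.0
        else:
            lam = (1.0 - smoothing_p) / smoothing_p
        new_v = make_smoothing_spline(t, curve.values, lam=lam)(new_t)
    meta = dict(curve.meta)
    meta.update({"interpolated_hr": target_hr, "interp_algorithm": algorithm})
    return SampledCurve(new_t, np.asarray(new_v, dtype=float), kind=curve.kind,
                        meta=meta)
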