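"""Core containers for time-stamped concentration curves.

Everything downstream (simulation, deconvolution, correction) passes
:class:`SampledCurve` objects around.  Curves are immutable-by-convention:
operations return new instances rather than mutating in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeGrid", "SampledCurve", "GroundTruth", "CurveKind"]

#: valid curve kinds
CurveKind = ("aif", "tissue", "irf", "residue")

#: relative tolerance used to decide whether a time vector is uniform
_UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid: ``times = start + dt * arange(n)``.

    The dense reference grid used for simulation defaults to 30 Hz over
    20 minutes, fine enough that a contrast bolus (features of several
    seconds) is effectively continuous.
    """

    start: float = 0.0
    dt: float = 1.0 / 30.0
    n: int = 36001

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n < 2:
            raise ValueError(f"need at least 2 samples, got n={self.n}")

    @property
    def duration(self) -> float:
        """Span ``(n - 1) * dt`` in seconds."""
        return (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.start + self.dt * np.arange(self.n)


def default_reference_grid() -> TimeGrid:
    """The dense simulation grid: 30 Hz sampling over 1200 s."""
    return TimeGrid(start=0.0, dt=1.0 / 30.0, n=36001)


@dataclass
class SampledCurve:
    """A concentration (or response-function) curve sampled in time.

    Parameters
    ----------
    times
        Sample times in seconds (or index units for an index time base),
        strictly increasing.
    values
        Sample values, arbitrary concentration units (1/s for an IRF,
        dimensionless for a residue function).
    kind
        One of ``aif``, ``tissue``, ``irf``, ``residue``.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "aif"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError(
                f"length mismatch: {self.times.size} times vs "
                f"{self.values.size} values"
            )
        if self.times.size < 2:
            raise ValueError("a curve needs at least 2 samples")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("non-finite time stamps")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite curve values")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.kind not in CurveKind:
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def __len__(self) -> int:
        return self.times.size

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.times)
        return bool(np.all(np.abs(d - d[0]) <= _UNIFORM_RTOL * abs(d[0]) + 1e-12))

    @property
    def dt(self) -> float:
        """Sampling interval; raises if the grid is non-uniform."""
        if not self.is_uniform:
            raise ValueError("curve is not uniformly sampled; use median_dt")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def integral(self) -> float:
        """Trapezoidal integral of the curve over its full span."""
        return float(np.trapezoid(self.values, self.times))

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "SampledCurve":
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=self.kind if kind is None else kind)


@dataclass(frozen=True)
class GroundTruth:
    """Exact perfusion parameters of a simulated reference pair.

    mbf : myocardial blood flow, mL/g/min
    vb  : myocardial blood volume, mL/g
    mtt : mean transit time, seconds; by the central volume theorem
          ``mtt = 60 * vb / mbf``
    density : myocardial density, g/mL (1 by convention)
    """

    mbf: float
    vb: float = 0.3
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.mbf <= 0:
            raise ValueError("mbf must be positive")
        if self.vb <= 0:
            raise ValueError("vb must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def mtt(self) -> float:
        """Mean transit time in seconds, ``60 * vb / mbf``."""
        return 60.0 * self.vb / self.mbf
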