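"""Time-dependent external inputs to the unit model.

An :class:`ExternalDrive` bundles four channels: glutamate release flux
into the ECS ``j_rel`` (mM/s), cerebral blood flow ``cbf`` (dimensionless
multiple of the baseline rate), noradrenaline ``ne`` (uM) and an injected
membrane current ``i_ext`` (uA/cm^2, only used when the electrical module
is coupled). Channels are signals with well-defined breakpoints so the
integrator can restart exactly at discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Signal",
    "Constant",
    "PiecewiseConstant",
    "ExpPulseTrain",
    "ExternalDrive",
]


class Signal:
    """Scalar function of time with breakpoint bookkeeping."""

    def at(self, t: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """Discontinuity/kink times strictly inside (t0, t1)."""
        return np.empty(0)

    def sample(self, t: np.ndarray) -> np.ndarray:
        return np.array([self.at(float(ti)) for ti in np.asarray(t)])


@dataclass(frozen=True)
class Constant(Signal):
    value: float = 0.0

    def at(self, t: float) -> float:
        return self.value

    def sample(self, t: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(t).shape, self.value, dtype=float)


@dataclass(frozen=True)
class PiecewiseConstant(Signal):
    """Right-continuous step function.

    ``value(t) = values[j]`` on ``[times[j], times[j+1])``; ``default``
    before the first breakpoint and after the last segment if ``values``
    is one shorter than ``times``, else the last value extends.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]
    default: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if len(self.values) not in (len(self.times), len(self.times) - 1):
            raise ValueError("values must have len(times) or len(times)-1 entries")

    def at(self, t: float) -> float:
        times = self.times
        if t < times[0]:
            return self.default
        j = int(np.searchsorted(times, t, side="right")) - 1
        if j >= len(self.values):
            return self.default
        return self.values[j]

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        t = np.asarray(self.times, dtype=float)
        return t[(t > t0) & (t < t1)]


@dataclass(frozen=True)
class ExpPulseTrain(Signal):
    """Superposed causal exponential transients, one per event time.

    ``f(t) = sum_k (q/tau) * exp(-(t - t_k)/tau)`` for ``t >= t_k``; each
    transient integrates to ``q``.
    """

    event_times: tuple[float, ...]
    q: float
    tau: float
    baseline: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.event_times, dtype=float)
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("event times must be sorted")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.q < 0:
            raise ValueError("q must be >= 0")

    def at(self, t: float) -> float:
        t_k = np.asarray(self.event_times, dtype=float)
        dt = t - t_k[t_k <= t]
        return self.baseline + float(np.sum((self.q / self.tau) * np.exp(-dt / self.tau)))

    def sample(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline, dtype=float)
        for t_k in self.event_times:
            mask = t >= t_k
            out[mask] += (self.q / self.tau) * np.exp(-(t[mask] - t_k) / self.tau)
        return out

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        t = np.asarray(self.event_times, dtype=float)
        return t[(t > t0) & (t < t1)]


@dataclass
class ExternalDrive:
    """The four external input channels of one unit."""

    j_rel: Signal = field(default_factory=Constant)
    cbf: Signal = field(default_factory=lambda: Constant(1.0))
    ne: Signal = field(default_factory=Constant)
    i_ext: Signal = field(default_factory=Constant)

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        pts = [sig.breakpoints(t0, t1) for sig in (self.j_rel, self.cbf, self.ne, self.i_ext)]
        return np.unique(np.concatenate([np.asarray(p, dtype=float) for p in pts]))

    def at(self, t: float) -> tuple[float, float, float, float]:
        return (self.j_rel.at(t), self.cbf.at(t), self.ne.at(t), self.i_ext.at(t))


RESTING_DRIVE = ExternalDrive()
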