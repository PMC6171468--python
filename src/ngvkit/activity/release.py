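"""Spike-train to glutamate-release conversion."""

from __future__ import annotations

import numpy as np

from ..metabolic_core.drive import ExpPulseTrain

__all__ = ["release_from_spikes"]


def release_from_spikes(spike_times, q: float, tau_rel: float = 0.002) -> ExpPulseTrain:
    """Exponential release transients from a sorted spike train.

    Each spike at ``t_k`` (s) contributes ``(q/tau_rel) exp(-(t-t_k)/tau_rel)``
    for ``t >= t_k`` so its time integral is exactly ``q`` (mM); coincident
    and overlapping transients superpose.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike_times must be a 1-D sequence")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spike_times must be sorted non-decreasing")
    if q < 0:
        raise ValueError("q must be >= 0")
    if tau_rel <= 0:
        raise ValueError("tau_rel must be > 0")
    return ExpPulseTrain(event_times=tuple(t), q=q, tau=tau_rel)
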