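"""Membrane excitability: classic single-compartment kinetics with
concentration-dependent reversal potentials.

The sodium reversal potential is recomputed every step from the current
intracellular Na of the metabolic state via the Nernst relation; the
potassium reversal is fixed by default (extracellular K is not a tracked
species) and can be made dynamic through ``dynamic_e_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["MembraneState", "nernst", "hh_step", "simulate_membrane", "HHParams"]

R_GAS = 8.314462618      # J/(mol K)
FARADAY = 96485.33212    # C/mol


def nernst(z: int, c_out: float, c_in: float, T: float = 310.0) -> float:
    """Nernst reversal potential in mV: ``(RT/zF) ln(c_out/c_in)``."""
    if c_out <= 0 or c_in <= 0:
        raise ValueError(
            f"concentrations must be > 0 (c_out={c_out}, c_in={c_in})"
        )
    if z == 0:
        raise ValueError("valence must be nonzero")
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    return 1e3 * R_GAS * T / (z * FARADAY) * np.log(c_out / c_in)


@dataclass(frozen=True)
class HHParams:
    """Squid-axon kinetics with fixed temperature factor."""

    c_m: float = 1.0          # uF/cm^2
    g_na: float = 120.0       # mS/cm^2
    g_k: float = 36.0
    g_leak: float = 0.3
    e_leak: float = -54.387   # mV
    e_k_fixed: float = -77.0  # mV, used unless dynamic_e_k
    na_out: float = 140.0     # mM extracellular Na
    k_out: float = 5.0        # mM extracellular K (dynamic mode only)
    k_in: float = 140.0       # mM intracellular K (dynamic mode only)
    temperature: float = 310.0  # K, for the Nernst relation
    phi: float = 1.0          # gating temperature factor
    dynamic_e_k: bool = False


@dataclass(frozen=True)
class MembraneState:
    V: float                  # mV
    m: float
    h: float
    n: float
    E_Na: float               # mV
    E_K: float                # mV

    def validate(self) -> None:
        vals = (self.V, self.m, self.h, self.n, self.E_Na, self.E_K)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite membrane state: {self}")
        for g, name in ((self.m, "m"), (self.h, "h"), (self.n, "n")):
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"gating variable {name} out of [0,1]: {g}")


def _alpha_beta(V: float) -> tuple[float, ...]:
    # singular points handled by the exact limits
    dv = V + 40.0
    a_m = 1.0 if abs(dv) < 1e-7 else 0.1 * dv / (1.0 - np.exp(-dv / 10.0))
    b_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    dv = V + 55.0
    a_n = 0.1 if abs(dv) < 1e-7 else 0.01 * dv / (1.0 - np.exp(-dv / 10.0))
    b_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def resting_membrane(params: HHParams = HHParams(), na_in: float = 10.0) -> MembraneState:
    """Gates at their steady values for the resting potential."""
    V = -65.0
    a_m, b_m, a_h, b_h, a_n, b_n = _alpha_beta(V)
    e_na = nernst(1, params.na_out, na_in, params.temperature)
    e_k = (nernst(1, params.k_out, params.k_in, params.temperature)
           if params.dynamic_e_k else params.e_k_fixed)
    return MembraneState(V=V, m=a_m / (a_m + b_m), h=a_h / (a_h + b_h),
                         n=a_n / (a_n + b_n), E_Na=e_na, E_K=e_k)


def _hh_rhs(v, m, h, n, i_ext, e_na, e_k, p: HHParams):
    a_m, b_m, a_h, b_h, a_n, b_n = _alpha_beta(v)
    i_na = p.g_na * m ** 3 * h * (v - e_na)
    i_k = p.g_k * n ** 4 * (v - e_k)
    i_l = p.g_leak * (v - p.e_leak)
    dv = (i_ext - i_na - i_k - i_l) / p.c_m
    return (dv,
            p.phi * (a_m * (1 - m) - b_m * m),
            p.phi * (a_h * (1 - h) - b_h * h),
            p.phi * (a_n * (1 - n) - b_n * n),
            i_na)


def hh_step(
    mem: MembraneState,
    i_ext: float,
    na_in: float,
    dt: float,
    params: HHParams = HHParams(),
) -> tuple[MembraneState, bool, float]:
    """One RK4 step of ``dt`` ms.

    Returns ``(new_state, spiked, i_na)`` where ``spiked`` flags an
    upward crossing of 0 mV and ``i_na`` (uA/cm^2) is the sodium current
    at the step start, available as a feedback flux for the metabolic
    model when coupling is enabled.

    ``na_in`` is the intracellular sodium (mM) used to refresh ``E_Na``.
    """
    if dt > 0.025:
        raise ValueError(f"dt must be <= 0.025 ms, got {dt}")
    mem.validate()
    e_na = nernst(1, params.na_out, na_in, params.temperature)
    e_k = (nernst(1, params.k_out, params.k_in, params.temperature)
           if params.dynamic_e_k else params.e_k_fixed)

    v, m, h, n = mem.V, mem.m, mem.h, mem.n
    k1 = _hh_rhs(v, m, h, n, i_ext, e_na, e_k, params)
    k2 = _hh_rhs(v + 0.5 * dt * k1[0], m + 0.5 * dt * k1[1],
                 h + 0.5 * dt * k1[2], n + 0.5 * dt * k1[3],
                 i_ext, e_na, e_k, params)
    k3 = _hh_rhs(v + 0.5 * dt * k2[0], m + 0.5 * dt * k2[1],
                 h + 0.5 * dt * k2[2], n + 0.5 * dt * k2[3],
                 i_ext, e_na, e_k, params)
    k4 = _hh_rhs(v + dt * k3[0], m + dt * k3[1], h + dt * k3[2],
                 n + dt * k3[3], i_ext, e_na, e_k, params)
    v2 = v + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    m2 = min(1.0, max(0.0, m + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])))
    h2 = min(1.0, max(0.0, h + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])))
    n2 = min(1.0, max(0.0, n + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])))
    spiked = v < 0.0 <= v2
    new = MembraneState(V=v2, m=m2, h=h2, n=n2, E_Na=e_na, E_K=e_k)
    return new, spiked, k1[4]


def na_influx_from_current(i_na: float, surface_to_volume: float = 3.0e4) -> float:
    """Convert a sodium membrane current to a concentration flux.

    ``i_na`` is the HH sodium current in uA/cm^2 (negative = inward);
    ``surface_to_volume`` in 1/cm. Returns the intracellular Na influx in
    mM/s, the feedback term added to the metabolic unit's sodium balance
    when electrical coupling is enabled.
    """
    # uA/cm^2 -> mol/(s cm^2) is 1e-6/F; times S/V gives mol/(s cm^3),
    # and 1 mol/cm^3 = 1e6 mM, so the 1e-6 and 1e6 cancel
    return -i_na * surface_to_volume / FARADAY


def simulate_membrane(
    i_ext,
    t_span_ms: tuple[float, float],
    dt: float = 0.01,
    na_in: float = 10.0,
    params: HHParams = HHParams(),
    mem0: MembraneState | None = None,
):
    """Fixed-step membrane simulation.

    ``i_ext`` is a callable of time in ms (or a constant). Returns
    ``(t_ms, V_trace, spike_times_ms)``.
    """
    if not callable(i_ext):
        amp = float(i_ext)
        i_ext = lambda t: amp  # noqa: E731
    t0, t1 = t_span_ms
    n_steps = int(round((t1 - t0) / dt))
    mem = mem0 or resting_membrane(params, na_in)
    t = t0 + dt * np.arange(n_steps + 1)
    v = np.empty(n_steps + 1)
    v[0] = mem.V
    spikes = []
    for i in range(n_steps):
        mem, spiked, _ = hh_step(mem, i_ext(t[i]), na_in, dt, params)
        v[i + 1] = mem.V
        if spiked:
            spikes.append(t[i + 1])
    return t, v, np.asarray(spikes)
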