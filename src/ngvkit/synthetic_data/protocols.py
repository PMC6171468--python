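"""Named drive protocols and their config (de)serialization.

A protocol config is a plain dict (YAML/TOML friendly) with one entry
per channel; each channel is either a constant, a pulse list, or a step
list. ``drive_from_config`` reconstructs the drive, so profiles round-
trip losslessly through the config reader.
"""

from __future__ import annotations

import numpy as np

from ..metabolic_core.drive import Constant, ExternalDrive, PiecewiseConstant

__all__ = ["make_drive_profile", "drive_to_config", "drive_from_config", "PROTOCOLS"]

_CHANNELS = ("j_rel", "cbf", "ne", "i_ext")
_BASELINES = {"j_rel": 0.0, "cbf": 1.0, "ne": 0.0, "i_ext": 0.0}


def _pulse(t_on: float, t_off: float, amplitude: float, baseline: float) -> PiecewiseConstant:
    if t_off <= t_on:
        raise ValueError("pulse must have t_off > t_on")
    return PiecewiseConstant((float(t_on), float(t_off)), (float(amplitude),), baseline)


def make_drive_profile(protocol: str, magnitudes: dict | None = None,
                       timings: dict | None = None) -> ExternalDrive:
    """Library of named protocols: rest, stimulus, ne_pulse, cbf_step."""
    mag = dict(magnitudes or {})
    tim = dict(timings or {})
    if protocol == "rest":
        return ExternalDrive()
    if protocol == "stimulus":
        return ExternalDrive(
            j_rel=_pulse(tim.get("t_on", 1.0), tim.get("t_off", 2.0),
                         mag.get("j_rel", 0.5), 0.0)
        )
    if protocol == "ne_pulse":
        return ExternalDrive(
            ne=_pulse(tim.get("t_on", 1.0), tim.get("t_off", 3.0),
                      mag.get("ne", 1.0), 0.0)
        )
    if protocol == "cbf_step":
        t_on = float(tim.get("t_on", 1.0))
        return ExternalDrive(
            cbf=PiecewiseConstant((t_on,), (float(mag.get("cbf", 1.5)),), 1.0)
        )
    raise ValueError(f"unknown protocol {protocol!r}")


def drive_to_config(drive: ExternalDrive) -> dict:
    cfg: dict = {}
    for ch in _CHANNELS:
        sig = getattr(drive, ch)
        if isinstance(sig, Constant):
            cfg[ch] = {"kind": "constant", "value": float(sig.value)}
        elif isinstance(sig, PiecewiseConstant):
            cfg[ch] = {
                "kind": "piecewise",
                "times": [float(t) for t in sig.times],
                "values": [float(v) for v in sig.values],
                "default": float(sig.default),
            }
        else:
            raise TypeError(f"cannot serialize signal of type {type(sig).__name__}")
    return cfg


def drive_from_config(cfg: dict) -> ExternalDrive:
    channels = {}
    for ch in _CHANNELS:
        entry = cfg.get(ch)
        if entry is None:
            channels[ch] = Constant(_BASELINES[ch])
            continue
        kind = entry.get("kind")
        if kind == "constant":
            channels[ch] = Constant(float(entry["value"]))
        elif kind == "piecewise":
            times = tuple(float(t) for t in entry["times"])
            values = tuple(float(v) for v in entry["values"])
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"channel {ch}: overlapping/contradictory segments")
            channels[ch] = PiecewiseConstant(times, values, float(entry.get("default", _BASELINES[ch])))
        else:
            raise ValueError(f"channel {ch}: unknown signal kind {kind!r}")
    return ExternalDrive(**channels)


PROTOCOLS = ("rest", "stimulus", "ne_pulse", "cbf_step")
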