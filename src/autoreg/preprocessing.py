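"""Turning raw diameter recordings and step descriptions into model inputs.

Raw traces are continuous (possibly non-uniformly sampled) internal-diameter
recordings together with the timed step changes of the intraluminal pressure
PI and the pressure gradient dP that were applied during the experiment.  The
compliance model is only valid for modest perturbations, so recordings are
truncated at the first point where the inputs leave the admissible window
(|PI - PI_base| > 40 cmH2O or |dP - dP_base| > 10 cmH2O).  Observations are
resampled onto the uniform 1.5-s grid the calibration compares on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .model import (CMH2O_PA, MMHG_PA, OBS_DT, DiameterTrace,
                    build_input_signals)

__all__ = [
    "RawTrace",
    "truncate_series",
    "build_input_signals",
    "resample_observed",
    "estimate_time_constant",
    "convert_pressure",
    "PI_LIMIT",
    "DP_LIMIT",
]

PI_LIMIT = 40.0 * CMH2O_PA   # admissible |PI - PI_base|, Pa
DP_LIMIT = 10.0 * CMH2O_PA   # admissible |dP - dP_base|, Pa


@dataclass(frozen=True)
class RawTrace:
    """A raw recording: times (s, strictly increasing), diameters (um) and the
    step descriptions (time s, value Pa) of both inputs."""

    times: np.ndarray
    diameters: np.ndarray
    PI_events: tuple[tuple[float, float], ...] = ()
    dP_events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.diameters, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "diameters", d)
        if t.shape != d.shape:
            raise ValueError("times and diameters must match in length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


def _step_value(t: float, base: float, events: Sequence[tuple[float, float]]) -> float:
    value = base
    for et, ev in sorted(events):
        if et <= t:
            value = ev
        else:
            break
    return value


def truncate_series(raw: RawTrace, PI_base: float, dP_base: float) -> RawTrace:
    """Drop the suffix starting at the first admissibility violation.

    A point violates when |PI - PI_base| > 40 cmH2O or |dP - dP_base| >
    10 cmH2O (strict inequalities: the boundary is retained).  The output ends
    immediately before the first violating point; truncation is idempotent.
    """
    keep = len(raw.times)
    for k, t in enumerate(raw.times):
        PI = _step_value(t, PI_base, raw.PI_events)
        dP = _step_value(t, dP_base, raw.dP_events)
        if abs(PI - PI_base) > PI_LIMIT or abs(dP - dP_base) > DP_LIMIT:
            keep = k
            break
    if keep == 0:
        raise ValueError("first sample already violates the perturbation limits")
    if keep == len(raw.times):
        return raw
    return replace(raw, times=raw.times[:keep], diameters=raw.diameters[:keep])


def resample_observed(raw: RawTrace, obs_dt: float = OBS_DT) -> DiameterTrace:
    """Linear interpolation of the raw recording onto the uniform 1.5-s grid."""
    if raw.times[-1] - raw.times[0] < obs_dt:
        raise ValueError("raw span shorter than one observation interval")
    t0 = raw.times[0]
    times = np.arange(t0, raw.times[-1] + 1e-9, obs_dt)
    if times[-1] > raw.times[-1] + 1e-9:
        raise ValueError("observation grid extends beyond the raw span")
    D = np.interp(times, raw.times, raw.diameters)
    return DiameterTrace(times=times, D=D)


def estimate_time_constant(trace: DiameterTrace, t_start: float,
                           noise_floor: float = 0.5) -> float:
    """Empirical time constant of a step response by the 1 - 1/e criterion.

    The response is measured between the diameter at ``t_start`` and the
    post-step plateau (mean of the last 10% of the window); the estimate is
    the time after ``t_start`` at which the diameter has completed a fraction
    1 - 1/e of that excursion, located by linear interpolation between
    samples.  Works for both dilations and constrictions.
    """
    mask = trace.times >= t_start
    if mask.sum() < 3:
        raise ValueError("too few samples after t_start")
    t = trace.times[mask]
    d = trace.D[mask]
    d0 = float(np.interp(t_start, trace.times, trace.D))
    n_tail = max(1, int(round(0.1 * len(d))))
    plateau = float(np.mean(d[-n_tail:]))
    excursion = plateau - d0
    if abs(excursion) <= noise_floor:
        raise ValueError("no measurable excursion: time constant undefined")
    frac = (d - d0) / excursion          # monotone 0 -> 1 modulo noise
    thresh = 1.0 - 1.0 / np.e
    above = np.nonzero(frac >= thresh)[0]
    if len(above) == 0:
        raise ValueError("response never reaches the 1 - 1/e level")
    k = above[0]
    if k == 0:
        return float(t[0] - t_start)
    # interpolate the crossing between samples k-1 and k
    f0, f1 = frac[k - 1], frac[k]
    w = (thresh - f0) / (f1 - f0) if f1 != f0 else 1.0
    t_cross = t[k - 1] + w * (t[k] - t[k - 1])
    return float(t_cross - t_start)


_TO_PA = {"Pa": 1.0, "mmHg": MMHG_PA, "cmH2O": CMH2O_PA}


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Exact pressure conversion between Pa, mmHg and cmH2O."""
    try:
        return value * _TO_PA[from_unit] / _TO_PA[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown pressure unit {exc.args[0]!r}") from None
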