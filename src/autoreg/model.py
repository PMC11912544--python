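"""Compliance-feedback model of a single autoregulating arteriole.

The vessel is described by three state variables: the internal radius ``R``
(m) and two dimensionless activation factors, myogenic ``xm`` (driven by wall
tension ``T = R*PI/2``) and endothelial ``xe`` (driven by the length-normalised
shear signal ``tau = R*dP/2``).  Each activation obeys first-order low-pass
dynamics with a gain and a reference value below which a ReLU clamps the drive
to zero.  The activation difference ``u = xe - xm`` sets the vessel compliance
per unit length through an asymmetric sigmoid

    C/Cb = 1 + delta_s * tanh(u / (G * delta_s)),

with ``delta_s = delta_plus`` for ``u >= 0`` and ``delta_minus`` for ``u < 0``,
so the map has central slope ``1/G``, upper asymptote ``1 + delta_plus`` and
lower asymptote ``1 - delta_minus`` and is C^1 at the origin.  The radius then
evolves through the compliance tube law

    2*pi*R * dR/dt = C * dPI/dt + Pv_bar * dC/dt.

Endothelial constriction on shear withdrawal is delayed: when the shear signal
``zeta`` seconds ago exceeds the current one, the endothelial drive uses the
older (higher) value, so a shear drop only reaches the endothelium after
``zeta`` seconds.

Integration uses a first-order hybrid implicit-explicit (IMEX) Euler scheme on
a uniform 0.2-s grid: the stiff linear decay terms ``-x/tau`` are treated
implicitly and every forcing/nonlinear term explicitly.  Simulated diameters
are sampled onto the 1.5-s observation grid by linear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CMH2O_PA",
    "MMHG_PA",
    "VesselParameters",
    "VesselState",
    "StepEvent",
    "ExperimentProtocol",
    "SimulatedTrace",
    "DiameterTrace",
    "SimulationFailure",
    "relative_compliance",
    "compliance_gradient_factor",
    "wall_tension",
    "shear_signal",
    "activation_rhs",
    "effective_delay",
    "radius_rhs",
    "steady_state_init",
    "build_input_signals",
    "simulate",
    "simulate_batch",
    "sample_observation_grid",
    "nominal_parameters",
    "OBS_DT",
    "SOLVER_DT",
]

CMH2O_PA = 98.0665   # 1 cmH2O in Pa
MMHG_PA = 133.322    # 1 mmHg in Pa

SOLVER_DT = 0.2      # s, fine integration step
OBS_DT = 1.5         # s, observation grid step


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselParameters:
    """Free parameters and fixed constants of one vessel (SI units).

    ``Sm``/``Se`` are the myogenic/endothelial gains, ``G`` the compliance
    slope parameter, ``T0`` the reference wall tension (N/m), ``tau0`` the
    reference length-normalised shear signal (kg/s^2), ``tau_m``/``tau_e`` the
    activation time constants (s), ``zeta`` the endothelial constriction delay
    (s), ``Cb`` the baseline compliance per unit length (m^3 s^2/kg) and
    ``Pv_bar`` the reference pressure (Pa).  ``tau_hist`` is the pre-recording
    shear signal, needed only for protocols whose shear drops at t = 0.
    """

    Sm: float
    Se: float
    G: float
    T0: float
    tau0: float
    tau_m: float
    tau_e: float
    zeta: float
    Cb: float
    Pv_bar: float
    L: float = 1.0e-3
    delta_plus: float = 10.0
    delta_minus: float = 0.8
    tau_hist: float | None = None

    def __post_init__(self) -> None:
        checks = [
            (self.tau_m > 0, "tau_m must be > 0"),
            (self.tau_e > 0, "tau_e must be > 0"),
            (self.zeta >= 0, "zeta must be >= 0"),
            (self.Cb > 0, "Cb must be > 0"),
            (self.G > 0, "G must be > 0"),
            (self.T0 > 0, "T0 must be > 0"),
            (self.tau0 > 0, "tau0 must be > 0"),
            (0 < self.delta_minus < 1, "delta_minus must lie in (0, 1)"),
            (self.delta_plus > 0, "delta_plus must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def with_tau_hist(self, tau_hist: float) -> "VesselParameters":
        return replace(self, tau_hist=tau_hist)


@dataclass(frozen=True)
class VesselState:
    """State (R, xm, xe) at one time point; R in metres."""

    R: float
    xm: float
    xe: float

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class StepEvent:
    """A timed step change of one input: target is 'PI' or 'dP', value in Pa."""

    time: float
    target: str
    value: float

    def __post_init__(self) -> None:
        if self.target not in ("PI", "dP"):
            raise ValueError(f"unknown step target {self.target!r}")


@dataclass(frozen=True)
class ExperimentProtocol:
    """Baseline inputs plus timed step events (all pressures in Pa).

    ``in_situ_dP`` is the pre-recording pressure gradient: when set, the
    initial endothelial activation and the pre-t=0 shear history refer to it
    rather than to ``dP_base`` (a shear drop at t = 0, delayed-constriction
    protocols).
    """

    PI_base: float
    dP_base: float
    events: tuple[StepEvent, ...] = ()
    duration: float = 300.0
    smoothing_width: float = 2.0
    in_situ_dP: float | None = None

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("event times must lie within [0, duration]")

    @property
    def init_dP(self) -> float:
        """Pressure gradient that sets the initial endothelial drive."""
        return self.dP_base if self.in_situ_dP is None else self.in_situ_dP


@dataclass
class SimulatedTrace:
    """Solver-grid histories of one simulation (SI units, C_rel dimensionless)."""

    times_fine: np.ndarray
    R: np.ndarray
    C_rel: np.ndarray
    xm: np.ndarray
    xe: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times_fine)
        if not all(len(a) == n for a in (self.R, self.C_rel, self.xm, self.xe)):
            raise ValueError("trace arrays must have equal length")


@dataclass
class DiameterTrace:
    """Observation-grid diameters: times in s (uniform 1.5-s), D in micrometres."""

    times: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.times.shape != self.D.shape:
            raise ValueError("times and D must have the same shape")


class SimulationFailure(RuntimeError):
    """Raised when a realization produces a non-physical state (R <= 0)."""


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _branch_delta(u, delta_plus: float, delta_minus: float):
    return np.where(np.asarray(u) >= 0.0, delta_plus, delta_minus)


def relative_compliance(u, params: VesselParameters):
    """Relative compliance C/Cb as a function of the activation difference u.

    Strictly increasing, bounded by (1 - delta_minus, 1 + delta_plus), with
    central slope 1/G on both sides of the origin.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("activation difference must be finite")
    delta = _branch_delta(u, params.delta_plus, params.delta_minus)
    out = 1.0 + delta * np.tanh(u / (params.G * delta))
    return out if out.ndim else float(out)


def compliance_gradient_factor(u, params: VesselParameters):
    """sech^2(u / (G * delta_s)): the saturation factor of dC/du = sech^2 / G."""
    u = np.asarray(u, dtype=float)
    delta = _branch_delta(u, params.delta_plus, params.delta_minus)
    with np.errstate(over="ignore"):            # saturated sech^2 -> 0
        out = 1.0 / np.cosh(u / (params.G * delta)) ** 2
    return out if out.ndim else float(out)


def wall_tension(R, PI):
    """Laplace wall tension T = R * PI / 2 (N/m)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("radius must be non-negative")
    out = R * np.asarray(PI, dtype=float) / 2.0
    return out if out.ndim else float(out)


def shear_signal(R, dP):
    """Length-normalised shear signal R * dP / 2 (kg/s^2).

    The vessel length is absorbed into the reference value tau0, so the
    endothelial drive compares R*dP/2 against tau0 directly.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("radius must be non-negative")
    out = R * np.asarray(dP, dtype=float) / 2.0
    return out if out.ndim else float(out)


def _relu(z):
    return np.maximum(z, 0.0)


def activation_rhs(state: VesselState, drive_m: float, drive_e_delayed: float,
                   params: VesselParameters) -> tuple[float, float]:
    """Time derivatives (dxm/dt, dxe/dt) of the two activation factors."""
    if params.tau_m <= 0 or params.tau_e <= 0:
        raise ValueError("time constants must be positive")
    dxm = (-state.xm + params.Sm * _relu((drive_m - params.T0) / params.T0)) / params.tau_m
    dxe = (-state.xe + params.Se * _relu((drive_e_delayed - params.tau0) / params.tau0)) / params.tau_e
    return float(dxm), float(dxe)


def effective_delay(times: np.ndarray, shear_history: np.ndarray, t: float,
                    params: VesselParameters, pre_history: float | None = None) -> float:
    """Delayed shear signal feeding the endothelial drive at time ``t``.

    The delay engages only against shear withdrawal: when the shear signal
    ``zeta`` seconds ago exceeds the current one, the older value is returned
    (the constriction stimulus reaches the endothelium ``zeta`` seconds late);
    otherwise the current value is used.  Lookups before the recorded history
    use ``pre_history`` (the pre-recording shear signal).
    """
    times = np.asarray(times, dtype=float)
    shear_history = np.asarray(shear_history, dtype=float)
    current = float(np.interp(t, times, shear_history))
    if params.zeta == 0.0:
        return current
    t_back = t - params.zeta
    if t_back < times[0]:
        if pre_history is None:
            raise ValueError("pre-history shear value required for lookup before the record")
        past = float(pre_history)
    else:
        past = float(np.interp(t_back, times, shear_history))
    return past if past > current else current


def radius_rhs(state: VesselState, C_rel: float, dPI_dt: float,
               dxm_dt: float, dxe_dt: float, params: VesselParameters) -> float:
    """dR/dt from the compliance tube law 2*pi*R dR/dt = C dPI/dt + Pv dC/dt."""
    if state.R <= 0:
        raise SimulationFailure("radius collapsed to a non-positive value")
    u = state.xe - state.xm
    sech2 = compliance_gradient_factor(u, params)
    dC_dt = (params.Cb / params.G) * sech2 * (dxe_dt - dxm_dt)
    return (params.Cb * C_rel * dPI_dt + params.Pv_bar * dC_dt) / (2.0 * math.pi * state.R)


def steady_state_init(R_target: float, protocol: ExperimentProtocol,
                      params: VesselParameters) -> VesselState:
    """Steady state (R_target, xm0, xe0) under constant baseline inputs.

    Setting each activation at its fixed point makes every term of dR/dt
    vanish, so simulating from here under constant inputs holds R constant.
    The endothelial drive uses ``in_situ_dP`` when the protocol defines one
    (shear present before the recording started).
    """
    if not R_target > 0:
        raise ValueError("target radius must be positive")
    T = wall_tension(R_target, protocol.PI_base)
    tau = shear_signal(R_target, protocol.init_dP)
    xm0 = params.Sm * float(_relu((T - params.T0) / params.T0))
    xe0 = params.Se * float(_relu((tau - params.tau0) / params.tau0))
    return VesselState(R=R_target, xm=xm0, xe=xe0)


# ---------------------------------------------------------------------------
# input signals
# ---------------------------------------------------------------------------

def build_input_signals(events: Sequence[StepEvent], baselines: tuple[float, float],
                        duration: float, smoothing_width: float,
                        dt: float = SOLVER_DT) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(PI(t), dP(t), dPI/dt(t)) on the uniform solver grid.

    Each step is replaced by a linear ramp of width ``smoothing_width`` centred
    on the event time; the signals are exact outside the ramp windows.
    dPI/dt is obtained by forward finite differences on the grid.
    """
    PI_base, dP_base = baselines
    t_grid = np.arange(0.0, duration + dt / 2, dt)
    PI = _step_signal([e for e in events if e.target == "PI"], PI_base,
                      duration, smoothing_width, t_grid)
    dP = _step_signal([e for e in events if e.target == "dP"], dP_base,
                      duration, smoothing_width, t_grid)
    dPI_dt = np.empty_like(PI)
    dPI_dt[:-1] = np.diff(PI) / dt
    dPI_dt[-1] = 0.0
    return PI, dP, dPI_dt


def _step_signal(events: Sequence[StepEvent], base: float, duration: float,
                 width: float, t_grid: np.ndarray) -> np.ndarray:
    half = width / 2.0
    events = sorted(events, key=lambda e: e.time)
    start = min([0.0] + [e.time - half for e in events]) - 1.0
    knots_t = [start]
    knots_v = [base]
    level = base
    for e in events:
        t0, t1 = e.time - half, e.time + half
        if t0 < knots_t[-1] - 1e-12:
            raise ValueError("smoothing ramps overlap; reduce smoothing_width")
        knots_t.extend([t0, t1])
        knots_v.extend([level, e.value])
        level = e.value
    knots_t.append(max(duration, knots_t[-1]) + 1.0)
    knots_v.append(level)
    return np.interp(t_grid, knots_t, knots_v)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

_THETA_KEYS = ("Sm", "Se", "G", "T0", "tau0", "tau_m", "tau_e", "zeta",
               "Ri", "xmi", "xei")


def simulate_batch(theta: Mapping[str, np.ndarray], constants: VesselParameters,
                   protocol: ExperimentProtocol, dt: float = SOLVER_DT,
                   record_states: bool = False) -> dict:
    """Integrate many realizations of the vessel ODEs simultaneously.

    ``theta`` maps each free-variable name (Sm, Se, G, T0, tau0, tau_m, tau_e,
    zeta, Ri, xmi, xei and optionally tau_hist) to an array of length M; the
    fixed constants (Cb, Pv_bar, delta_plus, delta_minus) come from
    ``constants``.  Returns a dict with the fine time grid, the radius history
    (n_t x M), a boolean ``failed`` mask (realizations whose radius collapsed
    or went non-finite are frozen and flagged, not raised) and, when
    ``record_states`` is set, the xm/xe/C_rel histories.
    """
    arrays = {k: np.asarray(theta[k], dtype=float) for k in _THETA_KEYS}
    M = arrays["Ri"].shape[0]
    PI, dP, dPI_dt = build_input_signals(protocol.events,
                                         (protocol.PI_base, protocol.dP_base),
                                         protocol.duration, protocol.smoothing_width, dt)
    n_t = PI.shape[0]
    times = np.arange(n_t) * dt

    Sm, Se, G = arrays["Sm"], arrays["Se"], arrays["G"]
    T0, tau0 = arrays["T0"], arrays["tau0"]
    tau_m, tau_e, zeta = arrays["tau_m"], arrays["tau_e"], arrays["zeta"]
    dp_, dm_ = constants.delta_plus, constants.delta_minus
    Cb, Pv = constants.Cb, constants.Pv_bar

    R = arrays["Ri"].copy()
    xm = arrays["xmi"].copy()
    xe = arrays["xei"].copy()

    if "tau_hist" in theta and theta["tau_hist"] is not None:
        pre_hist = np.asarray(theta["tau_hist"], dtype=float)
    elif protocol.in_situ_dP is not None:
        pre_hist = shear_signal(R, protocol.in_situ_dP)
    else:
        pre_hist = shear_signal(R, dP[0])

    R_hist = np.empty((n_t, M))
    shear_hist = np.empty((n_t, M))
    if record_states:
        xm_hist = np.empty((n_t, M))
        xe_hist = np.empty((n_t, M))
    failed = np.zeros(M, dtype=bool)

    lag = zeta / dt                      # fractional steps, per realization
    cols = np.arange(M)
    decay_m = 1.0 + dt / tau_m
    decay_e = 1.0 + dt / tau_e
    two_pi = 2.0 * math.pi

    R_hist[0] = R
    shear_hist[0] = R * dP[0] / 2.0
    if record_states:
        xm_hist[0], xe_hist[0] = xm, xe

    for n in range(n_t - 1):
        shear_now = shear_hist[n]
        # delayed endothelial drive: look back zeta seconds; before the record
        # use the pre-history value; engage only against shear withdrawal
        idx = n - lag
        below = idx < 0.0
        idx_c = np.clip(idx, 0.0, n)
        i0 = np.floor(idx_c).astype(np.intp)
        i1 = np.minimum(i0 + 1, n)
        frac = idx_c - i0
        past = shear_hist[i0, cols] * (1.0 - frac) + shear_hist[i1, cols] * frac
        past = np.where(below, pre_hist, past)
        drive_shear = np.maximum(shear_now, past)

        tension = R * PI[n] / 2.0
        f_m = (Sm / tau_m) * _relu((tension - T0) / T0)
        f_e = (Se / tau_e) * _relu((drive_shear - tau0) / tau0)
        xm_new = (xm + dt * f_m) / decay_m
        xe_new = (xe + dt * f_e) / decay_e

        u = xe - xm
        delta = np.where(u >= 0.0, dp_, dm_)
        arg = u / (G * delta)
        c_rel = 1.0 + delta * np.tanh(arg)
        with np.errstate(over="ignore"):        # saturated sech^2 -> 0
            sech2 = 1.0 / np.cosh(arg) ** 2
        dxe_minus_dxm = (xe_new - xe - (xm_new - xm)) / dt
        dRdt = (Cb * c_rel * dPI_dt[n] + Pv * (Cb / G) * sech2 * dxe_minus_dxm) / (two_pi * R)
        R_new = R + dt * dRdt

        bad = ~np.isfinite(R_new) | (R_new <= 0.0) | ~np.isfinite(xm_new) | ~np.isfinite(xe_new)
        newly = bad & ~failed
        if newly.any():
            failed |= newly
        keep = ~failed
        R = np.where(keep, R_new, R)
        xm = np.where(keep, xm_new, xm)
        xe = np.where(keep, xe_new, xe)

        R_hist[n + 1] = R
        shear_hist[n + 1] = R * dP[n + 1] / 2.0
        if record_states:
            xm_hist[n + 1], xe_hist[n + 1] = xm, xe

    out = {"times": times, "R": R_hist, "failed": failed}
    if record_states:
        u_hist = xe_hist - xm_hist
        delta = np.where(u_hist >= 0.0, dp_, dm_)
        out["xm"] = xm_hist
        out["xe"] = xe_hist
        out["C_rel"] = 1.0 + delta * np.tanh(u_hist / (G[np.newaxis, :] * delta))
    return out


def simulate(params: VesselParameters, init: VesselState,
             protocol: ExperimentProtocol, dt: float = SOLVER_DT) -> SimulatedTrace:
    """Integrate one realization and record full state histories.

    A realization whose radius collapses raises :class:`SimulationFailure`;
    the ABC layer treats that as a rejection.
    """
    theta = {
        "Sm": [params.Sm], "Se": [params.Se], "G": [params.G],
        "T0": [params.T0], "tau0": [params.tau0],
        "tau_m": [params.tau_m], "tau_e": [params.tau_e], "zeta": [params.zeta],
        "Ri": [init.R], "xmi": [init.xm], "xei": [init.xe],
    }
    if params.tau_hist is not None:
        theta["tau_hist"] = [params.tau_hist]
    res = simulate_batch({k: np.asarray(v) for k, v in theta.items()},
                         params, protocol, dt=dt, record_states=True)
    if res["failed"][0]:
        raise SimulationFailure("radius collapsed or state became non-finite")
    return SimulatedTrace(times_fine=res["times"], R=res["R"][:, 0],
                          C_rel=res["C_rel"][:, 0], xm=res["xm"][:, 0],
                          xe=res["xe"][:, 0])


def sample_observation_grid(trace: SimulatedTrace, obs_dt: float = OBS_DT) -> DiameterTrace:
    """Linear interpolation of D = 2R (micrometres) onto the 1.5-s grid."""
    if len(trace.times_fine) == 0:
        raise ValueError("empty trace")
    t_end = trace.times_fine[-1]
    times = np.arange(0.0, t_end + 1e-9, obs_dt)
    if times[-1] > t_end + 1e-9 or times[0] < trace.times_fine[0] - 1e-9:
        raise ValueError("observation grid outside the solver span")
    D = np.interp(times, trace.times_fine, 2.0e6 * trace.R)
    return DiameterTrace(times=times, D=D)


def observation_matrix(times_fine: np.ndarray, R_hist: np.ndarray,
                       obs_times: np.ndarray) -> np.ndarray:
    """Diameters (um) of a batch on the observation grid, shape (M, K)."""
    n_t = len(times_fine)
    dt = times_fine[1] - times_fine[0]
    idx = obs_times / dt
    i0 = np.floor(idx).astype(np.intp)
    i0 = np.minimum(i0, n_t - 2)
    frac = idx - i0
    D_fine = 2.0e6 * R_hist
    return (D_fine[i0, :] * (1.0 - frac[:, None]) + D_fine[i0 + 1, :] * frac[:, None]).T


# ---------------------------------------------------------------------------
# nominal parameter set
# ---------------------------------------------------------------------------

def nominal_parameters(R0: float = 30e-6,
                       PI_ref: float = 60.0 * CMH2O_PA,
                       dP_ref: float = 5.0 * MMHG_PA,
                       Cb: float | None = None,
                       E: float = 1.0e6, h: float = 6.0e-6,
                       L: float = 1.0e-3) -> VesselParameters:
    """Vessel parameters at their nominal (prior-mean) values.

    Gains, slope, time constants and delay take the literature prior means
    (Sm=4, Se=1, G=0.1, tau_m=18 s, tau_e=40 s, zeta=33 s); the references T0
    and tau0 are half the wall tension and shear signal of the in-situ
    baseline (PI_ref, dP_ref) at radius R0, and Pv_bar equals PI_ref.  The
    baseline compliance defaults to the independent-ring value
    Cb = 2*pi*R0^3/(E*h).
    """
    if Cb is None:
        Cb = 2.0 * math.pi * R0 ** 3 / (E * h)
    return VesselParameters(
        Sm=4.0, Se=1.0, G=0.1,
        T0=0.5 * wall_tension(R0, PI_ref),
        tau0=0.5 * shear_signal(R0, dP_ref),
        tau_m=18.0, tau_e=40.0, zeta=33.0,
        Cb=Cb, Pv_bar=PI_ref, L=L,
    )
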