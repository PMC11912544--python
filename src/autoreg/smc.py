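"""Shared machinery for the sequential Monte Carlo ABC stages.

The ABC variable space concatenates the eight free vessel parameters with the
per-experiment initial conditions (Ri, xmi, xei) and, for protocols whose
shear drops at t = 0, the pre-recording shear signal tau_hist.  Candidate
realizations are drawn independently per variable, simulated through the
vessel model, and compared to the observed diameter trace with L2, L4 and
Linf norms; tolerances shrink between iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .distributions import Distribution
from .model import (DiameterTrace, ExperimentProtocol, VesselParameters,
                    observation_matrix, simulate_batch)

__all__ = [
    "PARAM_VARIABLES",
    "INIT_VARIABLES",
    "Experiment",
    "Tolerances",
    "error_norms",
    "batch_error_norms",
    "sample_variables",
    "evaluate_candidates",
    "shrink_tolerances",
    "CalibrationError",
]

#: the eight shared model parameters, in canonical order
PARAM_VARIABLES = ("Sm", "Se", "G", "T0", "tau0", "tau_m", "tau_e", "zeta")
#: the per-experiment initial conditions
INIT_VARIABLES = ("Ri", "xmi", "xei")


class CalibrationError(RuntimeError):
    """Raised when an ABC iteration cannot reach the minimum accepted count."""


@dataclass(frozen=True)
class Experiment:
    """One calibration experiment: a protocol, its observed diameter trace and
    the in-situ reference baselines that anchor the T0/tau0 priors."""

    name: str
    protocol: ExperimentProtocol
    observed: DiameterTrace
    PI_ref: float
    dP_ref: float

    @property
    def R00(self) -> float:
        """Initial radius reading (m) from the observed trace."""
        return float(self.observed.D[0]) * 1e-6 / 2.0

    @property
    def needs_tau_hist(self) -> bool:
        return self.protocol.in_situ_dP is not None

    @property
    def variable_names(self) -> tuple[str, ...]:
        names = PARAM_VARIABLES + INIT_VARIABLES
        return names + ("tau_hist",) if self.needs_tau_hist else names


@dataclass(frozen=True)
class Tolerances:
    """Error tolerances (um) for the three norms; None means not yet set."""

    eps2: float | None = None
    eps4: float | None = None
    eps_inf: float | None = None

    def scaled(self, factor: float) -> "Tolerances":
        def s(v):
            return None if v is None else v * factor
        return Tolerances(s(self.eps2), s(self.eps4), s(self.eps_inf))


def error_norms(sim: DiameterTrace, obs: DiameterTrace) -> tuple[float, float, float]:
    """(L2, L4, Linf) of the residual between two traces on the same grid."""
    if sim.times.shape != obs.times.shape or not np.allclose(sim.times, obs.times):
        raise ValueError("traces must share the observation grid")
    r = np.abs(sim.D - obs.D)
    return (float(np.sqrt(np.sum(r ** 2))),
            float(np.sum(r ** 4) ** 0.25),
            float(np.max(r)))


def batch_error_norms(D_sim: np.ndarray, D_obs: np.ndarray) -> dict[str, np.ndarray]:
    """Per-realization norms for a (M, K) matrix of simulated diameters."""
    r = np.abs(D_sim - D_obs[np.newaxis, :])
    return {
        "L2": np.sqrt(np.sum(r ** 2, axis=1)),
        "L4": np.sum(r ** 4, axis=1) ** 0.25,
        "Linf": np.max(r, axis=1),
    }


def sample_variables(priors: Mapping[str, Distribution], n: int,
                     rng: np.random.Generator,
                     positive: tuple[str, ...] | None = None,
                     max_rounds: int = 200) -> dict[str, np.ndarray]:
    """Draw n independent realizations per variable, resampling negatives.

    Positivity-constrained variables are enforced by rejection (redraw the
    offending entries) rather than by truncating the densities.
    """
    out: dict[str, np.ndarray] = {}
    for name, dist in priors.items():
        x = np.asarray(dist.sample(rng, n), dtype=float)
        if positive is None or name in positive:
            for _ in range(max_rounds):
                bad = ~(x > 0.0) | ~np.isfinite(x)
                if not bad.any():
                    break
                x[bad] = dist.sample(rng, int(bad.sum()))
            else:
                raise CalibrationError(
                    f"could not draw positive samples for {name!r}")
        out[name] = x
    return out


def evaluate_candidates(theta: Mapping[str, np.ndarray], experiment: Experiment,
                        constants: VesselParameters | None = None,
                        ) -> dict[str, np.ndarray]:
    """Simulate a batch of candidates and return their error norms.

    Failed realizations (collapsed radius, non-finite state) get infinite
    norms, so the acceptance rule rejects them without raising.  The fixed
    constants default to the nominal vessel at the experiment's references.
    """
    if constants is None:
        from .model import nominal_parameters
        constants = nominal_parameters(R0=experiment.R00,
                                       PI_ref=experiment.PI_ref,
                                       dP_ref=experiment.dP_ref)
    res = simulate_batch(theta, constants, experiment.protocol)
    D_sim = observation_matrix(res["times"], res["R"], experiment.observed.times)
    norms = batch_error_norms(D_sim, experiment.observed.D)
    failed = res["failed"]
    for key in norms:
        norms[key] = np.where(failed, np.inf, norms[key])
    return norms


def accept_mask(norms: Mapping[str, np.ndarray], tol: Tolerances,
                iteration: int) -> np.ndarray:
    """First iteration: L2 rule only; later iterations: all three norms."""
    ok = norms["L2"] <= tol.eps2
    if iteration > 1:
        if tol.eps4 is not None:
            ok &= norms["L4"] <= tol.eps4
        if tol.eps_inf is not None:
            ok &= norms["Linf"] <= tol.eps_inf
    return ok


def shrink_tolerances(accepted_norms: Mapping[str, np.ndarray],
                      current: Tolerances, q: float = 0.5,
                      floors: Tolerances | None = None) -> Tolerances:
    """Next-iteration tolerances: the q-quantile of the accepted errors per
    norm, capped strictly below the current tolerance, never below the floor."""
    floors = floors or Tolerances(0.0, 0.0, 0.0)

    def one(errors: np.ndarray, cur: float | None, floor: float | None) -> float:
        new = float(np.quantile(errors[np.isfinite(errors)], q))
        if cur is not None and np.isfinite(cur):
            new = min(new, 0.99 * cur)
        if floor:
            new = max(new, floor)
        return new

    return Tolerances(
        eps2=one(accepted_norms["L2"], current.eps2, floors.eps2),
        eps4=one(accepted_norms["L4"], current.eps4, floors.eps4),
        eps_inf=one(accepted_norms["Linf"], current.eps_inf, floors.eps_inf),
    )
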