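"""Per-experiment sequential Monte Carlo ABC (stage 1).

Each iteration samples MC candidate realizations of the variable space from
the current distribution, simulates the vessel model under the experiment's
inputs, accepts realizations whose simulated diameter trace lies within the
error tolerances of the observed trace (L2 only on the first iteration; L2,
L4 and Linf afterwards), refits a univariate distribution to the accepted
samples of every variable, and shrinks the tolerances.  The refitted
posterior becomes the prior of the next iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator

from .distributions import Distribution, HalfNormal, Normal, fit_posterior
from .model import (VesselParameters, nominal_parameters,
                    steady_state_init, wall_tension, shear_signal)
from .smc import (CalibrationError, Experiment, Tolerances, accept_mask,
                  evaluate_candidates, sample_variables, shrink_tolerances)

__all__ = [
    "PosteriorFit",
    "default_priors",
    "run_iteration",
    "run_stage1",
    "Stage1Calibrator",
    "POSITIVE_VARIABLES",
]

#: every calibration variable is physically non-negative; negatives are
#: filtered out by rejection at the sampling step
POSITIVE_VARIABLES = ("Sm", "Se", "G", "T0", "tau0", "tau_m", "tau_e", "zeta",
                      "Ri", "xmi", "xei", "tau_hist")

#: relative prior sd for the experiment-dependent references T0/tau0/tau_hist
REFERENCE_REL_SD = 0.25


@dataclass
class PosteriorFit:
    """Result of one ABC iteration: per-variable fitted distributions, the
    accepted-sample table, the acceptance rate and the error summaries."""

    distributions: dict[str, Distribution]
    accepted: dict[str, np.ndarray]
    accepted_norms: dict[str, np.ndarray]
    acceptance_rate: float
    tolerances: Tolerances
    iteration: int
    relaxations: int = 0

    @property
    def n_accepted(self) -> int:
        return len(next(iter(self.accepted.values())))

    def credible_interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        x = self.accepted[name]
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))


def default_priors(experiment: Experiment,
                   constants: VesselParameters | None = None,
                   ) -> dict[str, Distribution]:
    """Initial (iteration-1) prior distributions for one experiment.

    Gaussians centred at the literature nominal values for the gains, slope,
    time constants and delay; the references T0 and tau0 centred at half the
    in-situ baseline wall tension and shear signal of the vessel; the initial
    radius at the first diameter reading (sd 5 um); the initial activations
    at their constant-baseline steady-state values.  When the protocol's
    baseline gives no endothelial activation, the xei prior is a half-normal
    at zero.
    """
    R00 = experiment.R00
    if constants is None:
        constants = nominal_parameters(R0=R00, PI_ref=experiment.PI_ref,
                                       dP_ref=experiment.dP_ref)
    T_ref = wall_tension(R00, experiment.PI_ref)
    tau_ref = shear_signal(R00, experiment.dP_ref)
    ss = steady_state_init(R00, experiment.protocol, constants)

    priors: dict[str, Distribution] = {
        "Sm": Normal(4.0, 2.0),
        "Se": Normal(1.0, 0.75),
        "G": Normal(0.1, float(np.sqrt(0.009))),
        "T0": Normal(0.5 * T_ref, REFERENCE_REL_SD * 0.5 * T_ref),
        "tau0": Normal(0.5 * tau_ref, REFERENCE_REL_SD * 0.5 * tau_ref),
        "tau_m": Normal(18.0, 10.0),
        "tau_e": Normal(40.0, 20.0),
        "zeta": Normal(33.0, 10.0),
        "Ri": Normal(R00, 5e-6),
        "xmi": Normal(ss.xm, 1.0),
    }
    priors["xei"] = HalfNormal(0.75) if ss.xe <= 0.0 else Normal(ss.xe, 0.75)
    if experiment.needs_tau_hist:
        tau_hist0 = shear_signal(R00, experiment.protocol.init_dP)
        priors["tau_hist"] = Normal(tau_hist0, REFERENCE_REL_SD * tau_hist0)
    return priors


def run_iteration(priors: Mapping[str, Distribution], experiment: Experiment,
                  tolerances: Tolerances, mc: int, iteration: int,
                  rng: np.random.Generator,
                  constants: VesselParameters | None = None,
                  min_accept: int = 200, relax_factor: float = 1.5,
                  max_relaxations: int = 2,
                  eps_quantile_init: float = 0.2) -> PosteriorFit:
    """One SMC ABC iteration: sample, simulate, accept, refit.

    On the first iteration an unset eps2 is initialised to the
    ``eps_quantile_init`` quantile of the prior-predictive L2 errors.  If
    fewer than ``min_accept`` realizations are accepted, the tolerances are
    relaxed by ``relax_factor`` and a fresh batch is drawn, at most
    ``max_relaxations`` times before aborting with diagnostics.
    """
    if mc < 1:
        raise ValueError("mc must be >= 1")
    if constants is None:
        constants = nominal_parameters(R0=experiment.R00,
                                       PI_ref=experiment.PI_ref,
                                       dP_ref=experiment.dP_ref)
    tol = tolerances
    relaxations = 0
    while True:
        theta = sample_variables(priors, mc, rng, positive=POSITIVE_VARIABLES)
        norms = evaluate_candidates(theta, experiment, constants)
        if iteration == 1 and tol.eps2 is None:
            finite = norms["L2"][np.isfinite(norms["L2"])]
            if len(finite) == 0:
                raise CalibrationError("every prior-predictive simulation failed")
            tol = Tolerances(eps2=float(np.quantile(finite, eps_quantile_init)),
                             eps4=tol.eps4, eps_inf=tol.eps_inf)
        ok = accept_mask(norms, tol, iteration)
        if int(ok.sum()) >= min(min_accept, mc):
            break
        if relaxations >= max_relaxations:
            raise CalibrationError(
                f"iteration {iteration}: only {int(ok.sum())} acceptances at "
                f"tolerances {tol} after {relaxations} relaxations")
        tol = tol.scaled(relax_factor)
        relaxations += 1

    accepted = {k: v[ok] for k, v in theta.items()}
    accepted_norms = {k: v[ok] for k, v in norms.items()}
    fits = {name: fit_posterior(vals) for name, vals in accepted.items()}
    return PosteriorFit(distributions=fits, accepted=accepted,
                        accepted_norms=accepted_norms,
                        acceptance_rate=float(ok.mean()),
                        tolerances=tol, iteration=iteration,
                        relaxations=relaxations)


def run_stage1(experiment: Experiment, r: int = 3, mc: int = 5000,
               seed: int = 0, q: float = 0.5,
               constants: VesselParameters | None = None,
               priors: Mapping[str, Distribution] | None = None,
               tolerances: Tolerances | None = None,
               min_accept: int = 200,
               floors: Tolerances | None = None) -> list[PosteriorFit]:
    """Chain r ABC iterations for one experiment; each refitted posterior
    becomes the next prior and tolerances shrink to the q-quantile of the
    accepted errors (capped strictly below the current value)."""
    rng_master = np.random.default_rng(np.random.SeedSequence(seed))
    streams = rng_master.spawn(r)
    if priors is None:
        priors = default_priors(experiment, constants)
    tol = tolerances or Tolerances()
    fits: list[PosteriorFit] = []
    for i in range(1, r + 1):
        fit = run_iteration(priors, experiment, tol, mc, i, streams[i - 1],
                            constants=constants, min_accept=min_accept)
        fits.append(fit)
        priors = fit.distributions
        tol = shrink_tolerances(fit.accepted_norms, fit.tolerances, q=q,
                                floors=floors)
    return fits


class Stage1Calibrator(BaseEstimator):
    """Per-experiment SMC ABC calibrator with a scikit-learn estimator shape.

    Parameters
    ----------
    r : number of SMC iterations.
    mc : realizations drawn per iteration.
    q : tolerance-shrinkage quantile applied to the accepted errors.
    seed : master seed; every random draw descends from it.
    min_accept : minimum accepted realizations before refitting.

    Attributes (after ``fit``)
    --------------------------
    fits_ : list of per-iteration :class:`PosteriorFit`.
    posterior_ : final per-variable fitted distributions.
    acceptance_rates_ : per-iteration acceptance rates.
    tolerances_ : per-iteration tolerance triples actually applied.
    """

    def __init__(self, r: int = 3, mc: int = 5000, q: float = 0.5,
                 seed: int = 0, min_accept: int = 200):
        self.r = r
        self.mc = mc
        self.q = q
        self.seed = seed
        self.min_accept = min_accept

    def fit(self, experiment: Experiment,
            constants: VesselParameters | None = None) -> "Stage1Calibrator":
        self.fits_ = run_stage1(experiment, r=self.r, mc=self.mc, q=self.q,
                                seed=self.seed, constants=constants,
                                min_accept=self.min_accept)
        self.posterior_ = self.fits_[-1].distributions
        self.acceptance_rates_ = [f.acceptance_rate for f in self.fits_]
        self.tolerances_ = [f.tolerances for f in self.fits_]
        return self
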