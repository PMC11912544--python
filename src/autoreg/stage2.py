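"""Grouped SMC ABC (stage 2): one shared parameter distribution per group.

Experiments are split by the sign of their myogenic response: group A
(dilation-type, experiments 1, 3, 5) and group B (constriction-type,
experiments 1, 2, 4); experiment 1 (no myogenic stimulus) belongs to both.
The eight model parameters are shared within a group and drawn from a single
pooled distribution, while the initial conditions (Ri, xmi, xei and, where
needed, tau_hist) stay per-experiment.  A realization is accepted only when
all three error norms pass for every experiment of the group, evaluated
sequentially with short-circuit rejection so later simulations are skipped as
soon as one experiment fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator

from .distributions import Distribution, EqualMixture, fit_bimodal, fit_posterior
from .model import VesselParameters, nominal_parameters
from .smc import (CalibrationError, Experiment, Tolerances,
                  evaluate_candidates, sample_variables, shrink_tolerances,
                  PARAM_VARIABLES)
from .stage1 import POSITIVE_VARIABLES

__all__ = [
    "GroupSpec",
    "GROUP_A",
    "GROUP_B",
    "pool_stage1_posteriors",
    "run_stage2",
    "Stage2Calibrator",
]

#: stage-1 posteriors of these parameters from the endothelial-only
#: experiment 1 are excluded from the iteration-1 pooled prior
MYOGENIC_PARAMETERS = ("T0", "tau_m", "Sm")


@dataclass(frozen=True)
class GroupSpec:
    """A group of experiments sharing one parameter distribution."""

    group_id: str
    experiment_ids: tuple[str, ...]
    endothelial_only: tuple[str, ...] = ("exp1",)

    def pooled_sources(self, variable: str) -> tuple[str, ...]:
        """Experiments whose stage-1 fit of ``variable`` enters the pooled
        iteration-1 prior (myogenic parameters skip endothelial-only runs)."""
        if variable in MYOGENIC_PARAMETERS:
            return tuple(e for e in self.experiment_ids
                         if e not in self.endothelial_only)
        return self.experiment_ids


GROUP_A = GroupSpec("A", ("exp1", "exp3", "exp5"))
GROUP_B = GroupSpec("B", ("exp1", "exp2", "exp4"))


def pool_stage1_posteriors(stage1_fits: Mapping[str, Mapping[str, Distribution]],
                           group: GroupSpec) -> tuple[dict[str, Distribution],
                                                      dict[str, dict[str, Distribution]]]:
    """Iteration-1 stage-2 priors from the stage-1 final posteriors.

    Shared parameters get an equal-probability mixture of the contributing
    per-experiment fits; initial-condition variables keep their own
    per-experiment fits.  Returns (shared_priors, individual_priors) with
    individual_priors keyed by experiment id.
    """
    missing = [e for e in group.experiment_ids if e not in stage1_fits]
    if missing:
        raise ValueError(f"missing stage-1 fits for {missing}")
    shared: dict[str, Distribution] = {}
    for p in PARAM_VARIABLES:
        comps = [stage1_fits[e][p] for e in group.pooled_sources(p)]
        shared[p] = comps[0] if len(comps) == 1 else EqualMixture(comps)
    individual: dict[str, dict[str, Distribution]] = {}
    for e in group.experiment_ids:
        individual[e] = {v: stage1_fits[e][v] for v in stage1_fits[e]
                         if v not in PARAM_VARIABLES}
    return shared, individual


@dataclass
class Stage2IterationResult:
    """Accepted shared-parameter samples plus bookkeeping for one iteration."""

    shared_fit: dict[str, Distribution]
    individual_fits: dict[str, dict[str, Distribution]]
    accepted_shared: dict[str, np.ndarray]
    accepted_individual: dict[str, dict[str, np.ndarray]]
    accepted_norms: dict[str, np.ndarray]       # worst norm over experiments
    acceptance_rate: float
    tolerances: Tolerances
    simulations_per_experiment: dict[str, int]
    iteration: int
    relaxations: int = 0


def _stage2_iteration(shared_priors, individual_priors, experiments, group,
                      tol, mc, iteration, rng, constants_by_exp,
                      min_accept, relax_factor, max_relaxations,
                      refit_individual, bimodal_seed):
    relaxations = 0
    while True:
        shared = sample_variables(shared_priors, mc, rng,
                                  positive=POSITIVE_VARIABLES)
        indiv = {e: sample_variables(individual_priors[e], mc, rng,
                                     positive=POSITIVE_VARIABLES)
                 for e in group.experiment_ids}
        alive = np.arange(mc)
        sim_counts: dict[str, int] = {}
        worst = {k: np.zeros(mc) for k in ("L2", "L4", "Linf")}
        for e in group.experiment_ids:
            exp = experiments[e]
            theta = {k: v[alive] for k, v in shared.items()}
            theta.update({k: v[alive] for k, v in indiv[e].items()})
            sim_counts[e] = len(alive)
            norms = evaluate_candidates(theta, exp, constants_by_exp[e])
            ok = ((norms["L2"] <= tol.eps2)
                  & (tol.eps4 is None or norms["L4"] <= tol.eps4)
                  & (tol.eps_inf is None or norms["Linf"] <= tol.eps_inf))
            for k in worst:
                w = worst[k][alive]
                worst[k][alive] = np.maximum(w, norms[k])
            alive = alive[ok]
            if len(alive) == 0:
                break
        if len(alive) >= min(min_accept, mc):
            break
        if relaxations >= max_relaxations:
            raise CalibrationError(
                f"stage 2 iteration {iteration}: only {len(alive)} acceptances "
                f"at tolerances {tol}")
        tol = tol.scaled(relax_factor)
        relaxations += 1

    accepted_shared = {k: v[alive] for k, v in shared.items()}
    accepted_individual = {e: {k: v[alive] for k, v in indiv[e].items()}
                           for e in group.experiment_ids}
    accepted_norms = {k: worst[k][alive] for k in worst}
    shared_fit = {}
    for p, vals in accepted_shared.items():
        shared_fit[p] = fit_bimodal(vals, seed=bimodal_seed)
    individual_fits = {}
    for e in group.experiment_ids:
        if refit_individual:
            individual_fits[e] = {k: fit_posterior(v[alive])
                                  for k, v in indiv[e].items()}
        else:
            individual_fits[e] = dict(individual_priors[e])
    return Stage2IterationResult(
        shared_fit=shared_fit, individual_fits=individual_fits,
        accepted_shared=accepted_shared, accepted_individual=accepted_individual,
        accepted_norms=accepted_norms,
        acceptance_rate=len(alive) / mc, tolerances=tol,
        simulations_per_experiment=sim_counts, iteration=iteration,
        relaxations=relaxations)


def run_stage2(group: GroupSpec, experiments: Mapping[str, Experiment],
               stage1_fits: Mapping[str, Mapping[str, Distribution]],
               stage1_final_tolerances: Mapping[str, Tolerances] | None = None,
               r: int = 3, mc: int = 5000, seed: int = 0, q: float = 0.5,
               tolerances: Tolerances | None = None,
               min_accept: int = 200, refit_individual: bool = True,
               constants_by_exp: Mapping[str, VesselParameters] | None = None,
               ) -> list[Stage2IterationResult]:
    """Run the grouped SMC ABC for one experiment group.

    Iteration 1 uses the pooled stage-1 priors (with the experiment-1
    myogenic-parameter exclusion); later iterations refit the accepted shared
    samples directly, allowing bimodal (two-normal-mixture) fits.  Initial
    tolerances default to twice the per-norm maximum of the group's stage-1
    final tolerances — a single realization must now fit all experiments, so
    the group tolerances start looser than any single-experiment fit.
    """
    rng_master = np.random.default_rng(np.random.SeedSequence(seed))
    streams = rng_master.spawn(r)
    shared_priors, individual_priors = pool_stage1_posteriors(stage1_fits, group)
    if constants_by_exp is None:
        constants_by_exp = {
            e: nominal_parameters(R0=experiments[e].R00,
                                  PI_ref=experiments[e].PI_ref,
                                  dP_ref=experiments[e].dP_ref)
            for e in group.experiment_ids}
    if tolerances is None:
        if stage1_final_tolerances is None:
            raise ValueError("provide tolerances or stage1_final_tolerances")
        tols = [stage1_final_tolerances[e] for e in group.experiment_ids]
        tolerances = Tolerances(
            eps2=2.0 * max(t.eps2 for t in tols),
            eps4=2.0 * max(t.eps4 for t in tols if t.eps4 is not None),
            eps_inf=2.0 * max(t.eps_inf for t in tols if t.eps_inf is not None),
        )
    tol = tolerances
    results: list[Stage2IterationResult] = []
    for i in range(1, r + 1):
        res = _stage2_iteration(shared_priors, individual_priors, experiments,
                                group, tol, mc, i, streams[i - 1],
                                constants_by_exp, min_accept, 1.5, 2,
                                refit_individual, bimodal_seed=seed)
        results.append(res)
        shared_priors = res.shared_fit
        individual_priors = res.individual_fits
        tol = shrink_tolerances(res.accepted_norms, res.tolerances, q=q)
    return results


class Stage2Calibrator(BaseEstimator):
    """Grouped SMC ABC calibrator (scikit-learn estimator shape).

    ``fit`` takes the group spec, the experiments and the stage-1 outputs and
    exposes ``results_``, ``posterior_`` (final shared-parameter fits) and
    ``acceptance_rates_``.  ``freeze_individual=True`` keeps the per-experiment
    initial-condition distributions at their stage-1 finals instead of
    refitting them each iteration.
    """

    def __init__(self, r: int = 3, mc: int = 5000, q: float = 0.5,
                 seed: int = 0, min_accept: int = 200,
                 freeze_individual: bool = False):
        self.r = r
        self.mc = mc
        self.q = q
        self.seed = seed
        self.min_accept = min_accept
        self.freeze_individual = freeze_individual

    def fit(self, group: GroupSpec, experiments: Mapping[str, Experiment],
            stage1_fits: Mapping[str, Mapping[str, Distribution]],
            stage1_final_tolerances: Mapping[str, Tolerances] | None = None,
            tolerances: Tolerances | None = None) -> "Stage2Calibrator":
        self.results_ = run_stage2(
            group, experiments, stage1_fits,
            stage1_final_tolerances=stage1_final_tolerances,
            r=self.r, mc=self.mc, seed=self.seed, q=self.q,
            tolerances=tolerances, min_accept=self.min_accept,
            refit_individual=not self.freeze_individual)
        self.posterior_ = self.results_[-1].shared_fit
        self.acceptance_rates_ = [r.acceptance_rate for r in self.results_]
        return self
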