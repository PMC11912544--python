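"""Synthetic five-experiment suite emulating pressurized-arteriole protocols.

The suite mirrors the structure of cannulated-arteriole experiments in which
a dual-reservoir system steps the intraluminal pressure PI (myogenic
stimulus) and/or the pressure gradient dP (endothelial stimulus) while the
internal diameter is recorded:

* experiment 1 — PI constant; dP steps up then back down (endothelial only);
* experiments 2 and 4 — PI step increases (myogenic constriction); experiment
  2 additionally starts with a shear drop at t = 0 from the in-situ pressure
  gradient, producing a delayed endothelial constriction and requiring the
  pre-recording shear signal tau_hist;
* experiments 3 and 5 — PI step decreases (myogenic dilation).

Group A = {1, 3, 5} (dilation-type myogenic response); group B = {1, 2, 4}
(constriction-type).  Ground truth is the nominal parameter set; traces are
forward-simulated from the constant-baseline steady state, sampled at 1.5 s
and corrupted with i.i.d. Gaussian observation noise.

The protocols run at a baseline PI of 35 cmH2O — below the 60 cmH2O in-situ
reference that fixes T0 and tau0 — so that the compliance map starts on its
sensitive flank (u0 = xe0 - xm0 = +1/3) rather than inside an asymptote; dP
steps then drive the relative compliance toward its saturation value, and PI
steps produce few-micrometre constrictions/dilations.  All perturbations stay
within the admissible truncation window (|PI| <= 40 cmH2O, |dP| <= 10 cmH2O
from baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (CMH2O_PA, MMHG_PA, DiameterTrace, ExperimentProtocol,
                    StepEvent, VesselParameters, VesselState,
                    nominal_parameters, sample_observation_grid, shear_signal,
                    simulate, steady_state_init)
from .preprocessing import DP_LIMIT, PI_LIMIT
from .smc import Experiment

__all__ = [
    "SyntheticExperiment",
    "SyntheticSuite",
    "default_truth",
    "make_suite",
    "suite_protocols",
    "PI_BASE",
    "DP_BASE",
    "PI_REF",
    "DP_REF",
]

PI_REF = 60.0 * CMH2O_PA     # in-situ intraluminal pressure (anchors T0, Pv)
DP_REF = 5.0 * MMHG_PA       # in-situ pressure gradient (anchors tau0)
PI_BASE = 35.0 * CMH2O_PA    # cannulated baseline intraluminal pressure
DP_BASE = 5.0 * MMHG_PA      # cannulated baseline pressure gradient
R0_DEFAULT = 30e-6           # baseline radius (in-vivo diameters 40-80 um)
NOISE_SD_DEFAULT = 0.5       # um


@dataclass(frozen=True)
class SyntheticExperiment(Experiment):
    """An :class:`~autoreg.smc.Experiment` plus its generating ground truth."""

    true_params: VesselParameters = None
    true_init: VesselState = None
    noise_sd: float = 0.0
    seed: int = 0
    noiseless: DiameterTrace = None


@dataclass(frozen=True)
class SyntheticSuite:
    experiments: dict[str, SyntheticExperiment]
    group_A: tuple[str, ...] = ("exp1", "exp3", "exp5")
    group_B: tuple[str, ...] = ("exp1", "exp2", "exp4")

    def __getitem__(self, key: str) -> SyntheticExperiment:
        return self.experiments[key]


def default_truth(R0: float = R0_DEFAULT) -> VesselParameters:
    """Ground-truth parameters: the nominal (prior-mean) vessel at radius R0,
    referenced to the in-situ baseline (60 cmH2O, 5 mmHg)."""
    return nominal_parameters(R0=R0, PI_ref=PI_REF, dP_ref=DP_REF)


def suite_protocols(duration: float = 300.0,
                    smoothing_width: float = 2.0) -> dict[str, ExperimentProtocol]:
    """The five step protocols (pressures in Pa)."""
    pi, dp = PI_BASE, DP_BASE
    up = 20.0 * CMH2O_PA
    dn = 20.0 * CMH2O_PA
    dp_up = 8.0 * CMH2O_PA
    dp_dn = 5.0 * CMH2O_PA
    protos = {
        "exp1": ExperimentProtocol(
            PI_base=pi, dP_base=dp, duration=duration,
            smoothing_width=smoothing_width,
            events=(StepEvent(60.0, "dP", dp + dp_up),
                    StepEvent(180.0, "dP", dp - dp_dn))),
        "exp2": ExperimentProtocol(
            PI_base=pi, dP_base=0.0, duration=duration,
            smoothing_width=smoothing_width, in_situ_dP=DP_REF,
            events=(StepEvent(150.0, "PI", pi + up),)),
        "exp3": ExperimentProtocol(
            PI_base=pi, dP_base=dp, duration=duration,
            smoothing_width=smoothing_width,
            events=(StepEvent(60.0, "PI", pi - dn),)),
        "exp4": ExperimentProtocol(
            PI_base=pi, dP_base=dp, duration=duration,
            smoothing_width=smoothing_width,
            events=(StepEvent(60.0, "PI", pi + up),)),
        "exp5": ExperimentProtocol(
            PI_base=pi, dP_base=dp, duration=duration,
            smoothing_width=smoothing_width,
            events=(StepEvent(60.0, "PI", pi - 15.0 * CMH2O_PA),
                    StepEvent(200.0, "PI", pi))),
    }
    for name, prot in protos.items():
        for e in prot.events:
            base = prot.PI_base if e.target == "PI" else prot.dP_base
            limit = PI_LIMIT if e.target == "PI" else DP_LIMIT
            if abs(e.value - base) > limit:
                raise ValueError(f"{name}: step exceeds the truncation limit")
    return protos


def make_suite(truth: VesselParameters | None = None, R0: float = R0_DEFAULT,
               noise_sd: float = NOISE_SD_DEFAULT, seed: int = 0,
               duration: float = 300.0,
               truth_by_experiment: dict[str, VesselParameters] | None = None,
               ) -> SyntheticSuite:
    """Forward-simulate the five experiments and add observation noise.

    ``truth_by_experiment`` overrides the shared truth per experiment (used
    for the dilation/constriction contrast studies); otherwise a single truth
    generates every trace.  Reproducible: all noise derives from ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth is None:
        truth = default_truth(R0)
    protos = suite_protocols(duration=duration)
    seeds = np.random.SeedSequence(seed).spawn(len(protos))
    experiments: dict[str, SyntheticExperiment] = {}
    for (name, prot), child in zip(sorted(protos.items()), seeds):
        tp = (truth_by_experiment or {}).get(name, truth)
        if prot.in_situ_dP is not None:
            tp = tp.with_tau_hist(shear_signal(R0, prot.in_situ_dP))
        init = steady_state_init(R0, prot, tp)
        trace = simulate(tp, init, prot)
        clean = sample_observation_grid(trace)
        rng = np.random.default_rng(child)
        noisy = DiameterTrace(times=clean.times,
                              D=clean.D + rng.normal(0.0, noise_sd, clean.D.shape))
        experiments[name] = SyntheticExperiment(
            name=name, protocol=prot, observed=noisy,
            PI_ref=PI_REF, dP_ref=DP_REF,
            true_params=tp, true_init=init, noise_sd=noise_sd,
            seed=seed, noiseless=clean)
    return SyntheticSuite(experiments=experiments)
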