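# autoreg

Simulation and likelihood-free calibration of a compliance-feedback model of
arteriolar autoregulation.

## The problem

Isolated, cannulated arterioles actively regulate their calibre: a rise in
intraluminal pressure `PI` triggers myogenic constriction, a rise in the
luminal shear stress (set by the axial pressure gradient `dP`) triggers
endothelium-mediated dilation, and a withdrawal of shear triggers a *delayed*
constriction.  A compact way to capture all three behaviours is to let the
autoregulatory mechanisms modulate the vessel's compliance per unit length
`C` rather than its radius directly.  This package implements that model and
the two-stage sequential Monte Carlo approximate Bayesian computation
(SMC ABC) scheme used to calibrate its parameters from diameter recordings,
together with a structural-identifiability checker and a synthetic-experiment
generator so the whole pipeline can be exercised and validated end to end
without access to the original (non-public) laboratory traces.

## The model

States: radius `R` and two dimensionless low-pass activation factors,

    dxm/dt = (1/τm) (−xm + Sm · ReLU((T − T0)/T0)),      T = R·PI/2
    dxe/dt = (1/τe) (−xe + Se · ReLU((τ̃(t−d) − τ0)/τ0)),  τ̃ = R·dP/2

where `d = ζ` while the shear signal is below its value ζ seconds earlier
(delayed endothelial constriction) and `d = 0` otherwise.  The activation
difference `u = xe − xm` sets the compliance through an asymmetric sigmoid

    C/Cb = 1 + δ± · tanh(u / (G·δ±)),    δ+ = 10 (u ≥ 0),  δ− = 0.8 (u < 0)

with central slope `1/G`, and the radius follows the compliance tube law

    2πR · dR/dt = C · dPI/dt + P̄v · dC/dt.

The system is integrated with a first-order IMEX Euler scheme (implicit
linear decay, explicit forcing) at Δt = 0.2 s and observed as diameter
`D = 2R` on a 1.5-s grid.  Calibration treats the eight model parameters
`(Sm, Se, G, T0, τ0, τm, τe, ζ)` plus the per-experiment initial conditions
`(Ri, xmi, xei)` as unknown: stage 1 runs a per-experiment SMC ABC with
L2/L4/L∞ error tolerances that shrink each iteration and a univariate
distribution refit of every accepted variable; stage 2 pools the stage-1
posteriors into one shared parameter distribution per experiment group
(dilation-type vs constriction-type myogenic response) with sequential
short-circuit acceptance across each group's three experiments.

## Worked example

```python
from autoreg import (nominal_parameters, steady_state_init, simulate,
                     sample_observation_grid, make_suite, run_stage1)
from autoreg.synthetic import suite_protocols

# endothelial protocol: dP steps +8 cmH2O at t=60 s, down to −5 cmH2O at 180 s
params = nominal_parameters()
protocol = suite_protocols()["exp1"]
init = steady_state_init(30e-6, protocol, params)
trace = simulate(params, init, protocol)
obs = sample_observation_grid(trace)
print(f"baseline diameter : {obs.D[0]:.1f} um")
print(f"peak dilation     : {obs.D.max():.1f} um")
print(f"peak C/Cb         : {trace.C_rel.max():.2f}")

# calibrate one synthetic dilation experiment (desk profile)
suite = make_suite(seed=0)
fits = run_stage1(suite["exp3"], r=3, mc=5000, seed=0)
lo, hi = fits[-1].credible_interval("tau_m", 0.9)
print(f"acceptance rates  : {[round(f.acceptance_rate, 3) for f in fits]}")
print(f"tau_m 90% CI      : ({lo:.1f}, {hi:.1f}) s")
```

prints

```
baseline diameter : 60.0 um
peak dilation     : 70.8 um
peak C/Cb         : 10.88
acceptance rates  : [0.195, 0.132, 0.135]
tau_m 90% CI      : (6.5, 33.6) s
```

The shear step drives the relative compliance close to its saturation value
11 and dilates the vessel by ~11 µm; the ABC posterior's 90% credible
interval comfortably contains the generating time constant (18 s).

The same functionality is available from the shell:

```
autoreg synth --seed 0 --out suite/
autoreg simulate --protocol suite/exp1_protocol.yaml --params suite/truth.json --out sim.csv
autoreg calibrate-stage1 --protocol suite/exp3_protocol.yaml --trace suite/exp3_trace.csv --out fit.json
autoreg identifiability --order 2 --out ident.json
autoreg study --seed 0 --out report.json
```

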