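# obsens — ensembles of observable dynamic models

Kinetic ODE models in systems biology are routinely unidentifiable: different
parameter vectors, and different internal state trajectories, produce exactly
the same measurable outputs.  Ensembles of models calibrated to data inherit
the problem — their predictions of *measured* quantities look fine while their
predictions of *unmeasured* states can be arbitrarily wrong, with uncertainty
bands that say nothing.  `obsens` is a toolbox for building trustworthy
ensembles: it first analyses structural identifiability and observability,
repairs the model by reparameterization when the analysis fails, and only
then calibrates and builds the ensemble.

The package is aimed at modellers working with small-to-medium kinetic ODE
models (rational right-hand sides, partially observed states, possibly
unmeasured inputs) who want state predictions with honest uncertainty.

## The methodology

For a model dx/dt = f(x, θ, u, w), y = g(x, θ, u, w) with rational `f`, `g`:

1. **Observability analysis.**  Augment the state with the parameters
   (θ̇ = 0) and the unknown-input derivatives; stack Lie derivatives of the
   outputs and take their Jacobian with respect to the augmented state.  Full
   generic rank ⇔ every state, parameter and unknown input is in principle
   recoverable from the outputs (the FISPO property).  Rank-deficient columns
   localize the unobservable states and unidentifiable parameters.
2. **Reparameterization.**  Symbolic substitutions — scaling an unobservable
   state by an unidentifiable parameter, merging parameter products,
   absorbing a redundant term into an unknown input — remove the redundancy;
   the transformed model is verified to be fully observable and to produce
   identical outputs.
3. **Synthetic data** from the nominal model with mixed noise
   ỹ = y + (σ_abs + σ_rel·y)·N(0,1).
4. **Calibration** by minimizing the exact Gaussian negative log-likelihood
   −log L = Σ [log(σ√2π) + (ỹ−y)²/2σ²] with an enhanced-scatter-search-style
   global optimizer that archives *every* evaluated parameter vector.
5. **Ensemble selection** from the archive: keep vectors whose objective lies
   in a likelihood-ratio interval around a χ²-based approximation of the
   nominal log-likelihood ([log L* − 3.841, log L* + Δ + 3.841]), thin by
   percentile groups, prune near-duplicates by relative Euclidean distance,
   and subsample to the target size (default 1000).
6. **Prediction.**  Simulate every member; report the pointwise median and
   percentile envelopes, scored by the range-normalized RMSE
   NRMSE = RMSE/(max(ref) − min(ref)).

Four benchmark case studies are bundled (original + repaired forms): a
glucose-regulation circuit (`big`), a cell-division-cycle oscillator
(`celldiv`, no repair exists), a circadian gene oscillator (`circad`) and a
JAK-STAT signalling model (`jakstat`).  See `docs/methods.md` for assumptions,
numerical choices and limitations.

## Worked example

```python
import numpy as np
from obsens import (load_benchmark, classify, apply_reparameterization,
                    generate_dataset, ess_optimize, build_ensemble,
                    ensemble_predict, nrmse, simulate)
from obsens.pipeline import benchmark_problem

case = load_benchmark("jakstat")
report = classify(case.original, seed=0)
print(report.summary())
```

```
model: jakstat
rank 9 of 10 (not FISPO)
Lie derivatives used: 5
unidentifiable parameters (3): p2, p5, p6
unobservable states (1): x1
```

The STAT pool `x1` is unobservable and three parameters are unidentifiable.
Scaling `x1` by `p2` repairs it:

```python
fixed = apply_reparameterization(case.original, case.transformation)
print(classify(fixed, seed=0).summary())
```

```
model: jakstat_obs
rank 9 of 9 (FISPO)
Lie derivatives used: 4
unidentifiable parameters (0):
unobservable states (0):
```

Calibrate on synthetic data and predict with uncertainty:

```python
ds = generate_dataset(case.original, times=case.measurement_times(),
                      sigma_abs=0.02, sigma_rel=0.10, seed=5,
                      inputs=case.known_input_truth)
problem = benchmark_problem(case, case.original, ds, repar=False)
result = ess_optimize(problem, budget=6000, seed=7)
ens = build_ensemble(result.archive, ds,
                     np.asarray(ds.noise_spec["sigma_abs_scaled"]),
                     ds.noise_spec["sigma_rel"], n_theta=problem.dim,
                     best_fit_outputs=problem.simulate_decision(result.best_x).outputs,
                     decision_names=problem.decision_names, seed=8)
print(ens.provenance)
pred = ensemble_predict(problem, ens, ds.times, percentiles=(40, 80))
y_median = pred.median[:, case.original.n_states:]
print("output NRMSE vs data:", round(nrmse(y_median, ds.y), 4))
```

```
{'archive': 6000, 'interval': 4681, 'thinned': 2456, 'pruned': 1195, 'sampled': 1000}
output NRMSE vs data: 0.081
```

The ensemble prediction tracks the measured outputs to within the noise
level; the envelopes quantify what the data do — and do not — constrain.

The same pipeline runs end-to-end from the command line:

```bash
obsens list-benchmarks
obsens classify big --seed 0
obsens predict big --budget 4000 --seed 1 --run-dir runs/big
```

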