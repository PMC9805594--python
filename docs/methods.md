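# Methods

`obsens` implements an ensemble-modelling workflow for kinetic ODE models in
six stages: structural observability analysis, observability-restoring
reparameterization, synthetic data generation, global calibration with a full
evaluation archive, likelihood-ratio ensemble selection, and median/percentile
trajectory prediction.  This note records the model assumptions, the numerical
choices, and the design decisions taken where the methodology leaves room.

## Model class

Models are deterministic ODE systems

    dx/dt = f(x, θ, u(t), w(t)),    y = g(x, θ, u(t), w(t)),    x(0) = x0,

with `f`, `g` rational in the states `x`, constant parameters `θ`, known
inputs `u` and unknown (unmeasured) inputs `w`.  Rationality is enforced at
construction; it is what makes the generic-rank observability test exact.
Initial conditions may be numeric or unknown; unknown ones join the estimation
vector.  Simulation uses a stiff-capable variable-step integrator (LSODA) with
`rtol=1e-8`, `atol=1e-10` by default — the circadian benchmark mixes relaxation
rates over four orders of magnitude, and looser tolerances visibly corrupt
finite-difference Jacobians in the local searches.

Known inputs are arbitrary callables of time (constants and piecewise-linear
interpolants are provided).  During estimation an unknown input is
parameterized as a piecewise-linear function on a uniform knot grid over the
measurement horizon; the knot count (default 10) trades representation error
against compensation freedom, and the synthetic study keeps the true input
smooth enough that the default grid represents it below the noise floor.

## Observability and identifiability (FISPO)

The test augments the state with the parameters (θ̇ = 0) and with the unknown
inputs and their derivatives up to a truncation order (default 1; the
derivative of the highest included order is set to zero).  Stacked Lie
derivatives of the outputs along the augmented vector field are differentiated
with respect to the augmented state; the model is fully observable (FISPO) iff
this observability–identifiability matrix has full generic rank.  Derivative
orders are added until the rank is unchanged between two consecutive orders or
full rank is reached; a non-stabilized rank within the derivative budget
raises an explicit error rather than returning a silent misclassification.
Per-variable classification deletes one column at a time: a variable is
observable/identifiable iff its deletion strictly decreases the rank.

Two evaluation routes exist.  The symbolic route builds the Lie derivatives
and the Jacobian explicitly (with a node-count budget that aborts on
expression blow-up).  The default route used by `classify` evaluates the same
matrix exactly at random points: Taylor coefficients of the augmented flow and
of its variational (tangent) system are propagated in exact arithmetic over
the prime field GF(2^31 − 1), giving the rows k!·∂/∂x̃0 [t^k] g(x̃(t)) without
any symbolic growth.  Random values are rationals with numerators and
denominators drawn uniformly from [2, 997]; two independent draws are taken
and the maximum rank kept; draws that hit a pole of the rational dynamics are
retried.  Known inputs are treated as differentially independent signals
(random derivative chains), the generic-input assumption of the framework.
A rank computed at a random point can only underestimate the generic rank, and
the probability that a random point is rank-deficient is bounded by
deg/p ≈ 10⁻⁸ per draw; the two routes are cross-checked on the JAK-STAT
benchmark in the tests.

Reparameterizations are given as invertible state/parameter/input
substitutions (e.g. scaling an unobservable state by an unidentifiable
parameter, merging parameter products, absorbing a term into an unknown
input).  The transformed dynamics are derived by the chain rule, rewritten in
the new variables, and rejected unless every removed parameter cancels
exactly; output equivalence of the transformed model is a tested invariant,
not an assumption.  Searching for new reparameterizations automatically is out
of scope; the bundled benchmark transformations are verified, not discovered.

## Synthetic data

Measurements are generated as ỹ = y + (σ_abs + σ_rel·y)·N(0, 1) per point.
The absolute component "2%" is interpreted as 2% of the per-output trajectory
maximum (configurable to a raw value); the per-output-max convention keeps σ
positive for oscillatory signals that pass through zero and makes noise levels
comparable across outputs of different magnitude.  Standard deviations are
floored at 1e-10 to protect the log-likelihood, and the per-point σ used for
generation is stored with the data.

## Calibration

The objective is the exact Gaussian negative log-likelihood,
Σ [log(σ√2π) + r²/2] with weighted residuals r.  When the noise levels are
unknown, σ_abs and σ_rel join the decision vector and σ is rebuilt from the
model output; otherwise the stored per-point σ is used.

The optimizer is an enhanced-scatter-search-style metaheuristic chosen because
the ensemble stage consumes the full exploration history, not just the
optimum: Latin-hypercube diversification (10·dim points), a reference set of
10 (half best, half maximally diverse), pairwise hyper-rectangle recombination
with a go-beyond rule, a few fresh uniform points injected every sweep
(sustained diversification), restarts of the worst half on stagnation, and
periodic derivative-free local polish started from the best not-yet-polished
reference member so refinement spreads across basins.  Local polish uses
least-squares on the weighted residuals (finite-difference Jacobian) when the
noise model is fixed and Nelder–Mead on the NLL otherwise.  Every evaluation —
including every local-search step — is archived with its decision vector.
Parameters with positive bounds are searched in log10 space (kinetic constants
span decades); candidates are clipped to the bounds before simulation so the
archive stays inside the feasible box; failed simulations are archived with a
penalty value of 1e10 and flagged, never silently dropped.

## Ensemble selection

The admissible band of objective values is centred on a χ²-based approximation
of the nominal log-likelihood: −½[Σ log(σ*_ij² 2π) + (t_f·n_y − n_θ)], with the
summed squared residuals replaced by the *expectation* of their χ² law (a
quantile can be substituted).  The lower bound subtracts Δα = 3.841, the
χ²₁ 95% quantile of the likelihood-ratio test; the upper bound adds Δα plus
the shift obtained when σ* is inflated per output by its maximum over time
(floored at zero when the inflation would shrink σ).  Negation between the
log-likelihood and archive (NLL) scales happens in exactly one method,
guarded by a unit test.

The construction assumes *estimated* noise levels.  Plugging in the true
generating σ makes the interval miss the realized optimum in roughly a third
of noise realizations, because the realized minimum SSR fluctuates around the
χ² expectation with SD √(2·dof) ≫ 3.841.  `build_ensemble` therefore rescales
the supplied σ* by the best-fit residual standard deviation
s = √(SSR_min/(N − n_free)) by default, which is exactly what estimating σ*
from the fit produces.  For consistency the archived objective values —
computed under the original σ — are mapped onto the same scale through the
exact NLL identity under σ → s·σ (an affine map,
v → Σ log(σ√2π) + N·log s + (v − Σ log(σ√2π))/s²), and the base term of the
interval is anchored on s·σ, so the transformed best fit sits at the
approximation centre by construction.

Thinning: per parameter, the 21 percentile values P0, P5, …, P100 define
groups; each vector joins the group of its nearest percentile value (ties to
the lower group); odd-numbered groups — both extremes and the median group —
are discarded.  Requiring an even group for *every* parameter has survival
probability ≈ 0.48^d and empirically annihilates candidate sets beyond a few
dimensions, so the pipeline applies the majority form (even group in more than
half of the coordinates), which coincides with the strict rule in one
dimension and keeps survival near 50% independent of dimension.  Both forms
are available (`mode="all"`/`"majority"`).

Pruning removes near-duplicates: visiting candidates in ascending objective
order (better fits win ties), a vector is dropped when its squared relative
Euclidean distance — coordinates rescaled by the best fit θ*, zero components
of θ* excluded with a warning — to an already-kept vector is below ε (default
1e-4).  Finally a uniform random subsample brings the ensemble to the target
size (default 1000; identity when fewer candidates remain).

## Prediction and scoring

Every ensemble member is simulated on the requested grid; members whose
simulation fails are excluded and reported, and more than 20% failures aborts.
The ensemble prediction is the pointwise median of the member trajectories
(states and outputs); a "P% confidence percentile" envelope spans the
(50 − P/2)–(50 + P/2) percentile pair, so 40%/80% correspond to 30–70 and
10–90, and 95% to 2.5–97.5.  NRMSE is the RMSE divided by the range of the
reference, computed per variable over time and averaged across variables; it
applies to outputs against data, states against the nominal-parameter ("true")
trajectories of synthetic studies, and parameter vectors against nominal
values.

## Benchmarks and the synthetic study

Four case studies are bundled as declarative model files: a glucose-regulation
circuit (`big`: 3 states, 5 parameters, glucose measured, meal input unknown),
a cdc2–cyclin cell-division oscillator (`celldiv`: 6/8, two pools measured), an
activator–repressor circadian oscillator (`circad`: 9/15, the three proteins
measured), and a JAK-STAT signalling cycle (`jakstat`: 4/6, two phospho-pools
measured, receptor input known).  Classification of the originals gives,
respectively: 2 unidentifiable parameters with insulin and β-cell mass
unobservable; non-FISPO with no known repair; 6 unidentifiable parameters with
both mRNAs unobservable; 3 unidentifiable parameters with the STAT pool
unobservable.  The bundled transformations (β-cell mass scaled by the
secretion capacity with the insulin-action term absorbed into the unknown
input; mRNAs rescaled by transcription rates; STAT scaled by its
unit-conversion parameter) each restore full observability, verified by the
rank test at import time of the test suite, not assumed.

Study conditions follow the published table: 200 points with 2%/2%
absolute/relative noise for the glucose model; 20 points at 2%/10% for cell
division; 30 at 2%/10% for the circadian model; 16 points for JAK-STAT (the
original study used real data here; this package substitutes synthetic data at
2%/10% and makes no claims about the real dataset).  Measurement grids are
uniform over each model's horizon (120 min, 100 min, 100 h, 60 min).  Nominal
parameters are set to physiologically sensible values with slow glucose
turnover (~0.04/min) and insulin expressed in units of its glycemic action, so
that the unit-absorbing input redefinition stays well-scaled; the meal
appearance is a smooth absorption bump (peak 0.3 mM/min at 25 min) that the
default 10-knot input grid represents below the noise floor.

What the synthetic studies do and do not show: passing tests demonstrate the
pipeline's selection logic, the observability classifications, and the
qualitative contrast between observable and unobservable state predictions on
data with known ground truth and well-specified noise.  They do not emulate
real-data features — model misspecification, correlated or non-Gaussian noise,
irregular sampling, or unknown input classes outside the piecewise-linear
family.

A measured limitation worth stating plainly: with a freely estimated
non-negative unknown input, the *baseline* of the unmeasured insulin state is
practically unidentifiable even in the fully observable reparameterized model
— a baseline shift δ maps to the input shift δ·x1(t), which is smoother than
the input itself and therefore always representable on the knot grid.  The
ensemble median then reflects the centre of the bound-limited feasible range
rather than the truth.  The observable-vs-unobservable error *reduction*
(about 60% at the package's reduced optimizer budgets) is robust across seeds;
the absolute insulin error of the reparameterized model remains an order of
magnitude above what an estimation setup with tighter input constraints could
achieve.

## Problem sizes

The bundled studies run at deliberately reduced scale: optimizer budgets of a
few thousand evaluations per calibration (the glucose case uses 4000–6000),
ensembles of whatever survives selection rather than a guaranteed 1000, and
single-realization noise.  The ensemble-size saturation experiment uses the
JAK-STAT case at a 20 000-evaluation budget, where the selection stages retain
more than 2000 candidates.
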