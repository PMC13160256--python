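# Methods

`hybridkin` is a self-contained benchmark for hybrid mechanistic/machine-
learning modelling of a bioconversion: an engineered *Pseudomonas putida*
culture growing on glucose while converting catechol, a cytotoxic
lignin-derived aromatic, into cis,cis-muconic acid (MA).  Everything is
synthetic: a ground-truth kinetic model generates the "experimental" data,
candidate models are fitted to sparse noisy batch observations, and all of
them are then judged on fed-batch extrapolation against the same ground
truth.  This note records the models, the estimation machinery, the
numerical choices, and what the synthetic setting can and cannot show.

## Ground-truth model

Six states: viable biomass `Xv` and dead biomass `Xd` (OD600), glucose
`Cg`, catechol `Cc`, muconate `Cm` (mM); the observable total biomass is
`Xt = Xv + Xd`.

    mu_gr = (1 - Xv/(Y_xg*Cg0)) * mu_g * Cg/(Cg+K_g)        growth
    mu_dt = k_d + mu_c * Cc/(Cc+K_c)                        death
    dXv/dt = (mu_gr - mu_dt) Xv
    dXd/dt = mu_dt Xv                                       (not degraded)
    dCg/dt = -(mu_gr/Y_xg + ms*m_k * Cc/(Cc+k_cm) * Cg/(Cg+k_mg)) Xv
    dCm/dt = (Y_mx mu_gr + beta) Xv Cc/(Cc+k_cr)
    dCc/dt = -dCm/dt                                        (mass balance)

Growth is logistic-Monod (the logistic capacity `Y_xg*Cg0` reproduces the
lag/exponential/stationary course of a batch culture; `Cg0` is the t=0
glucose level and is *not* updated on fed-batch spikes).  Death has a
zero-order component plus catechol toxicity.  Glucose is drawn by growth
and by a maintenance term tied to catechol detoxification; the factor
`Cg/(Cg+k_mg)` (`k_mg` = 0.5 mM) is a smooth regularisation this package
adds so the otherwise glucose-independent maintenance demand shuts off as
glucose runs out instead of driving `Cg` negative.  Catechol and MA are
stoichiometrically locked, so `Cc + Cm` is conserved in batch — the
sharpest structural invariant the test suite checks (to 1e-6 mM).

**Parameters.**  No kinetic constants for this process are established;
the committed defaults are repository-chosen and calibrated only
qualitatively: a 72 h batch from (0.01 OD600, 60 mM glucose, 30 mM
catechol) shows a sigmoidal biomass curve with a lag (final `Xt` ≈ 2.3,
of which ≈ 69% is dead biomass by 72 h), glucose depletion at ≈ 45 h, and
≈ 2/3 of the catechol converted to MA.

| parameter | value | units | role |
|---|---|---|---|
| `mu_g` | 0.25 | 1/h | max specific growth rate |
| `K_g` | 5 | mM | glucose half-saturation |
| `k_d` | 0.005 | 1/h | basal death |
| `mu_c` | 0.04 | 1/h | max catechol-toxicity death |
| `K_c` | 15 | mM | toxicity half-saturation |
| `Y_xg` | 0.04 | OD600/mM | biomass yield / logistic capacity |
| `m_k` | 0.1 | mM/(OD600 h) | maintenance draw |
| `k_cm` | 5 | mM | maintenance catechol half-saturation |
| `k_mg` | 0.5 | mM | maintenance glucose regularisation |
| `Y_mx` | 2 | mM/OD600 | growth-associated MA yield |
| `beta` | 0.35 | mM/(OD600 h) | non-growth MA production |
| `k_cr` | 5 | mM | MA-production half-saturation |

The *versatility* variant multiplies `m_k` by `maintenance_scale = 40`,
chosen so that the cumulative maintenance glucose draw over the default
batch (≈ 29 mM) matches the growth-linked draw (≈ 31 mM) — a deliberate
change of physics that none of the fitted model structures anticipate.

**Fed-batch.**  Substrate impulses (`+cg_in` glucose, `+cc_in` catechol)
are applied at `tau, 2 tau, ...`; the nominal t=0 dose is part of the
initial condition, never a spike.  Integration is piecewise (LSODA,
rtol/atol 1e-8) with an exact state jump at each spike; stored rows at a
spike time hold the post-impulse value.

**Training data.**  Three initial conditions are Latin-hypercube sampled
from glucose 50–70 mM × catechol 25–35 mM at a fixed 0.01 OD600 inoculum.
Batches are sampled at 10 uniform times over 72 h; only (`Xt`, `Cg`, `Cc`,
`Cm`) are kept, mirroring the practical fact that optical density cannot
split live from dead cells.  Noise is multiplicative Gaussian with CV 5%
(clipped at zero), a choice made once for realism — instrument noise on
OD and HPLC readings is roughly proportional.

## Candidate models

* **Phenomenological** (8 parameters): total biomass grows at a net
  Monod-promotion / Monod-inhibition rate
  `mu_PM = mu_g Cg/(Cg+K_g) - mu_c Cc/(Cc+K_c)`; product equations mirror
  the truth with `Xt` in place of `Xv`.  No death, no maintenance.
* **Hybrid** (4 mechanistic parameters + network): the same skeleton but
  the growth rate is an unknown time-variant quantity.  Two estimation
  strategies:
  * *sequential* — (a) time-variant parameter estimation (TVPE): one free
    rate value per (condition, measurement time), fitted under the
    transcribed dynamics with objective `w_m·MSE + w_s·SM` where `SM` is
    the mean squared second difference of the rate trajectory (defaults
    `w_m = 1`, `w_s = 10`; the full profile cross-validates
    `w_s ∈ {0.1, 1, 10, 100}` by leave-one-condition-out closed-loop
    error); (b) a network regressed on the recovered rates as a function
    of the measured state (architecture by 5-fold CV).
  * *integrated* — one estimation problem: the network weights are
    decision variables, tied to the time-variant rate by equality
    constraints at every collocation point, objective = pure MSE (no
    smoothing — regularity comes from the network), weights and biases
    boxed to [-1, 1].
* **Improved hybrid**: growth is explicit Monod in glucose
  (`mu_g`, `k_g` join the mechanistic parameters) and the network outputs
  the *viable fraction* of total biomass through a sigmoid — the physical
  insight suggested by the attribution analysis.
* **Black-box**: a network mapping (initial observable state, time)
  directly to the state at that time, inputs and outputs Z-scored,
  architecture by 5-fold CV grid search (activation × depth × width × L2).
  Its inputs carry no feed information, so fed-batch spikes are invisible
  to it by construction.

### Embedded-network conventions

Inputs (`Xt`, `Cg`, `Cc`, `Cm`) are affinely mapped to [0, 1] using the
training-data min/max, frozen into the network spec — with weights boxed
to [-1, 1], raw mM inputs would saturate every tanh unit.  The same
reasoning is applied at the output: a growth-rate head with an unbounded
(identity) output can reach ±5 1/h on states outside the training cloud,
which no bacterial culture exhibits and which makes closed-loop fed-batch
predictions blow up.  The growth head is therefore `mu = s·tanh(·)` with
the scale `s` set to twice the largest rate visible in the data
(`max |d ln Xt/dt|` over finite differences); the improved variant's
viable-fraction head is a sigmoid in (0, 1).  The sequential variant's
externally-trained network is a plain sklearn MLP (tanh, identity output,
standardised target, output layer re-solved exactly by least squares
after L-BFGS, which otherwise stalls on nearly-flat basins).

## Estimation machinery

All dynamic fits solve the same transcribed problem: Radau IIA collocation
(5 points per element, two sub-elements per measurement interval — the
committed estimation grid) turns the ODEs into equality constraints on
node states; the objective is the species-normalised state-space MSE (each
species divided by its maximum over the training data, so OD600-sized and
mM-sized residuals are commensurate) plus the optional smoothing index.
Free time-variant quantities (TVPE) live at the measurement nodes and
vary linearly across an interval inside the transcription; embedded
networks are instead evaluated on the state at every collocation point —
the algebraic-constraint convention of a DAE formulation — which makes the
training dynamics exactly the ODE the closed-loop simulator integrates
(verified to ~1e-9 at fixed weights, ~3e-4 at fitted solutions where the
closed loop adds its smooth state clamp).  Because state elimination would
otherwise drop the full-space formulation's nonnegativity bounds on the
states, a smooth one-sided penalty (weight 10, width 1e-6 in scaled units)
on the measurement-node states restores them; without it, fits exploit
unphysical negative-glucose excursions that the clamped closed-loop
simulator cannot follow.

The transcribed problem is solved in *reduced space*: for any candidate
parameter vector the collocation equations are solved interval-by-interval
by damped Newton (they are square in the unknown node states), leaving a
small least-squares problem over the mechanistic parameters, the free
time-variant values and/or the network weights.  That problem goes to
scipy's trust-region-reflective solver with box bounds and exact Jacobians
from the implicit-function theorem, every partial derivative obtained by
batched complex-step differentiation (machine precision, no hand-coded
derivative code).  Multistart wraps this: mechanistic parameters drawn
log-uniformly from decade-wide boxes around order-of-magnitude guesses
read off the data, rate trajectories warm-started from finite-difference
log-slopes of biomass, network weights uniform with a deliberately small
output layer; unmarchable draws are redrawn (logged), candidate points
where the collocation equations cannot be solved return a constant penalty
so the solver retreats, and every start is logged with its objective and
status.  Ties break to the lowest start index; the whole procedure is
deterministic given a seed.

Discretization accuracy: one 5-point element per 8 h interval integrates
the calibrated dynamics to ~1e-5 relative; the committed two-sub-element
fit grid reaches ~1e-6, small enough that noise-free parameter recovery is
unbiased at the 0.1% level (the 3-point scheme one might first reach for
is ~1e-2 here and visibly shifts weakly-identified parameters).

## Evaluation

Every fitted model predicts fed-batch cultures (10 mM glucose + 3 mM
catechol every 25 h) from initial conditions on a glucose 20–100 mM ×
catechol 5–55 mM grid — far outside the training box.  Agreement with the
ground truth is a single pooled R² per cell over the four species at 10
uniform times, after per-species max-normalisation.  Raw R² values are
kept (flooring at -1 is applied for heatmap rendering only); a cell whose
simulation fails outright (divergence guard: biomass beyond 100× the
training maximum) is scored -1.  Region summaries split the grid at 60 mM
glucose and 30 mM catechol into I (high glucose), II (low glucose, low
catechol) and III (low glucose, high catechol).

Closed-loop simulation of fitted models uses a smooth positive part
(`0.5(v + sqrt(v² + 1e-6))`) of the state inside the right-hand side
rather than a hard clip: fitted models may legitimately predict (slightly)
negative concentrations, and a hard clip's derivative discontinuity makes
stiff solvers grind at the zero boundary.  Network inputs outside the
training box by more than 0.25 (scaled units) are clipped to that guard
with a warning.

The model-ranking checks are explicitly stochastic: they assert a ranking
of grid-mean R² for at least 2 of 3 fixed seeds at the smoke profile
(5-start multistart, fixed architectures, 5×5 grid).

## Interpretability

Integrated Gradients with exact reverse-mode network gradients and a
midpoint Riemann path sum (default 128 steps; completeness gap below 1e-4
for the tanh networks used here).  The baseline is the all-zeros point of
the scaled input space, i.e. the training minimum of each feature.  The
headline check is sign-level only: averaged over training points, glucose
attribution positive, catechol negative.

## Study sizes and profiles

The `smoke` profile (default) uses 5-start multistart with a 150-evaluation
budget per start, fixed network architectures (one hidden layer of 4), and
a 5×5 evaluation grid; a full study runs in roughly two minutes per seed on
one CPU.  The `paper` profile enables the cross-validation protocols
(smoothing weight, architectures, black-box grid), 50 starts, and the full
9×11 grid.  Tests and the acceptance script run the smoke profile; the
problem sizes there are the package's committed study conditions, not
tuning knobs.

## What the synthetic benchmark does and does not show

Passing tests show that the estimation machinery recovers what it should
when the data-generating process is known (parameter recovery to <2% on
noise-free self-generated data; growth-rate trajectories to <10% where the
rate is appreciable), and that the comparative claims about model families
reproduce under one committed, plausible parameter regime.  They do not
show that any ranking generalises to real cultures: real measurement error
is not exactly multiplicative Gaussian, real kinetics have pathways this
ground truth lacks (byproducts, pH/oxygen effects, adaptation), and the
ground truth's mild-death, mild-maintenance regime is one point in a large
space.  The versatility variant probes exactly one such axis (maintenance
scaled to rival growth) and nothing more.

## Known limitations

* The relative ordering of the integrated hybrid and the phenomenological
  model is sensitive to how close the committed ground truth is to the
  phenomenological structure and to the treatment of rare catastrophic
  cells (raw-mean vs floored-mean R²); see the region summaries rather
  than single numbers.
* The reduced-space solver cannot represent fits where the collocation
  system is singular along the path (such starts are logged as failures);
  no global-optimality guarantee is implied by multistart.
* Time-variant parameters are linear within a measurement interval; rates
  that change sharply between samples are smoothed by construction.
* The catechol attribution score is weak (roughly a fifth of the glucose
  score) and its sign is not stable across noise draws: batch conservation
  makes catechol and muconate perfectly anti-correlated along training
  trajectories, so the network can assign the late-culture growth decline
  to either input with nearly equal objective.  The sign-level
  attribution check is therefore a majority-of-seeds assertion, and on
  some seed triples it fails.
* The black-box and sequential networks are trained with L-BFGS (plus an
  exact output-layer polish) rather than stochastic minibatch descent —
  with 30-row datasets, minibatch statistics are meaningless.
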