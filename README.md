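# hybridkin

Hybrid mechanistic/machine-learning dynamic modelling of a lignin-
valorisation bioprocess: engineered *Pseudomonas putida* grows on glucose
while converting catechol — a cytotoxic lignin-derived aromatic — into
cis,cis-muconic acid (MA), a bioplastics precursor.  The package is a
self-contained benchmark for people who build bioprocess models: it ships
a ground-truth kinetic simulator with a synthetic-data generator, four
competing model families fitted to the same sparse noisy batch data, and a
fed-batch extrapolation harness plus network interpretability to compare
them.

## The modelling problem

Only four quantities are measurable: total biomass `Xt` (OD600), glucose
`Cg`, catechol `Cc` and muconate `Cm` (mM).  The ground truth additionally
tracks the latent viable/dead biomass split (`Xt = Xv + Xd`): viable cells
grow logistic-Monod on glucose, die from catechol toxicity, spend glucose
on detoxification maintenance, and convert catechol to MA
stoichiometrically (`dCc/dt = -dCm/dt`).  The candidate models are

* a **phenomenological** ODE model, `dXt/dt = mu_PM(Cg, Cc) * Xt` with
  `mu_PM = mu_g Cg/(Cg+K_g) - mu_c Cc/(Cc+K_c)` (8 parameters);
* a **sequential hybrid**: time-variant parameter estimation of the growth
  rate `mu(t)` under the transcribed dynamics with objective
  `w_m*MSE + w_s*SM` (`SM` = mean squared second difference of `mu`),
  followed by a neural network regressing `mu` on the measured state;
* an **integrated hybrid**: the same skeleton, but the network weights are
  decision variables of one estimation problem, tied to the growth rate by
  equality constraints at the collocation points, pure-MSE objective,
  weights boxed to [-1, 1];
* an **improved hybrid**: Monod glucose growth made explicit, the network
  instead outputs the viable biomass fraction through a sigmoid;
* a **black-box** network `(Xt0, Cg0, Cc0, Cm0, t) -> (Xt, Cg, Cc, Cm)`
  with Z-scored inputs/outputs and 5-fold CV grid search — structurally
  blind to fed-batch feeding.

All dynamic fits share one estimation engine: Radau IIA collocation
transcription of the ODEs over the measurement grid, solved in reduced
space (interval-wise Newton elimination of the state variables, exact
implicit-function-theorem Jacobians via complex-step differentiation)
under seeded multistart.  Model comparison is pooled R² against the ground
truth on a grid of unseen initial conditions under periodic substrate
spikes; interpretability is Integrated Gradients with exact network
gradients.  See `docs/methods.md` for the full model and numerics account.

## Worked example

```python
import numpy as np
from hybridkin import GroundTruthState, SpikeSchedule, default_params, simulate

params = default_params()
init = GroundTruthState(Xv=0.01, Xd=0.0, Cg=60.0, Cc=30.0, Cm=0.0)
tr = simulate(params, init, SpikeSchedule.batch(72.0),
              output_grid=np.linspace(0, 72, 10))
for t, (xt, cg, cc, cm, xv, xd) in zip(tr.times, tr.states):
    print(f"{t:5.1f} {xt:6.3f} {cg:6.2f} {cc:6.2f} {cm:6.2f}")
```

prints the 72 h batch course (time, total biomass, glucose, catechol, MA):

```
  0.0  0.010  60.00  30.00   0.00
  8.0  0.054  58.87  29.87   0.13
 16.0  0.251  53.89  29.26   0.74
 24.0  0.881  37.84  27.14   2.86
 32.0  1.835  13.27  22.98   7.02
 40.0  2.314   0.45  18.70  11.30
 48.0  2.328   0.00  15.61  14.39
 56.0  2.328   0.00  13.22  16.78
 64.0  2.328   0.00  11.32  18.68
 72.0  2.328   0.00   9.81  20.19
```

— a sigmoidal biomass curve with a lag, glucose depleted by ~45 h, and
20.2 mM of the 30 mM catechol converted to muconate by harvest (`Cc + Cm`
stays at 30.00 throughout: the conservation the mass balance forces).
Biomass plateaus at 2.33 OD600 while the *viable* fraction keeps falling
(0.73 OD600 by 72 h) — the latent structure the improved hybrid's network
has to infer from total biomass alone.

The end-to-end comparison (fit all five models, score them on the 5×5
fed-batch extrapolation grid) is one call:

```python
from hybridkin import smoke_config
from hybridkin.study import build_study

result = build_study(smoke_config(seed=101))
print(result.mean_r2())
```

```
{'phenom': 0.587, 'sequential': 0.301, 'integrated': 0.730,
 'improved': 0.883, 'blackbox': -0.519}
```

Grid-mean R² (floored at -1): the spike-blind black-box surrogate
collapses under fed-batch extrapolation, the one-step integrated hybrid
clearly beats the two-step sequential one, and the improved variant —
which embeds the Monod-glucose insight recovered by the attribution
analysis — leads.  The `examples/` scripts walk through each capability
(simulation, data generation, fitting/comparison, attribution) with
commentary; the `hybridkin` CLI exposes the same steps
(`hybridkin run-study --seed 101 --out ws/`).

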