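# ergoflow

Simulation toolkit for studying adaptive behaviour as the self-organisation of
stochastic flows: ergodic densities of random attractors, value and cost
functions defined by those densities, optimal-control comparators, and an
active-inference agent that solves a goal-directed control task with an
*itinerant* (divergence-based) policy instead of a learned value function.

## Who this is for

Computational neuroscientists and dynamical-systems researchers who want
runnable, tested implementations of the free-energy view of behaviour:

- **Ensemble self-organisation** — globally coupled Lorenz oscillators whose
  mean field enslaves the microstates onto a synchronisation manifold, and the
  two ways that macroscopic order dies (incoherence under strong state noise,
  oscillator death under dispersed speeds).
- **Fokker–Planck machinery** — for any drift `f` and diffusion tensor `Γ`,
  the ergodic density solves `Λp = ∇·Γ∇p − ∇·(fp) = 0`. Value is defined as
  `V = ln p` (negative surprise), cost as the expected rate of increase of
  value, `c = f·∇V + ∇·Γ·∇V`, entropy and entropy production
  `∫ ∇p·Γ·∇p / p dx ≥ 0` follow. A standard-form (Helmholtz) constructor
  builds flows `f = (Γ + Q)∇V` with antisymmetric `Q`, whose stationary
  density is `exp(V)/Z` regardless of the divergence-free part.
- **Optimal-control comparators** — a greedy Hamilton–Jacobi–Bellman control
  (`π = argmax_u f(x,u)·∇V`) and a temporal-difference value-learning scheme
  whose reward-prediction error `δ = V̇ − c` vanishes at convergence.
- **Active inference** — generalized filtering (predictive coding) in
  generalized coordinates of motion, Laplace free energy, and an action law
  `da/dt = −∂s̃/∂a · ε̃s` that samples the sensations the agent predicts. The
  mountain-car agent's empirical prior is the flow
  `f(x, x') = [x', c(x, z)·x' − ∂φ/∂x]`, whose divergence *is* the cost
  function: costly regions repel (the car "expects to go faster"), the
  negative-cost target region contracts, and a satiety state `z` that rises
  with reward turns the goal into a weak attractor that is visited, consumed
  and left again.

## Worked example

Compute the stationary density of an Ornstein–Uhlenbeck flow and its derived
value and cost fields:

```python
import numpy as np
from ergoflow.fokker_planck import (GridSpec, VectorField, cost_from_value,
                                    discretize_fp_operator, entropy_of_density,
                                    stationary_density, value_from_density)

grid = GridSpec(lower=(-6.0,), upper=(6.0,), bins=(256,))
flow = VectorField.from_function(grid, lambda x: [-x])   # f = -x
p = stationary_density(discretize_fp_operator(flow, 0.5))  # Γ = 1/2
x = grid.centers(0)
print("stationary variance:", float(np.sum(p.flat() * x**2) * grid.cell_volume))
print("entropy:", entropy_of_density(p))
V = value_from_density(p)
c = cost_from_value(V, flow, 0.5)
print("cost at density peak:", float(c.values[np.argmax(p.values)]))
```

prints

```
stationary variance: 0.5000000000625585
entropy: 1.0723649429872548
cost at density peak: -0.9989013671611475
```

The variance matches the closed form Γ/θ = 0.5 (the exponential-fitting
discretization is stationary-exact for linear drift), the entropy matches the
Gaussian value ½ln(2πe·0.5) ≈ 1.0724, and cost at the density peak is
negative — attracting states are exactly the states where expected cost is
non-positive (its magnitude approaches the diffusion-curvature term Γ·V'' = −1
at the peak of a unit-variance-scaled Gaussian).

Run the goal-directed mountain-car agent from the shell:

```bash
ergoflow mountain-car --mode fixed-cost --duration 100 --seed 3 --out run/
```

which writes the episode time series as CSV plus a JSON summary; a typical
summary reports `"success": true` (the car backs away from the target, pumps
up its oscillation, parks at the top within |x−1| < 0.1 and holds for more
than ten seconds) and `"moved_left_first": true` — the paradoxical-but-adaptive
signature of the task. Other subcommands: `simulate-gcm` (oscillator
ensembles), `ergodic-density`, `value-learning` and `fixtures` (canonical
experiment configurations).

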