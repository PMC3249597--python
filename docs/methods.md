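# Methods

This note documents the models the package implements, the numerical choices
behind them, the calibrated defaults, and what the tests do and do not
establish. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## 1. Generalized coordinates of motion (`gencoord`)

A generalized state `x̃ = [x, x', x'', …]` carries a variable and its temporal
derivatives to embedding order `n`. The derivative operator `𝒟` is the block
matrix with identity blocks on its first superdiagonal: it shifts orders down
and is nilpotent (`𝒟ⁿ = 0`). Signals are embedded by local polynomial
(inverse-Taylor) interpolation over windows of `n` samples — exact for
polynomials of degree below `n`, one-sided at the boundaries.

Smooth fluctuations are modelled with a Gaussian autocorrelation
`γ(h) = σ² exp(−h²/2r²)` of width (roughness parameter) `r`; the covariance
between the i-th and j-th derivatives at lag zero is `(−1)^j γ^(i+j)(0)`, so
even-order cross terms couple and odd totals vanish. The generalized
precision is the inverse of this covariance (computed via Cholesky). Note the
marginal statement "order-0 precision equals 1/σ²" holds exactly only up to
order 2; beyond that the order-0/order-2 coupling makes the *covariance*
entry, not the precision entry, equal to σ². Wider autocorrelations (smoother
noise) give smaller derivative variances and hence larger derivative
precisions.

Defaults: embedding order n = 5 for the agent (see §5), roughness r = 0.5 s.
Both are conventions of the generalized-filtering literature, recorded in
the run configuration.

## 2. Coupled oscillator ensembles (`ensembles`)

Sixteen Lorenz systems (classical parameters σ = 10, ρ = 28, β = 8/3) are
coupled diffusively through their mean field,

    dx⁽ⁱ⁾/dt = exp(ω_i)·L(x⁽ⁱ⁾) + gain·κ·(x̄ − x⁽ⁱ⁾) + ω⁽ⁱ⁾(t),

with κ the coupling strength in [0, 1] and gain = 24 s⁻¹ (relaxation rate 12
at the default κ = 0.5). Diffusive relaxation is required for enslavement:
evaluating the drift at a convex combination of own state and mean field
leaves the transverse dynamics `δ̇ = (1−κ)Jδ` with a positive Lyapunov
exponent, and such ensembles never synchronize. The relaxation rate must
exceed the local expansion of the Lorenz Jacobian along the orbit, which is
why the default sits an order of magnitude above the largest Lyapunov
exponent (~0.9).

Integration is classical RK4 on the deterministic coupled drift with additive
`√dt`-scaled (Brownian) noise increments; plain Euler at dt = 1/32 s overflows
once speed multipliers exceed ~1.5. Speed multipliers `exp(ω_i)` are drawn
once per run and scale the drift only.

The three regimes at the configured noise levels (motion variance 2²,
log-rate variance 2⁻⁶ for coherence; motion variance 2¹⁰ for incoherence;
log-rate variance 2⁻⁴ for oscillator death):

- *coherent*: the normalized synchrony error (mean squared deviation of
  microstates about the macrostate, divided by macrostate variance) falls
  below 0.05;
- *oscillator death*: the ensemble collapses onto one of the Lorenz fixed
  points C± and the macrostate stalls. Because the dead ensemble still
  wobbles at ~10 rad/s under state noise, the macro speed is estimated from
  coarse (0.25 s) differences and compared against 1/8 of a reference
  attractor speed (120 units/s) — dead ensembles measure ≤ 10, live ones
  ≥ 30;
- *incoherent*: everything else (large synchrony error with a moving
  macrostate).

Thresholds are configurable (`RegimeThresholds`) and recorded. Classification
is statistical: across 8 seeds the majority votes are 7/8 coherent, 8/8
incoherent, and 6/8 oscillator death (death competes with a coherent basin
for some speed draws).

## 3. Fokker–Planck machinery (`fokker_planck`)

**Discretization.** Finite volume on rectangular cell-centred grids with
exponentially fitted (Scharfetter–Gummel) face fluxes: with face velocity `u`,
face diffusion `D` and spacing `h`, the flux is
`(D/h)[B(−uh/D) p_L − B(uh/D) p_R]`, `B(z) = z/(eᶻ−1)`. This blends central
differencing (diffusion-dominated) and upwinding (advection-dominated) while
preserving the generator property — off-diagonals ≥ 0, columns sum to zero
under reflecting boundaries — and is stationary-exact for locally linear
drift, which is why the linear-drift benchmark reproduces its closed-form
variance to ~1e-10 rather than the 2% a first-order upwind scheme would give.
Only diagonal diffusion tensors are supported (every configuration used by
the demos is diagonal). Reflecting boundaries are the default; absorbing
boundaries (zero-density ghost cells, renormalized densities) are available.

**Stationary density.** Shifted inverse iteration on the sparse generator:
factor `Λ − σI` once (σ = 1e-8·max|diag|) and iterate solves from a uniform
start until the relative residual falls below 1e-12; negative entries beyond
−1e-8·max(p) abort, smaller ones are clipped and the density renormalized.

**Sojourn-time estimator.** For strongly advective flows on coarse grids the
eigensolution is numerics-bound: at Péclet numbers ~10³ the scheme upwinds,
adding numerical diffusion ~h|f|/2 that can exceed a small physical Γ by three
orders of magnitude, and the 3-D sparse factorization is expensive (the
48³ chaotic-attractor generator takes ~15 min on one CPU and yields a density
smeared far beyond the true invariant measure). `sojourn_density` instead
estimates the ergodic density as what it is — the long-run sojourn time —
by binning a long solution of `dx = f dt + √(2Γ) dW` (RK4 + Brownian
increments, many walkers). The chaotic-attractor demo uses it by default;
the eigensolver remains the default on grids up to 50k cells.

**Derived fields.** `V = ln p` with a floor at 1e-12·max(p), normalized so
∫exp(V) = 1; gradients, divergence and `c = f·∇V + ∇·Γ∇V` by central
differences (one-sided at boundaries). Entropy is the cell-volume-weighted
sum −Σ p ln p; entropy production `∫ ∇p·Γ·∇p / p` is evaluated on the support
(p above 1e-12·max).

**Standard form.** `standard_form_flow` builds `f = (Γ+Q)∇V` from an analytic
or gridded value function and a constant antisymmetric `Q`; `(Q∇V)·∇V = 0`
holds identically, so `exp(V)/Z` is stationary and `∇V·f = ∇V·Γ·∇V ≥ 0` —
value is a Lyapunov function of its own policy. Setting
`V = −(φ(x) + x'²/2)` with the 2×2 rotation `Q` recovers Newtonian mechanics,
and adding diffusion on the velocity alone adds the friction term `−γx'`.

**Comparators.** `hjb_greedy_control` maximizes `f(x,u)·∇V` over a finite
control set per cell (ties toward the smallest |u|) and reports the residual
against a supplied cost. Value learning is TD(0) along a trajectory: the
reward-prediction error `δ = (V(x_t) − V(x_prev))/Δt − c(x_prev)` is credited
to the *previously* visited cell (`V(x_prev) += η Δt δ`); crediting the
current cell instead is linearly unstable (its update coefficient exceeds
one). On a periodic orbit the fixed point exists only when the cost has zero
circulation, so the ring benchmark uses a mean-centred localized bump; the
oracle is the direct path integral of cost along the orbit. The benchmark
ring uses 32 cells — the scheme's long-wavelength error decays diffusively,
so convergence to machine precision needs ~3000 laps there (a second of
compute; finer rings converge proportionally more slowly).

## 4. The mountain-car task (`mountain_car`)

Landscape: `φ(x) = x² + x` for x < 0 and `φ(x) = x(1+5x²)^(−1/2)` for x ≥ 0 —
the unique C¹ form consistent with the task's constraints (minimum at
x = −0.5, unit uphill force at x = 0, a target on the flattening hill at
x = 1). True motion: `ẋ' = σ(a) − ∂φ − x'/8` with σ = tanh, so the unit force
at the origin is exactly at the edge of the car's authority: the target is
unreachable without first backing away.

Cost: `c(x,z) = (16·e^{−64(x−1)²} − 1)(tanh(8(z−1)) − 1) − 1`. At z = 0 this
is `1 − 32 e^{−64(x−1)²}` (positive everywhere except a deep well at the
target); as z → ∞ it is uniformly −1. The generative (expected) flow
`[x', c·x' − ∂φ]` has divergence identically equal to c.

Satiety kinetics: `ż = α·max(−c − 1, 0) − z/τ` with α = 0.5, τ = 90 s. Only
reward beyond the sated baseline (|c(x,∞)| = 1) feeds satiety — without that
baseline the mildly negative sated landscape would sustain z indefinitely at
ατ and the goal would never re-arm. τ is chosen so the car settles in the
valley before the goal re-arms; much shorter time constants re-arm the cost
while the car is still swinging, and a rightward-moving car caught mid-flight
by the re-armed anti-friction can be driven over the hill for good.

## 5. The active-inference agent (`agent`)

Beliefs are conditional expectations `μ̃` in generalized coordinates (Laplace
assumption, fixed-form filtering at the mode; conditional covariances are not
propagated). The filtering drift is the predictive-coding form
`𝒟μ̃ + ∂g̃ᵀε̃s + ∂f̃ᵀε̃x − 𝒟ᵀε̃x` with second-order (Jacobian-derivative)
terms ignored; generalized predictions apply `f`, `g` at order 0 and their
Jacobians at higher orders. Action descends the same free energy through the
sensations: `ȧ = −gain·∂s̃/∂a·ε̃s`, with `∂s̃/∂a` obtained by central
differences through the true sensory mapping.

**Integration.** The coupled (environment, beliefs, action) system advances
by local-linearization steps `Δξ = (e^{JΔt} − I)J⁻¹ b` with the Jacobian
assembled analytically in Gauss–Newton form (the same ignored-second-order
structure as the drift). Differencing the drift numerically for `J` is not an
option: the landscape's curvature jump at the branch point x = 0 produces
spurious ~1e7 eigenvalues across the kink. Process noise enters the velocity
as a Brownian increment after each step. The action variable is clipped at
|a| ≤ 2.5 (σ(2.5) ≈ 0.99): the cap keeps the tanh-squashed action out of deep
saturation, where σ'(a) ≈ 0 would disconnect the only pathway by which errors
can move action — without it the agent can emerge from a hard-braking episode
locked at full wrong-way thrust for the rest of the run. An optional leak
term −leak·a is available but off by default (any appreciable leak drains the
small sustained thrust that parking requires).

**Calibrated defaults.** The agent's loop parameters are free parameters of
the scheme; the defaults below were calibrated once to produce the task's
characteristic behaviour and then frozen:

| parameter | default | role |
|---|---|---|
| embedding order n | 5 | generalized depth of beliefs/sensations |
| dt | 1/64 s | shared agent/environment step |
| sensory sd, order 0 | 1/256 | precise proprioception of (x, x', z) |
| sensory sd, order k ≥ 1 | 4^{k−1} | weak trust in sensed derivatives |
| state-motion sd | 0.45 | confidence in the divergence-based prior |
| process / sensor noise sd | 1/256 | environmental fluctuations |
| action gain / clip | 1.1 / 2.5 | realization bandwidth / saturation guard |

The order-0 vs higher-order sensory split is the load-bearing choice. The
anti-friction prior (`c ≈ +1` away from the target) demands exponential
energy growth; if sensed accelerations are trusted, action realizes that
demand at full strength, the oscillation grows ~e-fold per second, and the
car arrives at the target far too fast for its bounded thrust to capture
(the pure expected flow itself escapes over the hill from most starts).
Down-weighting the sensed derivatives meters the realization out to roughly
one e-fold per few swings, so the first crossing of the capture band
(arrival speed ≲ 1) is gentle; inside the deep-cost window the prediction
errors are ~30× larger, so braking and parking still engage at full
bandwidth. Conversely, an order of magnitude more environmental noise
(sd ~1/16) destroys parking: the deep cost multiplies belief jitter ~25× into
thrust noise and hold times collapse to ~2 s.

With these defaults, 15 of 16 seeded 100-s episodes from uniform random
starts in [−1, 0.5] park within |x−1| < 0.1 for at least 10 consecutive
seconds, and all 16 move left of their start before first reaching the
target. With satiety enabled, 600-s episodes cycle between the target and the
valley (typically ≥ 10 target entries); occasional seeds still end in a
right-side escape after many cycles — the expected flow itself has this
failure mode, since beyond the cost window the landscape flattens and
anti-friction acts unopposed.

## 6. What the synthetic conditions do and do not show

All inputs are generated by the package (flows, grids, episodes); there is no
external data. The ensemble and agent demonstrations are *phenomenological*
reproductions: they establish that the mechanisms (mean-field enslavement,
autovitiation of costly fixed points, divergence-based parking, satiety-driven
itinerancy) operate as described under one calibrated configuration, not that
the behaviour is robust across all parameterizations — several loop
parameters had to be chosen within an order of magnitude for the closed loop
to work at all, which is itself informative about the scheme's sensitivity.

Scaled-down sizes: the chaotic-attractor density demo uses a 48³ grid
(the 96³ resolution is supported by the same code but slow) with the
sojourn-time estimator (§3); at this resolution the eigensolution's effective
diffusion is numerical, so only the histogram estimator shows the expected
mass concentration (entropy ≈ 4.5 nats below uniform). The related claim that
cost is large where the orbit crosses steep value gradients holds strongly
across occupied grid cells (rank correlation ≈ 0.8) but *not* point-by-point
along an orbit (≈ 0.05–0.35): on the attractor ridge the value-gradient
magnitude has little dynamic range and the angle between flow and gradient
dominates `c = f·∇V`. The corresponding acceptance test asserts the
along-orbit form and is expected to fail; it is kept as an honest record of
that operationalization.

Known limitations: no parameter learning (the generative model's parameters
are fixed); conditional covariances are not propagated; diffusion tensors
must be diagonal in the grid discretization; the value-learning scheme is
plain TD(0) without eligibility traces and converges slowly on fine rings.
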