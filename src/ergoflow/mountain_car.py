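"""The mountain-car environment and its divergence-based generative policy.

A unit-mass car lives in a potential landscape φ(x) with a valley at
x = -0.5 and a parking target on the hill at x = +1.  Thrust is squashed,
|σ(a)| <= 1, while the uphill force at x = 0 is exactly 1, so the target can
only be reached by first backing away to gather momentum.

The agent's generative model replaces the true friction (1/8) with a
state-dependent coefficient equal to the cost function:

    f(x, x') = [x', c(x, z) x' - dφ/dx]   =>   ∇·f = c(x, z).

Divergence is cost: where cost is positive the model expects anti-friction
(the car "expects to go faster"), destroying any stable fixed point there;
where cost is negative flow contracts, so only low-cost regions can hold the
mass of the ergodic density.  A satiety state z switches the cost landscape
between goal-seeking (z near 0) and uniformly content (z large), which turns
the target into an unstable ("weak") attractor that is visited, consumed and
left again — itinerant behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandscapeSpec",
    "MountainCarState",
    "CostParams",
    "EnvConfig",
    "potential_and_gradient",
    "cost_function",
    "squash",
    "true_flow",
    "generative_flow",
    "satiety_dynamics",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Analytic potential: φ = x² + x for x < 0, φ = x (1 + 5x²)^(-1/2) for x >= 0.

    C¹ at the branch point with φ'(0) = 1 (unit force at the origin) and a
    unique minimum at x = -0.5.
    """

    minimum: float = -0.5
    force_at_origin: float = 1.0


@dataclass
class MountainCarState:
    position: float
    velocity: float
    satiety: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.position, self.velocity, self.satiety])):
            raise ValueError("state entries must be finite")

    def as_array(self, with_satiety: bool = False) -> np.ndarray:
        if with_satiety:
            return np.array([self.position, self.velocity, self.satiety])
        return np.array([self.position, self.velocity])


@dataclass(frozen=True)
class CostParams:
    """Parameters of c(x, z) = (A e^{-w (x-x*)²} - 1)(tanh(g (z-1)) - 1) + offset."""

    bump_amplitude: float = 16.0
    bump_width: float = 64.0
    target: float = 1.0
    tanh_gain: float = 8.0
    offset: float = -1.0
    satiety_enabled: bool = True


@dataclass(frozen=True)
class EnvConfig:
    """True-environment parameters (friction is constant, one eighth)."""

    friction: float = 1.0 / 8.0
    process_noise_sd: float = 1.0 / 256.0
    sensor_noise_sd: float = 1.0 / 256.0
    dt: float = 1.0 / 64.0
    seed: int = 0
    satiety_gain: float = 0.5     # alpha: satiety uptake per unit negative cost
    satiety_tau: float = 90.0     # first-order decay time constant (s)
    satiety_rest: float = 1.0     # reward baseline that does not feed satiety

    def __post_init__(self) -> None:
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def potential_and_gradient(x):
    """Evaluate the landscape φ and its gradient ∂xφ (vectorized)."""
    x = np.asarray(x, dtype=float)
    neg = x < 0
    phi = np.where(neg, x * x + x, x / np.sqrt(1.0 + 5.0 * x * x))
    dphi = np.where(neg, 2.0 * x + 1.0, (1.0 + 5.0 * x * x) ** -1.5)
    if phi.ndim == 0:
        return float(phi), float(dphi)
    return phi, dphi


def cost_function(x, z, params: CostParams = CostParams()):
    """Cost over position and satiety, exactly as parameterized.

    c(x, z) = (16 e^{-64 (x-1)²} - 1)(tanh(8(z-1)) - 1) - 1 by default.
    With satiety high, c -> -1 uniformly; with z = 0 cost is positive
    everywhere except a deep well at the target:
    c(x, 0) = 1 - 32 e^{-64 (x-1)²}.
    """
    x = np.asarray(x, dtype=float)
    bump = params.bump_amplitude * np.exp(-params.bump_width * (x - params.target) ** 2)
    if params.satiety_enabled:
        gate = np.tanh(params.tanh_gain * (np.asarray(z, float) - 1.0)) - 1.0
    else:
        gate = np.tanh(-params.tanh_gain) - 1.0  # frozen at z = 0
    c = (bump - 1.0) * gate + params.offset
    return float(c) if c.ndim == 0 else c


def squash(a):
    """Bounded thrust σ(a) = tanh(a) ∈ (-1, 1)."""
    return np.tanh(a)


def true_flow(state: MountainCarState, a: float, config: EnvConfig) -> np.ndarray:
    """Deterministic part of the real equations of motion.

    ẋ = x', ẋ' = σ(a) - ∂xφ(x) - friction * x'.
    """
    _, dphi = potential_and_gradient(state.position)
    return np.array([
        state.velocity,
        float(squash(a)) - dphi - config.friction * state.velocity,
    ])


def generative_flow(state: MountainCarState, params: CostParams = CostParams()
                    ) -> np.ndarray:
    """The agent's expected flow: [x', c(x, z) x' - ∂xφ]; its divergence is c."""
    _, dphi = potential_and_gradient(state.position)
    c = cost_function(state.position, state.satiety, params)
    return np.array([state.velocity, c * state.velocity - dphi])


def satiety_dynamics(state: MountainCarState, params: CostParams,
                     config: EnvConfig) -> float:
    """Satiety rises with reward (negative cost) and decays first-order.

    ż = α max(-c - c_rest, 0) - z/τ.  Only reward beyond the sated baseline
    c_rest (the uniform level |c(x, ∞)| = 1) feeds satiety; without the
    baseline the mildly negative sated landscape would sustain satiety
    indefinitely (equilibrium z = ατ) and the goal would never re-arm.
    """
    if state.satiety < 0:
        raise ValueError("satiety must be non-negative")
    c = cost_function(state.position, state.satiety, params)
    uptake = config.satiety_gain * max(-c - config.satiety_rest, 0.0)
    return uptake - state.satiety / config.satiety_tau
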