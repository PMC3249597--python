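"""Generalized coordinates of motion.

A generalized state x̃ = [x, x', x'', ...] carries a variable together with its
temporal derivatives up to some embedding order n.  Smooth (analytic) random
fluctuations induce correlations between derivative orders; representing states
in generalized coordinates lets a filtering scheme exploit that smoothness.

This module provides the block shift (derivative) operator 𝒟, a Taylor-series
signal embedding, and generalized precisions derived from a Gaussian
autocorrelation function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from math import factorial

__all__ = [
    "GeneralizedVector",
    "DerivativeOperator",
    "SmoothNoiseSpec",
    "build_shift_operator",
    "embed_signal",
    "generalized_precision",
    "generalized_covariance",
]


@dataclass(frozen=True)
class GeneralizedVector:
    """A state and its temporal derivatives.

    ``values`` has shape ``(state_dimension, order)``; column k holds the k-th
    temporal derivative (units of base-unit * time**-k).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("GeneralizedVector values must be 2-D (dim x order)")
        if values.shape[1] < 1:
            raise ValueError("embedding order must be >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("GeneralizedVector entries must be finite")
        object.__setattr__(self, "values", values)

    @property
    def state_dimension(self) -> int:
        return self.values.shape[0]

    @property
    def order(self) -> int:
        return self.values.shape[1]

    def flat(self) -> np.ndarray:
        """Flatten order-major: [x_0 (all dims), x_1 (all dims), ...]."""
        return self.values.T.reshape(-1)

    @classmethod
    def from_flat(cls, flat: np.ndarray, state_dimension: int) -> "GeneralizedVector":
        flat = np.asarray(flat, dtype=float)
        order = flat.size // state_dimension
        return cls(flat.reshape(order, state_dimension).T)


@dataclass(frozen=True)
class DerivativeOperator:
    """Block shift operator 𝒟 with identity blocks on the first superdiagonal.

    Acting on the order-major flattening of a GeneralizedVector it shifts
    derivative orders down by one: (𝒟x̃)_k = x̃_{k+1}, and the last order maps
    to zero.  𝒟 is nilpotent: 𝒟**order == 0.
    """

    order: int
    state_dimension: int
    matrix: np.ndarray

    def apply(self, x: GeneralizedVector) -> GeneralizedVector:
        if x.order != self.order or x.state_dimension != self.state_dimension:
            raise ValueError("operator/vector shape mismatch")
        shifted = np.zeros_like(x.values)
        shifted[:, :-1] = x.values[:, 1:]
        return GeneralizedVector(shifted)


def build_shift_operator(order: int, state_dimension: int) -> DerivativeOperator:
    """Construct the derivative matrix operator 𝒟 of a given embedding order."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if state_dimension < 1:
        raise ValueError("state_dimension must be >= 1")
    n, d = order, state_dimension
    mat = np.kron(np.diag(np.ones(n - 1), k=1), np.eye(d))
    return DerivativeOperator(order=n, state_dimension=d, matrix=mat)


def embed_signal(samples: np.ndarray, order: int, dt: float) -> np.ndarray:
    """Embed a uniformly sampled signal in generalized coordinates.

    Local derivative estimates come from an inverse Taylor (polynomial
    interpolation) matrix over a window of ``order`` samples, centred where
    possible and one-sided at the boundaries.  The embedding is exact for
    polynomials of degree < order.

    Parameters
    ----------
    samples : array, shape (T,) or (T, d)
    order : number of derivative orders to estimate (>= 1)
    dt : positive uniform sampling interval

    Returns
    -------
    array of shape (T, d, order); entry [t, :, k] estimates the k-th derivative.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    T, d = samples.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < order:
        raise ValueError(f"need at least {order} samples for order-{order} embedding")

    out = np.empty((T, d, order))
    half = (order - 1) // 2
    # Precompute inverse Taylor matrices for each window offset pattern.
    cache: dict[int, np.ndarray] = {}
    for t in range(T):
        start = min(max(t - half, 0), T - order)
        offset = t - start  # index of t inside the window
        if offset not in cache:
            # window sample j equals sum_k ((j-offset)*dt)^k / k! * x^(k)
            taylor = np.empty((order, order))
            for j in range(order):
                for k in range(order):
                    taylor[j, k] = ((j - offset) * dt) ** k / factorial(k)
            cache[offset] = np.linalg.inv(taylor)
        inv = cache[offset]
        window = samples[start : start + order]  # (order, d)
        out[t] = (inv @ window).T
    return out


@dataclass(frozen=True)
class SmoothNoiseSpec:
    """Smooth fluctuations with Gaussian autocorrelation.

    ``variance`` is the marginal variance of the order-0 process per channel;
    ``roughness`` is the autocorrelation width (time units).  A wider
    autocorrelation means a smoother process, hence smaller derivative
    variances and larger derivative precisions.
    """

    variance: float
    roughness: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.roughness <= 0:
            raise ValueError("roughness must be positive")


def generalized_covariance(spec: SmoothNoiseSpec, order: int) -> np.ndarray:
    """Covariance among derivative orders of a stationary Gaussian-correlated process.

    For autocovariance gamma(h) = variance * exp(-h^2 / (2 r^2)), the covariance
    between the i-th and j-th derivatives at lag zero is
    (-1)^j * gamma^(i+j)(0); odd totals vanish and even totals follow
    gamma^(2m)(0) = variance * (-1)^m (2m-1)!! / r^(2m).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    r2 = spec.roughness**2
    cov = np.zeros((order, order))
    for i in range(order):
        for j in range(order):
            total = i + j
            if total % 2:
                continue
            m = total // 2
            dfac = 1.0
            for q in range(1, 2 * m, 2):  # (2m-1)!!
                dfac *= q
            gamma_2m = spec.variance * ((-1.0) ** m) * dfac / r2**m
            cov[i, j] = ((-1.0) ** j) * gamma_2m
    return cov


def generalized_precision(spec: SmoothNoiseSpec, order: int) -> np.ndarray:
    """Precision (inverse covariance) among derivative orders for smooth noise.

    Symmetric positive-definite; for order 1 it is the scalar 1/variance.
    """
    cov = generalized_covariance(spec, order)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"generalized covariance not positive-definite for order={order}, "
            f"variance={spec.variance}, roughness={spec.roughness}"
        ) from exc
    inv_chol = np.linalg.inv(chol)
    prec = inv_chol.T @ inv_chol
    return 0.5 * (prec + prec.T)
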