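"""Grid discretization of the Fokker-Planck operator and derived quantities.

For a stochastic flow dx = f(x) dt + noise with diffusion tensor Γ (half the
noise covariance), the ensemble density obeys

    dp/dt = Λ p = ∇·(Γ∇p) − ∇·(f p).

The ergodic density is the principal eigensolution Λp = 0.  From it follow
value V = ln p, cost c = f·∇V + ∇·Γ∇V (the expected rate of increase of
value), differential entropy, and entropy production.  The module also houses
standard-form (Helmholtz) flows f = (Γ+Q)∇V with antisymmetric Q, a greedy
Hamilton-Jacobi-Bellman comparator, and a temporal-difference value-learning
scheme — the optimal-control counterparts of divergence-based policies.

Discretization: finite-volume with exponentially fitted (Scharfetter-Gummel)
face fluxes.  These blend central differencing (diffusion-dominated faces) and
upwinding (advection-dominated faces) while keeping the generator property:
off-diagonal entries are non-negative and columns sum to zero under reflecting
boundaries.  Only diagonal diffusion tensors are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridSpec",
    "ScalarField",
    "VectorField",
    "DiscreteFPOperator",
    "StandardFormSpec",
    "ValueLearningState",
    "discretize_fp_operator",
    "stationary_density",
    "sojourn_density",
    "value_from_density",
    "cost_from_value",
    "entropy_of_density",
    "entropy_production_rate",
    "standard_form_flow",
    "lyapunov_rate",
    "dissipation_rate",
    "divergence_field",
    "hjb_greedy_control",
    "value_learning_step",
    "learn_value_on_ring",
    "ring_value_oracle",
    "gradient_field",
    "sample_scalar_field",
    "integrate_deterministic_flow",
]


# --------------------------------------------------------------------------
# grids and fields
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Rectangular cell-centred grid.

    ``lower``/``upper`` give per-dimension bounds, ``bins`` the cell counts
    (>= 3 per dimension).  ``boundary_mode`` is ``reflecting`` (zero flux, mass
    conserving) or ``absorbing`` (zero-density ghost cells; stationary
    densities are renormalized).
    """

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    bins: tuple[int, ...]
    boundary_mode: str = "reflecting"

    def __post_init__(self) -> None:
        lower = tuple(float(v) for v in np.atleast_1d(self.lower))
        upper = tuple(float(v) for v in np.atleast_1d(self.upper))
        bins = tuple(int(v) for v in np.atleast_1d(self.bins))
        if not (len(lower) == len(upper) == len(bins)):
            raise ValueError("lower/upper/bins must have equal length")
        for lo, hi, nb in zip(lower, upper, bins):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lower < upper")
            if nb < 3:
                raise ValueError("need at least 3 bins per dimension")
        if self.boundary_mode not in ("reflecting", "absorbing"):
            raise ValueError("boundary_mode must be 'reflecting' or 'absorbing'")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "bins", bins)

    @property
    def ndim(self) -> int:
        return len(self.bins)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.bins

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.bins))

    @property
    def spacing(self) -> np.ndarray:
        return np.array(
            [(hi - lo) / nb for lo, hi, nb in zip(self.lower, self.upper, self.bins)]
        )

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def centers(self, axis: int) -> np.ndarray:
        h = self.spacing[axis]
        return self.lower[axis] + h * (np.arange(self.bins[axis]) + 0.5)

    def meshgrid(self) -> list[np.ndarray]:
        return list(
            np.meshgrid(*[self.centers(a) for a in range(self.ndim)], indexing="ij")
        )

    def evaluate(self, fn: Callable[..., np.ndarray]) -> np.ndarray:
        """Evaluate fn(x0, x1, ...) on cell centres; returns array of grid shape."""
        return np.asarray(fn(*self.meshgrid()), dtype=float)


@dataclass
class ScalarField:
    """A scalar quantity sampled on grid cells (density, value, cost, ...)."""

    grid: GridSpec
    values: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            values = values.reshape(self.grid.shape)
        self.values = values

    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)


@dataclass
class VectorField:
    """A drift vector sampled on grid cells: values shape = grid.shape + (ndim,)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        expected = self.grid.shape + (self.grid.ndim,)
        if values.shape != expected:
            values = values.reshape(expected)
        if not np.all(np.isfinite(values)):
            raise ValueError("VectorField entries must be finite")
        self.values = values

    @classmethod
    def from_function(cls, grid: GridSpec, fn: Callable[..., Sequence]) -> "VectorField":
        comps = fn(*grid.meshgrid())
        values = np.stack([np.broadcast_to(np.asarray(c, float), grid.shape)
                           for c in comps], axis=-1)
        return cls(grid, values)


def _axis_diffusion(grid: GridSpec, gamma) -> np.ndarray:
    """Normalize a diffusion specification to per-axis fields, shape (ndim,) + grid.shape.

    Accepts a scalar, a length-ndim vector, a diagonal (ndim, ndim) matrix, or an
    array of per-cell per-axis values with shape grid.shape + (ndim,).
    """
    d = grid.ndim
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim == 0:
        out = np.broadcast_to(gamma, (d,) + grid.shape)
    elif gamma.shape == (d,):
        out = np.broadcast_to(gamma.reshape((d,) + (1,) * d), (d,) + grid.shape)
    elif gamma.shape == (d, d):
        off = gamma - np.diag(np.diag(gamma))
        if np.any(off != 0):
            raise ValueError("only diagonal diffusion tensors are supported")
        if np.any(np.diag(gamma) < 0):
            raise ValueError("diffusion tensor must be positive semi-definite")
        out = np.broadcast_to(np.diag(gamma).reshape((d,) + (1,) * d), (d,) + grid.shape)
    elif gamma.shape == grid.shape + (d,):
        out = np.moveaxis(gamma, -1, 0)
    else:
        raise ValueError(f"unrecognized diffusion specification of shape {gamma.shape}")
    if np.any(out < 0):
        raise ValueError("diffusion entries must be non-negative")
    return np.ascontiguousarray(out)


@dataclass
class DiscreteFPOperator:
    """Sparse generator Λ(f, Γ) over grid cells (CSC matrix)."""

    matrix: sp.spmatrix
    grid: GridSpec
    diffusion: np.ndarray  # per-axis per-cell, shape (ndim,) + grid.shape

    @property
    def n_cells(self) -> int:
        return self.grid.n_cells


def _bernoulli(z: np.ndarray) -> np.ndarray:
    """B(z) = z / (exp(z) - 1), the exponential-fitting weight; B(0) = 1."""
    z = np.clip(z, -700.0, 700.0)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-10
    out[small] = 1.0 - 0.5 * z[small]
    zb = z[~small]
    # stable for both signs: for large positive z, z/(e^z-1) underflows to 0
    out[~small] = np.where(
        zb > 0, zb * np.exp(-zb) / (1.0 - np.exp(-zb)), zb / np.expm1(zb)
    )
    return out


def discretize_fp_operator(flow: VectorField, gamma, grid: GridSpec | None = None
                           ) -> DiscreteFPOperator:
    """Assemble the sparse Fokker-Planck generator for a drift and diffusion.

    Face fluxes are exponentially fitted: with face velocity u, face diffusion
    D and spacing h, the flux between cells i and i+1 is
    (D/h) * [B(-uh/D) p_i - B(uh/D) p_{i+1}], which reduces to upwinding when
    D -> 0 and to central diffusion when u -> 0.  Off-diagonals are
    non-negative; with reflecting boundaries columns sum to zero.
    """
    if grid is None:
        grid = flow.grid
    if grid is not flow.grid and grid != flow.grid:
        raise ValueError("flow and grid specifications disagree")
    diff = _axis_diffusion(grid, gamma)
    shape = grid.shape
    N = grid.n_cells
    idx = np.arange(N).reshape(shape)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def _take(arr: np.ndarray, axis: int, sl: slice) -> np.ndarray:
        slicer = [slice(None)] * arr.ndim
        slicer[axis] = sl
        return arr[tuple(slicer)]

    for a in range(grid.ndim):
        h = grid.spacing[a]
        f_a = flow.values[..., a]
        d_a = diff[a]
        # interior faces between cells (.., i, ..) and (.., i+1, ..)
        left = _take(idx, a, slice(0, -1)).ravel()
        right = _take(idx, a, slice(1, None)).ravel()
        u = 0.5 * (_take(f_a, a, slice(0, -1)) + _take(f_a, a, slice(1, None))).ravel()
        D = 0.5 * (_take(d_a, a, slice(0, -1)) + _take(d_a, a, slice(1, None))).ravel()
        # coefficients: flux J = c_from_left * p_left - c_from_right * p_right
        c_left = np.empty_like(u)
        c_right = np.empty_like(u)
        diffusive = D > 0
        pe = np.zeros_like(u)
        pe[diffusive] = u[diffusive] * h / D[diffusive]
        c_left[diffusive] = (D[diffusive] / h) * _bernoulli(-pe[diffusive])
        c_right[diffusive] = (D[diffusive] / h) * _bernoulli(pe[diffusive])
        c_left[~diffusive] = np.maximum(u[~diffusive], 0.0)
        c_right[~diffusive] = np.maximum(-u[~diffusive], 0.0)
        # dp_left/dt -= J/h ; dp_right/dt += J/h
        rows += [left, left, right, right]
        cols += [left, right, left, right]
        vals += [-c_left / h, c_right / h, c_left / h, -c_right / h]
        if grid.boundary_mode == "absorbing":
            # zero-density ghost cells: outflux through the two boundary faces
            for edge_sl, sign in ((slice(0, 1), -1.0), (slice(-1, None), 1.0)):
                cells = _take(idx, a, edge_sl).ravel()
                ub = sign * _take(f_a, a, edge_sl).ravel()  # outward velocity
                Db = _take(d_a, a, edge_sl).ravel()
                c_out = np.empty_like(ub)
                dif = Db > 0
                peb = np.zeros_like(ub)
                peb[dif] = ub[dif] * h / Db[dif]
                c_out[dif] = (Db[dif] / h) * _bernoulli(-peb[dif])
                c_out[~dif] = np.maximum(ub[~dif], 0.0)
                rows.append(cells)
                cols.append(cells)
                vals.append(-c_out / h)

    mat = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    if np.max(np.abs(flow.values)) * grid.spacing.min() > 0 and diff.max() == 0:
        pass  # pure advection: upwind only, first order
    return DiscreteFPOperator(matrix=mat, grid=grid, diffusion=diff)


# --------------------------------------------------------------------------
# ergodic density and derived fields
# --------------------------------------------------------------------------


def stationary_density(op: DiscreteFPOperator, tol: float = 1e-12,
                       max_iter: int = 500) -> ScalarField:
    """Principal eigensolution of the generator (eigenvalue zero).

    Solved by shifted inverse iteration: factor (Λ - σI) once with a tiny
    shift σ and iterate solves from a uniform start.  ``tol`` bounds the
    relative residual ||Λp||_inf / (||Λ||_max ||p||_inf).
    """
    A = op.matrix.tocsc()
    N = A.shape[0]
    scale = float(np.abs(A.diagonal()).max())
    if scale == 0:
        raise RuntimeError("degenerate generator (zero matrix)")
    sigma = 1e-8 * scale
    lu = spla.splu((A - sigma * sp.identity(N, format="csc")).tocsc())
    v = np.full(N, 1.0 / N)
    res = np.inf
    for _ in range(max_iter):
        v = lu.solve(v)
        norm = np.linalg.norm(v, 1)
        if norm == 0 or not np.isfinite(norm):
            raise RuntimeError("inverse iteration broke down")
        v /= norm
        # orient positive
        if v.sum() < 0:
            v = -v
        res = np.abs(A @ v).max() / (scale * np.abs(v).max())
        if res < tol:
            break
    else:
        raise RuntimeError(
            f"eigensolver did not converge: relative residual {res:.3e} > {tol:.1e}"
        )
    neg = v < 0
    if np.any(v < -1e-8 * v.max()):
        raise RuntimeError(
            f"stationary density has significant negative entries (min {v.min():.3e})"
        )
    if np.any(neg):
        v = np.where(neg, 0.0, v)
    v /= v.sum() * op.grid.cell_volume
    out = ScalarField(op.grid, v.reshape(op.grid.shape), role="density")
    out.residual = res  # type: ignore[attr-defined]  # relative to ||Λ||_max
    out.residual_raw = float(np.abs(A @ v).max() / np.abs(v).max())  # type: ignore[attr-defined]
    return out


def value_from_density(p: ScalarField, floor_ratio: float = 1e-12) -> ScalarField:
    """Value (negative surprise) V = ln p, floored, normalized so ∫exp(V) = 1."""
    values = p.values
    floor = floor_ratio * values.max()
    V = np.log(np.maximum(values, floor))
    V -= np.log(np.sum(np.exp(V)) * p.grid.cell_volume)
    return ScalarField(p.grid, V, role="value")


def gradient_field(f: ScalarField) -> VectorField:
    """Central-difference gradient (one-sided at boundaries)."""
    grads = np.gradient(f.values, *[f.grid.centers(a) for a in range(f.grid.ndim)])
    if f.grid.ndim == 1:
        grads = [grads]
    return VectorField(f.grid, np.stack(grads, axis=-1))


def cost_from_value(V: ScalarField, flow: VectorField, gamma) -> ScalarField:
    """Cost c = f·∇V + ∇·Γ∇V — the expected rate of increase of value."""
    if V.grid != flow.grid:
        raise ValueError("value and flow live on different grids")
    grid = V.grid
    gradV = gradient_field(V).values
    c = np.einsum("...i,...i->...", flow.values, gradV)
    diff = _axis_diffusion(grid, gamma)
    for a in range(grid.ndim):
        flux_a = diff[a] * gradV[..., a]
        c += np.gradient(flux_a, grid.centers(a), axis=a)
    return ScalarField(grid, c, role="cost")


def entropy_of_density(p: ScalarField) -> float:
    """Differential entropy −∫ p ln p dx via a cell-volume-weighted sum."""
    vals = p.flat()
    mask = vals > 0
    return float(-np.sum(vals[mask] * np.log(vals[mask])) * p.grid.cell_volume)


def entropy_production_rate(p: ScalarField, gamma, support_floor: float = 1e-12
                            ) -> float:
    """Entropy production ∫ (∇p·Γ·∇p)/p dx ≥ 0 under pure diffusion."""
    grid = p.grid
    gradp = gradient_field(p).values
    diff = np.moveaxis(_axis_diffusion(grid, gamma), 0, -1)
    num = np.einsum("...i,...i->...", gradp * diff, gradp)
    mask = p.values > support_floor * p.values.max()
    rate = np.sum(num[mask] / p.values[mask]) * grid.cell_volume
    return float(max(rate, 0.0))


def divergence_field(flow: VectorField) -> ScalarField:
    """Central-difference divergence ∇·f."""
    grid = flow.grid
    div = np.zeros(grid.shape)
    for a in range(grid.ndim):
        div += np.gradient(flow.values[..., a], grid.centers(a), axis=a)
    return ScalarField(grid, div, role="divergence")


def sojourn_density(drift: Callable[[np.ndarray], np.ndarray], grid: GridSpec,
                    gamma: float, duration: float = 300.0, dt: float = 1.0 / 128.0,
                    n_walkers: int = 64, burn_in: float = 15.0, seed: int = 0,
                    smoothing: float = 0.0) -> ScalarField:
    """Ergodic density estimated as sojourn time of the stochastic flow.

    The ergodic density at a point is the long-run fraction of time the system
    spends there, so it can be estimated directly by binning a long solution
    of dx = f(x) dt + √(2Γ) dW onto the grid.  This is the estimator of choice
    for strongly advective flows on coarse grids, where the grid generator's
    exponential-fitting limit (upwinding) adds numerical diffusion ~ h|f|/2
    that can dwarf a small physical Γ and smear the eigensolution.

    ``drift`` maps (n, ndim) -> (n, ndim) (vectorized over walkers); the
    deterministic part advances by classical RK4 with an additive Brownian
    increment.  Walkers are clipped to the box (reflecting in distribution).
    ``smoothing`` optionally applies a Gaussian kernel of that many cell
    widths before normalization.
    """
    rng = np.random.default_rng(seed)
    lo = np.array(grid.lower)
    hi = np.array(grid.upper)
    h = grid.spacing
    x = lo + (hi - lo) * rng.random((n_walkers, grid.ndim))
    sd = np.sqrt(2.0 * gamma * dt)
    counts = np.zeros(grid.shape)
    n_steps = int(round(duration / dt))
    burn_steps = int(round(burn_in / dt))
    for step in range(n_steps):
        k1 = drift(x)
        k2 = drift(x + 0.5 * dt * k1)
        k3 = drift(x + 0.5 * dt * k2)
        k4 = drift(x + dt * k3)
        x = x + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0 \
            + rng.normal(0.0, sd, x.shape)
        np.clip(x, lo + 1e-9 * h, hi - 1e-9 * h, out=x)
        if step >= burn_steps:
            idx = ((x - lo) / h).astype(int)
            np.add.at(counts, tuple(idx.T), 1)
    if smoothing > 0:
        from scipy.ndimage import gaussian_filter
        counts = gaussian_filter(counts, smoothing)
    total = counts.sum()
    if total == 0:
        raise RuntimeError("no samples accumulated; increase duration")
    return ScalarField(grid, counts / (total * grid.cell_volume), role="density")


# --------------------------------------------------------------------------
# standard-form (Helmholtz) flows
# --------------------------------------------------------------------------


@dataclass
class StandardFormSpec:
    """Flow in standard form f = (Γ + Q)∇V with antisymmetric Q.

    ``value`` is a ScalarField or a callable V(*coords); ``grad_value`` an
    optional analytic gradient returning one array per dimension.  ``Q`` is a
    constant antisymmetric matrix or a callable returning one per point.
    """

    value: ScalarField | Callable
    Q: np.ndarray
    gamma: object
    grad_value: Callable | None = None

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if not np.allclose(Q + Q.T, 0.0, atol=1e-12):
            raise ValueError("Q must be antisymmetric (Q + Q^T = 0)")
        self.Q = Q


def _grad_on_grid(spec: StandardFormSpec, grid: GridSpec) -> np.ndarray:
    if spec.grad_value is not None:
        comps = spec.grad_value(*grid.meshgrid())
        return np.stack(
            [np.broadcast_to(np.asarray(c, float), grid.shape) for c in comps], axis=-1
        )
    if callable(spec.value):
        V = ScalarField(grid, grid.evaluate(spec.value), role="value")
    else:
        V = spec.value
    return gradient_field(V).values


def standard_form_flow(spec: StandardFormSpec, grid: GridSpec) -> VectorField:
    """Construct f = (Γ + Q)∇V on a grid.

    The Γ∇V part is dissipative (ascends value); the Q∇V part is conservative
    and pointwise orthogonal to ∇V, so exp(V)/Z is the stationary density.
    """
    gradV = _grad_on_grid(spec, grid)
    gamma = np.asarray(spec.gamma, dtype=float)
    if gamma.ndim == 0:
        gamma = gamma * np.eye(grid.ndim)
    elif gamma.ndim == 1:
        gamma = np.diag(gamma)
    A = gamma + spec.Q
    return VectorField(grid, np.einsum("ij,...j->...i", A, gradV))


def lyapunov_rate(V: ScalarField | Callable, flow: VectorField,
                  grad_value: Callable | None = None) -> ScalarField:
    """Rate of change of value along the flow: ∇V·f per cell.

    For a standard-form flow this equals ∇V·Γ·∇V ≥ 0 — value is a Lyapunov
    function of its own policy.
    """
    grid = flow.grid
    spec_like = StandardFormSpec(value=V, Q=np.zeros((grid.ndim, grid.ndim)),
                                 gamma=0.0, grad_value=grad_value)
    gradV = _grad_on_grid(spec_like, grid)
    return ScalarField(grid, np.einsum("...i,...i->...", gradV, flow.values),
                       role="lyapunov_rate")


def dissipation_rate(V: ScalarField | Callable, gamma, grid: GridSpec,
                     grad_value: Callable | None = None) -> ScalarField:
    """∇V·Γ·∇V per cell (the dissipative part of the Lyapunov rate)."""
    spec_like = StandardFormSpec(value=V, Q=np.zeros((grid.ndim, grid.ndim)),
                                 gamma=0.0, grad_value=grad_value)
    gradV = _grad_on_grid(spec_like, grid)
    diff = np.moveaxis(_axis_diffusion(grid, gamma), 0, -1)
    return ScalarField(grid, np.einsum("...i,...i->...", gradV * diff, gradV),
                       role="dissipation_rate")


# --------------------------------------------------------------------------
# optimal-control comparators
# --------------------------------------------------------------------------


def hjb_greedy_control(flow_family: Callable[[float], VectorField] | Mapping,
                       V: ScalarField, control_set: Iterable[float],
                       cost: ScalarField | None = None
                       ) -> tuple[ScalarField, ScalarField]:
    """Greedy Hamilton-Jacobi-Bellman control: per-cell argmax_u f(x,u)·∇V.

    Returns the control field and the residual f(x,π)·∇V − c (zero wherever V
    solves the HJB equation).  Ties are broken toward the smallest |u|.
    """
    controls = sorted(set(float(u) for u in control_set), key=lambda u: (abs(u), u))
    if not controls:
        raise ValueError("control set must be non-empty")
    grid = V.grid
    gradV = gradient_field(V).values
    best_rate = np.full(grid.shape, -np.inf)
    best_u = np.zeros(grid.shape)
    for u in controls:
        fu = flow_family[u] if isinstance(flow_family, Mapping) else flow_family(u)
        rate = np.einsum("...i,...i->...", fu.values, gradV)
        better = rate > best_rate + 1e-12  # ties keep the earlier (smaller |u|)
        best_u = np.where(better, u, best_u)
        best_rate = np.where(better, rate, best_rate)
    residual = best_rate - (cost.values if cost is not None else 0.0)
    return (ScalarField(grid, best_u, role="control"),
            ScalarField(grid, residual, role="hjb_residual"))


@dataclass
class ValueLearningState:
    """State of temporal-difference value learning on a 1-D ring of cells."""

    values: np.ndarray
    lower: float
    upper: float
    learning_rate: float = 0.2
    last_delta: float = 0.0
    _prev_cell: int | None = field(default=None, repr=False)
    _prev_cost: float = field(default=0.0, repr=False)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def cell_of(self, x: float) -> int:
        span = self.upper - self.lower
        u = (x - self.lower) % span
        return int(u / span * self.n_bins) % self.n_bins


def value_learning_step(state: ValueLearningState, x: float, xdot: float,
                        cost_fn: Callable[[float], float], dt: float
                        ) -> ValueLearningState:
    """One value-learning update from a trajectory sample.

    The reward-prediction error δ = V̇ − c is formed from consecutive visits,
    V̇ ≈ (V(x_t) − V(x_prev))/dt, and credited to the previously visited cell:
    V(x_prev) += η δ dt.  At convergence δ → 0, so c = V̇ along visited states.
    ``xdot`` is carried in the sample for bookkeeping and boundary checks only.
    """
    if not np.isfinite(x):
        raise ValueError("sample outside grid")
    cell = state.cell_of(x)
    if state._prev_cell is not None and cell != state._prev_cell:
        delta = (state.values[cell] - state.values[state._prev_cell]) / dt \
            - state._prev_cost
        state.values[state._prev_cell] += state.learning_rate * dt * delta
        state.last_delta = float(delta)
    state._prev_cell = cell
    state._prev_cost = float(cost_fn(x))
    return state


def learn_value_on_ring(speed: float, cost_fn: Callable[[float], float],
                        n_bins: int = 32, circumference: float = 2 * np.pi,
                        learning_rate: float = 0.5, n_laps: int = 3000
                        ) -> tuple[ValueLearningState, float]:
    """Drive value learning along a constant-speed deterministic ring orbit.

    The orbit is sampled once per cell (at cell centres).  Returns the
    learning state and the mean |δ| over the final lap.  The cost must have
    (near) zero circulation for the scheme to converge, since the fixed point
    requires the value increments to telescope around the ring.
    """
    state = ValueLearningState(values=np.zeros(n_bins), lower=0.0,
                               upper=circumference, learning_rate=learning_rate)
    h = circumference / n_bins
    dt = h / abs(speed)
    x = 0.5 * h  # start at a cell centre
    deltas: list[float] = []
    for lap in range(n_laps):
        record = lap == n_laps - 1
        for _ in range(n_bins):
            value_learning_step(state, x, speed, cost_fn, dt)
            if record:
                deltas.append(abs(state.last_delta))
            x = (x + speed * dt) % circumference
    return state, float(np.mean(deltas))


def ring_value_oracle(speed: float, cost_fn: Callable[[float], float],
                      n_bins: int, circumference: float = 2 * np.pi) -> np.ndarray:
    """Direct path-integral solution of V̇ = c on the ring, mean-centred.

    Along the orbit dV/dx = c(x)/speed, so V at the i-th cell centre is the
    running path integral Σ_{j<i} c(x_j) h / speed up to an additive constant
    (well defined when the circulation of c vanishes).
    """
    h = circumference / n_bins
    centres = (np.arange(n_bins) + 0.5) * h
    c = np.array([cost_fn(x) for x in centres])
    V = np.concatenate([[0.0], np.cumsum(c[:-1])]) * h / speed
    return V - V.mean()


# --------------------------------------------------------------------------
# helpers shared by demos and tests
# --------------------------------------------------------------------------


def sample_scalar_field(f: ScalarField, points: np.ndarray) -> np.ndarray:
    """Linear interpolation of a grid field at arbitrary points (N, ndim)."""
    interp = RegularGridInterpolator(
        [f.grid.centers(a) for a in range(f.grid.ndim)], f.values,
        bounds_error=False, fill_value=None)
    return interp(np.atleast_2d(points))


def integrate_deterministic_flow(drift: Callable[[np.ndarray], np.ndarray],
                                 x0: np.ndarray, duration: float, dt: float
                                 ) -> np.ndarray:
    """Integrate dx/dt = drift(x) and return states at multiples of dt."""
    ts = np.arange(0.0, duration + 0.5 * dt, dt)
    sol = solve_ivp(lambda t, x: drift(np.asarray(x)), (0.0, ts[-1]), np.asarray(x0, float),
                    t_eval=ts, rtol=1e-8, atol=1e-10, method="RK45", max_step=dt)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    return sol.y.T
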