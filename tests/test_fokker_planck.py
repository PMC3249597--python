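"""Fokker-Planck discretization, ergodic densities and control comparators."""

import numpy as np
import pytest
from scipy import stats

from ergoflow.fokker_planck import (
    GridSpec,
    ScalarField,
    StandardFormSpec,
    VectorField,
    cost_from_value,
    discretize_fp_operator,
    dissipation_rate,
    divergence_field,
    entropy_of_density,
    entropy_production_rate,
    gradient_field,
    hjb_greedy_control,
    integrate_deterministic_flow,
    learn_value_on_ring,
    lyapunov_rate,
    ring_value_oracle,
    sample_scalar_field,
    stationary_density,
    value_from_density,
    value_learning_step,
    ValueLearningState,
)


@pytest.fixture(scope="module")
def ou_density():
    """Ornstein-Uhlenbeck stationary density: f = -x, Γ = 1/2 on [-6, 6]."""
    grid = GridSpec((-6.0,), (6.0,), (256,))
    flow = VectorField.from_function(grid, lambda x: [-x])
    op = discretize_fp_operator(flow, 0.5)
    return grid, flow, op, stationary_density(op)


@pytest.fixture(scope="module")
def double_well():
    """2-D double-well value with a rotational (divergence-free) component."""
    grid = GridSpec((-2.0, -2.0), (2.0, 2.0), (64, 64))
    Q = np.array([[0.0, -0.5], [0.5, 0.0]])

    def V(x, y):
        return -((x**2 - 1.0) ** 2 + y**2)

    def gradV(x, y):
        return [-4.0 * x * (x**2 - 1.0), -2.0 * y]

    spec = StandardFormSpec(value=V, Q=Q, gamma=1.0, grad_value=gradV)
    flow = __import__("ergoflow.fokker_planck", fromlist=["standard_form_flow"]
                      ).standard_form_flow(spec, grid)
    return grid, V, gradV, spec, flow


class TestOperatorStructure:
    def test_pure_diffusion_uniform_is_stationary(self):
        grid = GridSpec((-1.0,), (1.0,), (32,))
        flow = VectorField.from_function(grid, lambda x: [0.0 * x])
        op = discretize_fp_operator(flow, 1.0)
        ones = np.ones(grid.n_cells)
        np.testing.assert_allclose(op.matrix @ ones, 0.0, atol=1e-12)

    def test_columns_sum_to_zero_reflecting(self, ou_density):
        _, _, op, _ = ou_density
        np.testing.assert_allclose(np.asarray(op.matrix.sum(axis=0)).ravel(),
                                   0.0, atol=1e-10)

    def test_offdiagonals_nonnegative(self, ou_density):
        _, _, op, _ = ou_density
        mat = op.matrix.tocoo()
        off = mat.data[mat.row != mat.col]
        assert np.all(off >= 0.0)

    def test_non_psd_diffusion_rejected(self):
        grid = GridSpec((-1.0, -1.0), (1.0, 1.0), (8, 8))
        flow = VectorField.from_function(grid, lambda x, y: [0 * x, 0 * y])
        with pytest.raises(ValueError):
            discretize_fp_operator(flow, np.array([[1.0, 0.0], [0.0, -1.0]]))
        with pytest.raises(ValueError):
            discretize_fp_operator(flow, np.array([[1.0, 0.3], [0.3, 1.0]]))

    def test_absorbing_boundary_loses_mass(self):
        grid = GridSpec((-1.0,), (1.0,), (32,), boundary_mode="absorbing")
        flow = VectorField.from_function(grid, lambda x: [0.0 * x])
        op = discretize_fp_operator(flow, 1.0)
        sums = np.asarray(op.matrix.sum(axis=0)).ravel()
        assert sums[0] < 0 and sums[-1] < 0
        assert np.allclose(sums[1:-1], 0.0, atol=1e-12)


class TestStationaryDensity:
    def test_uniform_under_pure_diffusion(self):
        grid = GridSpec((0.0,), (4.0,), (48,))
        flow = VectorField.from_function(grid, lambda x: [0.0 * x])
        p = stationary_density(discretize_fp_operator(flow, 0.7))
        np.testing.assert_allclose(p.values, 0.25, rtol=1e-8)

    def test_ou_matches_gaussian_closed_form(self, ou_density):
        grid, _, _, p = ou_density
        x = grid.centers(0)
        mean = np.sum(p.flat() * x) * grid.cell_volume
        var = np.sum(p.flat() * (x - mean) ** 2) * grid.cell_volume
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert var == pytest.approx(0.5, rel=0.02)  # Γ/θ = 0.5
        expected = np.exp(-x**2)
        expected /= expected.sum() * grid.cell_volume
        assert np.corrcoef(p.flat(), expected)[0, 1] > 0.9999

    def test_normalized_and_nonnegative(self, ou_density):
        grid, _, _, p = ou_density
        assert p.flat().sum() * grid.cell_volume == pytest.approx(1.0, abs=1e-10)
        assert np.all(p.values >= 0.0)

    def test_residual_small(self, ou_density):
        _, _, _, p = ou_density
        assert p.residual_raw < 1e-6

    def test_ou_variance_exact_at_all_resolutions(self):
        """Exponential fitting is stationary-exact for linear drift."""
        for bins in (32, 64, 128):
            grid = GridSpec((-6.0,), (6.0,), (bins,))
            flow = VectorField.from_function(grid, lambda x: [-x])
            p = stationary_density(discretize_fp_operator(flow, 0.5))
            x = grid.centers(0)
            var = np.sum(p.flat() * x**2) * grid.cell_volume
            assert var == pytest.approx(0.5, abs=1e-8)

    def test_grid_refinement_improves_quartic_well_variance(self):
        """For nonlinear drift the discretization error shrinks with bin width."""
        from scipy.integrate import quad
        gamma = 0.5
        num = quad(lambda x: x**2 * np.exp(-x**4 / (4 * gamma)), -6, 6)[0]
        den = quad(lambda x: np.exp(-x**4 / (4 * gamma)), -6, 6)[0]
        target = num / den
        errs = []
        for bins in (16, 32, 64):
            grid = GridSpec((-6.0,), (6.0,), (bins,))
            flow = VectorField.from_function(grid, lambda x: [-(x**3)])
            p = stationary_density(discretize_fp_operator(flow, gamma))
            x = grid.centers(0)
            var = np.sum(p.flat() * x**2) * grid.cell_volume
            errs.append(abs(var - target))
        assert errs[0] > errs[1] > errs[2]

    def test_boltzmann_oracle_double_well(self, double_well):
        """For f = (Γ+Q)∇V the stationary density is exp(V)/Z (detailed-balance
        breaking Q does not change the equilibrium)."""
        grid, V, _, _, flow = double_well
        p = stationary_density(discretize_fp_operator(flow, 1.0))
        boltz = np.exp(grid.evaluate(V))
        boltz /= boltz.sum() * grid.cell_volume
        assert np.corrcoef(p.flat(), boltz.reshape(-1))[0, 1] > 0.99
        assert p.residual_raw < 1e-6


class TestChaoticAttractorOperator:
    def test_operator_builds_at_full_resolution(self):
        """The 96-bin chaotic-attractor generator assembles with the
        conservation and generator properties intact."""
        from ergoflow.ensembles import lorenz_drift
        grid = GridSpec((-32.0, -32.0, 4.0), (32.0, 32.0, 64.0), (96, 96, 96))
        mesh = np.stack(grid.meshgrid(), axis=-1)
        op = discretize_fp_operator(VectorField(grid, lorenz_drift(mesh)),
                                    1.0 / 64.0)
        assert op.matrix.shape == (96**3, 96**3)
        sums = np.asarray(op.matrix.sum(axis=0)).ravel()
        np.testing.assert_allclose(sums, 0.0, atol=1e-8)
        coo = op.matrix.tocoo()
        assert np.all(coo.data[coo.row != coo.col] >= 0.0)

    def test_eigensolve_converges_on_small_grid(self):
        from ergoflow.ensembles import lorenz_drift
        grid = GridSpec((-32.0, -32.0, 4.0), (32.0, 32.0, 64.0), (20, 20, 20))
        mesh = np.stack(grid.meshgrid(), axis=-1)
        op = discretize_fp_operator(VectorField(grid, lorenz_drift(mesh)),
                                    1.0 / 64.0)
        p = stationary_density(op)
        assert p.residual_raw < 1e-6
        assert p.flat().sum() * grid.cell_volume == pytest.approx(1.0, abs=1e-9)

    def test_sojourn_density_concentrates_on_attractor(self):
        from ergoflow.ensembles import lorenz_drift
        from ergoflow.fokker_planck import sojourn_density
        grid = GridSpec((-32.0, -32.0, 4.0), (32.0, 32.0, 64.0), (24, 24, 24))
        p = sojourn_density(lorenz_drift, grid, 1.0 / 64.0, duration=60.0,
                            n_walkers=16, seed=3)
        assert p.flat().sum() * grid.cell_volume == pytest.approx(1.0, abs=1e-9)
        uniform = np.log(np.prod(np.array(grid.upper) - np.array(grid.lower)))
        assert entropy_of_density(p) < uniform - 2.0


class TestValueAndCost:
    def test_uniform_density_gives_constant_log_volume(self):
        grid = GridSpec((0.0,), (4.0,), (32,))
        p = ScalarField(grid, np.full(grid.shape, 0.25), role="density")
        V = value_from_density(p)
        np.testing.assert_allclose(V.values, np.log(0.25), atol=1e-12)

    def test_ou_value_quadratic(self, ou_density):
        grid, _, _, p = ou_density
        V = value_from_density(p)
        x = grid.centers(0)
        core = np.abs(x) < 3.0
        coeffs = np.polyfit(x[core], V.values[core], 2)
        assert coeffs[0] == pytest.approx(-1.0, rel=0.02)  # V = -x² + const

    def test_argmax_preserved(self, ou_density):
        _, _, _, p = ou_density
        V = value_from_density(p)
        assert np.argmax(V.values) == np.argmax(p.values)

    def test_uniform_value_zero_cost(self):
        grid = GridSpec((-1.0,), (1.0,), (32,))
        V = ScalarField(grid, np.zeros(grid.shape), role="value")
        flow = VectorField.from_function(grid, lambda x: [np.sin(x)])
        c = cost_from_value(V, flow, 0.3)
        np.testing.assert_allclose(c.values, 0.0, atol=1e-12)

    def test_deterministic_limit_cost_is_value_rate(self, ou_density):
        """With Γ = 0, c = f·∇V equals dV/dt along trajectories."""
        grid, flow, _, p = ou_density
        V = value_from_density(p)
        c = cost_from_value(V, flow, 0.0)
        rate = lyapunov_rate(V, flow)
        np.testing.assert_allclose(c.values, rate.values, atol=1e-12)

    def test_cost_nonpositive_at_density_peak(self, ou_density):
        grid, flow, _, p = ou_density
        V = value_from_density(p)
        c = cost_from_value(V, flow, 0.5)
        peak = np.argmax(p.values)
        assert c.values[peak] <= 1e-6


class TestEntropy:
    def test_uniform_on_support_gives_log_volume(self):
        grid = GridSpec((0.0,), (10.0,), (100,))
        vals = np.zeros(grid.shape)
        vals[20:70] = 1.0 / 5.0  # uniform on a region of measure 5
        p = ScalarField(grid, vals, role="density")
        assert entropy_of_density(p) == pytest.approx(np.log(5.0), rel=1e-9)

    def test_gaussian_entropy_closed_form(self):
        grid = GridSpec((-8.0,), (8.0,), (512,))
        x = grid.centers(0)
        sd = 1.3
        vals = np.exp(-0.5 * (x / sd) ** 2)
        vals /= vals.sum() * grid.cell_volume
        p = ScalarField(grid, vals, role="density")
        expected = 0.5 * np.log(2 * np.pi * np.e * sd**2)
        assert entropy_of_density(p) == pytest.approx(expected, rel=0.02)

    def test_concentration_lowers_entropy(self):
        grid = GridSpec((-8.0,), (8.0,), (512,))
        x = grid.centers(0)
        ents = []
        for sd in (1.0, 0.1, 0.01):
            vals = np.exp(-0.5 * (x / sd) ** 2)
            vals /= vals.sum() * grid.cell_volume
            ents.append(entropy_of_density(ScalarField(grid, vals, role="density")))
        assert ents[0] > ents[1] > ents[2]
        assert ents[2] < 0.0

    def test_production_zero_for_uniform(self):
        grid = GridSpec((0.0,), (1.0,), (64,))
        p = ScalarField(grid, np.ones(grid.shape), role="density")
        assert entropy_production_rate(p, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_production_nonnegative_for_random_smooth_densities(self):
        rng = np.random.default_rng(5)
        grid = GridSpec((0.0,), (1.0,), (128,))
        x = grid.centers(0)
        for _ in range(100):
            coef = rng.normal(size=4)
            vals = np.exp(np.polyval(coef, np.cos(2 * np.pi * x)))
            vals /= vals.sum() * grid.cell_volume
            p = ScalarField(grid, vals, role="density")
            assert entropy_production_rate(p, 1.0) >= 0.0

    def test_production_matches_heat_kernel_entropy_rate(self):
        """Under pure diffusion dH/dt equals ∫ ∇p·Γ·∇p / p dx."""
        gamma, sd = 0.25, 1.0
        grid = GridSpec((-12.0,), (12.0,), (1024,))
        x = grid.centers(0)

        def gaussian(s):
            vals = np.exp(-0.5 * (x / s) ** 2)
            return vals / (vals.sum() * grid.cell_volume)

        p = ScalarField(grid, gaussian(sd), role="density")
        rate = entropy_production_rate(p, gamma)
        # H(t) = 0.5 ln(2πe (sd² + 2Γt)); dH/dt = Γ / sd²
        dt = 1e-4
        sd_later = np.sqrt(sd**2 + 2 * gamma * dt)
        H0 = entropy_of_density(p)
        H1 = entropy_of_density(ScalarField(grid, gaussian(sd_later), role="density"))
        assert rate == pytest.approx((H1 - H0) / dt, rel=0.05)
        assert rate == pytest.approx(gamma / sd**2, rel=0.05)


class TestStandardForm:
    def test_q_symmetry_violation_rejected(self):
        with pytest.raises(ValueError):
            StandardFormSpec(value=lambda x: -x**2, Q=np.array([[0.0, 1.0],
                                                                [1.0, 0.0]]),
                             gamma=1.0)

    def test_pure_gradient_flow_when_q_zero(self):
        grid = GridSpec((-2.0, -2.0), (2.0, 2.0), (16, 16))
        spec = StandardFormSpec(
            value=lambda x, y: -(x**2 + y**2), Q=np.zeros((2, 2)), gamma=0.5,
            grad_value=lambda x, y: [-2 * x, -2 * y])
        flow = __import__("ergoflow.fokker_planck", fromlist=["standard_form_flow"]
                          ).standard_form_flow(spec, grid)
        X, Y = grid.meshgrid()
        np.testing.assert_allclose(flow.values[..., 0], -X, atol=1e-12)
        np.testing.assert_allclose(flow.values[..., 1], -Y, atol=1e-12)

    def test_newtonian_flow_from_lagrangian(self):
        """ℒ = φ(x) + x'²/2 with rotational Q yields f = [x', -∇φ]."""
        from ergoflow.fokker_planck import standard_form_flow
        grid = GridSpec((-2.0, -2.0), (2.0, 2.0), (24, 24))
        Q = np.array([[0.0, -1.0], [1.0, 0.0]])
        # V = -ℒ so that f = (Γ+Q)∇V with Γ=0 gives -Q∇ℒ
        spec = StandardFormSpec(
            value=lambda x, v: -(x**4 / 4 + v**2 / 2), Q=Q, gamma=0.0,
            grad_value=lambda x, v: [-(x**3), -v])
        flow = standard_form_flow(spec, grid)
        X, Vel = grid.meshgrid()
        np.testing.assert_allclose(flow.values[..., 0], Vel, atol=1e-12)
        np.testing.assert_allclose(flow.values[..., 1], -(X**3), atol=1e-12)

    def test_velocity_diffusion_emerges_as_friction(self):
        """Adding Γ = diag(0, γ) to the Newtonian flow yields -∇φ - γ x'."""
        from ergoflow.fokker_planck import standard_form_flow
        grid = GridSpec((-2.0, -2.0), (2.0, 2.0), (24, 24))
        gamma_v = 0.3
        spec = StandardFormSpec(
            value=lambda x, v: -(x**4 / 4 + v**2 / 2),
            Q=np.array([[0.0, -1.0], [1.0, 0.0]]),
            gamma=np.diag([0.0, gamma_v]),
            grad_value=lambda x, v: [-(x**3), -v])
        flow = standard_form_flow(spec, grid)
        X, Vel = grid.meshgrid()
        np.testing.assert_allclose(flow.values[..., 1], -(X**3) - gamma_v * Vel,
                                   atol=1e-12)

    def test_conservative_part_orthogonal_to_gradient(self, double_well):
        grid, _, gradV, _, _ = double_well
        from ergoflow.fokker_planck import standard_form_flow
        spec_q = StandardFormSpec(
            value=lambda x, y: -((x**2 - 1) ** 2 + y**2),
            Q=np.array([[0.0, -0.5], [0.5, 0.0]]), gamma=0.0,
            grad_value=gradV)
        qflow = standard_form_flow(spec_q, grid)
        gv = np.stack([np.broadcast_to(c, grid.shape)
                       for c in gradV(*grid.meshgrid())], axis=-1)
        dots = np.einsum("...i,...i->...", qflow.values, gv)
        np.testing.assert_allclose(dots, 0.0, atol=1e-10)

    def test_lyapunov_rate_equals_dissipation_pointwise(self, double_well):
        grid, V, gradV, spec, flow = double_well
        rate = lyapunov_rate(V, flow, grad_value=gradV)
        diss = dissipation_rate(V, spec.gamma, grid, grad_value=gradV)
        np.testing.assert_allclose(rate.values, diss.values, atol=1e-8)
        assert np.all(rate.values >= -1e-8)

    def test_value_nondecreasing_along_deterministic_trajectory(self, double_well):
        grid, V, gradV, spec, _ = double_well
        A = np.asarray(spec.gamma) * np.eye(2) if np.ndim(spec.gamma) == 0 \
            else np.asarray(spec.gamma)
        A = spec.Q + (np.eye(2) * spec.gamma if np.ndim(spec.gamma) == 0 else A)

        def drift(x):
            g = np.array([gv for gv in gradV(*x)])
            return A @ g

        traj = integrate_deterministic_flow(drift, [0.3, 1.2], 5.0, 0.01)
        values = np.array([V(*p) for p in traj])
        assert np.all(np.diff(values) >= -1e-9)


class TestDivergence:
    def test_constant_flow_divergence_free(self):
        grid = GridSpec((-1.0, -1.0), (1.0, 1.0), (16, 16))
        flow = VectorField.from_function(grid, lambda x, y: [1.0 + 0 * x,
                                                             -2.0 + 0 * y])
        np.testing.assert_allclose(divergence_field(flow).values, 0.0, atol=1e-12)

    def test_linear_flow_divergence_is_trace(self):
        grid = GridSpec((-1.0, -1.0), (1.0, 1.0), (16, 16))
        A = np.array([[0.7, 0.2], [-0.4, -1.1]])
        flow = VectorField.from_function(
            grid, lambda x, y: [A[0, 0] * x + A[0, 1] * y,
                                A[1, 0] * x + A[1, 1] * y])
        np.testing.assert_allclose(divergence_field(flow).values, np.trace(A),
                                   atol=1e-10)

    def test_mountain_car_generative_divergence_equals_cost(self):
        from ergoflow.mountain_car import cost_function, potential_and_gradient
        grid = GridSpec((-2.0, -2.0), (2.0, 2.0), (256, 256))

        def components(x, v):
            _, dphi = potential_and_gradient(x)
            return [v, cost_function(x, 0.0) * v - dphi]

        flow = VectorField.from_function(grid, components)
        div = divergence_field(flow)
        X, _ = grid.meshgrid()
        c = cost_function(X, 0.0)
        # second-order interior accuracy; the cost bump has curvature ~ 4e3,
        # so the central-difference error bound is ~ c'''(x) h² / 6
        h = grid.spacing[0]
        interior = div.values[1:-1, 1:-1]
        np.testing.assert_allclose(interior, c[1:-1, 1:-1],
                                   atol=2e5 * h**2 / 6)


class TestHJBControl:
    def test_bang_bang_follows_gradient_sign(self):
        grid = GridSpec((-2.0,), (2.0,), (64,))
        V = ScalarField(grid, -grid.centers(0) ** 2, role="value")

        def family(u):
            return VectorField.from_function(grid, lambda x: [u + 0 * x])

        ctrl, _ = hjb_greedy_control(family, V, [-1.0, 1.0])
        x = grid.centers(0)
        gradV = -2 * x
        interior = np.abs(gradV) > 0.1
        np.testing.assert_array_equal(ctrl.values[interior],
                                      np.sign(gradV[interior]))

    def test_constant_value_ties_break_to_smallest_control(self):
        grid = GridSpec((-1.0,), (1.0,), (16,))
        V = ScalarField(grid, np.zeros(grid.shape), role="value")

        def family(u):
            return VectorField.from_function(grid, lambda x: [u + 0 * x])

        ctrl, _ = hjb_greedy_control(family, V, [-2.0, -0.5, 0.5, 2.0])
        np.testing.assert_allclose(np.abs(ctrl.values), 0.5)

    def test_residual_zero_when_value_solves_hjb(self):
        """Construct c := max_u f·∇V so the HJB equation holds by definition."""
        grid = GridSpec((-2.0,), (2.0,), (64,))
        V = ScalarField(grid, np.sin(grid.centers(0)), role="value")

        def family(u):
            return VectorField.from_function(grid, lambda x: [u - 0.3 * x])

        _, best = hjb_greedy_control(family, V, [-1.0, 0.0, 1.0])
        cost = ScalarField(grid, best.values, role="cost")
        _, residual = hjb_greedy_control(family, V, [-1.0, 0.0, 1.0], cost=cost)
        np.testing.assert_allclose(residual.values, 0.0, atol=1e-12)

    def test_empty_control_set_rejected(self):
        grid = GridSpec((-1.0,), (1.0,), (8,))
        V = ScalarField(grid, np.zeros(grid.shape), role="value")
        with pytest.raises(ValueError):
            hjb_greedy_control(lambda u: None, V, [])


def _ring_bump(x):
    d = np.minimum(np.abs(x - np.pi), 2 * np.pi - np.abs(x - np.pi))
    return np.exp(-4.0 * d**2)


_BUMP_MEAN = float(np.mean(_ring_bump(np.linspace(0, 2 * np.pi, 4096,
                                                  endpoint=False))))


def centred_bump(x):
    """Localized cost bump with zero circulation around the ring."""
    return float(_ring_bump(x) - _BUMP_MEAN)


class TestValueLearning:
    def test_zero_cost_no_update(self):
        state = ValueLearningState(values=np.zeros(16), lower=0.0,
                                   upper=2 * np.pi)
        for x in np.linspace(0, 2, 40):
            value_learning_step(state, float(x), 1.0, lambda _: 0.0, dt=0.05)
        np.testing.assert_allclose(state.values, 0.0)
        assert state.last_delta == 0.0

    def test_converges_and_matches_path_integral_oracle(self):
        state, mean_abs_delta = learn_value_on_ring(
            speed=1.0, cost_fn=centred_bump, n_bins=32, learning_rate=0.5,
            n_laps=3000)
        assert mean_abs_delta < 1e-3
        oracle = ring_value_oracle(1.0, centred_bump, 32)
        learned = state.values - state.values.mean()
        rmse = np.sqrt(np.mean((learned - oracle) ** 2))
        assert rmse < 0.05 * np.sqrt(np.mean(oracle**2))

    def test_delta_reports_value_rate_minus_cost(self):
        """After convergence V̇ ≈ c along the orbit (reward prediction error → 0)."""
        state, _ = learn_value_on_ring(speed=1.0, cost_fn=centred_bump,
                                       n_bins=32, n_laps=1000)
        h = 2 * np.pi / 32
        vdot = (np.roll(state.values, -1) - state.values) / h  # forward along orbit
        centres = (np.arange(32) + 0.5) * h
        c = np.array([centred_bump(x) for x in centres])
        assert np.corrcoef(vdot, c)[0, 1] > 0.99


class TestFieldHelpers:
    def test_gradient_of_linear_field_exact(self):
        grid = GridSpec((-1.0, -1.0), (1.0, 1.0), (12, 12))
        X, Y = grid.meshgrid()
        f = ScalarField(grid, 2.0 * X - 3.0 * Y)
        g = gradient_field(f)
        np.testing.assert_allclose(g.values[..., 0], 2.0, atol=1e-12)
        np.testing.assert_allclose(g.values[..., 1], -3.0, atol=1e-12)

    def test_sample_scalar_field_interpolates(self):
        grid = GridSpec((0.0,), (1.0,), (64,))
        f = ScalarField(grid, grid.centers(0) ** 2)
        pts = np.array([[0.25], [0.5]])
        np.testing.assert_allclose(sample_scalar_field(f, pts),
                                   [0.0625, 0.25], atol=1e-3)
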