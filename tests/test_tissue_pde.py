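import numpy as np
import pytest

from oxynet.grid import Grid
from oxynet.parameters import default_params
from oxynet.tissue_pde import (
    MultigridLevel,
    build_hierarchy,
    consumption,
    consumption_deriv,
    laplacian_h,
    neighbor_sum,
    pseudo_time_step,
    v_cycle,
)


@pytest.fixture
def p():
    return default_params()


class TestConsumption:
    def test_half_max_at_p0(self, p):
        assert consumption(p.P0, p) == pytest.approx(p.M0 / 2)

    def test_anchors(self, p):
        assert consumption(0.0, p) == 0.0
        assert consumption(99 * p.P0, p) == pytest.approx(0.99 * p.M0)

    def test_derivative_matches_finite_difference(self, p):
        P = np.linspace(0.0, 50, 101)
        eps = 1e-6
        fd = (consumption(P + eps, p) - consumption(P, p)) / eps
        assert np.allclose(consumption_deriv(P + eps / 2, p), fd, rtol=1e-5)

    def test_negative_rejected(self, p):
        with pytest.raises(ValueError):
            consumption(-0.1, p)


class TestLaplacian:
    def test_constant_field_maps_to_zero(self):
        u = np.full((17, 17), 3.7)
        assert np.abs(laplacian_h(u, 0.1)).max() < 1e-12

    def test_exact_on_quadratic_interior(self):
        g = Grid(2, 32, 1.0)
        x = g.axis_coords()
        u = np.tile(x**2, (33, 1)).T
        lap = laplacian_h(u, g.h)
        assert np.allclose(lap[1:-1, 1:-1], 2.0, atol=1e-9)

    def test_discrete_divergence_theorem(self, rng):
        # with no-flux reflection the trapezoid-weighted integral of the
        # Laplacian vanishes for any field (summation by parts)
        for shape in [(17, 17), (9, 9, 9)]:
            u = rng.normal(size=shape)
            lap = laplacian_h(u, 0.05)
            wt = np.ones(shape[0])
            wt[0] = wt[-1] = 0.5
            w = wt
            for _ in range(len(shape) - 1):
                w = np.multiply.outer(w, wt)
            assert abs((lap * w).sum()) < 1e-10 * np.abs(lap).sum()


class TestVCycle:
    def _poisson_setup(self, n, rng, dim=2):
        g = Grid(dim, n, 1.0)
        c = np.full(g.shape, 1e-2)  # mild diagonal shift removes the Neumann nullspace
        rhs = rng.normal(size=g.shape)
        levels = build_hierarchy(g, c, D_alpha=1.0)
        return g, c, rhs, levels

    def test_residual_reduction_ten_orders(self, rng):
        g, c, rhs, levels = self._poisson_setup(64, rng)
        from oxynet.tissue_pde import _linop_residual

        u = np.zeros(g.shape)
        r0 = np.linalg.norm(_linop_residual(u, rhs, c, 1.0 / g.h**2))
        for _ in range(10):
            v_cycle(u, rhs, levels)
        r = np.linalg.norm(_linop_residual(u, rhs, c, 1.0 / g.h**2))
        assert r < 1e-10 * r0

    def test_zero_rhs_zero_guess_gives_zero(self, rng):
        g, c, _, levels = self._poisson_setup(32, rng)
        u = v_cycle(np.zeros(g.shape), np.zeros(g.shape), levels)
        assert np.abs(u).max() == 0.0

    def test_cycle_count_mesh_independent(self, rng):
        from oxynet.tissue_pde import _linop_residual

        counts = []
        for n in (64, 128, 256):
            g, c, rhs, levels = self._poisson_setup(n, rng)
            u = np.zeros(g.shape)
            r0 = np.linalg.norm(_linop_residual(u, rhs, c, 1.0 / g.h**2))
            k = 0
            while k < 30:
                v_cycle(u, rhs, levels)
                k += 1
                if np.linalg.norm(_linop_residual(u, rhs, c, 1.0 / g.h**2)) < 1e-10 * r0:
                    break
            counts.append(k)
        assert max(counts) - min(counts) <= 1


class TestPseudoTimeStep:
    def test_uniform_steady_state_preserved(self, p):
        g = Grid(2, 16, 1.0)
        # no source, no consumption pressure scale -> uniform field is steady
        P0 = np.full(g.shape, 40.0)
        S = consumption(P0, p) * np.ones(g.shape)  # balances M exactly
        P1, info = pseudo_time_step(P0, S, 1e3, p, g, tol=1e-12 * p.M0, max_newton=5)
        assert np.allclose(P1, 40.0, atol=1e-6)

    def test_manufactured_solution_second_order(self, p):
        L = 0.512
        errs = []
        for n in (32, 64, 128):
            g = Grid(2, n, L)
            x, y = np.meshgrid(g.axis_coords(), g.axis_coords(), indexing="ij")
            Pstar = 50 + 20 * np.cos(np.pi * x / L) * np.cos(np.pi * y / L)
            lap = -40 * (np.pi / L) ** 2 * np.cos(np.pi * x / L) * np.cos(np.pi * y / L)
            S = -p.D_alpha * lap + consumption(Pstar, p)
            u, _ = pseudo_time_step(np.full(g.shape, 50.0), S, 1e13, p, g,
                                    tol=1e-9 * p.M0, max_newton=40,
                                    max_vcycles_per_newton=10)
            errs.append(np.linalg.norm(u - Pstar) / np.linalg.norm(Pstar))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert abs(orders.mean() - 2.0) < 0.1

    def test_fixed_point_of_steady_equation(self, p):
        # if P already solves the steady equation, the step returns it
        L = 0.512
        g = Grid(2, 32, L)
        x, y = np.meshgrid(g.axis_coords(), g.axis_coords(), indexing="ij")
        Pstar = 30 + 10 * np.cos(np.pi * x / L)
        S = -p.D_alpha * laplacian_h(Pstar, g.h) + consumption(Pstar, p)
        u, info = pseudo_time_step(Pstar.copy(), S, 5e3, p, g, tol=1e-10 * p.M0)
        assert np.abs(u - Pstar).max() < 1e-8
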