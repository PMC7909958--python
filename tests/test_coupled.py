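import numpy as np
import pytest

from oxynet.coupled import SolverConfig, default_dt, residual_metrics, solve_steady
from oxynet.grid import Grid
from oxynet.network import BoundaryNode, Segment, VesselNetwork, make_cobweb_2d, make_single_vessel_3d
from oxynet.parameters import default_params
from oxynet.tissue_pde import consumption, laplacian_h


class TestResidualMetrics:
    def test_identical_states_give_zero(self, rng):
        q = rng.uniform(0, 1, 100)
        P = rng.uniform(0, 40, (17, 17))
        assert residual_metrics((q, P), (q, P)) == (0.0, 0.0)

    def test_relative_scaling_first_order(self, rng):
        q = rng.uniform(0.1, 1, 100)
        P = rng.uniform(1, 40, (17, 17))
        eps = 1e-4
        rq, rp = residual_metrics((q, P), (q * (1 + eps), P * (1 + eps)))
        assert rq == pytest.approx(eps / (1 + eps), rel=1e-10)
        assert rp == pytest.approx(eps / (1 + eps), rel=1e-10)

    def test_matches_elementwise_computation(self, rng):
        q0, q1 = rng.normal(size=50), rng.normal(size=50)
        P0, P1 = rng.normal(size=(9, 9)), rng.normal(size=(9, 9))
        rq, rp = residual_metrics((q0, P0), (q1, P1))
        assert rq == pytest.approx(
            np.sqrt(((q1 - q0) ** 2).sum()) / np.sqrt((q1**2).sum())
        )
        assert rp == pytest.approx(
            np.sqrt(((P1 - P0) ** 2).sum()) / np.sqrt((P1**2).sum())
        )


def _tiny_vessel_2d(inflow=1e-7):
    nodes = np.array([[0.02, 0.064], [0.108, 0.064]])
    net = VesselNetwork(
        2, nodes, [Segment(0, 1, 1e-3, nodes.copy())],
        [BoundaryNode(0, "inlet", inflow), BoundaryNode(1, "outlet", inflow)],
    )
    net.validate()
    return net


class TestSolveSteady:
    def test_zero_inflow_trivial_fixed_point(self):
        net = _tiny_vessel_2d(inflow=0.0)
        p = default_params()
        tissue, blood, flow, diag = solve_steady(net, p, SolverConfig(), Grid(2, 32, 0.128))
        assert np.abs(tissue.values).max() == 0.0
        assert blood.q_vector().max() == 0.0
        assert diag.converged and diag.iterations == 1

    def test_converged_state_satisfies_steady_equation(self):
        net = _tiny_vessel_2d()
        p = default_params()
        cfg = SolverConfig(outer_tol=1e-4)
        tissue, blood, flow, diag = solve_steady(net, p, cfg, Grid(2, 64, 0.128))
        # the raw field solves D lap P - M(P) + S = residual, |residual| small
        res = (p.D_alpha * laplacian_h(tissue.raw, tissue.grid.h)
               - consumption(tissue.raw, p) + tissue.source)
        assert np.sqrt(np.mean(res**2)) < 1e-2 * p.M0

    def test_supply_balances_consumption(self):
        net = _tiny_vessel_2d()
        p = default_params()
        tissue, blood, flow, diag = solve_steady(net, p, SolverConfig(), Grid(2, 64, 0.128))
        assert diag.supply > 0
        assert diag.consumption == pytest.approx(diag.supply, rel=0.02)

    def test_full_relaxation_weight_stalls(self):
        # lam = 1 never updates the flux: the iteration freezes at the
        # useless zero-transfer state instead of oxygenating the tissue
        net = _tiny_vessel_2d()
        p = default_params()
        g = Grid(2, 32, 0.128)
        _, _, _, stalled = solve_steady(net, p, SolverConfig(lam=1.0, max_outer=30), g)
        assert stalled.supply == 0.0
        _, _, _, ok = solve_steady(net, p, SolverConfig(lam=0.5), g)
        assert ok.supply > 0.0

    def test_default_relaxation_converges_on_fixtures(self):
        p3 = default_params().replace(M0=2.0e-3)
        _, _, _, d3 = solve_steady(make_single_vessel_3d(), p3, SolverConfig(),
                                   Grid(3, 16, 0.064))
        assert d3.converged
        _, _, _, d2 = solve_steady(make_cobweb_2d(), default_params(), SolverConfig(),
                                   Grid(2, 128, 0.512))
        assert d2.converged

    def test_residual_history_decays_after_transient(self):
        net = _tiny_vessel_2d()
        p = default_params()
        _, _, _, diag = solve_steady(net, p, SolverConfig(outer_tol=1e-4),
                                     Grid(2, 64, 0.128))
        r = np.array(diag.residual_q[2:])
        # fast initial decay then a roughly monotone tail: no late growth
        # beyond small flicker
        assert r[-1] < r[0]
        assert np.max(r[len(r) // 2:]) < 10 * np.min(r[: len(r) // 2])

    def test_gauss_seidel_variant_reaches_same_state(self):
        net = _tiny_vessel_2d()
        p = default_params()
        g = Grid(2, 64, 0.128)
        t_j, *_ = solve_steady(net, p, SolverConfig(), g)
        t_gs, *_ = solve_steady(net, p, SolverConfig(gauss_seidel_flux=True), g)
        denom = np.linalg.norm(t_j.values)
        assert np.linalg.norm(t_gs.values - t_j.values) < 5e-3 * denom

    def test_uncorrected_run_differs_near_vessel(self):
        # the correction sharpens the near-wall field upward
        net = _tiny_vessel_2d()
        p = default_params()
        g = Grid(2, 64, 0.128)
        t_on, *_ = solve_steady(net, p, SolverConfig(), g)
        t_off, *_ = solve_steady(net, p, SolverConfig(use_correction=False), g)
        assert t_on.values.max() > t_off.values.max()


def test_default_dt_schedule_values():
    assert default_dt(Grid(2, 1024, 0.512)) == pytest.approx(5000.0)
    assert default_dt(Grid(2, 2048, 0.512)) == pytest.approx(2500.0)
    assert default_dt(Grid(3, 64, 0.064)) == pytest.approx(5000.0)
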