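import numpy as np
import pytest

from oxynet.blood_oxygen import (
    integrate_segment,
    invert_f,
    oxygen_flux_f,
    saturation,
    traverse_network,
)
from oxynet.hemodynamics import FlowSolution, solve_flow
from oxynet.network import BoundaryNode, Segment, VesselNetwork
from oxynet.parameters import default_params


@pytest.fixture
def p():
    return default_params()


class TestSaturation:
    def test_half_saturation_at_p50(self, p):
        assert saturation(38.0, p) == pytest.approx(0.5)

    def test_anchor_values(self, p):
        assert saturation(0.0, p) == 0.0
        # P = 100, P50 = 38, n = 2: 10000/11444
        assert saturation(100.0, p) == pytest.approx(10000.0 / 11444.0, rel=1e-12)

    def test_strictly_increasing_and_bounded(self, p):
        P = np.linspace(0, 400, 2000)
        s = saturation(P, p)
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s < 1))

    def test_negative_rejected(self, p):
        with pytest.raises(ValueError):
            saturation(-1.0, p)


class TestFluxFunction:
    def test_values(self, p):
        assert oxygen_flux_f(0.0, 5e-8, p) == 0.0
        expected = 5e-8 * (3.1e-3 + 0.45 * 0.5 * (10000.0 / 11444.0))
        assert oxygen_flux_f(100.0, 5e-8, p) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_flow(self, p):
        assert oxygen_flux_f(60.0, 2e-7, p) == pytest.approx(
            2 * oxygen_flux_f(60.0, 1e-7, p)
        )

    def test_inverse_round_trip(self, p):
        for pb in (0.5, 12.0, 38.0, 77.0, 250.0):
            f = oxygen_flux_f(pb, 5e-8, p)
            assert invert_f(f, 5e-8, p) == pytest.approx(pb, abs=1e-10)

    def test_invert_anchors(self, p):
        assert invert_f(0.0, 5e-8, p) == 0.0
        f50 = 5e-8 * (p.alpha_b * 38.0 + p.H_D * p.C0 * 0.5)
        assert invert_f(f50, 5e-8, p) == pytest.approx(38.0, abs=1e-9)


class TestSegmentIntegration:
    def test_zero_flux_keeps_pressure(self, p):
        out = integrate_segment(80.0, 5e-8, np.zeros(50), 0.1, p)
        assert np.allclose(out, 80.0)

    def test_constant_flux_exact_f_decay(self, p):
        Q, L, q = 5e-8, 0.1, 5e-8
        out = integrate_segment(100.0, Q, np.full(301, q), L, p)
        f_expected = oxygen_flux_f(100.0, Q, p) - q * L
        assert oxygen_flux_f(out[-1], Q, p) == pytest.approx(f_expected, rel=1e-9)

    def test_rk4_fourth_order_on_smooth_flux(self, p):
        Q, L = 5e-8, 0.1
        qfun = lambda s: 4e-8 * (1 + 0.8 * np.sin(3 * np.pi * s / L))
        ref = integrate_segment(100.0, Q, qfun(np.linspace(0, L, 1 << 14)), L, p)[-1]
        errs = []
        for m in (32, 64, 128, 256):
            out = integrate_segment(100.0, Q, qfun(np.linspace(0, L, m + 1)), L, p)
            errs.append(abs(out[-1] - ref))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert orders.min() > 3.5


def _y_network(q_len=7):
    """Two parents merging into one child along x."""
    nodes = np.array([[0.0, 0.1], [0.0, -0.1], [0.1, 0.0], [0.25, 0.0]])
    segs = [
        Segment(0, 2, 1e-4, nodes[[0, 2]].copy()),
        Segment(1, 2, 1e-4, nodes[[1, 2]].copy()),
        Segment(2, 3, 1e-4, nodes[[2, 3]].copy()),
    ]
    bc = [BoundaryNode(0, "inlet", 1e-7), BoundaryNode(1, "inlet", 1e-7),
          BoundaryNode(3, "outlet", 2e-7)]
    return VesselNetwork(2, nodes, segs, bc)


class TestTraversal:
    def test_equal_parents_mix_to_parent_value(self, p):
        net = _y_network()
        flow = solve_flow(net, p)
        h_k = 0.02
        q = [np.zeros(len(s.sample_grid(h_k))) for s in net.segments]
        blood = traverse_network(net, flow, q, p, h_k)
        for prof in blood.profiles:
            assert np.allclose(prof.P_b, 100.0)

    def test_junction_mixing_conserves_oxygen(self, p):
        net = _y_network()
        flow = solve_flow(net, p)
        h_k = 0.005
        # deplete parent 0 only: constant flux there
        q = [np.full(len(s.sample_grid(h_k)), 3e-7) if k == 0 else
             np.zeros(len(s.sample_grid(h_k))) for k, s in enumerate(net.segments)]
        blood = traverse_network(net, flow, q, p, h_k, clamp=False)
        p_end0 = blood.profiles[0].P_b[-1]
        p_end1 = blood.profiles[1].P_b[-1]
        # brute-force conservation: mixed f equals sum of parent f
        f_mix = oxygen_flux_f(p_end0, 1e-7, p) + oxygen_flux_f(p_end1, 1e-7, p)
        p_child = invert_f(f_mix, 2e-7, p)
        assert blood.profiles[2].P_b[0] == pytest.approx(p_child, rel=1e-10)

    def test_single_vessel_matches_direct_integration(self, p):
        nodes = np.array([[0.0, 0.0], [0.2, 0.0]])
        net = VesselNetwork(2, nodes, [Segment(0, 1, 1e-4, nodes.copy())],
                            [BoundaryNode(0, "inlet", 1e-7),
                             BoundaryNode(1, "outlet", 1e-7)])
        flow = solve_flow(net, p)
        h_k = 0.004
        s = net.segments[0].sample_grid(h_k)
        q = 2e-7 * (1 + np.cos(np.pi * s / 0.2))
        blood = traverse_network(net, flow, [q], p, h_k)
        direct = integrate_segment(100.0, 1e-7, q, 0.2, p)
        assert np.allclose(blood.profiles[0].P_b, direct)

    def test_network_oxygen_balance(self, p):
        net = _y_network()
        flow = solve_flow(net, p)
        h_k = 0.002
        q = [np.full(len(s.sample_grid(h_k)), 5e-8) for s in net.segments]
        blood = traverse_network(net, flow, q, p, h_k, clamp=False)
        f_in = 2 * oxygen_flux_f(100.0, 1e-7, p)
        f_out = oxygen_flux_f(blood.profiles[2].P_b[-1], 2e-7, p)
        assert f_in - f_out == pytest.approx(blood.total_release(), rel=1e-8)

    def test_raising_inlet_pressure_never_lowers_downstream(self, p):
        net = _y_network()
        flow = solve_flow(net, p)
        h_k = 0.005
        q = [np.full(len(s.sample_grid(h_k)), 2e-7) for s in net.segments]
        lo = traverse_network(net, flow, q, p, h_k, inlet_Pb0=80.0)
        hi = traverse_network(net, flow, q, p, h_k, inlet_Pb0=95.0)
        for a, b in zip(lo.profiles, hi.profiles):
            assert np.all(b.P_b >= a.P_b - 1e-12)

    def test_depleted_vessel_stops_releasing(self, p):
        nodes = np.array([[0.0, 0.0], [0.5, 0.0]])
        net = VesselNetwork(2, nodes, [Segment(0, 1, 1e-4, nodes.copy())],
                            [BoundaryNode(0, "inlet", 1e-8),
                             BoundaryNode(1, "outlet", 1e-8)])
        flow = solve_flow(net, p)
        h_k = 0.005
        s = net.segments[0].sample_grid(h_k)
        q = np.full(len(s), 1e-7)  # far more than the blood carries
        blood = traverse_network(net, flow, [q], p, h_k)
        f_in = oxygen_flux_f(100.0, 1e-8, p)
        assert blood.total_release() <= f_in * (1 + 1e-9)
        assert blood.profiles[0].q[-1] == 0.0
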