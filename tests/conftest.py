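"""Shared fixtures.

The acceptance-style studies (nested-mesh refinement, near-vessel error
maps) reuse one set of converged solves per geometry, built lazily and
session-scoped because the finest meshes take minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from oxynet import Grid, SolverConfig, default_params, make_cobweb_2d, make_single_vessel_3d
from oxynet.coupled import solve_steady


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def single3d_net():
    return make_single_vessel_3d()


@pytest.fixture(scope="session")
def cobweb_net():
    return make_cobweb_2d()


@pytest.fixture(scope="session")
def single3d_solves(single3d_net):
    """Converged single-vessel runs at h = 40, 20, 10, 5 um (n = 16..128)."""
    p = default_params().replace(M0=2.0e-3)
    out = {}
    for n in (16, 32, 64, 128):
        # tighter outer tolerance: iteration residue must stay well below
        # the discretization errors these runs are used to measure
        tissue, blood, flow, diag = solve_steady(
            single3d_net, p, SolverConfig(outer_tol=2e-4, stall_action="accept"),
            Grid(3, n, 0.064)
        )
        out[n] = (tissue, blood, flow, diag)
    return out


@pytest.fixture(scope="session")
def cobweb_solves(cobweb_net):
    """Converged cobweb runs at n = 256..2048 (h = 20..2.5 um)."""
    p = default_params()
    out = {}
    for n in (256, 512, 1024, 2048):
        tissue, blood, flow, diag = solve_steady(
            cobweb_net, p, SolverConfig(max_outer=250, stall_action="accept"),
            Grid(2, n, 0.512)
        )
        out[n] = (tissue, blood, flow, diag)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
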