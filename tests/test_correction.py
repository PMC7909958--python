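import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from oxynet.correction import (
    CorrectionOperator,
    apply_correction,
    build_stencil,
    correction_field,
    heat_kernel_response,
    heat_kernel_response_quad,
    point_source_response,
)
from oxynet.grid import Grid
from oxynet.parameters import default_params
from oxynet.spreading import SourcePointSet, peskin_phi, spread


@pytest.fixture
def p():
    return default_params()


def _points(pts, w, radius=1e-3):
    pts = np.atleast_2d(pts)
    w = np.atleast_1d(w).astype(float)
    return SourcePointSet(pts, w, np.full(len(w), radius),
                          np.zeros(len(w), int), np.arange(len(w)))


class TestKernels:
    @pytest.mark.parametrize("d", [2, 3])
    @pytest.mark.parametrize("r,dt", [(5e-4, 5000.0), (2e-3, 1000.0), (1e-3, 2e4)])
    def test_heat_kernel_closed_form_matches_quadrature(self, p, d, r, dt):
        cf = heat_kernel_response(r, dt, p, d)
        quad = heat_kernel_response_quad(r, dt, p, d)
        assert cf == pytest.approx(quad, rel=1e-10)

    def test_long_time_3d_limit_is_steady_green_function(self, p):
        # dt -> infinity recovers 1/(4 pi D r)
        r = 1e-3
        val = heat_kernel_response(r, 1e14, p, 3)
        assert val == pytest.approx(1.0 / (4 * np.pi * p.D_alpha * r), rel=1e-5)

    def test_monotone_decreasing_in_r(self, p):
        r = np.linspace(1e-4, 5e-3, 200)
        v = heat_kernel_response(r, 5000.0, p, 3)
        assert np.all(np.diff(v) < 0)

    def test_divergence_at_source_rejected(self, p):
        with pytest.raises(ValueError):
            heat_kernel_response(0.0, 100.0, p, 3)
        with pytest.raises(ValueError):
            point_source_response(0.0, None, p, 2)


class TestStencil:
    def test_boundary_values_vanish_and_interior_localizes(self, p):
        st = build_stencil(5e-4, None, p, 2, r_min=5e-4)
        assert np.abs(st.tables[..., st.boundary_mask()]).max() == 0.0
        # the error is concentrated within ~2 cells of the source
        for off in np.ndindex(4, 4):
            tab = st.tables[off]
            peak = np.abs(tab).max()
            assert np.abs(tab[0, :]).max() < 0.05 * peak

    def test_cell_center_offset_patch_is_symmetric(self, p):
        st = build_stencil(5e-4, None, p, 2, r_min=5e-4, offsets=3)
        tab = st.tables[1, 1]  # offset (1/2, 1/2): symmetric about host cell
        assert np.allclose(tab, tab[::-1, :][:, ::-1], rtol=1e-10, atol=1e-18)

    def test_patch_matches_large_domain_solve(self, p):
        # independent oracle: solve the same error-patch equation on a much
        # larger Dirichlet domain and restrict; the small-patch truncation
        # leaves only the nonlocal discretization tail (a few % of peak)
        h, rmin = 5e-4, 1e-3
        st = build_stencil(h, None, p, 2, r_min=rmin)
        fr = np.array([1 / 3, 1 / 3])
        N = 64
        xs = (np.arange(N + 1) - N // 2) * h
        xk = fr * h
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        r = np.sqrt((X - xk[0]) ** 2 + (Y - xk[1]) ** 2)
        Pk = point_source_response(np.maximum(r, rmin), None, p, 2, log_scale=h)
        db = np.outer(peskin_phi((xk[0] - xs) / h), peskin_phi((xk[1] - xs) / h)) / h**2
        ni = N - 1
        T1 = sp.diags([np.ones(ni - 1), -2 * np.ones(ni), np.ones(ni - 1)], [-1, 0, 1]) / h**2
        lap = sp.kron(T1, sp.identity(ni)) + sp.kron(sp.identity(ni), T1)
        A = -p.D_alpha * lap
        rhs = db[1:-1, 1:-1].copy()
        bnd = Pk.copy()
        bnd[1:-1, 1:-1] = 0.0
        ns = np.zeros_like(bnd)
        ns[1:-1, 1:-1] = bnd[:-2, 1:-1] + bnd[2:, 1:-1] + bnd[1:-1, :-2] + bnd[1:-1, 2:]
        rhs += p.D_alpha / h**2 * ns[1:-1, 1:-1]
        u = spla.spsolve(A.tocsr(), rhs.ravel()).reshape(ni, ni)
        Pbar = Pk.copy()
        Pbar[1:-1, 1:-1] = u
        dP_big = Pk - Pbar
        sl = slice(N // 2 + st.lo, N // 2 + st.lo + st.p)
        diff = np.abs(st.tables[1, 1] - dP_big[sl, sl]).max()
        assert diff < 0.05 * np.abs(dP_big).max()


class TestApply:
    def test_zero_weights_leave_field_unchanged(self, p):
        g = Grid(2, 32, 0.016)
        st = build_stencil(g.h, None, p, 2, r_min=1e-3)
        pts = _points([[0.008, 0.008], [0.004, 0.011]], [0.0, 0.0])
        P = np.random.default_rng(0).normal(size=g.shape)
        out = apply_correction(P, pts, st, g)
        assert np.array_equal(out, P)

    def test_correction_is_linear_in_sources(self, p):
        g = Grid(2, 32, 0.016)
        st = build_stencil(g.h, None, p, 2, r_min=1e-3)
        a = _points([0.008, 0.008], 2e-11)
        b = _points([0.006, 0.009], 3e-11)
        both = _points([[0.008, 0.008], [0.006, 0.009]], [2e-11, 3e-11])
        fa = correction_field(a, st, g)
        fb = correction_field(b, st, g)
        fab = correction_field(both, st, g)
        assert np.allclose(fab, fa + fb, rtol=1e-12, atol=1e-18)

    def test_stencil_mesh_mismatch_rejected(self, p):
        g = Grid(2, 32, 0.016)
        st = build_stencil(2 * g.h, None, p, 2, r_min=1e-3)
        with pytest.raises(ValueError, match="mesh size"):
            correction_field(_points([0.008, 0.008], 1e-11), st, g)

    def test_corrected_point_source_beats_uncorrected_near_field(self, p):
        # single interior point source on a 3D mesh: after correction the
        # near-field matches the analytic steady response much better
        g = Grid(3, 32, 0.064)
        rmin = 2e-4
        w = 2e-11
        x0 = np.array([0.032, 0.032, 0.032]) + g.h * np.array([0.3, 0.45, 0.2])
        pts = _points(x0, w, radius=rmin)
        S = spread(pts, g)
        # screened solve on the grid via an independent sparse oracle; the
        # screening length sqrt(D dt) stays well below the box size so the
        # closed-box response matches the free-space kernel locally
        dt = 5000.0
        n1 = g.n + 1
        T1 = sp.diags([np.ones(n1 - 1), -2 * np.ones(n1), np.ones(n1 - 1)],
                      [-1, 0, 1]).tolil()
        T1[0, 1] += 1.0
        T1[-1, -2] += 1.0
        T1 = (T1 / g.h**2).tocsr()
        I1 = sp.identity(n1)
        lap = (sp.kron(sp.kron(T1, I1), I1) + sp.kron(sp.kron(I1, T1), I1)
               + sp.kron(sp.kron(I1, I1), T1))
        A = sp.identity(n1**3) / dt - p.D_alpha * lap
        P = spla.spsolve(A.tocsr(), S.ravel()).reshape(g.shape)
        op = CorrectionOperator(g, dt, p)
        P_corr = P + op.field(pts)
        # analytic screened response at the 8 cell-corner nodes around x0
        base = np.floor(x0 / g.h).astype(int)
        err_raw, err_corr = [], []
        for corner in np.ndindex(2, 2, 2):
            idx = tuple(base + corner)
            rr = max(np.linalg.norm(np.array(idx) * g.h - x0), rmin)
            exact = w * point_source_response(rr, dt, p, 3)
            err_raw.append(abs(P[idx] - exact))
            err_corr.append(abs(P_corr[idx] - exact))
        assert max(err_corr) * 5 < max(err_raw)


def test_point_patches_agree_with_tabulated_stencil_on_lattice(p=default_params()):
    # per-point patches at exact offset-lattice positions must reproduce the
    # tabulated stencil (same operator, same kernel, no interpolation)
    g = Grid(2, 16, 0.008)
    st = build_stencil(g.h, None, p, 2, r_min=1e-3, offsets=4)
    from oxynet.correction import build_point_patches

    x0 = np.array([8 * g.h + g.h / 3, 8 * g.h + 2 * g.h / 3])
    pts = _points(x0, 1.0)
    patches, lin, ok = build_point_patches(pts, g, None, p)
    assert np.allclose(patches[0].reshape(8, 8), st.tables[1, 2], rtol=1e-10)
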