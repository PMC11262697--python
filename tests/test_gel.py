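"""Gel mechanics: thickness relation, traction stress, the implicit
displacement solve against an independent dense assembly, and
conservative density advection."""

import numpy as np
import pytest
from scipy.linalg import circulant

from capnet.gel import (GelState, MechanicsSolver, advect_conservative,
                        thickness, traction_field, update_density)
from capnet.params import GelParams


# -- independent dense operator assembly (Kronecker construction) --------

def _circ(n, stencil):
    col = np.zeros(n)
    for off, v in stencil.items():
        col[off % n] += v
    return circulant(col)


def dense_system(nx, ny, dx, p, dt, f):
    """Assemble the implicit-step operator and RHS builder as explicit
    matrices from 1-D circulant difference operators."""
    # circulant(col)[i, j] = col[i - j]; forward shift needs col[-1] = 1
    D1x = _circ(nx, {-1: 1 / (2 * dx), 1: -1 / (2 * dx)})
    D1y = _circ(ny, {-1: 1 / (2 * dx), 1: -1 / (2 * dx)})
    L1x = _circ(nx, {-1: 1 / dx ** 2, 1: 1 / dx ** 2, 0: -2 / dx ** 2})
    L1y = _circ(ny, {-1: 1 / dx ** 2, 1: 1 / dx ** 2, 0: -2 / dx ** 2})
    Ix, Iy = np.eye(nx), np.eye(ny)
    Dx = np.kron(D1x, Iy)
    Dy = np.kron(Ix, D1y)
    Lap = np.kron(L1x, Iy) + np.kron(Ix, L1y)
    N = nx * ny
    Z = np.zeros((N, N))
    BL = np.block([[Lap, Z], [Z, Lap]])
    GD = np.block([[Dx @ Dx, Dx @ Dy], [Dy @ Dx, Dy @ Dy]])
    c1 = p.E / (1 + p.nu)
    cnu = p.nu / (1 - 2 * p.nu)
    A_vis = (p.mu1 / 2) * BL + (p.mu1 / 2 + p.mu2) * GD
    A_el = c1 * (0.5 * BL + (0.5 + cnu) * GD) \
        - c1 * (0.5 * p.beta1 * (BL @ BL + GD @ BL)
                + cnu * p.beta2 * (BL @ GD))
    F = np.diag(np.concatenate([f.ravel(), f.ravel()]))
    M = A_vis / dt + A_el - F @ (c1 * (np.eye(2 * N) - p.beta1 * BL)) \
        - F * (p.mu1 / dt)
    return M, A_vis, F, Dx, Dy


@pytest.mark.parametrize("rho_rel, expected", [
    (1.0, 300.0),
    (1.01, 336.0),
])
def test_thickness_relation(rho_rel, expected):
    """h(rho0) = h0 fixes the bracket grouping; at nu = 0.48 a 1% density
    rise thickens the gel to 336 um."""
    p = GelParams()
    h = thickness(np.array([rho_rel * p.rho0]), p)
    assert h[0] == pytest.approx(expected, rel=1e-6)


def test_thickness_floor():
    p = GelParams()
    h = thickness(np.array([0.5 * p.rho0]), p)  # bracket goes negative
    assert h[0] == p.h_min


def test_poisson_half_rejected():
    with pytest.raises(ValueError):
        GelParams(nu=0.5).validate()


def test_traction_field():
    p = GelParams()
    mask = np.zeros((6, 6))
    mask[2, 3] = 1
    rho = np.full((6, 6), p.rho0)
    tr = traction_field(mask, rho, p.kappa)
    assert tr[2, 3] == pytest.approx(4.0e4)      # kappa * rho0
    assert tr.sum() == pytest.approx(4.0e4)      # zero elsewhere
    assert traction_field(np.zeros((6, 6)), rho, p.kappa).max() == 0.0
    rho0_zero = rho.copy()
    rho0_zero[2, 3] = 0.0
    assert traction_field(mask, rho0_zero, p.kappa)[2, 3] == 0.0


def test_zero_traction_stays_zero():
    p = GelParams()
    gel = GelState.uniform((16, 16), p)
    s = MechanicsSolver((16, 16), 10.0, p, 120.0)
    for _ in range(3):
        u = s.solve(gel, np.zeros((16, 16)))
    assert np.abs(u).max() == 0.0


def test_uniform_traction_relaxes_to_zero():
    """Spatially uniform traction has zero divergence on the periodic
    domain: the displacement stays (relaxes to) zero."""
    p = GelParams()
    gel = GelState.uniform((16, 16), p)
    s = MechanicsSolver((16, 16), 10.0, p, 120.0)
    tr = np.full((16, 16), p.kappa * p.rho0)
    u = s.solve(gel, tr)
    assert np.abs(u).max() < 1e-10


def test_solver_matches_dense_direct_solve():
    """Matrix-free preconditioned solve vs an independent dense assembly
    on a 32x32 grid with spatially varying friction and a traction spot."""
    p = GelParams()
    nx = ny = 32
    dx, dt = 10.0, 120.0
    rng = np.random.default_rng(0)
    rho = p.rho0 * (1 + 0.05 * rng.standard_normal((nx, ny)))
    h = thickness(rho, p)
    f = 1.0 / h ** 2
    mask = np.zeros((nx, ny))
    mask[12:17, 10:14] = 1
    tr = traction_field(mask, rho, p.kappa)
    gel = GelState(rho=rho, u=np.zeros((2, nx, ny)), h=h,
                   du_dt=np.zeros((2, nx, ny)))
    solver = MechanicsSolver((nx, ny), dx, p, dt)
    u = solver.solve(gel, tr)

    M, A_vis, F, Dx, Dy = dense_system(nx, ny, dx, p, dt, f)
    rhs = -np.concatenate([Dx @ tr.ravel(), Dy @ tr.ravel()])  # u_n = 0
    ud = np.linalg.solve(M, rhs).reshape(2, nx, ny)
    assert np.abs(u - ud).max() < 1e-6 * np.abs(ud).max()
    # displacement points inward toward the traction spot
    assert u[0, 8, 12] > 0 and u[0, 22, 12] < 0


def test_beta_zero_reduces_to_local_problem():
    """With beta1 = beta2 = 0 the long-range stress vanishes: the
    solution coincides with the purely local viscoelastic problem."""
    p0 = GelParams(beta1=0.0, beta2=0.0)
    nx = ny = 24
    rng = np.random.default_rng(3)
    rho = p0.rho0 * (1 + 0.03 * rng.standard_normal((nx, ny)))
    mask = (rng.random((nx, ny)) < 0.2).astype(float)
    tr = traction_field(mask, rho, p0.kappa)
    h = thickness(rho, p0)
    gel = GelState(rho=rho, u=np.zeros((2, nx, ny)), h=h,
                   du_dt=np.zeros((2, nx, ny)))
    u = MechanicsSolver((nx, ny), 10.0, p0, 120.0).solve(gel, tr)
    M, _, _, Dx, Dy = dense_system(nx, ny, 10.0, p0, 120.0, 1.0 / h ** 2)
    rhs = -np.concatenate([Dx @ tr.ravel(), Dy @ tr.ravel()])
    ud = np.linalg.solve(M, rhs).reshape(2, nx, ny)
    assert np.abs(u - ud).max() < 1e-6 * np.abs(ud).max()


class TestDensityAdvection:
    def test_zero_velocity_noop(self):
        rho = np.random.default_rng(0).random((12, 12)) + 0.5
        out, clips = update_density(rho, np.zeros((2, 12, 12)), 120.0, 10.0)
        assert np.array_equal(out, rho)
        assert clips == 0

    def test_uniform_translation_conserves_mass(self):
        rho = np.zeros((24, 24))
        rho[8:16, 8:16] = 1.0 + np.arange(8)[:, None] * 0.1  # compact blob
        v = np.zeros((2, 24, 24))
        v[0] = 0.02  # um/s
        out = rho
        for _ in range(5):
            out, clips = update_density(out, v, 120.0, 10.0)
            assert clips == 0
        assert out.sum() == pytest.approx(rho.sum(), rel=1e-12)
        # centre of mass moved along +x by ~ v * t (blob stays interior)
        x = np.arange(24)
        com0 = (rho.sum(axis=1) * x).sum() / rho.sum()
        com1 = (out.sum(axis=1) * x).sum() / out.sum()
        assert (com1 - com0) * 10.0 == pytest.approx(0.02 * 600.0, rel=0.1)

    def test_convergent_flow_concentrates_at_sink(self):
        """A velocity field converging on a point raises the density
        there; mass is conserved to < 1e-6 relative (machine precision
        for the flux-form scheme)."""
        nx = ny = 32
        x = (np.arange(nx) - nx / 2)[:, None] * np.ones((1, ny))
        y = np.ones((nx, 1)) * (np.arange(ny) - ny / 2)[None, :]
        v = np.zeros((2, nx, ny))
        v[0] = -0.01 * np.sign(x)
        v[1] = -0.01 * np.sign(y)
        rho = np.full((nx, ny), 1.0)
        out = rho
        for _ in range(20):
            out, _ = advect_conservative(out, v, 120.0, 10.0)
        assert out[nx // 2, ny // 2] > 1.5
        assert abs(out.sum() - rho.sum()) / rho.sum() < 1e-6

    def test_cfl_substepping(self):
        """Fast flows are integrated with internal substeps instead of
        blowing up."""
        rng = np.random.default_rng(2)
        rho = rng.random((16, 16)) + 0.5
        v = np.zeros((2, 16, 16))
        v[0] = 0.5  # CFL = v dt / dx = 6 without substepping
        out, _ = advect_conservative(rho, v, 120.0, 10.0)
        assert np.isfinite(out).all()
        assert out.min() >= 0
        assert out.sum() == pytest.approx(rho.sum(), rel=1e-12)
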