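"""Continuum biogel mechanics on the periodic grid.

The gel is a viscoelastic sheet pulled by cell traction.  A quasi-static
force balance equates the divergence of four stresses -- isotropic cell
traction ``kappa*rho`` on occupied sites, viscous stress from strain and
dilatation rates, local Hookean elasticity, and a long-range (Laplacian
of strain) fibre-elasticity term -- to a Petri-dish friction force that
scales with 1/h^2 of the local gel thickness.  Gel density is advected
conservatively by the displacement rate, and thickness follows density
through a linearized Poisson-effect relation.

Discretization: second-order central differences on the periodic grid;
the displacement update is implicit in the viscous and friction rate
terms and solved matrix-free (BiCGStab) with an exact FFT inverse of the
constant-coefficient operator as preconditioner, warm-started from the
previous step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, bicgstab, lgmres

from .params import GelParams


# -- discrete operators (periodic, central differences) ------------------

def _ddx(f, dx):
    return (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2.0 * dx)


def _ddy(f, dx):
    return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2.0 * dx)


def _lap(f, dx):
    return (np.roll(f, -1, axis=0) + np.roll(f, 1, axis=0)
            + np.roll(f, -1, axis=1) + np.roll(f, 1, axis=1) - 4.0 * f) / dx ** 2


def _grad_div(u, dx):
    div = _ddx(u[0], dx) + _ddy(u[1], dx)
    return np.stack([_ddx(div, dx), _ddy(div, dx)])


def _lap_vec(u, dx):
    return np.stack([_lap(u[0], dx), _lap(u[1], dx)])


@dataclass
class GelState:
    """Gel density, displacement, displacement rate and thickness fields."""

    rho: np.ndarray                 # ng/um^3, (nx, ny)
    u: np.ndarray                   # um, (2, nx, ny)
    h: np.ndarray                   # um, (nx, ny)
    du_dt: np.ndarray               # um/s, (2, nx, ny)
    clip_events: int = 0            # density negativity clips (logged)
    clamp_fraction: float = 0.0     # fraction of sites at the h_min floor
    last_residual: float = 0.0
    last_iterations: int = 0

    @classmethod
    def uniform(cls, shape, params: GelParams) -> "GelState":
        nx, ny = shape
        return cls(rho=np.full((nx, ny), params.rho0),
                   u=np.zeros((2, nx, ny)),
                   h=np.full((nx, ny), params.h0),
                   du_dt=np.zeros((2, nx, ny)))

    def total_mass(self, dx: float) -> float:
        return float(self.rho.sum() * dx * dx)


def traction_field(cell_mask, rho, kappa) -> np.ndarray:
    """Isotropic cell traction stress kappa*rho on occupied sites (Pa)."""
    return kappa * np.asarray(rho, float) * (np.asarray(cell_mask) > 0)


def thickness(rho, params: GelParams, out_clamped=None) -> np.ndarray:
    """Gel thickness from density: h = h0[(1-3v)/(1-2v) + v/(1-2v) rho/rho0].

    The grouping is fixed by the consistency condition h(rho0) = h0.  The
    relation is a linearization around rho0, so h is floored at ``h_min``
    (the friction term divides by h^2)."""
    v = params.nu
    c = 1.0 / (1.0 - 2.0 * v)
    h = params.h0 * ((1.0 - 3.0 * v) * c + v * c * np.asarray(rho, float) / params.rho0)
    clamped = h < params.h_min
    if out_clamped is not None:
        out_clamped[:] = clamped
    return np.where(clamped, params.h_min, h)


class MechanicsSolver:
    """Implicit displacement solver, reusable across steps (caches the FFT
    preconditioner symbols and the previous solution as warm start)."""

    def __init__(self, shape, dx, params: GelParams, dt,
                 rtol=1e-9, maxiter=500):
        self.nx, self.ny = shape
        self.dx = float(dx)
        self.p = params
        self.dt = float(dt)
        self.rtol = rtol
        self.maxiter = maxiter
        p = params
        self.c1 = p.E / (1.0 + p.nu)
        self.cnu = p.nu / (1.0 - 2.0 * p.nu)
        # FFT symbols of the discrete operators
        kx = 2.0 * np.pi * np.fft.fftfreq(self.nx)
        ky = 2.0 * np.pi * np.fft.rfftfreq(self.ny)
        tx, ty = np.meshgrid(kx, ky, indexing="ij")
        self._s1 = np.sin(tx) / self.dx
        self._s2 = np.sin(ty) / self.dx
        self._L = (2.0 * np.cos(tx) - 2.0 + 2.0 * np.cos(ty) - 2.0) / self.dx ** 2

    # full operator ------------------------------------------------------

    def _a_vis(self, u):
        p = self.p
        return (0.5 * p.mu1) * _lap_vec(u, self.dx) \
            + (0.5 * p.mu1 + p.mu2) * _grad_div(u, self.dx)

    def _a_el(self, u):
        p = self.p
        lap_u = _lap_vec(u, self.dx)
        gd = _grad_div(u, self.dx)
        lin = self.c1 * (0.5 * lap_u + (0.5 + self.cnu) * gd)
        lr = -self.c1 * (0.5 * p.beta1 * (_lap_vec(lap_u, self.dx)
                                          + _grad_div(lap_u, self.dx))
                         + self.cnu * p.beta2 * _lap_vec(gd, self.dx))
        return lin + lr

    def _matvec_fields(self, u, f):
        p = self.p
        mu = self._a_vis(u) / self.dt + self._a_el(u)
        mu -= f * (self.c1 * (u - p.beta1 * _lap_vec(u, self.dx)))
        mu -= (f * p.mu1 / self.dt) * u
        return mu

    # preconditioner -----------------------------------------------------

    def _precond_blocks(self, fbar):
        p = self.p
        L, s1, s2 = self._L, self._s1, self._s2
        gcoef = ((0.5 * p.mu1 + p.mu2) / self.dt + self.c1 * (0.5 + self.cnu)
                 - self.c1 * (0.5 * p.beta1 + self.cnu * p.beta2) * L)
        a = ((0.5 * p.mu1 / self.dt) * L
             + self.c1 * (0.5 * L - 0.5 * p.beta1 * L * L)
             - fbar * self.c1 * (1.0 - p.beta1 * L) - fbar * p.mu1 / self.dt)
        g11 = -gcoef * s1 * s1
        g12 = -gcoef * s1 * s2
        g22 = -gcoef * s2 * s2
        m11 = a + g11
        m22 = a + g22
        det = m11 * m22 - g12 * g12
        return m11, g12, m22, det

    def solve(self, gel: GelState, traction, u_prev=None):
        """Advance the displacement field by one implicit step.

        ``traction`` is the scalar isotropic cell stress field (Pa).
        Returns the new displacement; also updates ``gel.u``, ``gel.du_dt``
        and the solver diagnostics on ``gel``.
        """
        nx, ny, dx = self.nx, self.ny, self.dx
        f = 1.0 / gel.h ** 2
        un = gel.u if u_prev is None else u_prev
        rhs = -np.stack([_ddx(traction, dx), _ddy(traction, dx)])
        rhs += self._a_vis(un) / self.dt
        rhs -= (f * self.p.mu1 / self.dt) * un

        m11, m12, m22, det = self._precond_blocks(float(f.mean()))

        def matvec(vec):
            u = vec.reshape(2, nx, ny)
            return self._matvec_fields(u, f).ravel()

        def psolve(vec):
            r = vec.reshape(2, nx, ny)
            r0 = np.fft.rfft2(r[0])
            r1 = np.fft.rfft2(r[1])
            x0 = (m22 * r0 - m12 * r1) / det
            x1 = (m11 * r1 - m12 * r0) / det
            return np.stack([np.fft.irfft2(x0, s=(nx, ny)),
                             np.fft.irfft2(x1, s=(nx, ny))]).ravel()

        n2 = 2 * nx * ny
        A = LinearOperator((n2, n2), matvec=matvec)
        M = LinearOperator((n2, n2), matvec=psolve)
        bvec = rhs.ravel()
        bnorm = np.linalg.norm(bvec)
        if bnorm == 0.0:
            u_new = np.zeros_like(un)
            gel.last_residual = 0.0
            gel.last_iterations = 0
        else:
            it = [0]

            def cb(xk):
                it[0] += 1

            x, info = bicgstab(A, bvec, x0=un.ravel(), M=M,
                               rtol=self.rtol, atol=0.0,
                               maxiter=self.maxiter, callback=cb)
            res = np.linalg.norm(matvec(x) - bvec) / bnorm
            if info != 0 or not np.isfinite(res):
                # fall back to LGMRES before giving up
                x, info = lgmres(A, bvec, x0=x if np.all(np.isfinite(x)) else None,
                                 M=M, rtol=self.rtol, atol=0.0, maxiter=200)
                res = np.linalg.norm(matvec(x) - bvec) / bnorm
                if info != 0 and res > 1e-6:
                    raise RuntimeError(
                        f"mechanics solve did not converge: relative residual {res:.3e}")
            gel.last_residual = float(res)
            gel.last_iterations = it[0]
            u_new = x.reshape(2, nx, ny)
        gel.du_dt = (u_new - gel.u) / self.dt
        gel.u = u_new
        return u_new


def solve_displacement_step(gel: GelState, cell_mask, params: GelParams,
                            dt, dx, solver: MechanicsSolver | None = None):
    """One implicit displacement step under the current cell traction.

    Convenience wrapper constructing a throwaway :class:`MechanicsSolver`;
    the driver keeps a persistent solver for warm starts."""
    if solver is None:
        solver = MechanicsSolver(gel.rho.shape, dx, params, dt)
    tr = traction_field(cell_mask, gel.rho, params.kappa)
    return solver.solve(gel, tr)


# -- conservative advection ----------------------------------------------

def advect_conservative(field, vel, dt, dx, cfl=0.4):
    """First-order upwind advection in conservative flux form, periodic.

    ``vel`` has shape (2, nx, ny) at cell centres; face velocities are the
    arithmetic means.  Internal substepping enforces the CFL bound so the
    scheme never blows up silently.  Returns (advected field, clip count);
    with the CFL bound the scheme is positivity-preserving, so the clip
    count stays 0 in practice (clipping renormalizes mass and is logged).
    """
    f = np.asarray(field, float).copy()
    vmax = np.abs(vel).max()
    nsub = max(1, int(np.ceil(vmax * dt / (cfl * dx))))
    dts = dt / nsub
    clips = 0
    for _ in range(nsub):
        for axis in (0, 1):
            v = vel[axis]
            vf = 0.5 * (v + np.roll(v, -1, axis=axis))        # face i+1/2
            up = np.where(vf > 0.0, f, np.roll(f, -1, axis=axis))
            flux = vf * up
            f = f - dts / dx * (flux - np.roll(flux, 1, axis=axis))
        if f.min() < 0.0:
            clips += 1
            total = f.sum()
            f = np.clip(f, 0.0, None)
            if f.sum() > 0:
                f *= total / f.sum()
    return f, clips


def update_density(rho, du_dt, dt, dx):
    """Advect the gel density by the displacement rate (mass-conserving).

    Returns (new rho, clip events)."""
    return advect_conservative(rho, du_dt, dt, dx)
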