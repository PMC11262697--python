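"""Two-species VEGF dynamics: diffusing soluble VEGF exchanging with a
finite pool of gel-bound binding sites, with the bound form advected along
with the deforming gel.

The free-binding-site concentration is ``gamma*rho - mw_ratio*b`` where
``mw_ratio = M_FN/M_VEGF`` converts bound-VEGF mass into occupied
fibronectin mass.  The exchange terms in the two equations are equal and
opposite, so the total VEGF content is a conserved quantity; the solver
preserves it to machine precision (implicit FFT diffusion keeps the mean,
kinetics exchange pointwise, advection is in conservative flux form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gel import advect_conservative
from .params import VegfParams


@dataclass
class VegfState:
    c: np.ndarray   # soluble concentration, ng/um^3
    b: np.ndarray   # bound concentration, ng/um^3

    @classmethod
    def initial(cls, shape, params: VegfParams) -> "VegfState":
        """Uniform soluble VEGF at c0; no bound VEGF at seeding time."""
        return cls(c=np.full(shape, params.c0), b=np.zeros(shape))

    def total(self, dx: float) -> float:
        return float((self.c.sum() + self.b.sum()) * dx * dx)


class _Diffuser:
    """Backward-Euler diffusion via the FFT symbol of the 5-point Laplacian."""

    def __init__(self, shape, dx, D, dt):
        nx, ny = shape
        tx = 2.0 * np.pi * np.fft.fftfreq(nx)[:, None]
        ty = 2.0 * np.pi * np.fft.rfftfreq(ny)[None, :]
        L = (2.0 * np.cos(tx) - 2.0 + 2.0 * np.cos(ty) - 2.0) / dx ** 2
        self._denom = 1.0 - dt * D * L
        self._shape = shape

    def step(self, f):
        return np.fft.irfft2(np.fft.rfft2(f) / self._denom, s=self._shape)


def _kinetics(c, b, rho, params: VegfParams, dt):
    """Pointwise mass-action exchange over dt with RK4 substepping.

    Within the kinetics stage c + b =: s is pointwise constant, so only
    the bound concentration is integrated:
        db/dt = k_on (s - b)(gamma*rho - mw*b) - k_off*b.
    Substeps are chosen from the local linearized rate so RK4 stays well
    inside its stability/accuracy region; b is kept inside its physical
    box [0, min(s, gamma*rho/mw)] (an overshoot triggers extra substeps).
    """
    s = c + b
    cap = params.gamma * np.asarray(rho, float)
    mw = params.mw_ratio
    rate = params.k_on * (cap + mw * s) + params.k_off
    nsub = max(1, int(np.ceil(dt * float(rate.max()) / 0.25)))
    dts = dt / nsub
    bmax = np.minimum(s, cap / mw)
    for _ in range(nsub):
        def f(bb):
            return params.k_on * (s - bb) * (cap - mw * bb) - params.k_off * bb
        k1 = f(b)
        k2 = f(b + 0.5 * dts * k1)
        k3 = f(b + 0.5 * dts * k2)
        k4 = f(b + dts * k3)
        b = b + dts / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(b, 0.0, bmax, out=b)
    return s - b, b


def step_vegf(c, b, rho, du_dt, params: VegfParams, dt, dx,
              diffuser: _Diffuser | None = None):
    """Advance (c, b) by one interval: implicit diffusion of c, upwind
    advection of b with the gel, then pointwise binding kinetics.

    Returns (c, b, clip_events)."""
    if diffuser is None:
        diffuser = _Diffuser(np.shape(c), dx, params.D_c, dt)
    c = diffuser.step(np.asarray(c, float))
    clips = 0
    if du_dt is not None and np.any(du_dt):
        b, clips = advect_conservative(b, du_dt, dt, dx)
    else:
        b = np.asarray(b, float).copy()
    c, b = _kinetics(c, b, rho, params, dt)
    return c, b, clips


def equilibrium_binding(total, rho, params: VegfParams):
    """Well-mixed fixed point of the binding kinetics.

    Solves k_on c (gamma*rho - mw*b) = k_off b with c = total - b for the
    physically admissible root 0 <= b <= min(total, gamma*rho/mw).
    Accepts scalars or arrays.  Returns (c_eq, b_eq)."""
    total = np.asarray(total, float)
    cap = params.gamma * np.asarray(rho, float)
    mw = params.mw_ratio
    A = params.k_on * mw
    B = params.k_on * (cap + mw * total) + params.k_off
    C = params.k_on * cap * total
    disc = np.sqrt(np.maximum(B * B - 4.0 * A * C, 0.0))
    # smaller quadratic root is the admissible one; numerically stable form
    b = np.where(B > 0, 2.0 * C / (B + disc), 0.0)
    b = np.minimum(b, np.minimum(total, cap / mw))
    c = total - b
    if np.ndim(total) == 0 and np.ndim(rho) == 0:
        return float(c), float(b)
    return c, b
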