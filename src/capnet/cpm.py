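"""Cellular Potts dynamics of endothelial cells on a periodic lattice.

Each cell is a connected (in practice) set of lattice sites identified by
a positive integer index; empty medium is index 0.  The system evolves by
Metropolis-accepted copy attempts biased by a haptotaxis term on the
bound-VEGF field, under a Hamiltonian with interface, area, perimeter and
head-to-tail-length terms.  Round cells switch irreversibly to an
elongated morphology at a rate set by the local soluble VEGF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _cpm_kernels as _k
from .params import PottsParams

#: lattice offsets of the 21-site quasi-disk initial cell footprint
#: (rows of widths 3/5/5/5/3 around the centre; ~50 um across at dx = 10 um)
FOOTPRINT_21 = np.array(
    [(ox, oy)
     for oy, half in zip(range(-2, 3), (1, 2, 2, 2, 1))
     for ox in range(-half, half + 1)],
    dtype=np.int64,
)


class LatticeState:
    """CPM grid plus per-cell registry and cached geometry.

    Parameters
    ----------
    grid
        int array (nx, ny) of cell indices (0 = empty).  Copied.
    dx
        lattice spacing in um.
    n_cells
        number of cell indices (defaults to ``grid.max()``).
    site_capacity
        per-cell site-list capacity; the quadratic area restraint makes
        cells larger than a few times the target area unreachable.
    """

    def __init__(self, grid, dx=10.0, n_cells=None, site_capacity=160):
        grid = np.array(grid, dtype=np.int32, order="C", copy=True)
        if grid.min() < 0:
            raise ValueError("cell indices must be non-negative")
        self.grid = grid
        self.nx, self.ny = grid.shape
        self.dx = float(dx)
        self.n_cells = int(grid.max()) if n_cells is None else int(n_cells)
        cap = int(site_capacity)
        counts = np.bincount(grid.ravel(), minlength=self.n_cells + 1)
        if counts.max(initial=0) > cap:
            cap = int(counts.max()) + 32
        n1 = self.n_cells + 1
        self.sites_x = np.zeros((n1, cap), dtype=np.int32)
        self.sites_y = np.zeros((n1, cap), dtype=np.int32)
        self.n_sites = np.zeros(n1, dtype=np.int32)
        self.pos_idx = np.full((self.nx, self.ny), -1, dtype=np.int32)
        self.perim_edges = np.zeros(n1, dtype=np.int32)
        self.empty_edges = np.zeros(n1, dtype=np.int32)
        self.phi = np.zeros(n1, dtype=np.uint8)
        self.length = np.full(n1, -1.0, dtype=np.float64)
        self.refresh_caches()

    # -- bookkeeping -----------------------------------------------------

    def refresh_caches(self) -> None:
        """Rebuild all cached geometry from the grid (full scan)."""
        _k.recompute_geometry(self.grid, self.sites_x, self.sites_y,
                              self.n_sites, self.pos_idx, self.perim_edges,
                              self.empty_edges, self.phi, self.length)

    def check_consistency(self) -> None:
        """Raise if the cached registry disagrees with the grid."""
        counts = np.bincount(self.grid.ravel(), minlength=self.n_cells + 1)
        if not np.array_equal(counts[1:], self.n_sites[1:]):
            raise AssertionError("cached areas disagree with the grid")
        for s in range(1, self.n_cells + 1):
            for i in range(self.n_sites[s]):
                x, y = self.sites_x[s, i], self.sites_y[s, i]
                if self.grid[x, y] != s or self.pos_idx[x, y] != i:
                    raise AssertionError("site list / grid mismatch")

    @property
    def occupancy(self):
        """tau field: 1 on cell-occupied sites, 0 elsewhere."""
        return (self.grid > 0).astype(np.uint8)

    def areas(self):
        """Cell areas in um^2, indexed by cell id (entry 0 unused)."""
        return self.n_sites.astype(float) * self.dx ** 2

    def live_cells(self):
        return np.nonzero(self.n_sites[1:])[0] + 1

    def centroids(self):
        """Periodic-aware cell centroids in um, shape (n_cells+1, 2)."""
        out = np.zeros((self.n_cells + 1, 2))
        _k.centroids(self.sites_x, self.sites_y, self.n_sites,
                     self.nx, self.ny, out)
        return out * self.dx

    def copy(self) -> "LatticeState":
        new = LatticeState(self.grid, dx=self.dx, n_cells=self.n_cells,
                           site_capacity=self.sites_x.shape[1])
        new.phi[:] = self.phi
        new.refresh_caches()
        return new


@dataclass
class CellRecord:
    """Snapshot of one cell's bookkeeping (see :func:`cell_geometry`)."""

    id: int
    phi: int
    area: float        # um^2
    perimeter: float   # um
    length: float      # um (head-to-tail, periodic minimal image)
    free_boundary_fraction: float  # r_sigma
    centroid: tuple


def cell_geometry(lattice: LatticeState, sigma: int) -> CellRecord:
    """Geometry of cell ``sigma``: area, perimeter, head-to-tail length,
    free-boundary fraction and periodic centroid."""
    if not 1 <= sigma <= lattice.n_cells or lattice.n_sites[sigma] == 0:
        raise KeyError(f"no live cell with index {sigma}")
    m = int(lattice.n_sites[sigma])
    ell = _k.max_pairwise(lattice.sites_x[sigma], lattice.sites_y[sigma],
                          m, -1, lattice.nx, lattice.ny) * lattice.dx
    pe = int(lattice.perim_edges[sigma])
    r = lattice.empty_edges[sigma] / pe if pe > 0 else 0.0
    cen = lattice.centroids()[sigma]
    return CellRecord(id=sigma, phi=int(lattice.phi[sigma]),
                      area=m * lattice.dx ** 2, perimeter=pe * lattice.dx,
                      length=ell, free_boundary_fraction=float(r),
                      centroid=(float(cen[0]), float(cen[1])))


# -- energies ------------------------------------------------------------

def hamiltonian(lattice: LatticeState, params: PottsParams) -> float:
    """Total system energy (a.e.u.): interface + area + perimeter + length.

    Reference implementation by direct summation over all neighbour pairs;
    the Monte-Carlo kernel never evaluates it (it works with local energy
    differences), so this doubles as the oracle for those increments.
    """
    g = lattice.grid
    tau = (g > 0).astype(np.intp)
    jm = params.j_matrix
    w2 = params.neighbor_weight_order2
    e = 0.0
    # unordered pairs: shift by 4 unique offsets
    for (ox, oy), w in ((( 1, 0), 1.0), ((0, 1), 1.0),
                        (( 1, 1), w2), ((1, -1), w2)):
        gn = np.roll(np.roll(g, -ox, axis=0), -oy, axis=1)
        taun = np.roll(np.roll(tau, -ox, axis=0), -oy, axis=1)
        diff = g != gn
        e += w * lattice.dx * np.sum(jm[tau, taun] * diff)
    for s in range(1, lattice.n_cells + 1):
        m = lattice.n_sites[s]
        if m == 0:
            continue
        a = m * lattice.dx ** 2
        e += params.lambda_a * (a - params.a0) ** 2
        e += params.lambda_p * lattice.perim_edges[s] * lattice.dx
        if lattice.phi[s] == 1:
            ell = _k.max_pairwise(lattice.sites_x[s], lattice.sites_y[s],
                                  int(m), -1, lattice.nx, lattice.ny) * lattice.dx
            e += params.lambda_l / max(ell, lattice.dx)
    return float(e)


def delta_h(lattice: LatticeState, params: PottsParams, x, xprime) -> float:
    """Energy change of copying the state at site ``x`` onto ``xprime``.

    Computed incrementally from locally affected terms; exactly equal to
    ``hamiltonian(after) - hamiltonian(before)``.
    """
    xs, ys = x
    xt, yt = xprime
    if lattice.grid[xs, ys] == lattice.grid[xt, yt]:
        return 0.0
    dH, _, _ = _k.delta_h(lattice.grid, lattice.sites_x, lattice.sites_y,
                          lattice.n_sites, lattice.phi, lattice.length,
                          xs, ys, xt, yt, params.j_matrix,
                          params.neighbor_weight_order2, lattice.dx,
                          params.lambda_a, params.lambda_p, params.lambda_l,
                          params.a0)
    return float(dH)


def haptotaxis_bias(dH, b_field, x, xprime, params: PottsParams,
                    occupancy=None, lattice: LatticeState | None = None):
    """Haptotaxis-modified energy change.

    dH_m = dH - mu_h (b_x' - b_x) (1 - delta_{tau_x tau_x'}); the bias
    vanishes when both sites share the same occupancy state (in particular
    when both are cell-occupied: contact inhibition).
    """
    if occupancy is None:
        occupancy = lattice.occupancy
    xs, ys = x
    xt, yt = xprime
    if occupancy[xs, ys] == occupancy[xt, yt]:
        return float(dH)
    return float(dH - params.mu_h * (b_field[xt, yt] - b_field[xs, ys]))


def acceptance_probability(dHm) -> float:
    """Metropolis rule at fixed unit temperature: 1 if dHm <= 0 else exp(-dHm)."""
    dHm = float(dHm)
    return 1.0 if dHm <= 0.0 else float(np.exp(-dHm))


# -- dynamics ------------------------------------------------------------

def monte_carlo_step(lattice: LatticeState, b_field, params: PottsParams,
                     rng_state, haptotaxis_on: bool = True) -> int:
    """One MCS: nx*ny copy attempts (source extends onto a 1st/2nd-order
    neighbour, diagonal picks down-weighted).  Returns accepted count."""
    mu_h = params.mu_h if haptotaxis_on else 0.0
    if b_field is None:
        b_field = np.zeros((lattice.nx, lattice.ny))
    return int(_k.mcs_sweep(
        lattice.grid, lattice.sites_x, lattice.sites_y, lattice.n_sites,
        lattice.pos_idx, lattice.perim_edges, lattice.empty_edges,
        lattice.phi, lattice.length, np.ascontiguousarray(b_field, float),
        rng_state, params.j_matrix, params.neighbor_weight_order2,
        lattice.dx, params.lambda_a, params.lambda_p, params.lambda_l,
        params.a0, mu_h, lattice.sites_x.shape[1] - 1))


def morphology_update(lattice: LatticeState, c_field, params: PottsParams,
                      rng_state) -> int:
    """Evaluate the irreversible elongation switch once for every round
    cell; returns the number of cells that switched this MCS."""
    return int(_k.morphology_sweep(
        lattice.sites_x, lattice.sites_y, lattice.n_sites,
        lattice.perim_edges, lattice.empty_edges, lattice.phi,
        lattice.length, np.ascontiguousarray(c_field, float), rng_state,
        params.mu_m, lattice.nx, lattice.ny))


def initialize_cells(n_cells, lattice_shape, rng, dx=10.0,
                     footprint=None, max_tries_per_cell=2000) -> LatticeState:
    """Place ``n_cells`` disjoint copies of the 21-site quasi-disk footprint
    uniformly at random on the periodic lattice (rejection sampling)."""
    nx, ny = lattice_shape
    fp = FOOTPRINT_21 if footprint is None else np.asarray(footprint)
    grid = np.zeros((nx, ny), dtype=np.int32)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for s in range(1, n_cells + 1):
        for _ in range(max_tries_per_cell):
            cx = int(rng.integers(nx))
            cy = int(rng.integers(ny))
            xs = (cx + fp[:, 0]) % nx
            ys = (cy + fp[:, 1]) % ny
            if not grid[xs, ys].any():
                grid[xs, ys] = s
                break
        else:
            raise RuntimeError(
                f"could not place cell {s}/{n_cells}: cell density too high")
    return LatticeState(grid, dx=dx, n_cells=n_cells)
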