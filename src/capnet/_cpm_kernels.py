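"""Numba inner loops for the Cellular Potts engine.

State layout (shared with :mod:`capnet.cpm`):

* ``grid``        int32 (nx, ny): cell index per site, 0 = empty.
* ``sites_x/y``   int32 (n_cells+1, cap): site coordinates per cell.
* ``n_sites``     int32 (n_cells+1): live site count per cell.
* ``pos_idx``     int32 (nx, ny): position of a site inside its owner's
                  site list (-1 on empty sites).
* ``perim_edges`` int32: first-order edges to a different cell or empty.
* ``empty_edges`` int32: first-order edges to empty sites.
* ``phi``         uint8: morphology flag (0 round, 1 elongated).
* ``length``      float64: head-to-tail length in lattice units; only
                  maintained for phi = 1 cells (-1 marks "not tracked").

All distances inside the kernels are in lattice units; callers convert
with the lattice spacing ``dx``.  The RNG is xorshift128+, seeded via
splitmix64, so runs are reproducible independent of NumPy's global state.
"""

import numpy as np
from numba import njit

# neighbour offsets: 4 first-order then 4 second-order (diagonal)
_NBR = np.array(
    [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)],
    dtype=np.int64,
)


@njit(cache=True, inline="always")
def _rng_next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 = s1 ^ s0 ^ (s1 >> np.uint64(18)) ^ (s0 >> np.uint64(5))
    state[1] = s1
    return s1 + s0


@njit(cache=True, inline="always")
def _rng_uniform(state):
    return float(_rng_next(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def seed_rng(seed):
    """Expand a 64-bit seed into an xorshift128+ state via splitmix64."""
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = t ^ (t >> np.uint64(31))
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(1)
    return state


@njit(cache=True, inline="always")
def _sqdist(x1, y1, x2, y2, nx, ny):
    mx = x1 - x2
    my = y1 - y2
    mx -= nx * int(np.rint(mx / nx))
    my -= ny * int(np.rint(my / ny))
    return float(mx * mx + my * my)


@njit(cache=True)
def max_dist_from_site(sites_x, sites_y, m, x, y, nx, ny):
    """Max minimal-image distance (lattice units) from (x, y) to m sites."""
    best = 0.0
    for i in range(m):
        d = _sqdist(x, y, sites_x[i], sites_y[i], nx, ny)
        if d > best:
            best = d
    return np.sqrt(best)


@njit(cache=True)
def max_pairwise(sites_x, sites_y, m, skip, nx, ny):
    """Max pairwise minimal-image distance, optionally skipping one index."""
    best = 0.0
    for i in range(m):
        if i == skip:
            continue
        for j in range(i + 1, m):
            if j == skip:
                continue
            d = _sqdist(sites_x[i], sites_y[i], sites_x[j], sites_y[j], nx, ny)
            if d > best:
                best = d
    return np.sqrt(best)


@njit(cache=True)
def recompute_geometry(grid, sites_x, sites_y, n_sites, pos_idx,
                       perim_edges, empty_edges, phi, length):
    """Rebuild all cached per-cell geometry from the grid (full scan)."""
    nx, ny = grid.shape
    n_sites[:] = 0
    perim_edges[:] = 0
    empty_edges[:] = 0
    pos_idx[:, :] = -1
    for x in range(nx):
        for y in range(ny):
            s = grid[x, y]
            if s <= 0:
                continue
            k = n_sites[s]
            sites_x[s, k] = x
            sites_y[s, k] = y
            pos_idx[x, y] = k
            n_sites[s] = k + 1
            for d in range(4):
                xn = (x + _NBR[d, 0]) % nx
                yn = (y + _NBR[d, 1]) % ny
                sn = grid[xn, yn]
                if sn != s:
                    perim_edges[s] += 1
                    if sn == 0:
                        empty_edges[s] += 1
    for s in range(1, length.shape[0]):
        if phi[s] == 1 and n_sites[s] > 0:
            length[s] = max_pairwise(sites_x[s], sites_y[s], n_sites[s], -1, nx, ny)
        else:
            length[s] = -1.0


@njit(cache=True, inline="always")
def _inv_len(l_lattice, dx):
    """1 / length with the one-lattice-unit floor, in 1/um."""
    l_um = l_lattice * dx
    if l_um < dx:
        l_um = dx
    return 1.0 / l_um


@njit(cache=True)
def delta_h(grid, sites_x, sites_y, n_sites, phi, length,
            xs, ys, xt, yt, jmat, w2, dx,
            lambda_a, lambda_p, lambda_l, a0):
    """Energy change of copying the state at (xs, ys) onto (xt, yt).

    Returns (dH, l_new_src, l_new_tgt): the candidate head-to-tail lengths
    of the gaining / losing cell (lattice units; -1 when untracked) so the
    caller can commit them without recomputation on acceptance.
    """
    nx, ny = grid.shape
    s = grid[xs, ys]
    t = grid[xt, yt]
    dH = 0.0

    # interface term: all pairs involving the target site
    taus = 1 if s > 0 else 0
    taut = 1 if t > 0 else 0
    for d in range(8):
        w = 1.0 if d < 4 else w2
        xn = (xt + _NBR[d, 0]) % nx
        yn = (yt + _NBR[d, 1]) % ny
        sn = grid[xn, yn]
        taun = 1 if sn > 0 else 0
        e_after = jmat[taus, taun] if s != sn else 0.0
        e_before = jmat[taut, taun] if t != sn else 0.0
        dH += w * dx * (e_after - e_before)

    dx2 = dx * dx
    # area terms
    if t > 0:
        a = n_sites[t] * dx2
        dH += lambda_a * ((a - dx2 - a0) ** 2 - (a - a0) ** 2)
    if s > 0:
        a = n_sites[s] * dx2
        dH += lambda_a * ((a + dx2 - a0) ** 2 - (a - a0) ** 2)

    # perimeter term: change in total boundary-edge count over affected cells
    d_edges = 0
    for d in range(4):
        xn = (xt + _NBR[d, 0]) % nx
        yn = (yt + _NBR[d, 1]) % ny
        sn = grid[xn, yn]
        if s > 0:
            d_edges += 1 if sn != s else 0
        if t > 0:
            d_edges -= 1 if sn != t else 0
        if sn > 0:
            d_edges += (1 if sn != s else 0) - (1 if sn != t else 0)
    dH += lambda_p * dx * d_edges

    # head-to-tail length term (only phi = 1 cells carry it)
    l_new_src = -1.0
    l_new_tgt = -1.0
    if s > 0 and phi[s] == 1:
        l_new_src = max_dist_from_site(sites_x[s], sites_y[s], n_sites[s],
                                       xt, yt, nx, ny)
        if length[s] > l_new_src:
            l_new_src = length[s]
        dH += lambda_l * (_inv_len(l_new_src, dx) - _inv_len(length[s], dx))
    if t > 0 and phi[t] == 1:
        k = -1
        # locate target inside t's list by scanning is avoided: caller
        # guarantees pos_idx valid; recompute without that site
        # (skip index passed from caller loop would need pos_idx; use search)
        for i in range(n_sites[t]):
            if sites_x[t, i] == xt and sites_y[t, i] == yt:
                k = i
                break
        l_new_tgt = max_pairwise(sites_x[t], sites_y[t], n_sites[t], k, nx, ny)
        dH += lambda_l * (_inv_len(l_new_tgt, dx) - _inv_len(length[t], dx))
    return dH, l_new_src, l_new_tgt


@njit(cache=True)
def _commit(grid, sites_x, sites_y, n_sites, pos_idx, perim_edges,
            empty_edges, phi, length, xs, ys, xt, yt, l_new_src, l_new_tgt):
    nx, ny = grid.shape
    s = grid[xs, ys]
    t = grid[xt, yt]
    # perimeter / empty-edge bookkeeping around the flipped site
    for d in range(4):
        xn = (xt + _NBR[d, 0]) % nx
        yn = (yt + _NBR[d, 1]) % ny
        sn = grid[xn, yn]
        if t > 0 and sn != t:
            perim_edges[t] -= 1
            if sn == 0:
                empty_edges[t] -= 1
        if s > 0 and sn != s:
            perim_edges[s] += 1
            if sn == 0:
                empty_edges[s] += 1
        if sn > 0:
            if sn != s and sn == t:
                perim_edges[sn] += 1
            elif sn == s and sn != t:
                perim_edges[sn] -= 1
            if sn != t and t == 0:
                empty_edges[sn] -= 1
            if sn != s and s == 0:
                empty_edges[sn] += 1
    # site lists
    if t > 0:
        k = pos_idx[xt, yt]
        last = n_sites[t] - 1
        sites_x[t, k] = sites_x[t, last]
        sites_y[t, k] = sites_y[t, last]
        pos_idx[sites_x[t, k], sites_y[t, k]] = k
        n_sites[t] = last
        if phi[t] == 1:
            length[t] = l_new_tgt
    if s > 0:
        k = n_sites[s]
        sites_x[s, k] = xt
        sites_y[s, k] = yt
        pos_idx[xt, yt] = k
        n_sites[s] = k + 1
        if phi[s] == 1:
            length[s] = l_new_src
        grid[xt, yt] = s
    else:
        grid[xt, yt] = 0
        pos_idx[xt, yt] = -1


@njit(cache=True)
def mcs_sweep(grid, sites_x, sites_y, n_sites, pos_idx, perim_edges,
              empty_edges, phi, length, b_field, rng_state,
              jmat, w2, dx, lambda_a, lambda_p, lambda_l, a0, mu_h, cap):
    """One Monte-Carlo step: nx*ny biased copy attempts.

    Returns the number of accepted copies.
    """
    nx, ny = grid.shape
    n_attempts = nx * ny
    sel_first = 4.0 / (4.0 + 4.0 * w2)  # probability mass of 1st-order picks
    accepted = 0
    for _ in range(n_attempts):
        xs = int(_rng_uniform(rng_state) * nx)
        ys = int(_rng_uniform(rng_state) * ny)
        u = _rng_uniform(rng_state)
        if u < sel_first:
            d = int(u / sel_first * 4.0)
            if d > 3:
                d = 3
        else:
            d = 4 + int((u - sel_first) / (1.0 - sel_first) * 4.0)
            if d > 7:
                d = 7
        xt = (xs + _NBR[d, 0]) % nx
        yt = (ys + _NBR[d, 1]) % ny
        s = grid[xs, ys]
        t = grid[xt, yt]
        if s == t:
            continue
        if t > 0 and n_sites[t] <= 1:
            continue  # annihilation guard: cell count is conserved
        if s > 0 and n_sites[s] >= cap:
            continue  # site-list capacity guard (area restraint makes this moot)
        dH, l_ns, l_nt = delta_h(grid, sites_x, sites_y, n_sites, phi, length,
                                 xs, ys, xt, yt, jmat, w2, dx,
                                 lambda_a, lambda_p, lambda_l, a0)
        taus = 1 if s > 0 else 0
        taut = 1 if t > 0 else 0
        if mu_h != 0.0 and taus != taut:
            dH -= mu_h * (b_field[xt, yt] - b_field[xs, ys])
        if dH > 0.0:
            if _rng_uniform(rng_state) >= np.exp(-dH):
                continue
        _commit(grid, sites_x, sites_y, n_sites, pos_idx, perim_edges,
                empty_edges, phi, length, xs, ys, xt, yt, l_ns, l_nt)
        accepted += 1
    return accepted


@njit(cache=True)
def morphology_sweep(sites_x, sites_y, n_sites, perim_edges, empty_edges,
                     phi, length, c_field, rng_state, mu_m, nx, ny):
    """Per-MCS morphology switching: round cells elongate irreversibly.

    The switch probability is ``mu_m * c_sigma * r_sigma`` clamped to [0, 1],
    with ``c_sigma`` the soluble VEGF averaged over the cell's sites and
    ``r_sigma`` the fraction of boundary edges facing empty sites.
    Returns the number of switches.
    """
    n = phi.shape[0]
    switched = 0
    for s in range(1, n):
        if phi[s] != 0 or n_sites[s] == 0:
            continue
        m = n_sites[s]
        csum = 0.0
        for i in range(m):
            csum += c_field[sites_x[s, i], sites_y[s, i]]
        c_mean = csum / m
        r = empty_edges[s] / perim_edges[s] if perim_edges[s] > 0 else 0.0
        p = mu_m * c_mean * r
        if p > 1.0:
            p = 1.0
        if p > 0.0 and _rng_uniform(rng_state) < p:
            phi[s] = 1
            length[s] = max_pairwise(sites_x[s], sites_y[s], m, -1, nx, ny)
            switched += 1
    return switched


@njit(cache=True)
def centroids(sites_x, sites_y, n_sites, nx, ny, out):
    """Periodic-aware centroids (lattice units) via the circular mean."""
    n = n_sites.shape[0]
    for s in range(1, n):
        m = n_sites[s]
        if m == 0:
            out[s, 0] = np.nan
            out[s, 1] = np.nan
            continue
        cx = 0.0
        sx = 0.0
        cy = 0.0
        sy = 0.0
        for i in range(m):
            ax = 2.0 * np.pi * sites_x[s, i] / nx
            ay = 2.0 * np.pi * sites_y[s, i] / ny
            cx += np.cos(ax)
            sx += np.sin(ax)
            cy += np.cos(ay)
            sy += np.sin(ay)
        px = np.arctan2(sx, cx) / (2.0 * np.pi) * nx
        py = np.arctan2(sy, cy) / (2.0 * np.pi) * ny
        out[s, 0] = px % nx
        out[s, 1] = py % ny
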