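"""Monte-Carlo dynamics: Metropolis acceptance frequencies, unbiased and
haptotaxis-biased migration, morphology switching, geometry caches and
cell placement."""

import numpy as np
import pytest
from scipy import stats

from capnet import (PottsParams, cell_geometry, initialize_cells,
                    monte_carlo_step, morphology_update)
from capnet import _cpm_kernels as _k
from capnet.fixtures import gradient_field, single_cell_lattice
from capnet.morphometrics import direction_histogram


def _steps(lattice, params, b, n_mcs, rng_state, haptotaxis_on=True):
    cents = [lattice.centroids()[1].copy()]
    for _ in range(n_mcs):
        monte_carlo_step(lattice, b, params, rng_state,
                         haptotaxis_on=haptotaxis_on)
        cents.append(lattice.centroids()[1].copy())
    c = np.array(cents)
    L = lattice.nx * lattice.dx
    d = np.diff(c, axis=0)
    d -= L * np.rint(d / L)
    return d


def test_metropolis_acceptance_frequency():
    """Over repeated evaluation of one fixed uphill proposal (the cell
    growing beyond its target area), the empirical acceptance frequency
    under the engine's own random stream matches exp(-dH) within a
    binomial confidence interval."""
    from capnet import acceptance_probability, delta_h

    lat = single_cell_lattice((12, 12))
    p = PottsParams()
    # cell extends onto an empty neighbour: area term makes this uphill
    prop = None
    for (xs, ys, xt, yt) in [(6, 8, 6, 9), (8, 6, 9, 6), (6, 4, 6, 3)]:
        if lat.grid[xs, ys] == 1 and lat.grid[xt, yt] == 0:
            d = delta_h(lat, p, (xs, ys), (xt, yt))
            if d > 0.1:
                prop = d
                break
    assert prop is not None
    p_theory = acceptance_probability(prop)
    assert 0.001 < p_theory < 0.99
    state = _k.seed_rng(7)
    n = 4000
    acc = sum(_k._rng_uniform(state) < np.exp(-prop) for _ in range(n))
    se = np.sqrt(p_theory * (1 - p_theory) / n)
    assert abs(acc / n - p_theory) < 4 * se


def test_unbiased_random_walk_symmetry():
    """With haptotaxis and morphology off, single-cell displacement
    directions are isotropic: a 12-bin chi-square test does not reject
    uniformity at alpha = 0.01 (aggregated over replicates)."""
    p = PottsParams()
    all_steps = []
    for seed in range(6):
        lat = single_cell_lattice((24, 24))
        st_ = _k.seed_rng(100 + seed)
        d = _steps(lat, p, np.zeros((24, 24)), 120, st_, haptotaxis_on=False)
        all_steps.append(d)
    steps = np.concatenate(all_steps)
    counts = direction_histogram(steps)
    assert counts.sum() > 200
    chi2 = stats.chisquare(counts).pvalue
    assert chi2 > 0.01
    # mean displacement ~ 0
    mean_disp = steps.sum(axis=0) / len(all_steps)
    assert np.all(np.abs(mean_disp) < 30.0)  # um, loose random-walk bound


def test_haptotaxis_drift_up_gradient():
    """On a linear bound-VEGF gradient at the typical mu_h, the mean
    displacement has a positive component along the gradient."""
    p = PottsParams()
    drift = 0.0
    for seed in range(6):
        lat = single_cell_lattice((24, 24))
        b = gradient_field((24, 24), slope=1e-14, axis=0)
        st_ = _k.seed_rng(200 + seed)
        d = _steps(lat, p, b, 100, st_)
        drift += d[:, 0].sum()
    assert drift / 6 > 10.0  # um of net drift per replicate


def test_infinite_cost_freezes_state():
    """When every admissible copy has an enormous energy cost (huge area
    restraint centred on the current area), no move is ever accepted."""
    lat = single_cell_lattice((12, 12))
    p = PottsParams(J11=0, J10=0, J01=0, lambda_p=0.0, lambda_a=1e9,
                    a0=2100.0)
    before = lat.grid.copy()
    st_ = _k.seed_rng(3)
    monte_carlo_step(lat, np.zeros((12, 12)), p, st_)
    assert np.array_equal(lat.grid, before)


def test_cell_count_conserved_and_phi_monotone():
    """No birth or death: the number of live cells is constant; the
    morphology flag never reverts."""
    lat = initialize_cells(12, (48, 48), np.random.default_rng(5))
    p = PottsParams()
    st_ = _k.seed_rng(5)
    c = np.full((48, 48), 2e-11)
    phi_prev = lat.phi.copy()
    for _ in range(40):
        morphology_update(lat, c, p, st_)
        monte_carlo_step(lat, np.zeros((48, 48)), p, st_)
        assert (lat.n_sites[1:] > 0).all()
        assert (lat.phi >= phi_prev).all()
        phi_prev = lat.phi.copy()
    lat.check_consistency()


class TestMorphologyUpdate:
    def test_zero_vegf_never_switches(self):
        lat = single_cell_lattice((12, 12))
        p = PottsParams()
        st_ = _k.seed_rng(1)
        for _ in range(50):
            morphology_update(lat, np.zeros((12, 12)), p, st_)
        assert lat.phi[1] == 0

    def test_switch_probability_magnitude(self):
        """mu_m c r = 1.3e8 * 2e-11 * 1 = 2.6e-3 per step for a fully
        free cell; empirical switch frequency agrees binomially."""
        p = PottsParams()
        n, hits = 6000, 0
        st_ = _k.seed_rng(9)
        c = np.full((12, 12), 2e-11)
        for i in range(n):
            lat = single_cell_lattice((12, 12))
            hits += morphology_update(lat, c, p, st_)
        prob = 2.6e-3
        se = np.sqrt(prob * (1 - prob) / n)
        assert abs(hits / n - prob) < 4 * se

    def test_surrounded_cell_never_elongates(self):
        """A cell with no free boundary (r = 0) cannot switch."""
        grid = np.ones((8, 8), dtype=int) * 2
        grid[3:5, 3:5] = 1
        from capnet import LatticeState

        lat = LatticeState(grid, n_cells=2)
        p = PottsParams(mu_m=1e30)
        st_ = _k.seed_rng(4)
        c = np.full((8, 8), 2e-11)
        # cell 2 wraps the torus: it has no empty edges either
        for _ in range(20):
            morphology_update(lat, c, p, st_)
        assert lat.phi[1] == 0


class TestCellGeometry:
    def test_single_site(self):
        from capnet import LatticeState

        grid = np.zeros((9, 9), dtype=int)
        grid[4, 4] = 1
        lat = LatticeState(grid)
        rec = cell_geometry(lat, 1)
        assert rec.area == 100.0
        assert rec.perimeter == 40.0
        assert rec.length == 0.0
        assert rec.free_boundary_fraction == 1.0

    def test_domino(self):
        from capnet import LatticeState

        grid = np.zeros((9, 9), dtype=int)
        grid[4, 4] = grid[5, 4] = 1
        lat = LatticeState(grid)
        rec = cell_geometry(lat, 1)
        assert rec.area == 200.0
        assert rec.perimeter == 60.0
        assert rec.length == pytest.approx(10.0)

    def test_initial_disk(self):
        """21-site quasi-disk: area 2100 um^2; perimeter and length
        validated against exhaustive enumeration over the site set."""
        lat = single_cell_lattice((16, 16))
        rec = cell_geometry(lat, 1)
        assert rec.area == 2100.0
        sites = {(int(x), int(y)) for x, y
                 in zip(lat.sites_x[1][:21], lat.sites_y[1][:21])}
        edges = sum((x + ox, y + oy) not in sites
                    for x, y in sites
                    for ox, oy in ((1, 0), (-1, 0), (0, 1), (0, -1)))
        assert rec.perimeter == pytest.approx(edges * 10.0)
        lmax = max(np.hypot(a[0] - b[0], a[1] - b[1])
                   for a in sites for b in sites) * 10.0
        assert rec.length == pytest.approx(lmax)
        assert rec.length == pytest.approx(np.sqrt(20) * 10.0)

    def test_missing_cell_raises(self):
        lat = single_cell_lattice((12, 12))
        with pytest.raises(KeyError):
            cell_geometry(lat, 7)


class TestInitializeCells:
    def test_single_cell(self):
        lat = initialize_cells(1, (170, 170), np.random.default_rng(0))
        assert lat.n_sites[1] == 21
        assert lat.areas()[1] == 2100.0

    def test_full_density(self):
        lat = initialize_cells(400, (170, 170), np.random.default_rng(0))
        assert (lat.n_sites[1:] == 21).all()
        assert lat.n_sites[1:].sum() == 8400
        assert (lat.phi[1:] == 0).all()

    def test_seed_determinism(self):
        a = initialize_cells(50, (100, 100), np.random.default_rng(42))
        b = initialize_cells(50, (100, 100), np.random.default_rng(42))
        assert np.array_equal(a.grid, b.grid)

    def test_overcrowding_raises(self):
        with pytest.raises(RuntimeError):
            initialize_cells(40, (20, 20), np.random.default_rng(0))
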