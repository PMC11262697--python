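"""Hartigan dip statistic and Monte-Carlo-calibrated sequential tests for
binned circular direction data.

The dip of an empirical CDF F is min over unimodal CDFs G of
sup_x |F(x) - G(x)|.  For our use the sample is discrete (12 direction
bins), so the dip is computed exactly by bisection on the deviation
bound e: for a given e the admissible G values at the distinct sample
points form boxes, and a unimodal G within the boxes exists iff, for some
mode position, a convex non-decreasing path through the left boxes and a
concave non-decreasing path through the right boxes exist and can be
joined.  Path feasibility and the extremal joint values are computed by a
fixpoint of slope-propagation bounds (exact for this 1-D interpolation
problem; cross-checked in the test-suite against a direct LP solution).

Uniformity (stage 1) is tested with the circular Kuiper statistic on the
same binned lattice.  Both null distributions are simulated from the
uniform 12-bin multinomial; the 0.90 quantiles used by the default
alpha = 0.1 tests ship with the package and can be regenerated with
``python -m capnet.make_null_tables``.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
from numba import njit

from ._cpm_kernels import _rng_uniform, seed_rng

N_BINS = 12


# -- dip statistic -------------------------------------------------------

@njit(cache=True)
def _min_terminal_convex(lo, hi, x, m):
    """Minimal feasible terminal value of a convex non-decreasing path
    g_i in [lo_i, hi_i] at abscissae x_i.  Returns (feasible, min g_m-1).

    Lower bounds are propagated to a fixpoint: monotonicity pushes the
    running max forward, and any forced slope (LB_j above hi_i) is
    extrapolated to later points.
    """
    LB = lo.copy()
    for _ in range(m + 2):
        changed = False
        run = -1.0e30
        for k in range(m):
            if LB[k] > run:
                run = LB[k]
            elif run > LB[k] + 1e-15:
                LB[k] = run
                changed = True
        for i in range(m - 1):
            for j in range(i + 1, m):
                if LB[j] > hi[i] + 1e-15:
                    s = (LB[j] - hi[i]) / (x[j] - x[i])
                    for k in range(j + 1, m):
                        v = LB[j] + s * (x[k] - x[j])
                        if v > LB[k] + 1e-15:
                            LB[k] = v
                            changed = True
        if not changed:
            break
    for k in range(m):
        if LB[k] > hi[k] + 1e-12:
            return False, 0.0
    return True, LB[m - 1]


@njit(cache=True)
def _max_initial_concave(lo, hi, x, m):
    """Maximal feasible initial value of a concave non-decreasing path.

    Mirror of :func:`_min_terminal_convex` (reverse the axis, flip values).
    """
    lo2 = np.empty(m)
    hi2 = np.empty(m)
    x2 = np.empty(m)
    for k in range(m):
        lo2[k] = 1.0 - hi[m - 1 - k]
        hi2[k] = 1.0 - lo[m - 1 - k]
        x2[k] = -x[m - 1 - k]
    ok, t = _min_terminal_convex(lo2, hi2, x2, m)
    return ok, 1.0 - t


@njit(cache=True)
def _boxes(c, e, i0, i1, out_lo, out_hi):
    """Standard deviation-e boxes for knots i0..i1-1: g_i must be within e
    of both F(x_i) = c_i and F(x_i-) = c_{i-1}."""
    for i in range(i0, i1):
        lo = c[i + 1] - e          # c is padded: c[0] = 0
        hi = c[i] + e
        if lo < 0.0:
            lo = 0.0
        if hi > 1.0:
            hi = 1.0
        out_lo[i - i0] = lo
        out_hi[i - i0] = hi


@njit(cache=True)
def _dip_feasible(c, x, m, e):
    """Is there a unimodal CDF within deviation e of the discrete ECDF?

    c is the padded cumulative-fraction array (c[0] = 0, c[i] = F(x_{i-1})),
    x the distinct sample values.
    """
    lo = np.empty(m)
    hi = np.empty(m)
    lo_r = np.empty(m)
    hi_r = np.empty(m)
    # case (a): mode at knot t with an atom; left part ends at the left
    # limit L_t (within e of c_{t-1} only), right part starts at g_t
    # (within e of c_t only)
    for t in range(m):
        _boxes(c, e, 0, t, lo, hi)
        lo[t] = max(0.0, c[t] - e)       # L_t vs F(x_t-) = c[t]
        hi[t] = min(1.0, c[t] + e)
        okl, ml = _min_terminal_convex(lo, hi, x, t + 1)
        if not okl:
            continue
        lo_r[0] = max(0.0, c[t + 1] - e)  # g_t vs F(x_t) = c[t+1]
        hi_r[0] = min(1.0, c[t + 1] + e)
        _boxes(c, e, t + 1, m, lo_r[1:], hi_r[1:])
        okr, mr = _max_initial_concave(lo_r, hi_r, x[t:], m - t)
        if okr and ml <= mr + 1e-12:
            return True
    # case (b): mode strictly between knots t and t+1 (no atom needed;
    # slope coupling across the gap is released)
    for t in range(m - 1):
        _boxes(c, e, 0, t + 1, lo, hi)
        okl, ml = _min_terminal_convex(lo, hi, x, t + 1)
        if not okl:
            continue
        _boxes(c, e, t + 1, m, lo_r, hi_r)
        okr, mr = _max_initial_concave(lo_r, hi_r, x[t + 1:], m - t - 1)
        if okr and ml <= mr + 1e-12:
            return True
    return False


@njit(cache=True)
def dip_from_counts(counts):
    """Exact dip statistic of a binned sample (counts per ordered bin).

    Bin centres act as the distinct sample values on a unit-spaced axis.
    """
    n = counts.sum()
    if n <= 1:
        return 0.0
    m = 0
    for k in range(counts.shape[0]):
        if counts[k] > 0:
            m += 1
    x = np.empty(m)
    c = np.zeros(m + 1)
    j = 0
    acc = 0.0
    for k in range(counts.shape[0]):
        if counts[k] > 0:
            x[j] = float(k)
            acc += counts[k] / n
            c[j + 1] = acc
            j += 1
    c[m] = 1.0
    if m == 1:
        return 0.0
    lo_e, hi_e = 0.0, 0.5
    for _ in range(30):
        mid = 0.5 * (lo_e + hi_e)
        if _dip_feasible(c, x, m, mid):
            hi_e = mid
        else:
            lo_e = mid
    return hi_e


def dip_statistic(values) -> float:
    """Dip statistic of a 1-D sample (values are binned to their exact
    discrete levels; intended for small integer-coded samples)."""
    vals = np.asarray(values, float)
    uniq, counts = np.unique(vals, return_counts=True)
    # map onto an integer lattice preserving spacing order: use ranks;
    # dip depends on x only through order/convexity, but spacing matters,
    # so interpolate actual spacings onto the grid positions
    n = len(uniq)
    if n == 0:
        return 0.0
    cpad = np.zeros(n + 1)
    cpad[1:] = np.cumsum(counts) / counts.sum()
    if n == 1:
        return 0.0
    lo_e, hi_e = 0.0, 0.5
    x = uniq.astype(float)
    for _ in range(30):
        mid = 0.5 * (lo_e + hi_e)
        if _dip_feasible(cpad, x, n, mid):
            hi_e = mid
        else:
            lo_e = mid
    return float(hi_e)


# -- Kuiper statistic on the binned circle -------------------------------

@njit(cache=True)
def kuiper_from_counts(counts):
    """Circular Kuiper statistic V = D+ + D- of binned directions against
    the uniform null, evaluated on the bin lattice (rotation invariant)."""
    n = counts.sum()
    nb = counts.shape[0]
    if n == 0:
        return 0.0
    dplus = 0.0
    dminus = 0.0
    acc = 0.0
    for k in range(nb):
        acc += counts[k] / n
        u = (k + 1.0) / nb
        if acc - u > dplus:
            dplus = acc - u
        if u - acc > dminus:
            dminus = u - acc
    return dplus + dminus


@njit(cache=True)
def _rotate_modal_center(counts):
    """Rotate the circular histogram so the modal bin sits at the centre
    index (ties resolved to the lowest bin index)."""
    nb = counts.shape[0]
    kmax = 0
    best = -1
    for k in range(nb):
        if counts[k] > best:
            best = counts[k]
            kmax = k
    shift = nb // 2 - kmax
    out = np.empty_like(counts)
    for k in range(nb):
        out[(k + shift) % nb] = counts[k]
    return out


@njit(cache=True)
def _null_sample_stats(n, n_resamples, seed_state, nb):
    """Simulate (kuiper, dip) under the uniform nb-bin multinomial null."""
    kv = np.empty(n_resamples)
    dv = np.empty(n_resamples)
    counts = np.zeros(nb, dtype=np.int64)
    for r in range(n_resamples):
        counts[:] = 0
        for _ in range(n):
            counts[int(_rng_uniform(seed_state) * nb) % nb] += 1
        kv[r] = kuiper_from_counts(counts)
        dv[r] = dip_from_counts(_rotate_modal_center(counts))
    return kv, dv


def simulate_null_quantiles(n, alpha=0.1, n_resamples=10_000, seed=9001,
                            n_bins=N_BINS):
    """(1-alpha) quantiles of the Kuiper and dip statistics under the
    uniform binned null for sample size n."""
    state = seed_rng(seed + 131 * n)
    kv, dv = _null_sample_stats(n, n_resamples, state, n_bins)
    q = 1.0 - alpha
    return float(np.quantile(kv, q)), float(np.quantile(dv, q))


class NullTables:
    """Critical values of the two-stage procedure.

    For the default alpha = 0.1 the 0.90 quantiles ship with the package
    (simulated at 10^4 resamples); other alphas or sample sizes outside
    the table are simulated on demand and cached per instance.
    """

    def __init__(self, alpha1=0.1, alpha2=0.1, n_resamples=10_000, seed=9001):
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.n_resamples = n_resamples
        self.seed = seed
        self._kuiper: dict[int, float] = {}
        self._dip: dict[int, float] = {}
        if alpha1 == 0.1 and alpha2 == 0.1:
            self._load_shipped()

    def _load_shipped(self):
        try:
            text = (importlib.resources.files("capnet") / "data"
                    / "modality_null_q90.csv").read_text()
        except FileNotFoundError:
            return
        for line in text.strip().splitlines()[1:]:
            n_s, kq, dq = line.split(",")
            self._kuiper[int(n_s)] = float(kq)
            self._dip[int(n_s)] = float(dq)

    def _ensure(self, n):
        if n not in self._kuiper or n not in self._dip:
            kq, dq = simulate_null_quantiles(
                n, self.alpha1, self.n_resamples, self.seed)
            if self.alpha2 != self.alpha1:
                _, dq = simulate_null_quantiles(
                    n, self.alpha2, self.n_resamples, self.seed)
            self._kuiper[n] = kq
            self._dip[n] = dq

    def kuiper_crit(self, n) -> float:
        self._ensure(n)
        return self._kuiper[n]

    def dip_crit(self, n) -> float:
        self._ensure(n)
        return self._dip[n]
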