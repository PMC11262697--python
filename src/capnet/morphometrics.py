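"""Quantification layer: network topology from label images, cell-shape
indices, migration-modality classification, dose-response regressions and
between-condition significance tests.

Network metrics follow the convention used for angiogenesis assays: the
cell pattern is skeletonized (periodic boundary respected), the skeleton
is converted to a graph, spurs shorter than the segment threshold
(default 100 um) are pruned, and then a *segment* is a surviving skeleton
path at least as long as the threshold while a *junction* is a node with
at least three incident counted segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.morphology import skeletonize

from ._dip import (N_BINS, NullTables, _rotate_modal_center,
                   dip_from_counts, kuiper_from_counts)

_NBR8 = [(1, 0), (-1, 0), (0, 1), (0, -1),
         (1, 1), (1, -1), (-1, 1), (-1, -1)]


# -- network extraction --------------------------------------------------

@dataclass
class NetworkGraph:
    """Skeleton-derived network with its integrity metrics."""

    graph: nx.MultiGraph
    junction_count: int
    segment_count: int
    total_length: float            # um, over counted segments
    min_segment_um: float = 100.0
    all_segment_lengths: list = field(default_factory=list)


def _skeleton_periodic(binary, pad=24):
    """Skeletonize a periodic binary image via wrap-padding and cropping."""
    padded = np.pad(binary, pad, mode="wrap")
    sk = skeletonize(padded)
    return sk[pad:-pad, pad:-pad]


def _trace_paths(sk):
    """Convert a periodic skeleton mask into (nodes, edges).

    Node pixels are skeleton pixels of 8-degree != 2; adjacent node pixels
    are merged into single graph nodes (merge radius one site).  Edges are
    traced through degree-2 pixels; pure cycles with no node pixel count
    as one closed segment (a self-loop on an arbitrary cycle pixel).
    Lengths are polyline step lengths in lattice units.
    """
    nx_, ny_ = sk.shape
    pix = {(int(x), int(y)) for x, y in zip(*np.nonzero(sk))}

    def nbrs(p):
        """8-neighbours with redundant diagonals suppressed: a diagonal
        link is dropped when an orthogonal bridge pixel provides the same
        connection (keeps skeleton degrees meaningful)."""
        out = []
        for dx, dy in _NBR8:
            q = ((p[0] + dx) % nx_, (p[1] + dy) % ny_)
            if q not in pix:
                continue
            if dx != 0 and dy != 0:
                if ((p[0] + dx) % nx_, p[1]) in pix or \
                        (p[0], (p[1] + dy) % ny_) in pix:
                    continue
            out.append(q)
        return out

    degree = {p: len(nbrs(p)) for p in pix}
    node_pix = {p for p, d in degree.items() if d != 2}

    # cluster adjacent node pixels
    cluster_of = {}
    clusters = []
    for p in sorted(node_pix):
        if p in cluster_of:
            continue
        cid = len(clusters)
        stack = [p]
        members = []
        cluster_of[p] = cid
        while stack:
            q = stack.pop()
            members.append(q)
            for r in nbrs(q):
                if r in node_pix and r not in cluster_of:
                    cluster_of[r] = cid
                    stack.append(r)
        clusters.append(members)

    def steplen(a, b):
        dx = min(abs(a[0] - b[0]), nx_ - abs(a[0] - b[0]))
        dy = min(abs(a[1] - b[1]), ny_ - abs(a[1] - b[1]))
        return float(np.hypot(dx, dy))

    edges = []
    visited = set()   # directed (pixel, next-pixel) path starts already walked
    covered = set()   # every pixel lying on a traced path
    for p in sorted(node_pix):
        for q in nbrs(p):
            if (p, q) in visited:
                continue
            visited.add((p, q))
            length = steplen(p, q)
            prev, cur = p, q
            covered.add(p)
            while cur not in node_pix:
                covered.add(cur)
                nxt = [r for r in nbrs(cur) if r != prev]
                if not nxt:
                    break  # dangling single-pixel stub
                # at degree-2 pixels there is exactly one continuation
                prev, cur = cur, nxt[0]
                length += steplen(prev, cur)
            if cur in node_pix:
                covered.add(cur)
                visited.add((cur, prev))
                edges.append((cluster_of[p], cluster_of[cur], length))

    # pure cycles: degree-2 components never reached from any node pixel
    rem = set(pix) - node_pix - covered
    for p in sorted(rem):
        if p not in rem:
            continue
        length = 0.0
        start, prev, cur = p, None, p
        while True:
            rem.discard(cur)
            options = [r for r in nbrs(cur)
                       if r != prev and (r in rem or r == start)]
            if not options:
                break
            nxt = options[0]
            length += steplen(cur, nxt)
            prev, cur = cur, nxt
            if cur == start:
                break
        cid = len(clusters)
        clusters.append([start])
        edges.append((cid, cid, length))
    return len(clusters), edges


def _prune_graph(g: nx.MultiGraph, min_len: float) -> nx.MultiGraph:
    """Clean the raw skeleton graph before computing metrics.

    Iterated until stable: spurs (leaf edges) and isolated loops shorter
    than the segment threshold are removed as skeletonization noise, and
    degree-2 nodes concatenate their two incident paths.  Internal
    branch-to-branch paths are kept whatever their length: they still
    make their end nodes intersections of the network.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for u, v, k, data in list(g.edges(keys=True, data=True)):
            if data["length"] >= min_len:
                continue
            if u == v:
                g.remove_edge(u, v, key=k)
                changed = True
            elif g.degree(u) == 1 or g.degree(v) == 1:
                g.remove_edge(u, v, key=k)
                changed = True
        for u in list(g.nodes):
            if u in g and g.degree(u) == 0:
                g.remove_node(u)
                changed = True
        # merge paths through degree-2 nodes
        for u in list(g.nodes):
            if u in g and g.degree(u) == 2:
                inc = list(g.edges(u, keys=True, data=True))
                if len(inc) != 2:
                    continue  # a self-loop already accounts for degree 2
                (a, b, k1, d1), (c, d, k2, d2) = inc
                n1 = b if a == u else a
                n2 = d if c == u else c
                g.remove_edge(a, b, key=k1)
                g.remove_edge(c, d, key=k2)
                g.remove_node(u)
                g.add_edge(n1, n2, length=d1["length"] + d2["length"])
                changed = True
    return g


def extract_network(label_image, dx: float = 10.0,
                    min_segment_um: float = 100.0) -> NetworkGraph:
    """Extract the capillary-like network graph from a label (or binary)
    image on the periodic domain and compute its integrity metrics."""
    binary = np.asarray(label_image) > 0
    if not binary.any():
        return NetworkGraph(nx.MultiGraph(), 0, 0, 0.0, min_segment_um, [])
    sk = _skeleton_periodic(binary)
    if not sk.any():
        return NetworkGraph(nx.MultiGraph(), 0, 0, 0.0, min_segment_um, [])
    n_nodes, edges = _trace_paths(sk)
    g = nx.MultiGraph()
    g.add_nodes_from(range(n_nodes))
    for u, v, length in edges:
        g.add_edge(u, v, length=length * dx)
    g.remove_nodes_from([u for u in list(g.nodes) if g.degree(u) == 0])
    g = _prune_graph(g, min_segment_um)
    lengths = [d["length"] for _, _, d in g.edges(data=True)]
    counted = [L for L in lengths if L >= min_segment_um]
    # a junction is a node where >= 3 skeleton paths of the pruned
    # network intersect; the length threshold defines *segments* (for the
    # segment count and total length), not intersection membership
    junctions = 0
    for u in g.nodes:
        inc = sum((2 if a == b else 1) for a, b in g.edges(u))
        if inc >= 3:
            junctions += 1
    return NetworkGraph(graph=g, junction_count=junctions,
                        segment_count=len(counted),
                        total_length=float(sum(counted)),
                        min_segment_um=min_segment_um,
                        all_segment_lengths=lengths)


# -- cell shape ----------------------------------------------------------

def shape_indices(cell_sites, dx: float = 10.0, lattice_shape=None):
    """Roundness 4*pi*a/p^2 and principal-axis aspect ratio of one cell.

    ``cell_sites`` is an (m, 2) array of occupied lattice coordinates.
    The perimeter is the lattice boundary-edge count times dx (so discrete
    disks score below the continuum value of 1).  The aspect ratio is the
    square-root ratio of the eigenvalues of the second-moment tensor of
    the occupied area (site scatter plus the dx^2/12 per-site square
    term), which makes an n x 1 bar of length L score exactly L/dx and a
    single site exactly 1.
    """
    sites = np.asarray(cell_sites)
    if sites.size == 0:
        raise ValueError("empty site set")
    m = len(sites)
    if lattice_shape is None:
        nx_ = ny_ = None
        rel = sites - sites.mean(axis=0)
    else:
        nx_, ny_ = lattice_shape
        # unwrap around the first site (cells are small vs the domain)
        rel = sites - sites[0]
        rel[:, 0] -= nx_ * np.rint(rel[:, 0] / nx_).astype(int)
        rel[:, 1] -= ny_ * np.rint(rel[:, 1] / ny_).astype(int)
        rel = rel - rel.mean(axis=0)
    occupied = {tuple(s) for s in map(tuple, sites)}

    def wrapped(x, y):
        if nx_ is None:
            return (x, y)
        return (x % nx_, y % ny_)

    edges = 0
    for (x, y) in occupied:
        for ox, oy in _NBR8[:4]:
            if wrapped(x + ox, y + oy) not in occupied:
                edges += 1
    a = m * dx * dx
    p = edges * dx
    roundness = 4.0 * np.pi * a / p ** 2
    cov = (rel.T @ rel) / m * dx * dx + (dx * dx / 12.0) * np.eye(2)
    ev = np.linalg.eigvalsh(cov)
    aspect = float(np.sqrt(ev[1] / ev[0]))
    return float(roundness), aspect


# -- migration modality --------------------------------------------------

ISOTROPIC = "isotropic"
ONE_DIRECTION = "one-direction"
HEAD_AND_TAIL = "head-and-tail"


def direction_histogram(steps, n_bins: int = N_BINS):
    """Bin step angles into n_bins 30-degree intervals centred on 0, 30,
    ... degrees; zero-length steps are excluded from the sample."""
    steps = np.asarray(steps, float)
    norms = np.hypot(steps[:, 0], steps[:, 1])
    nz = norms > 0
    ang = np.arctan2(steps[nz, 1], steps[nz, 0])
    width = 2.0 * np.pi / n_bins
    bins = np.floor(ang / width + 0.5).astype(int) % n_bins
    return np.bincount(bins, minlength=n_bins).astype(np.int64)


def classify_modality(centroid_steps, alpha1: float = 0.1,
                      alpha2: float = 0.1, min_steps: int = 10,
                      tables: NullTables | None = None) -> str:
    """Classify one cell-window of displacement vectors.

    Sequential procedure on the 12-bin direction histogram: stage 1 tests
    uniformity (circular Kuiper, Monte-Carlo null) at ``alpha1``; if not
    rejected the window is isotropic.  Otherwise stage 2 tests
    unimodality (dip statistic of the modal-bin-centred histogram,
    Monte-Carlo null) at ``alpha2``: unimodal gives one-direction, and a
    rejected stage 2 with the two dominant bins opposed (6 +/- 1 bins
    apart) gives head-and-tail.  Windows with fewer than ``min_steps``
    non-zero steps are isotropic by convention.
    """
    counts = direction_histogram(centroid_steps)
    n = int(counts.sum())
    if n < min_steps:
        return ISOTROPIC
    if tables is None or (tables.alpha1, tables.alpha2) != (alpha1, alpha2):
        tables = NullTables(alpha1, alpha2)
    if kuiper_from_counts(counts) <= tables.kuiper_crit(n):
        return ISOTROPIC
    rotated = _rotate_modal_center(counts)
    if dip_from_counts(rotated) <= tables.dip_crit(n):
        return ONE_DIRECTION
    top2 = np.argsort(counts)[-2:]
    sep = abs(int(top2[0]) - int(top2[1]))
    sep = min(sep, N_BINS - sep)
    if abs(sep - N_BINS // 2) <= 1:
        return HEAD_AND_TAIL
    return ONE_DIRECTION


def modality_census(centroid_history, config, window: int = 60,
                    alpha1: float = 0.1, alpha2: float = 0.1,
                    tables: NullTables | None = None) -> pd.DataFrame:
    """Per-window modality counts over all cells of a run.

    ``centroid_history`` has shape (n_cells+1, n_mcs+1, 2) in um; steps
    are consecutive minimal-image centroid displacements, grouped into
    non-overlapping windows of ``window`` steps (2 hours at 2 min/MCS).
    """
    if tables is None:
        tables = NullTables(alpha1, alpha2)
    Lx = config.nx * config.dx
    Ly = config.ny * config.dx
    hist = np.asarray(centroid_history)
    steps = np.diff(hist, axis=1)
    steps[..., 0] -= Lx * np.rint(steps[..., 0] / Lx)
    steps[..., 1] -= Ly * np.rint(steps[..., 1] / Ly)
    n_cells = hist.shape[0] - 1
    n_steps = steps.shape[1]
    rows = []
    for w0 in range(0, n_steps - window + 1, window):
        counts = {ISOTROPIC: 0, ONE_DIRECTION: 0, HEAD_AND_TAIL: 0}
        for s in range(1, n_cells + 1):
            label = classify_modality(steps[s, w0:w0 + window],
                                      alpha1, alpha2, tables=tables)
            counts[label] += 1
        rows.append({"window_start_mcs": w0,
                     "hours": (w0 + window) * config.mcs_minutes / 60.0,
                     "isotropic": counts[ISOTROPIC],
                     "one_direction": counts[ONE_DIRECTION],
                     "head_and_tail": counts[HEAD_AND_TAIL]})
    return pd.DataFrame(rows)


# -- regression fits -----------------------------------------------------

def _exp_saturation(P, a, b, c):
    return a - b * np.exp(-c * np.asarray(P, float))


def _linear(x, a, b):
    return a + b * np.asarray(x, float)


def _logistic(h, a, b, c, d):
    return a + b / (1.0 + np.exp(-c * np.asarray(h, float) + d))


def _junction_time_surface(X, A, B, C, D, E, F, G, H, I, J):
    """Two-factor junction-vs-time model: the first factor is the
    asymptotic junction number, the bracketed factor its rise rate.
    X columns: mu_m, mu_h, c0, kon/koff ratio, t (seconds)."""
    mu_m, mu_h, c0, r, t = (np.asarray(X, float).T if np.ndim(X) == 2
                            else X)
    plateau = A * (1.0 - np.exp(-B * mu_m - C * mu_h - D * c0 - E * r))
    rate = 1.0 - np.exp(-F * mu_m ** G * mu_h ** H * c0 ** I * r ** J * t)
    return plateau * rate

REGRESSION_FORMS = {
    "exp_saturation": (_exp_saturation, ("a", "b", "c")),
    "linear": (_linear, ("a", "b")),
    "logistic": (_logistic, ("a", "b", "c", "d")),
    "junction_time": (_junction_time_surface, tuple("ABCDEFGHIJ")),
}


@dataclass
class FitResult:
    form: str
    params: dict
    r2: float
    adj_r2: float
    converged: bool

    def predict(self, x):
        fn, names = REGRESSION_FORMS[self.form]
        return fn(x, *[self.params[k] for k in names])


def fit_regressions(x, y, form: str = "exp_saturation", p0=None,
                    n_restarts: int = 20, seed: int = 0) -> FitResult:
    """Nonlinear least squares for the dose-response and time-course
    regression forms, with multi-start restarts on non-convergence.

    Scales of the predictors vary over many decades (rate constants,
    concentrations), so restarts draw initial parameters log-uniformly
    around a data-driven guess.
    """
    fn, names = REGRESSION_FORMS[form]
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    npar = len(names)
    if y.size < npar:
        raise ValueError("need at least as many points as coefficients")
    rng = np.random.default_rng(seed)

    def guess():
        if form == "exp_saturation":
            span = max(y.max() - y.min(), 1.0)
            xs = np.abs(x[x != 0])
            cx = 1.0 / np.median(xs) if xs.size else 1.0
            return np.array([y.max(), span, cx])
        if form == "linear":
            return np.polyfit(x, y, 1)[::-1]
        if form == "logistic":
            span = max(y.max() - y.min(), 1.0)
            xspan = max(float(np.ptp(x)), 1.0)
            return np.array([y.min(), span, 4.0 / xspan,
                             np.median(x) * 4.0 / xspan])
        # junction_time
        cols = np.asarray(x, float)
        return np.array([y.max(), *(1.0 / np.maximum(np.abs(cols).mean(0), 1e-300))[:4],
                         1e-4, 0.5, 0.5, 0.5, 0.5])[:npar]

    base = np.asarray(p0, float) if p0 is not None else guess()
    best = None
    for trial in range(n_restarts):
        if trial == 0:
            start = base
        else:
            start = base * np.exp(rng.normal(0, 1.0, size=npar))
        try:
            popt, _ = optimize.curve_fit(fn, x, y, p0=start, maxfev=20000)
        except (RuntimeError, TypeError, ValueError):
            continue
        resid = y - fn(x, *popt)
        ss_res = float(resid @ resid)
        if best is None or ss_res < best[0]:
            best = (ss_res, popt)
        if ss_res <= 1e-12 * max(1.0, float(y @ y)):
            break
    if best is None:
        return FitResult(form, {k: np.nan for k in names}, np.nan, np.nan, False)
    ss_res, popt = best
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    nobs = y.size
    adj = 1.0 - (1.0 - r2) * (nobs - 1) / max(nobs - npar - 1, 1)
    return FitResult(form, dict(zip(names, popt)), r2, adj, True)


# -- condition comparison ------------------------------------------------

def compare_conditions(tables: pd.DataFrame, reference: str,
                       metrics=("junctions", "segments", "total_length_um"),
                       group_col: str = "condition",
                       time_col: str = "mcs") -> pd.DataFrame:
    """Two-sample t-tests of every condition against the reference, per
    metric and time point, with the usual significance stars (* p<0.05,
    ** p<0.01, ns otherwise); degenerate zero-variance pairs are marked."""
    rows = []
    for (cond, t), grp in tables.groupby([group_col, time_col]):
        if cond == reference:
            continue
        ref = tables[(tables[group_col] == reference)
                     & (tables[time_col] == t)]
        if ref.empty:
            continue
        for metric in metrics:
            a = np.asarray(grp[metric], float)
            b = np.asarray(ref[metric], float)
            if a.std() == 0 and b.std() == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
                note = "degenerate (zero variance)"
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
                note = ""
            stars = "**" if p < 0.01 else ("*" if p < 0.05 else "ns")
            rows.append({group_col: cond, time_col: t, "metric": metric,
                         "mean": a.mean(), "ref_mean": b.mean(),
                         "p_value": p, "stars": stars, "note": note})
    return pd.DataFrame(rows)
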