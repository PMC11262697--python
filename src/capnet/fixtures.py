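"""Deterministic toy-input generators.

Every stage of the pipeline can be exercised without running the coupled
model: small lattices for the energy-delta oracle, analytic fields for
the transport solvers, masks with known network metrics, synthetic
trajectories of prescribed migration modality, and noiseless datasets
for the regression forms.  The same spec + seed always regenerates a
bit-identical object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cpm import FOOTPRINT_21, LatticeState
from .params import GelParams

KINDS = ("single_cell_lattice", "random_lattice", "gradient_field",
         "uniform_gel", "toy_network_mask", "synthetic_trajectory",
         "regression_dataset")


@dataclass
class FixtureSpec:
    kind: str
    size: tuple = (12, 12)
    seed: int = 0
    params: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec):
    """Materialize a fixture; see the per-kind helpers for details."""
    if spec.kind == "single_cell_lattice":
        return single_cell_lattice(spec.size, **spec.params)
    if spec.kind == "random_lattice":
        return random_lattice(spec.size, seed=spec.seed, **spec.params)
    if spec.kind == "gradient_field":
        return gradient_field(spec.size, **spec.params)
    if spec.kind == "uniform_gel":
        from .gel import GelState

        return GelState.uniform(spec.size, spec.params.get("gel", GelParams()))
    if spec.kind == "toy_network_mask":
        return toy_network_mask(spec.size, **spec.params)
    if spec.kind == "synthetic_trajectory":
        return synthetic_trajectory(seed=spec.seed, **spec.params)
    if spec.kind == "regression_dataset":
        return regression_dataset(seed=spec.seed, **spec.params)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def single_cell_lattice(size=(12, 12), dx=10.0, footprint=None, center=None):
    """One cell stamped at the centre; default is the 21-site quasi-disk."""
    nx, ny = size
    fp = FOOTPRINT_21 if footprint is None else np.asarray(footprint)
    cx, cy = (nx // 2, ny // 2) if center is None else center
    grid = np.zeros((nx, ny), dtype=np.int32)
    grid[(cx + fp[:, 0]) % nx, (cy + fp[:, 1]) % ny] = 1
    return LatticeState(grid, dx=dx, n_cells=1)


def random_lattice(size=(12, 12), n_cells=3, seed=0, dx=10.0, fill=0.35):
    """Random multi-cell lattice (possibly ragged cells) for oracles."""
    nx, ny = size
    rng = np.random.default_rng(seed)
    grid = np.zeros((nx, ny), dtype=np.int32)
    # grow cells by seeded random flood fill
    seeds = rng.choice(nx * ny, size=n_cells, replace=False)
    frontiers = []
    for s, flat in enumerate(seeds, start=1):
        x, y = divmod(int(flat), ny)
        grid[x, y] = s
        frontiers.append([(x, y)])
    target = int(fill * nx * ny / n_cells)
    for _ in range(target):
        for s in range(1, n_cells + 1):
            if not frontiers[s - 1]:
                continue
            i = int(rng.integers(len(frontiers[s - 1])))
            x, y = frontiers[s - 1][i]
            opts = [((x + ox) % nx, (y + oy) % ny)
                    for ox, oy in ((1, 0), (-1, 0), (0, 1), (0, -1))]
            opts = [p for p in opts if grid[p] == 0]
            if not opts:
                frontiers[s - 1].pop(i)
                continue
            p = opts[int(rng.integers(len(opts)))]
            grid[p] = s
            frontiers[s - 1].append(p)
    return LatticeState(grid, dx=dx, n_cells=n_cells)


def gradient_field(size=(12, 12), slope=1e-14, axis=0, offset=None):
    """Linear field with the given per-site slope along one axis (used as
    a bound-VEGF field with a known haptotaxis gradient)."""
    nx, ny = size
    coord = np.arange(nx if axis == 0 else ny, dtype=float)
    base = slope * coord
    if offset is None:
        offset = max(0.0, -base.min())
    f = np.zeros((nx, ny)) + offset
    if axis == 0:
        f += base[:, None]
    else:
        f += base[None, :]
    return f


def toy_network_mask(size=(80, 80), shape="plus", arm_sites=20,
                     bar_sites=50, ring_radius=25):
    """Binary masks with known network metrics.

    * ``bar``: straight 1-site-wide bar of ``bar_sites`` sites.
    * ``plus``: four ``arm_sites``-site arms from a centre site.
    * ``ring``: 1-site-wide circle of radius ``ring_radius`` sites.
    """
    nx, ny = size
    m = np.zeros((nx, ny), dtype=bool)
    cx, cy = nx // 2, ny // 2
    if shape == "bar":
        x0 = cx - bar_sites // 2
        m[x0:x0 + bar_sites, cy] = True
    elif shape == "plus":
        m[cx - arm_sites:cx + arm_sites + 1, cy] = True
        m[cx, cy - arm_sites:cy + arm_sites + 1] = True
    elif shape == "ring":
        th = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
        xs = np.round(cx + ring_radius * np.cos(th)).astype(int) % nx
        ys = np.round(cy + ring_radius * np.sin(th)).astype(int) % ny
        m[xs, ys] = True
    else:
        raise ValueError(f"unknown mask shape {shape!r}")
    return m


def synthetic_trajectory(modality="isotropic", n_steps=60, seed=0,
                         step_um=5.0, zero_fraction=0.0):
    """Displacement steps (n_steps, 2) um of a prescribed modality.

    isotropic: uniform angles; one_direction: all angles inside one
    30-degree bin; head_and_tail: equal split between one bin and its
    opposite.
    """
    rng = np.random.default_rng(seed)
    width = 2.0 * np.pi / 12.0
    if modality == "isotropic":
        ang = rng.uniform(0, 2 * np.pi, n_steps)
    elif modality == "one_direction":
        ang = rng.uniform(-width / 2, width / 2, n_steps)
    elif modality == "head_and_tail":
        half = n_steps // 2
        ang = np.concatenate([
            rng.uniform(-width / 2, width / 2, half),
            np.pi + rng.uniform(-width / 2, width / 2, n_steps - half)])
    else:
        raise ValueError(f"unknown modality {modality!r}")
    steps = step_um * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    if zero_fraction > 0:
        k = int(zero_fraction * n_steps)
        steps[rng.choice(n_steps, k, replace=False)] = 0.0
    return steps


#: generating-truth coefficients for the junction-number dose-response
#: curve f(P) = a - b exp(-c P) as calibrated for the morphology-strength
#: parameter (a, b in junctions; c in um^3/ng inverse of mu_m units)
EQ1_MU_M_COEFFS = {"a": 148.0, "b": 143.0, "c": 8.32e-9}


def regression_dataset(form="exp_saturation", coeffs=None, x=None,
                       noise_sd=0.0, seed=0):
    """Noiseless (or noisy) synthetic dataset from a regression form."""
    from .morphometrics import REGRESSION_FORMS

    fn, names = REGRESSION_FORMS[form]
    if coeffs is None:
        if form != "exp_saturation":
            raise ValueError("coeffs required for this form")
        coeffs = EQ1_MU_M_COEFFS
    if x is None:
        if form == "exp_saturation":
            c = coeffs["c"]
            x = np.linspace(0.25, 8.0, 12) / c  # spans the curve's rise
        else:
            raise ValueError("x required for this form")
    x = np.asarray(x, float)
    y = fn(x, *[coeffs[k] for k in names])
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, size=y.shape)
    return x, y, dict(coeffs)
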