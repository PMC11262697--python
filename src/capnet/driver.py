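"""Coupled-run orchestration: CPM and continuum fields advance in
lockstep, one mechanics/transport interval per Monte-Carlo step.

Within each MCS the fixed update order is: morphology switch (if on) ->
CPM copy attempts (haptotaxis term zeroed if off) -> gel mechanics
(displacement solve, density advection, thickness update) -> VEGF
transport.  A run is fully determined by its configuration and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd

from . import _cpm_kernels as _k
from .cpm import LatticeState, initialize_cells, monte_carlo_step, \
    morphology_update
from .gel import GelState, MechanicsSolver, thickness, traction_field, \
    update_density
from .params import SimConfig
from .vegf import VegfState, _Diffuser, step_vegf


@dataclass
class Trajectory:
    """In-memory record of one coupled run."""

    config: SimConfig
    seed: int
    centroid_history: np.ndarray      # (n_cells+1, duration+1, 2) um
    phi_history: np.ndarray           # (duration+1,) fraction of phi=1 cells
    accepted: np.ndarray              # accepted copy attempts per MCS
    gel_mass: np.ndarray              # (duration+1,) total gel mass ledger
    vegf_total: np.ndarray            # (duration+1,) total VEGF ledger
    snapshots: dict = _field(default_factory=dict)   # mcs -> field dict
    lattice: LatticeState | None = None
    gel: GelState | None = None
    vegf: VegfState | None = None
    clip_events: int = 0

    @property
    def snapshot_times(self):
        return sorted(self.snapshots)

    def label_at(self, mcs: int):
        return self.snapshots[mcs]["label"]

    def hours(self, mcs: int) -> float:
        return mcs * self.config.mcs_minutes / 60.0

    def network_metrics(self) -> pd.DataFrame:
        """Junction/segment/total-length metrics for every stored snapshot."""
        from .morphometrics import extract_network

        rows = []
        for t in self.snapshot_times:
            g = extract_network(self.snapshots[t]["label"], self.config.dx)
            rows.append({"mcs": t, "hours": self.hours(t),
                         "junctions": g.junction_count,
                         "segments": g.segment_count,
                         "total_length_um": g.total_length})
        return pd.DataFrame(rows)

    def shape_table(self, mcs: int | None = None) -> pd.DataFrame:
        """Roundness and aspect ratio of every cell at a snapshot time
        (default: the final state)."""
        from .morphometrics import shape_indices

        if mcs is None:
            label = self.lattice.grid
        else:
            label = self.snapshots[mcs]["label"]
        rows = []
        for s in range(1, self.config.n_cells + 1):
            xs, ys = np.nonzero(label == s)
            if len(xs) == 0:
                continue
            rnd, ar = shape_indices(np.stack([xs, ys], axis=1),
                                    self.config.dx,
                                    lattice_shape=label.shape)
            rows.append({"cell": s, "roundness": rnd, "aspect_ratio": ar})
        return pd.DataFrame(rows)

    def modality_census(self, window: int = 60, **kwargs) -> pd.DataFrame:
        """Per-2-hour-window migration-modality counts over all cells."""
        from .morphometrics import modality_census

        return modality_census(self.centroid_history, self.config, window=window,
                               **kwargs)


def run(config: SimConfig, seed: int | None = None,
        progress: bool = False) -> Trajectory:
    """Execute one coupled simulation; deterministic given (config, seed)."""
    cfg = config.copy()
    cfg.validate()
    if seed is not None:
        cfg.seed = int(seed)
    # scheduler unit bookkeeping: 2 min/MCS <=> 18 h = 540 MCS, 2 h = 60 MCS
    if cfg.mcs_minutes == 2.0:
        assert cfg.mcs_at_hours(18.0) == 540 and cfg.mcs_at_hours(2.0) == 60

    master = np.random.default_rng(cfg.seed)
    lattice = initialize_cells(cfg.n_cells, (cfg.nx, cfg.ny), master, dx=cfg.dx)
    rng_state = _k.seed_rng(int(master.integers(1, 2 ** 62)))
    gel = GelState.uniform((cfg.nx, cfg.ny), cfg.gel)
    vegf = VegfState.initial((cfg.nx, cfg.ny), cfg.vegf)
    solver = MechanicsSolver((cfg.nx, cfg.ny), cfg.dx, cfg.gel, cfg.dt)
    diffuser = _Diffuser((cfg.nx, cfg.ny), cfg.dx, cfg.vegf.D_c, cfg.dt)

    T = cfg.duration
    traj = Trajectory(
        config=cfg, seed=cfg.seed,
        centroid_history=np.zeros((cfg.n_cells + 1, T + 1, 2)),
        phi_history=np.zeros(T + 1),
        accepted=np.zeros(T, dtype=np.int64),
        gel_mass=np.empty(T + 1), vegf_total=np.empty(T + 1),
    )

    def record(t):
        traj.centroid_history[:, t, :] = lattice.centroids()
        traj.phi_history[t] = lattice.phi[1:].mean()
        traj.gel_mass[t] = gel.total_mass(cfg.dx)
        traj.vegf_total[t] = vegf.total(cfg.dx)

    def snapshot(t):
        traj.snapshots[t] = {
            "label": lattice.grid.copy(),
            "phi": lattice.phi.copy(),
            "rho": gel.rho.astype(np.float32),
            "b": vegf.b.astype(np.float32),
            "c": vegf.c.astype(np.float32),
            "h": gel.h.astype(np.float32),
            "u_mag": np.hypot(gel.u[0], gel.u[1]).astype(np.float32),
        }

    record(0)
    snapshot(0)
    for t in range(1, T + 1):
        if cfg.morphology_on:
            morphology_update(lattice, vegf.c, cfg.potts, rng_state)
        traj.accepted[t - 1] = monte_carlo_step(
            lattice, vegf.b, cfg.potts, rng_state,
            haptotaxis_on=cfg.haptotaxis_on)
        tr = traction_field(lattice.occupancy, gel.rho, cfg.gel.kappa)
        solver.solve(gel, tr)
        gel.rho, clips = update_density(gel.rho, gel.du_dt, cfg.dt, cfg.dx)
        traj.clip_events += clips
        gel.h = thickness(gel.rho, cfg.gel)
        gel.clamp_fraction = float((gel.h <= cfg.gel.h_min).mean())
        vegf.c, vegf.b, vclips = step_vegf(vegf.c, vegf.b, gel.rho, gel.du_dt,
                                           cfg.vegf, cfg.dt, cfg.dx,
                                           diffuser=diffuser)
        traj.clip_events += vclips
        record(t)
        if cfg.snapshot_every and t % cfg.snapshot_every == 0:
            snapshot(t)
        if progress and t % 30 == 0:
            print(f"  mcs {t}/{T} ({traj.hours(t):.0f} h)  "
                  f"phi={traj.phi_history[t]:.2f}  "
                  f"it={gel.last_iterations}", flush=True)
    traj.lattice, traj.gel, traj.vegf = lattice, gel, vegf
    return traj


def sweep(base_config: SimConfig, parameter: str, multipliers,
          replicates: int = 3, progress: bool = False) -> pd.DataFrame:
    """Factorial parameter sweep: ``parameter`` (a flat config symbol, or
    the combined ratio ``"k_on/k_off"``) is scaled by each multiplier and
    each condition is repeated with ``replicates`` distinct seeds.

    Returns one row per (multiplier, replicate, snapshot time) with the
    network metrics, ready for the dose-response regression fits.
    """
    rows = []
    for mult in multipliers:
        for rep in range(replicates):
            cfg = base_config.copy()
            if parameter == "k_on/k_off":
                cfg.set_symbol("k_on", cfg.get_symbol("k_on") * mult)
            else:
                cfg.set_symbol(parameter, base_config.get_symbol(parameter) * mult)
            cfg.seed = base_config.seed + 1000 * rep + 1
            traj = run(cfg, progress=progress)
            met = traj.network_metrics()
            for _, m in met.iterrows():
                rows.append({"parameter": parameter, "multiplier": mult,
                             "value": (cfg.get_symbol("k_on") / cfg.get_symbol("k_off")
                                       if parameter == "k_on/k_off"
                                       else cfg.get_symbol(parameter)),
                             "replicate": rep, "seed": cfg.seed,
                             "mcs": int(m["mcs"]), "hours": m["hours"],
                             "junctions": m["junctions"],
                             "segments": m["segments"],
                             "total_length_um": m["total_length_um"]})
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame, at_mcs: int | None = None) -> pd.DataFrame:
    """Mean +/- SD of the endpoint metrics across replicates."""
    t = table if at_mcs is None else table[table["mcs"] == at_mcs]
    if t.empty:
        return pd.DataFrame(columns=["parameter", "multiplier", "mcs",
                                     "junctions_mean", "junctions_sd"])
    g = t.groupby(["parameter", "multiplier", "mcs"])
    out = g.agg(junctions_mean=("junctions", "mean"),
                junctions_sd=("junctions", "std"),
                segments_mean=("segments", "mean"),
                total_length_mean=("total_length_um", "mean"),
                n=("junctions", "size")).reset_index()
    return out
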