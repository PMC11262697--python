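"""Disk formats: label images and continuum fields as single-channel
TIFF, per-snapshot cell tables and run metrics as CSV, configuration as
a flat key-value text file."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cpm import cell_geometry


def write_trajectory(traj, outdir) -> Path:
    """Write snapshots, cell tables, metrics and ledgers for one run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = traj.config
    cfg.save(out / "config.txt")
    (out / "run_info.txt").write_text(
        f"seed = {traj.seed}\nconfig_hash = {cfg.config_hash()}\n"
        f"clip_events = {traj.clip_events}\n")
    field_summaries = []
    for t in traj.snapshot_times:
        snap = traj.snapshots[t]
        tag = f"t{t:05d}"
        tifffile.imwrite(out / f"label_{tag}.tif",
                         snap["label"].astype(np.uint16))
        for name in ("rho", "b", "c", "h", "u_mag"):
            tifffile.imwrite(out / f"{name}_{tag}.tif", snap[name])
            field_summaries.append({
                "mcs": t, "field": name,
                "min": float(snap[name].min()),
                "max": float(snap[name].max()),
                "mean": float(snap[name].mean())})
    pd.DataFrame(field_summaries).to_csv(out / "field_summary.csv", index=False)
    # per-MCS ledgers
    pd.DataFrame({
        "mcs": np.arange(len(traj.phi_history)),
        "phi_fraction": traj.phi_history,
        "gel_mass": traj.gel_mass,
        "vegf_total": traj.vegf_total,
    }).to_csv(out / "ledger.csv", index=False)
    # final cell table
    cell_table(traj).to_csv(out / "cells_final.csv", index=False)
    traj.network_metrics().to_csv(out / "network_metrics.csv", index=False)
    ch = traj.centroid_history
    n_cells = ch.shape[0] - 1
    rows = {"cell": np.repeat(np.arange(1, n_cells + 1), ch.shape[1]),
            "mcs": np.tile(np.arange(ch.shape[1]), n_cells),
            "x_um": ch[1:, :, 0].ravel(), "y_um": ch[1:, :, 1].ravel()}
    pd.DataFrame(rows).to_csv(out / "centroids.csv", index=False)
    return out


def cell_table(traj) -> pd.DataFrame:
    """Final-state per-cell table: id, phi, area, perimeter, length,
    free-boundary fraction and centroid."""
    rows = []
    for s in traj.lattice.live_cells():
        rec = cell_geometry(traj.lattice, int(s))
        rows.append({"id": rec.id, "phi": rec.phi, "area_um2": rec.area,
                     "perimeter_um": rec.perimeter, "length_um": rec.length,
                     "free_boundary_fraction": rec.free_boundary_fraction,
                     "x_um": rec.centroid[0], "y_um": rec.centroid[1]})
    return pd.DataFrame(rows)


def read_label_snapshots(rundir):
    """Load the label images written by :func:`write_trajectory`,
    returned as {mcs: array}."""
    out = {}
    for f in sorted(Path(rundir).glob("label_t*.tif")):
        mcs = int(f.stem.split("_t")[1])
        out[mcs] = tifffile.imread(f).astype(np.int32)
    return out
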