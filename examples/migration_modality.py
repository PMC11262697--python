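"""Classify per-cell migration modality from centroid trajectories.

Each cell's displacement directions over a 2-hour window (60 Monte-Carlo
steps) are binned into 12 sectors and passed through the sequential
test: a circular uniformity test (isotropic random walk?) followed by a
dip test of unimodality (one preferred direction, or back-and-forth
head-and-tail movement?).  Both nulls are Monte-Carlo calibrated at
alpha = 0.1, so about 10% of perfect random walkers are flagged
directional by construction.
"""

from capnet import SimConfig, run
from capnet.fixtures import synthetic_trajectory
from capnet.morphometrics import classify_modality

# the three pure cases
for kind in ("isotropic", "one_direction", "head_and_tail"):
    steps = synthetic_trajectory(kind, seed=1)
    print(f"synthetic {kind:14s} -> {classify_modality(steps)}")

# census over a short simulated run (6 h; use duration=720 for the
# full 24-hour census)
cfg = SimConfig(duration=180)
traj = run(cfg, seed=1)
census = traj.modality_census()
print("\nper-2-hour-window counts over 400 simulated cells:")
print(census.to_string(index=False))
print("\nmost cells walk isotropically; directional movers appear "
      "while scattered cells aggregate into cords.")
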