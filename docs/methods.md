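# Methods

`capnet` simulates short-term in vitro vasculogenesis: human umbilical
vein endothelial cells (HUVECs) seeded on a soft collagen gel
reorganize within about a day from a scattered monolayer into a
capillary-like network of cords enclosing cell-free lacunae.  The model
is a hybrid of a lattice cell model and continuum field equations,
coupled through two forms of the growth factor VEGF: the soluble form
in the medium triggers an irreversible elongation of cell morphology,
and the gel-bound form provides the spatial gradients that bias cell
migration (haptotaxis).

## Cell model

Cells are resolved on a periodic square lattice (default 170x170 sites
of 10 um) as connected site sets evolving by the Cellular Potts /
Metropolis scheme.  The system energy is

    H = sum_pairs J[tau,tau'] (1 - delta_{sigma,sigma'}) dx
      + sum_cells [ lambda_a (a - a0)^2 + lambda_p p
                    + lambda_l phi / l ]

with interface energies over first- and second-order neighbour pairs
(second order down-weighted by 1/2 in both the energy and the proposal
kernel), a quadratic area restraint around the round-cell area
a0 = 1960 um^2 (a 50-um disk), a linear perimeter restraint, and, for
cells that have switched morphology (phi = 1), a reward for increasing
the head-to-tail length l (the maximum pairwise distance between the
cell's site centres under the periodic minimal image, floored at one
lattice spacing where it enters a denominator).  One Monte-Carlo step
(MCS) performs nx*ny copy attempts and represents 2 simulated minutes.
Each attempt copies the state of a random site onto a random first- or
second-order neighbour and is accepted with probability 1 if the
haptotaxis-biased energy change

    dH_m = dH - mu_h (b_target - b_source) (1 - delta_{tau,tau'})

is non-positive and exp(-dH_m) otherwise (fixed unit temperature).  The
occupancy factor cancels the bias when both sites are cell-occupied
(contact inhibition).  A copy that would delete a cell's last site is
rejected outright, so the 400 cells are conserved.  No hard
connectivity constraint is imposed; fragmentation is discouraged only
by the perimeter restraint and monitored in the cell tables.

Round cells test the irreversible elongation switch once per MCS with
probability `mu_m * c_cell * r_cell` (clamped to [0, 1]), where
`c_cell` is the soluble VEGF averaged over the cell and `r_cell` the
fraction of its boundary edges facing empty medium - cells enclosed in
a cobblestone-like group cannot elongate.  At the typical parameters
this calibrates to roughly one-third of cells elongated by 12 h.

## Gel mechanics

The gel is a viscoelastic continuum on the same grid.  Cell traction
enters as an isotropic stress kappa*rho on occupied sites.  The
quasi-static force balance equates the divergence of traction, viscous
stress (shear and bulk viscosities acting on strain and dilatation
rates), local Hookean stress, and a long-range fibre-elasticity stress
(-beta * Laplacian of strain terms) to a Petri-dish friction force

    R = (1/h^2) [ E/(1+nu) (u - beta1 lap u) + mu1 du/dt ].

Thickness follows density through the linearized Poisson-effect
relation h = h0 [ (1-3nu)/(1-2nu) + nu/(1-2nu) * rho/rho0 ], the unique
grouping of the printed bracket with h(rho0) = h0; because it is a
linearization, h is floored at 1 um (the floor also keeps the 1/h^2
friction finite).  Gel density is advected by the displacement rate in
conservative flux form (first-order upwind, CFL-substepped), so total
gel mass is conserved to machine precision; negativity clipping exists
as a guard and is logged, but the CFL bound makes the scheme
positivity-preserving in practice.

Numerics: all spatial operators are second-order central differences on
the periodic grid, with the fourth-order long-range terms composed from
nested Laplacians/derivative compositions.  The displacement update is
implicit (backward difference) in the viscous and friction rate terms,
which makes the 2-minute coupling interval unconditionally stable.  The
resulting linear system is solved matrix-free by BiCGStab,
preconditioned with the exact FFT inverse of the constant-coefficient
operator (friction at its spatial mean) and warm-started from the
previous step; in coupled runs it converges in a handful of iterations.
An LGMRES fallback guards rare stagnation, and non-convergence aborts
with the residual.  The solver is validated against a dense direct
solve of an independently assembled (Kronecker-product) operator on
32x32 grids.

## VEGF transport

Soluble VEGF c diffuses (D = 59 um^2/s) and exchanges with the bound
form b by mass action against the finite free binding sites
`gamma*rho - (M_FN/M_VEGF) b`; bound VEGF is advected with the gel.
One step applies implicit FFT diffusion of c, conservative upwind
advection of b, then the pointwise kinetics ODE (RK4, sub-stepped from
the local linearized rate), each stage conserving total VEGF exactly,
so the integral of c + b drifts only at machine precision.  A
closed-form well-mixed equilibrium (quadratic root) serves as oracle
and fixed-point check.

Molecular weights default to M_FN = 440 kDa and M_VEGF = 45 kDa.  The
binding-site ratio gamma defaults to 4.8e-5, set by the calibration
criterion that about 10% of the VEGF dose is bound at the initial
equilibrium.  This criterion is load-bearing: with an order of
magnitude less bound VEGF the haptotaxis bias per lattice step falls to
~0.2 a.e.u. (versus thermal scale 1) and the positive feedback loop -
traction concentrates gel, denser gel binds more VEGF, bound-VEGF
gradients attract cells - is too weak to organize cords; simulated
patterns then remain blob-like.  The tabulated literature value 5e-6
(about 1% bound) remains available by setting `VegfParams(gamma=5e-6)`.

## Coupling and conditions

Per MCS, in fixed order: morphology switch (if enabled), CPM sweep
(haptotaxis term zeroed if disabled), mechanics step, VEGF step.
Morphology-off and haptotaxis-off are implemented as mu_m = 0 and
mu_h = 0, giving the four factorial conditions.  Runs are bit-exact
reproducible from (config, seed): one master seed drives cell placement
and seeds a self-contained xorshift128+ stream used by all kernel
randomness.  Default durations are 720 MCS (24 h), with snapshots every
30 MCS; 18 h corresponds to 540 MCS and the 2-hour modality window to
60 MCS, identities asserted by the scheduler.

## Quantification

**Network topology.**  The occupancy image is skeletonized with the
periodic boundary respected (wrap-padding), the skeleton converted to a
graph (branch/end pixels clustered within one site; redundant diagonal
adjacencies suppressed), spur branches and isolated loops shorter than
the 100 um threshold pruned iteratively, and degree-2 nodes merged.
*Segments* are the surviving skeleton paths of at least 100 um (their
count and summed length are reported); *junctions* are nodes where at
least three skeleton paths of the pruned network intersect.  Fixture
masks (bar, plus sign, ring) with exactly known metrics pin the
conventions down in the tests.

**Cell shape.**  Roundness is 4*pi*a/p^2 with the lattice edge-count
perimeter, so discrete disks score below the continuum value of 1 (a
lattice square scores pi/4); histograms use this convention
consistently.  The aspect ratio is the square-root eigenvalue ratio of
the occupied-area second-moment tensor (site scatter plus the per-site
dx^2/12 term), which scores an n x 1 bar exactly n and a single site
exactly 1.

**Migration modality.**  Per cell and per 2-hour window, consecutive
minimal-image centroid displacements are binned into 12 30-degree
sectors (zero steps excluded; fewer than 10 usable steps defaults to
isotropic).  Stage 1 tests uniformity on the circle with the Kuiper
statistic evaluated on the binned lattice; stage 2, reached only on
rejection, tests unimodality with the Hartigan dip statistic of the
modal-bin-centred histogram.  Both null distributions are simulated
from the uniform 12-bin multinomial (10^4 resamples, fixed seed); the
0.90 quantiles for the default alpha1 = alpha2 = 0.1 ship with the
package (`capnet/data/modality_null_q90.csv`, regenerable via
`python -m capnet.make_null_tables`) and other levels are simulated on
demand.  A stage-2 rejection is labelled head-and-tail when the two
dominant sectors are opposed (6 +/- 1 bins apart) and one-direction
otherwise.  The dip statistic itself is computed exactly for binned
samples by bisection over the deviation bound with an
envelope-feasibility test (convex/concave monotone paths through boxes,
mode atom allowed); the test-suite checks it against an independent
linear-programming minimax oracle, and the stage-1 type-I rate against
its nominal 0.1.  How exactly to run a dip-based sequential test on
binned circular data admits several readings; this one is documented
and used consistently for data and null.

**Regressions and comparisons.**  Dose-response summaries use
nonlinear least squares (multi-start, log-normal restarts) for the
saturating exponential a - b exp(-c P), linear, 4-parameter logistic
a3 + b3/(1 + exp(-c3 h0 + d3)) (the location parameter d3 sits in the
exponent), and the 10-coefficient two-factor junction-versus-time
surface; r^2 and adjusted r^2 are reported.  Between-condition
comparisons are plain two-sample t-tests per metric and time with
*/**/ns stars and no multiple-testing correction (noted in reports).

## Problem sizes and reproducibility

A full coupled run (170x170, 400 cells, 720 MCS) takes about one
minute on one CPU core.  The test-suite shares four such 24-hour runs
(the factorial conditions) plus one 4x-haptotaxis run across its
end-to-end checks and uses one replicate seed each; the acceptance
script averages three replicate seeds per condition.  Oracle tests run
on reduced grids (12x12 lattices for energy increments, 24x24-32x32
for the mechanics dense solve) where exhaustive or dense reference
computations are exact.

## Known limitations

* The mechanochemical feedback under the tabulated long-range elastic
  coefficients (beta1 = beta2 = 1e4 um^2) smooths gel-density ridges
  over ~100 um, which makes simulated cords thicker and the network
  mesh coarser than the published micrograph-like patterns; endpoint
  junction counts are correspondingly lower than the reported
  dose-response plateaus, and more cells are flagged as directional
  movers during aggregation.  Sensitivity runs show a ten-fold smaller
  beta restores a fine, temporally stable mesh; the default
  nevertheless keeps the tabulated value.
* The thickness relation is a linearization and is clamped; strongly
  driven tractions (several times the default kappa) push it into the
  clamp and the friction contrast degrades the mechanics solver's
  conditioning.
* Cells neither secrete nor consume VEGF, do not divide or die, do not
  merge cytoplasm, and do not block transport; the gel does not remodel
  plastically.  All are short-term-culture assumptions.
* The synthetic fixtures emulate geometry and statistics, not imaging
  noise; passing fixture tests demonstrates metric conventions, not
  robustness to real microscopy artefacts.
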