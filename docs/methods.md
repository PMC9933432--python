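# Methods

This package is a self-contained, desk-scale simulator of grand canonical
solvent sampling: instantaneous grand canonical Monte Carlo (GCMC)
insertions and deletions in the Adams formulation, and their gradual,
nonequilibrium counterparts (GCNCMC) in which a molecule is coupled or
decoupled alchemically and the move is accepted on the accumulated
protocol work.  This note records the model, the numerical choices, and
what the synthetic test systems do and do not establish.

## The grand canonical model

Sampling is at fixed chemical potential, volume and temperature.  All
chemical-potential and volume information is folded into the
dimensionless Adams parameter

    B = β μ_ex + ln(V_gcmc / V°),

where μ_ex is the excess chemical potential of the movable species (for
water, its hydration free energy; default −6.09 kcal/mol), V° its
standard-state volume (30.345 Å³ for the rigid 3-site water model used
here) and V_gcmc the volume of the move region.  B is held fixed during a
run and is computed from the *nominal* region volume, never from
instantaneous fluctuations.  The acceptance probabilities of the
instantaneous moves are

    insertion:  min(1, e^B e^{−βΔU} / (N + 1))
    deletion:   min(1, N e^{−B} e^{−βΔU}),

with N the number of movable molecules inside the region before the move
and ΔU the potential-energy change of the proposal.  For a
non-interacting system this chain has a Poisson(e^B) stationary occupancy
— the exact oracle used throughout the test suite.

## Nonequilibrium (NCMC) moves

A GCNCMC move couples or decouples one molecule along an equally spaced
λ schedule with `n_pert` perturbation steps, each segment of the schedule
flanked by `n_prop` steps of Langevin relaxation of the whole system
(propagation makes up the first and last part of every move, so there are
n_pert + 1 segments and the switching time is τ = (n_pert + 1)·n_prop·δt).
The protocol work W is the sum of the potential-energy changes caused by
the perturbations, evaluated at fixed coordinates.  Shadow work — the
integrator-error contribution accumulated during propagation — is
neglected; the BAOAB integrator's configurational sampling error is
O(δt²) and small at the 2 fs default.  The acceptance tests are the
instantaneous ones with ΔU → W and the counts corrected for diffusion
during the switch: insertions use N_T, the number of region members in
the proposed final state including the switched molecule, and deletions
use N_0, the count at the start of the switch.  With these substitutions
the ideal-gas chain is again exactly Poisson(e^B), which is how the form
of the count substitution is verified.  An insertion whose molecule lies
outside the region at the end of the switch is automatically rejected as
non-reversible.

Rejected moves restore a complete pre-move snapshot.  Two independent
random streams are used: a proposal stream (move kind, pose, inserted
velocities, acceptance draw) that always advances, and a dynamics stream
(Langevin noise) that is part of the snapshot and is rewound on
rejection.  Rewinding the dynamics stream keeps rejected switching from
perturbing the downstream noise sequence; keeping the proposal stream
independent is what makes consecutive rejected moves propose different
trials rather than deterministically replaying the same one.

## Interactions

Lennard-Jones interactions of a partially coupled molecule use a
Beutler-style soft-core form,

    U(r; λ) = 4 ε λ [ (σ/r_eff)¹² − (σ/r_eff)⁶ ],
    r_eff⁶  = α σ⁶ (1 − λ) + r⁶,     α = 1/2,

which is finite at r = 0 for λ < 1, identically zero at λ = 0 and exactly
the 12-6 potential at λ = 1 (both endpoint identities are asserted
exactly in the tests).  The coupling is split linearly: λ_vdw = clamp(2λ,
0, 1) engages over the first half of the schedule and λ_elec =
clamp(2λ − 1, 0, 1) over the second, so charges are never exposed without
a repulsive core.  Lorentz-Berthelot combining rules apply.

Electrostatics use cutoff Coulomb shifted to zero at the cutoff, scaled
linearly in λ_elec, with k_e = 332.0637 kcal·Å/(mol·e²).  This is a
deliberate simplification: production biomolecular work uses Ewald
summation, and the cutoff scheme makes quantitative bulk-water
observables (acceptance rates, densities) systematically different from
Ewald-based values.  Acceptance statistics are dominated by short-range
interactions, which is what the desk-scale experiments exercise.  Fully
coupled Lennard-Jones terms are switched smoothly to zero between
`switch_start` (default 10 Å) and the cutoff (default 12 Å) with a
quintic taper; fixtures use smaller boxes with proportionally smaller
cutoffs, and the box must exceed twice the cutoff.

Internal units are Å, ps, amu, kcal/mol, Kelvin and elementary charge,
with k_B = 0.0019872041 kcal/(mol·K).

## Dynamics and constraints

Propagation is BAOAB Langevin splitting (defaults: 2 fs time step,
1.0 ps⁻¹ friction, 298 K) with the exact Ornstein-Uhlenbeck velocity
update exp(−γδt) in the O step.  Forces from the end of one step are
cached and reused at the start of the next, so a warm step costs one
force evaluation.  Rigid molecules (the 3-site water) are maintained by
matrix constraint projection: a Newton iteration on the Lagrange
multipliers after each drift (positions) and a single exact mass-weighted
solve after each velocity update.  The analytic 3-site solution used by
production water codes has the same contract; the iterative projection
was chosen because its convergence is directly assertable.  Constrained
distances hold to a relative tolerance of 1e-10 (contract: 1e-8), the
projection conserves each molecule's linear momentum, and constrained
degrees of freedom are removed from the kinetic-temperature denominator.

A constraint or force blow-up during an NCMC switch (possible in dense
water when a partially charged hydrogen, which carries no Lennard-Jones
core of its own, approaches a neighboring oxygen) is caught and recorded
as an automatically rejected move with the snapshot restored — the same
restart-on-rejection rule as any other failed trial.  Blow-ups during
plain inter-move MD are raised as errors, since there is no trial to
reject.

## Campaigns, counting and equilibration

A campaign iterates a move block (one NCMC move, or a batch of
instantaneous moves, default 20) followed by a fixed stretch of MD
(defaults in the examples: 10 steps desk-scale; production-style configs
would use 4–10 ps).  A frame is recorded at the end of every iteration
whether or not the move was accepted.  Cost is counted in force
evaluations: one per MD step (plain or propagation), one per
instantaneous move, and one per perturbation-energy evaluation — the last
is a counting choice (perturbations require interatomic distances) and is
flagged in every summary report.  MD retained from accepted NCMC moves
counts toward total sampled MD.

The staged equilibration schedule is: 10,000 instantaneous moves; 100
iterations of 1,000 moves plus 10 fs MD; an optional NPT stage (500 ps of
MD with isotropic Monte Carlo volume moves at 1 bar every 25 steps);
then 500 iterations of 1 ps MD plus 200 moves.  Every stage count scales
by a single reduction factor so the same code path runs at desk scale;
reduction 0 skips equilibration.

## Synthetic systems and what they show

* **Ideal gas** — the exact Poisson oracle for the acceptance machinery;
  shows nothing about energetics.
* **LJ fluid** — single-site particles (ε = 0.2 kcal/mol, σ = 3 Å, mass
  18 amu) in a 20 Å box; used for detailed-balance, instantaneous-limit
  and cross-method consistency experiments at fixed B = 3 (mean occupancy
  around 20, a moderately dense fluid).
* **Water box** — rigid 3-site waters with literature (TIP3P) geometry
  and nonbonded parameters stored in a versioned parameter file; random
  non-overlapping packing (O-O ≥ 2.5 Å) needs a few ps of Langevin
  relaxation before production-style measurements.
* **Toy pocket** — a frozen scaffold: two anchor sites defining the
  center of a 6 Å spherical move region, a 9 Å cage of mildly repulsive
  sites, and planted wells built as square rings of four attractive sites
  (ε = 20 kcal/mol) at 1.07× the solvent pair-minimum distance.  A ring
  center is the deepest point of the landscape (≈ −7 kcal/mol for the
  movable LJ solvent) and is reached through a smooth axial funnel with
  no blocking local minima; the returned reference sites are the
  numerically minimized probe positions, at which the scaffold exerts
  zero net force.  Campaigns at B = −4 keep transient bulk occupancy low
  while well deletions (β-depth ≈ 12) remain rare, so the planted sites
  dominate the clustering.

None of the fixtures contain protein force fields, long-range
electrostatics, flexible intramolecular terms or crystallographic data,
so passing tests establish the correctness of the sampling machinery and
analysis pipeline, not agreement with experimental hydration structure.

## Analysis

Hydration sites are found by average-linkage hierarchical clustering of
primary-site (water oxygen) positions pooled over frames, cutting the
dendrogram at 2.4 Å.  Cluster occupancy is reported as the fraction of
frames contributing at least one member (and mean members per frame is
reported alongside, since both conventions exist).  Clusters are matched
to reference coordinates greedily by ascending distance, one-to-one, with
a 1.4 Å threshold (the van der Waals radius of a water molecule); greedy
matching coincides with optimal assignment on the well-separated site
sets produced here.  Frames are superposed on designated reference sites
(Kabsch least squares) before clustering; whole-box bulk systems and
frozen-scaffold fixtures skip alignment.

## Numerical conventions

* Minimum image: component-wise wrap; exact half-box ties resolve to the
  negative image (deterministic tests on a measure-zero set).
* Region membership is strict (distance < radius); a molecule exactly on
  the boundary is outside.  Membership is evaluated for the molecule's
  primary site (the oxygen for water) under minimum image, with the
  sphere center recomputed from the current reference-site coordinates at
  every use.
* Deletion candidates are drawn uniformly from current region members
  only; molecules outside the sphere are never deleted.
* Ghost molecules are parked at the origin with zero velocity, excluded
  from propagation and analysis, and the ghost pool grows on demand.
* `n_prop = 0` is permitted only as a testing degenerate (it reduces a
  GCNCMC move to the instantaneous limit, which is asserted move-for-move
  against the instantaneous implementation).
* Frozen molecules (rigid scaffolds) interact but are never propagated;
  this status exists for the synthetic fixtures and is outside the
  real/ghost lifecycle of the movable species.

## Problem sizes

The test suite and examples run everything at desk scale: 2×10⁵ moves per
chain for the ideal-gas stationarity checks, 10⁴ shared-stream moves for
the instantaneous-limit equivalence, 1,500 iterations per method for the
cross-method consistency experiment, 500-iteration campaigns for the toy
pocket, and a 24-molecule water box for the bulk-water machinery.  These
sizes were chosen as the smallest at which the statistical contracts
(3-standard-error agreement) are meaningful.

## Known limitations

* No Ewald/PME: quantitative bulk-water acceptance rates and densities
  differ from production values obtained with lattice-sum
  electrostatics; the published bulk-water rates are therefore retained
  as long-run targets only.
* O(N²) pairwise evaluation without neighbor lists: appropriate for
  hundreds of sites, not thousands.
* Rigid molecules only; no flexible bonds, angles or torsions, and no
  barostat during production sampling.
* Nonequilibrium work values are recorded per move (and exportable as
  λ/cumulative-work traces) but free-energy estimation from work
  distributions is not implemented.
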