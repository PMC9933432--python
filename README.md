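# gcncmc

Grand canonical (nonequilibrium candidate) Monte Carlo for explicit
solvent sites — a self-contained Python simulator for studying how water
(or any small rigid species) occupies sub-volumes of a periodic system at
fixed chemical potential.

Buried hydration sites in protein cavities exchange with bulk solvent on
time scales far beyond plain molecular dynamics.  Grand canonical Monte
Carlo (GCMC) sidesteps the kinetics by inserting and deleting molecules
directly, but instantaneous insertions into dense solvent almost always
clash and are rejected.  This package implements both the classical
instantaneous moves and their *gradual* counterparts (GCNCMC): the
molecule is coupled or decoupled alchemically through a ladder of small λ
perturbations interleaved with Langevin relaxation, and the move is
accepted on the accumulated nonequilibrium work.  It is aimed at method
developers and students who want a compact, fully testable implementation
of the sampling machinery — not at production biomolecular simulation
(there is no Ewald electrostatics or protein force field; see
`docs/methods.md`).

## The statistics in brief

The Adams parameter folds chemical potential and region volume into one
constant, `B = β μ_ex + ln(V_gcmc/V°)`.  Instantaneous moves use

    P_ins = min(1, e^B e^{−βΔU} / (N+1)),     P_del = min(1, N e^{−B} e^{−βΔU}),

and GCNCMC moves replace ΔU by the protocol work `W = Σ_i [U(λ_{i+1}) −
U(λ_i)]` (evaluated at fixed coordinates; shadow work neglected) with the
region counts corrected for diffusion during the switch: `N_T` (final
state, insertions) and `N_0` (initial state, deletions).  The switching
time obeys `τ = (n_pert + 1) · n_prop · δt`.  Partially coupled molecules
interact through a Beutler-style soft-core potential with the van der
Waals and electrostatic couplings switched on over the first and second
half of the λ schedule respectively.  On a non-interacting system both
chains have an exactly Poisson(e^B) stationary occupancy — the oracle the
test suite leans on throughout.

## Worked example

`examples/` contains one short script per capability.
`examples/04_toy_pocket_hydration_sites.py` builds a rigid synthetic
pocket with two attractive wells inside a 6 Å spherical move region, runs
a GCNCMC/MD campaign, clusters the sampled solvent positions
(average-linkage, 2.4 Å cutoff) and matches them to the planted well
minima (1.4 Å threshold):

```
$ python examples/04_toy_pocket_hydration_sites.py
move region: sphere, radius 6.0 Å; 2 planted sites
mean occupancy of the region after burn-in: 4.87
planted site 1: recovered at 0.17 Å (cluster occupancy 0.85)
planted site 0: recovered at 0.25 Å (cluster occupancy 0.92)
```

Both planted hydration sites are recovered well inside the 1.4 Å
crystallographic matching threshold, with the well clusters occupied in
85–92 % of frames.  Likewise, `examples/01_adams_and_protocols.py` prints
the equilibrium Adams parameter of a 64.02 nm³ water box (`B_equil =
−2.630`) and the perturbation counts implied by the switching-time
relation (`τ = 10 ps, n_prop = 10 → n_pert = 499`; `τ = 15 ps, n_prop =
50 → n_pert = 149`), and `examples/02_ideal_gas_poisson.py` shows both
move methods reproducing the exact Poisson mean `e^B`.

A thin CLI wraps the library for shell use (`gcncmc run|equilibrate|
analyze config.yaml`); the YAML schema and all file formats are described
in `docs/formats.md`.

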