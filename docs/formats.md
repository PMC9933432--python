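# File formats

## Template parameter files (`*.params`)

Key-value text, `#` comments, one template per `template ... end` block:

```
version 1
template water
resname HOH WAT TIP3        # PDB residue names this template claims
primary O                   # site used for region membership / clustering
site O   15.9994 -0.834 0.1521 3.15061  0.000000 0.000000 0.000000
site H1   1.008   0.417 0.0    0.0      0.957200 0.000000 0.000000
site H2   1.008   0.417 0.0    0.0     -0.239987 0.926627 0.000000
end
```

`site` columns: label, mass (amu), charge (e), LJ epsilon (kcal/mol), LJ
sigma (Å), x, y, z reference coordinates (Å).  Multi-site templates are
rigid; distance constraints are derived from all site pairs of the
reference geometry.  The packaged water file is
`src/gcncmc/data/water_tip3p.params`.

## PDB

Standard fixed-column records via biotite.  Molecules are grouped by
residue; residue names are matched against template `resname`
declarations.  The box is read from `CRYST1` (orthorhombic) and written
back the same way.  Ghost molecules are omitted on write unless
requested; occupancy is written as 1.00, and cluster-representative PDB
output places the site occupancy in the B-factor column.

## XYZ trajectories

Plain XYZ: atom count line, comment line, then `label x y z` (Å).  The
campaign writer emits one frame per iteration containing the primary
sites of real movable molecules; the comment records the iteration index
and region occupancy.

## Move logs (TSV)

One line per attempted move with columns: `move`, `kind`
(insert/delete), `method` (instantaneous/ncmc), `accepted` (0/1),
`work_kcal_mol` (ΔU or protocol work W), `probability`, `n_before`, `n0`,
`nT`, `auto_rejected` (0/1), `auto_reject_reason`, `force_evaluations`.

Per-move work traces (optional) are TSV with columns `lambda` and
`cumulative_work_kcal_mol`.

## Summary reports (JSON)

`moves_attempted`, `moves_accepted`, `acceptance_rate`,
`attempted_by_kind`, `accepted_by_kind`, `force_evaluations`,
`md_steps_total`, `perturbation_evaluations`, `frames`, plus a note that
perturbation energy evaluations are counted as force evaluations.

## CLI configuration (YAML)

```yaml
system:
  fixture: lj-fluid          # or:  pdb: path.pdb / parameters: path.params
  n: 20
  box: 20.0
  seed: 100
region: {mode: whole-box, species: lj}   # or sphere + radius + center_sites
adams: {B: 3.0}              # or mu_excess/V_std for equilibrium B
method: gcncmc               # or gcmc
protocol: {tau: 0.05, n_prop: 5}         # or n_pert/n_prop
iterations: 200
md_steps: 10
seed: 7
output:
  move_log: moves.tsv
  summary: summary.json
  frames_xyz: frames.xyz
  final_pdb: final.pdb
```

Subcommands: `gcncmc run config.yaml`, `gcncmc equilibrate config.yaml`
(`equilibration: {reduction: 0.01, npt_pressure_bar: 1.0}`), and
`gcncmc analyze config.yaml` (`analysis: {frames_xyz: ..., reference:
[[x, y, z], ...], report: analysis.json}`).
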