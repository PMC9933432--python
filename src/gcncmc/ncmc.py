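"""Nonequilibrium switching (NCMC) insertions and deletions.

A GCNCMC move replaces the abrupt particle transfer of instantaneous GCMC
with a gradual alchemical switch: the coupling parameter λ is driven
between 0 and 1 through ``n_pert`` equally spaced perturbation steps, each
preceded and followed by ``n_prop`` steps of Langevin relaxation of the
whole system (propagation segments form the first and last part of every
move, so a move contains n_pert + 1 of them).  The switching time obeys

    τ = (n_pert + 1) · n_prop · δt.

The protocol work is the sum of the potential-energy changes caused by the
perturbation steps, evaluated at fixed coordinates; the integrator's shadow
work is neglected.  The acceptance tests are the instantaneous ones with
ΔU replaced by the work and the particle counts corrected for diffusion in
and out of the move region during the switch:

    insertion:  min(1, exp(B) exp(−βW) / N_T)
    deletion:   min(1, N_0 exp(−B) exp(−βW))

where N_0 counts region members at the start of the switch and N_T at the
proposed final state (including the switched molecule when it is coupled).
An insertion whose molecule has left the region by the end of the switch is
automatically rejected as non-reversible.  Rejected moves restore a
pre-move snapshot — including the dynamics rng state, so that rejected
switching never perturbs the downstream noise stream; proposal randomness
is drawn from a separate stream that always advances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .dynamics import IntegratorSettings, baoab_step
from .errors import ConfigurationError, ConstraintError, DomainError, IntegrationError
from .grand_moves import (AdamsParameters, GCRegion, MoveRecord,
                          _prepare_insertion, region_members)
from .model import ParticleSystem, lambda_split, molecule_interaction_energy


@dataclass(frozen=True)
class NCMCProtocol:
    """λ schedule of one switching move.

    ``lambdas`` runs from 0 to 1 inclusive with n_pert + 1 equally spaced
    values; a move is propagation, then n_pert repetitions of
    (perturbation, propagation).
    """

    n_pert: int
    n_prop: int
    timestep: float = 0.002  # ps

    def __post_init__(self):
        if self.n_pert < 0 or self.n_prop < 0:
            raise ConfigurationError("n_pert and n_prop must be non-negative")
        if self.timestep <= 0:
            raise ConfigurationError("timestep must be positive")

    @property
    def switching_time(self) -> float:
        """τ = (n_pert + 1) · n_prop · δt, ps."""
        return (self.n_pert + 1) * self.n_prop * self.timestep

    @property
    def lambdas(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_pert + 1)

    @property
    def total_md_steps(self) -> int:
        return (self.n_pert + 1) * self.n_prop


def protocol_from_time(tau, n_prop, timestep=0.002) -> NCMCProtocol:
    """Build a protocol from a switching time: n_pert = τ/(n_prop·δt) − 1."""
    if tau <= 0:
        raise ConfigurationError("switching time must be positive")
    if n_prop < 1:
        raise ConfigurationError("n_prop must be at least 1")
    if timestep <= 0:
        raise ConfigurationError("timestep must be positive")
    segments = tau / (n_prop * timestep)
    n_seg = round(segments)
    if n_seg < 1 or abs(segments - n_seg) > 1e-9 * max(1.0, n_seg):
        nearest = max(1, n_seg) * n_prop * timestep
        raise ConfigurationError(
            f"switching time {tau} ps is not divisible by n_prop*dt = "
            f"{n_prop * timestep} ps; nearest valid value is {nearest} ps"
        )
    return NCMCProtocol(n_pert=n_seg - 1, n_prop=n_prop, timestep=timestep)


def take_snapshot(system: ParticleSystem, md_rng=None) -> dict:
    """System snapshot plus (optionally) the dynamics rng state."""
    snap = system.snapshot()
    snap["md_rng_state"] = None if md_rng is None else md_rng.bit_generator.state
    return snap


def restore_snapshot(system: ParticleSystem, snap: dict, md_rng=None) -> None:
    system.restore(snap)
    if md_rng is not None and snap.get("md_rng_state") is not None:
        md_rng.bit_generator.state = snap["md_rng_state"]


def run_switch(system: ParticleSystem, mol_id: int, direction: str,
               protocol: NCMCProtocol, region: GCRegion,
               settings: IntegratorSettings, md_rng):
    """Drive one molecule's coupling along the protocol, relaxing the whole
    system between perturbations.

    direction "couple" takes λ from 0 to 1 (insertion), "decouple" from 1 to
    0 (deletion).  Returns ``(work, N_0, N_T, du_trace, evals)`` where
    ``work`` is the protocol work (kcal/mol), ``N_0``/``N_T`` the region
    member counts at the start/end of the switch (counting the switched
    molecule whenever it is coupled), ``du_trace`` the per-perturbation
    energy differences and ``evals`` the number of force/energy evaluations
    consumed.
    """
    if direction not in ("couple", "decouple"):
        raise ConfigurationError(f"unknown switch direction {direction!r}")
    if protocol.n_pert < 1:
        raise ConfigurationError(
            "a switching move needs at least one perturbation step "
            "(n_pert = 0 protocols only describe the time relation)")
    mol = system.molecules[mol_id]
    lambdas = protocol.lambdas
    if direction == "decouple":
        lambdas = lambdas[::-1]

    # the switched molecule is propagated at every λ, including λ = 0
    mol.active = True
    start_lam = lambdas[0]
    system.set_lambda(mol_id, start_lam)

    others_start = [i for i in region_members(system, region) if i != mol_id]
    N_0 = len(others_start) + (1 if direction == "decouple" else 0)

    du_trace = []
    evals = 0
    work = 0.0
    try:
        for k in range(len(lambdas)):
            for _ in range(protocol.n_prop):
                baoab_step(system, settings, md_rng)
                evals += 1
            if k + 1 < len(lambdas):
                lam_old, lam_new = lambdas[k], lambdas[k + 1]
                e_old = molecule_interaction_energy(system, mol_id, state=float(lam_old))
                e_new = molecule_interaction_energy(system, mol_id, state=float(lam_new))
                du = e_new - e_old
                du_trace.append(du)
                work += du
                system.set_lambda(mol_id, float(lam_new))
                evals += 1
    finally:
        mol.active = False

    others_end = [i for i in region_members(system, region) if i != mol_id]
    in_region = region.contains(system, system.primary_position(mol_id))
    N_T = len(others_end) + (1 if (direction == "couple" and in_region) else 0)
    return work, N_0, N_T, np.asarray(du_trace), evals


def gcncmc_insertion_acceptance(W, B, N_T, temperature=298.0) -> float:
    """min(1, exp(B) exp(−βW)/N_T); N_T includes the inserted molecule."""
    if N_T < 1:
        raise DomainError("N_T must include the inserted molecule (>= 1)")
    beta = 1.0 / (KB * temperature)
    log_acc = B - beta * W - math.log(N_T)
    return min(1.0, math.exp(min(log_acc, 0.0)))


def gcncmc_deletion_acceptance(W, B, N_0, temperature=298.0) -> float:
    """min(1, N_0 exp(−B) exp(−βW)); N_0 is the initial region count."""
    if N_0 < 1:
        raise DomainError("N_0 must be at least 1")
    beta = 1.0 / (KB * temperature)
    log_acc = math.log(N_0) - B - beta * W
    return min(1.0, math.exp(min(log_acc, 0.0)))


def attempt_ncmc_move(system: ParticleSystem, region: GCRegion,
                      adams: AdamsParameters, protocol: NCMCProtocol,
                      settings: IntegratorSettings, rng, md_rng=None) -> MoveRecord:
    """One GCNCMC move: snapshot, gradual switch, work-based acceptance.

    ``rng`` supplies proposal randomness (move kind, pose, velocities,
    acceptance) and always advances; ``md_rng`` supplies the Langevin noise
    of the switch and is rewound on rejection together with the rest of the
    snapshot.  When ``md_rng`` is omitted a private stream is spawned from
    ``rng`` once per call.
    """
    if md_rng is None:
        md_rng = np.random.default_rng(rng.integers(2**31))
    snap = take_snapshot(system, md_rng)
    insert = rng.random() < 0.5
    members = region_members(system, region)
    N = len(members)

    if insert:
        record = MoveRecord(kind="insert", method="ncmc", n_before=N)
        mol_id, pose = _prepare_insertion(system, region, rng)
        record.molecule_id = mol_id
        record.pose = pose
        try:
            work, n0, nT, du, evals = run_switch(
                system, mol_id, "couple", protocol, region, settings, md_rng)
        except (IntegrationError, ConstraintError) as exc:
            restore_snapshot(system, snap, md_rng)
            record.auto_rejected = True
            record.auto_reject_reason = f"integration failure: {exc}"
            return record
        record.work, record.n0, record.nT = work, n0, nT
        record.perturbation_du = du
        record.force_evaluations = evals
        if not region.contains(system, system.primary_position(mol_id)):
            restore_snapshot(system, snap, md_rng)
            record.auto_rejected = True
            record.auto_reject_reason = "inserted molecule left the region (non-reversible)"
            return record
        record.probability = gcncmc_insertion_acceptance(work, adams.B, nT, adams.temperature)
        if rng.random() < record.probability:
            record.accepted = True
            system.make_real(mol_id)
            system.tracked_energy = None  # relaxation moved the whole system
        else:
            restore_snapshot(system, snap, md_rng)
        return record

    record = MoveRecord(kind="delete", method="ncmc", n_before=N)
    if N == 0:
        record.auto_rejected = True
        record.auto_reject_reason = "empty region"
        return record
    mol_id = members[int(rng.integers(N))]
    record.molecule_id = mol_id
    try:
        work, n0, nT, du, evals = run_switch(
            system, mol_id, "decouple", protocol, region, settings, md_rng)
    except (IntegrationError, ConstraintError) as exc:
        restore_snapshot(system, snap, md_rng)
        record.auto_rejected = True
        record.auto_reject_reason = f"integration failure: {exc}"
        return record
    record.work, record.n0, record.nT = work, n0, nT
    record.perturbation_du = du
    record.force_evaluations = evals
    record.probability = gcncmc_deletion_acceptance(work, adams.B, n0, adams.temperature)
    if rng.random() < record.probability:
        record.accepted = True
        system.make_ghost(mol_id)
        system.tracked_energy = None
    else:
        restore_snapshot(system, snap, md_rng)
    return record
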