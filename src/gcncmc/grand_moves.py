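"""Instantaneous grand canonical Monte Carlo moves (Adams formulation).

Insertions and deletions of a movable species are attempted inside a
spherical sub-volume (or the whole box) at fixed Adams parameter B, which
folds the chemical potential and the move-region volume into a single
dimensionless constant:

    B = β μ_ex + ln(V_gcmc / V°).

Acceptance probabilities (Metropolis-Hastings, Adams formulation):

    insertion:  min(1, exp(B) exp(−βΔU) / (N + 1))
    deletion:   min(1, N exp(−B) exp(−βΔU))

with N the number of movable molecules in the region before the move and
ΔU the potential-energy change of the proposal.  Ghost molecules form the
insertion reservoir; deletions turn a molecule back into a ghost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .errors import ConfigurationError, DomainError
from .model import ParticleSystem, MoleculeTemplate, minimum_image, molecule_interaction_energy

#: Standard-state volume of a water molecule, Å³ (literature value for the
#: rigid 3-site water model used here).
STANDARD_STATE_VOLUME = 30.345

#: Default excess chemical potential of the same water model, kcal/mol
#: (equal to its hydration free energy).
DEFAULT_MU_EXCESS = -6.09


def adams_equilibrium(mu_excess, V_gcmc, V_std=STANDARD_STATE_VOLUME, temperature=298.0):
    """Adams parameter in equilibrium with bulk solvent:
    B = μ_ex/(k_B T) + ln(V_gcmc/V°)."""
    if V_gcmc <= 0 or V_std <= 0:
        raise DomainError("volumes must be positive")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return mu_excess / (KB * temperature) + math.log(V_gcmc / V_std)


@dataclass
class AdamsParameters:
    """Thermodynamic parameters of a grand canonical run.

    ``B`` is held fixed during a run and, when derived for equilibrium with
    bulk, is computed from the *nominal* region volume.
    """

    B: float
    temperature: float = 298.0
    mu_excess: float | None = None
    V_std: float = STANDARD_STATE_VOLUME
    V_gcmc: float | None = None

    @classmethod
    def equilibrium(cls, mu_excess, V_gcmc, V_std=STANDARD_STATE_VOLUME, temperature=298.0):
        B = adams_equilibrium(mu_excess, V_gcmc, V_std, temperature)
        return cls(B=B, temperature=temperature, mu_excess=mu_excess,
                   V_std=V_std, V_gcmc=V_gcmc)

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


@dataclass
class GCRegion:
    """Sub-volume in which insertions/deletions are attempted.

    Sphere mode: the center is the mean of the positions of the named
    reference sites (recomputed from current coordinates at every use) and
    membership is strict (< radius) for the molecule's primary site under
    minimum image.  Whole-box mode covers all movable molecules.
    """

    mode: str  # "sphere" | "whole-box"
    species: str  # movable template name
    radius: float | None = None  # Å, sphere mode
    center_sites: tuple[int, ...] = ()  # flat site indices, sphere mode

    def __post_init__(self):
        if self.mode not in ("sphere", "whole-box"):
            raise ConfigurationError(f"unknown region mode {self.mode!r}")
        if self.mode == "sphere":
            if self.radius is None or self.radius <= 0:
                raise ConfigurationError("sphere mode requires a positive radius")
            if not self.center_sites:
                raise ConfigurationError("sphere mode requires reference center sites")

    def center(self, system: ParticleSystem) -> np.ndarray:
        idx = np.asarray(self.center_sites, dtype=int)
        return system.positions[idx].mean(axis=0)

    def volume(self, system: ParticleSystem) -> float:
        if self.mode == "sphere":
            return (4.0 / 3.0) * math.pi * self.radius**3
        return float(np.prod(system.box))

    def contains(self, system: ParticleSystem, point) -> bool:
        if self.mode == "whole-box":
            return True
        d = minimum_image(np.asarray(point) - self.center(system), system.box)
        return float(np.dot(d, d)) < self.radius**2


def region_members(system: ParticleSystem, region: GCRegion) -> list[int]:
    """Ids of real movable molecules whose primary site lies inside the region."""
    ids = system.real_molecule_ids(species=region.species)
    if region.mode == "whole-box":
        return ids
    center = region.center(system)
    r2 = region.radius**2
    out = []
    for i in ids:
        d = minimum_image(system.primary_position(i) - center, system.box)
        if float(np.dot(d, d)) < r2:
            out.append(i)
    return out


def _random_rotation_matrix(rng) -> np.ndarray:
    """Uniform random rotation from a normalized 4-normal quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def sample_insertion_pose(system: ParticleSystem, region: GCRegion,
                          template: MoleculeTemplate, rng) -> np.ndarray:
    """Random rigid pose: primary site uniform in the region, orientation
    uniform over rotations.  Returns (n_sites, 3) coordinates."""
    if region.mode == "sphere":
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        r = region.radius * rng.random() ** (1.0 / 3.0)
        anchor = region.center(system) + r * direction
    else:
        anchor = rng.random(3) * system.box
    rel = template.reference_coords - template.reference_coords[template.primary_index]
    if template.n_sites > 1:
        rel = rel @ _random_rotation_matrix(rng).T
    return anchor + rel


def gcmc_insertion_acceptance(delta_U, B, N, temperature=298.0) -> float:
    """min(1, exp(B) exp(−βΔU)/(N+1)); N is the pre-move region count."""
    if N < 0:
        raise DomainError("N must be non-negative")
    beta = 1.0 / (KB * temperature)
    log_acc = B - beta * delta_U - math.log(N + 1)
    return min(1.0, math.exp(min(log_acc, 0.0)))


def gcmc_deletion_acceptance(delta_U, B, N, temperature=298.0) -> float:
    """min(1, N exp(−B) exp(−βΔU)); ΔU is the energy change of the deletion."""
    if N < 1:
        raise DomainError("deletion requires at least one region member")
    beta = 1.0 / (KB * temperature)
    log_acc = math.log(N) - B - beta * delta_U
    return min(1.0, math.exp(min(log_acc, 0.0)))


@dataclass
class MoveRecord:
    """One attempted insertion/deletion move and everything measured about it."""

    kind: str  # "insert" | "delete"
    method: str  # "instantaneous" | "ncmc"
    accepted: bool = False
    work: float = 0.0  # ΔU (instantaneous) or protocol work W (ncmc), kcal/mol
    probability: float = 0.0
    n_before: int = 0
    n0: int | None = None  # region count at switch start (ncmc)
    nT: int | None = None  # region count at proposed state (ncmc)
    molecule_id: int | None = None
    pose: np.ndarray | None = None
    auto_rejected: bool = False
    auto_reject_reason: str | None = None
    force_evaluations: int = 0
    rng_draws: int = 0
    perturbation_du: np.ndarray | None = None  # per-perturbation ΔU trace (ncmc)

    def __post_init__(self):
        if self.accepted and self.auto_rejected:
            raise ConfigurationError("a move cannot be both accepted and auto-rejected")


def _prepare_insertion(system, region, rng):
    """Common insertion proposal: fetch/park a ghost, sample pose + velocities.

    Returns (mol_id, pose, n_draws).  The ghost is positioned but left
    decoupled; the caller couples it (instantly or gradually).
    """
    template = _movable_template(system, region)
    mol_id = system.find_ghost(template)
    if mol_id is None:
        mol_id = system.add_molecule(template, real=False)
    pose = sample_insertion_pose(system, region, template, rng)
    sl = system.mol_slice(mol_id)
    system.positions[sl] = pose
    system.draw_maxwell_boltzmann(mol_id, rng)
    system.invalidate_forces()
    return mol_id, pose


def _movable_template(system, region) -> MoleculeTemplate:
    for m in system.molecules:
        if m.template.name == region.species:
            return m.template
    raise ConfigurationError(f"no molecule of species {region.species!r} in system")


def attempt_instantaneous_move(system: ParticleSystem, region: GCRegion,
                               adams: AdamsParameters, rng) -> MoveRecord:
    """One instantaneous GCMC move (insert or delete with probability 1/2).

    The system is mutated in place on acceptance and restored exactly on
    rejection; the tracked total energy is updated incrementally.
    """
    insert = rng.random() < 0.5
    members = region_members(system, region)
    N = len(members)

    if insert:
        record = MoveRecord(kind="insert", method="instantaneous", n_before=N)
        mol_id, pose = _prepare_insertion(system, region, rng)
        record.molecule_id = mol_id
        record.pose = pose
        delta_U = molecule_interaction_energy(system, mol_id, state=1.0)
        record.work = delta_U
        record.force_evaluations = 1
        record.probability = gcmc_insertion_acceptance(delta_U, adams.B, N, adams.temperature)
        if rng.random() < record.probability:
            record.accepted = True
            system.make_real(mol_id)
            if system.tracked_energy is not None:
                system.tracked_energy += delta_U
        else:
            system.make_ghost(mol_id)
        return record

    record = MoveRecord(kind="delete", method="instantaneous", n_before=N)
    if N == 0:
        record.auto_rejected = True
        record.auto_reject_reason = "empty region"
        return record
    mol_id = members[int(rng.integers(N))]
    record.molecule_id = mol_id
    e_int = molecule_interaction_energy(system, mol_id)
    delta_U = -e_int
    record.work = delta_U
    record.force_evaluations = 1
    record.probability = gcmc_deletion_acceptance(delta_U, adams.B, N, adams.temperature)
    if rng.random() < record.probability:
        record.accepted = True
        system.make_ghost(mol_id)
        if system.tracked_energy is not None:
            system.tracked_energy += delta_U
    return record
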