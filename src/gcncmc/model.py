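"""System representation and potential-energy evaluation.

The model is a periodic orthorhombic box of rigid molecules interacting
through Lennard-Jones and Coulomb terms.  Every molecule carries an
alchemical coupling parameter λ ∈ [0, 1]: λ = 0 is a fully decoupled
("ghost") molecule contributing nothing to the energy, λ = 1 a fully
interacting one.  The coupling is split — the van der Waals interaction is
scaled on over λ ∈ [0, 1/2] and the electrostatics over λ ∈ [1/2, 1] — so
that charges are never exposed without a repulsive core.

Partially coupled Lennard-Jones interactions use a Beutler-style soft-core
form,

    U(r; λ) = 4 ε λ [ (σ/r_eff)¹² − (σ/r_eff)⁶ ],
    r_eff   = ( α σ⁶ (1 − λ) + r⁶ )^{1/6},      α = 1/2,

which is finite at r = 0 for λ < 1 and reduces exactly to the 12-6
potential at λ = 1.  Electrostatics are scaled linearly in λ_elec and use a
cutoff Coulomb potential shifted to zero at the cutoff (a deliberate,
documented simplification relative to Ewald summation; see
docs/methods.md).  Fully coupled Lennard-Jones interactions are smoothly
switched to zero between ``switch_start`` and ``cutoff``.

Internal units: Å, ps, amu, kcal/mol, K, elementary charge.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB, KB, KCAL_MOL_TO_AKMA
from .errors import ConfigurationError, DomainError, SingularityError

SOFTCORE_ALPHA = 0.5


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def minimum_image(displacement, box):
    """Wrap a displacement vector into the primary image of an orthorhombic box.

    Each component of the result has magnitude at most half the corresponding
    box edge; exact ties are broken toward the negative image.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ConfigurationError(f"box edges must be positive, got {box}")
    d = np.asarray(displacement, dtype=float)
    return d - box * np.floor(d / box + 0.5)


def lambda_split(lam: float) -> tuple[float, float]:
    """Split the global coupling λ into (λ_vdw, λ_elec).

    λ_vdw = clamp(2λ, 0, 1) and λ_elec = clamp(2λ − 1, 0, 1): van der Waals
    switches on over the first half of the schedule, electrostatics over the
    second half.
    """
    if lam < 0.0 or lam > 1.0:
        raise DomainError(f"lambda must lie in [0, 1], got {lam}")
    return min(2.0 * lam, 1.0), max(2.0 * lam - 1.0, 0.0)


def softcore_pair_energy(r, lambda_vdw, epsilon, sigma, alpha=SOFTCORE_ALPHA):
    """Soft-core Lennard-Jones energy between two sites at separation ``r``.

    Finite for all r ≥ 0 while λ_vdw < 1; identically zero at λ_vdw = 0 and
    exactly the standard 12-6 potential at λ_vdw = 1.
    """
    lambda_vdw = float(lambda_vdw)
    if lambda_vdw < 0.0 or lambda_vdw > 1.0:
        raise DomainError(f"lambda_vdw must lie in [0, 1], got {lambda_vdw}")
    if lambda_vdw == 0.0 or epsilon == 0.0:
        return 0.0
    sig6 = sigma**6
    reff6 = alpha * sig6 * (1.0 - lambda_vdw) + float(r) ** 6
    core = sig6 / reff6
    return 4.0 * epsilon * lambda_vdw * (core * core - core)


def electrostatic_pair_energy(r, q1, q2, lambda_elec, cutoff):
    """Shifted cutoff Coulomb energy, linear in λ_elec and zero at the cutoff."""
    lambda_elec = float(lambda_elec)
    if lambda_elec < 0.0 or lambda_elec > 1.0:
        raise DomainError(f"lambda_elec must lie in [0, 1], got {lambda_elec}")
    if lambda_elec == 0.0:
        return 0.0
    r = float(r)
    if r == 0.0:
        raise SingularityError("bare Coulomb interaction at zero separation")
    if r >= cutoff:
        return 0.0
    return COULOMB * lambda_elec * q1 * q2 * (1.0 / r - 1.0 / cutoff)


# ---------------------------------------------------------------------------
# templates and system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    label: str
    mass: float  # amu
    charge: float  # e
    epsilon: float  # kcal/mol
    sigma: float  # Å


@dataclass(frozen=True)
class MoleculeTemplate:
    """A rigid molecular species: sites, reference geometry and constraints.

    ``reference_coords`` give the internal geometry with the primary site at
    an arbitrary origin; ``constraints`` are the pairwise distances that the
    rigid body must satisfy (all three pair distances for a 3-site species,
    empty for a single site).
    """

    name: str
    sites: tuple[Site, ...]
    reference_coords: np.ndarray  # (n_sites, 3) Å
    constraints: tuple[tuple[int, int, float], ...] = ()
    primary_index: int = 0

    def __post_init__(self):
        if len(self.sites) == 0:
            raise ConfigurationError("template needs at least one site")
        for s in self.sites:
            if s.mass <= 0:
                raise ConfigurationError(f"site {s.label}: mass must be > 0")
            if s.sigma < 0 or s.epsilon < 0:
                raise ConfigurationError(f"site {s.label}: LJ parameters must be >= 0")
        coords = np.asarray(self.reference_coords, dtype=float).reshape(len(self.sites), 3)
        object.__setattr__(self, "reference_coords", coords)
        if len(self.sites) == 3 and len(self.constraints) != 3:
            raise ConfigurationError("a rigid 3-site template requires exactly 3 distance constraints")
        for i, j, d in self.constraints:
            got = float(np.linalg.norm(coords[i] - coords[j]))
            if abs(got - d) > 1e-6 * max(d, 1.0):
                raise ConfigurationError(
                    f"reference geometry violates constraint {i}-{j}: {got:.6f} != {d:.6f}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.sites)

    @classmethod
    def single_site(cls, name, mass, charge=0.0, epsilon=0.0, sigma=0.0, label=None):
        return cls(name=name, sites=(Site(label or name, mass, charge, epsilon, sigma),),
                   reference_coords=np.zeros((1, 3)))

    @classmethod
    def rigid(cls, name, sites, coords, primary_index=0):
        """Build a rigid template from sites and coordinates; constraints are
        derived as all pairwise distances (valid closure for up to 4 sites)."""
        coords = np.asarray(coords, dtype=float)
        n = len(sites)
        cons = tuple(
            (i, j, float(np.linalg.norm(coords[i] - coords[j])))
            for i in range(n) for j in range(i + 1, n)
        )
        return cls(name=name, sites=tuple(sites), reference_coords=coords,
                   constraints=cons, primary_index=primary_index)


@dataclass
class Molecule:
    """One molecule instance inside a :class:`ParticleSystem`."""

    template: MoleculeTemplate
    first: int  # index of its first site in the flat arrays
    real: bool = True
    frozen: bool = False
    #: propagate this molecule even while it is formally a ghost (used for
    #: the molecule undergoing an alchemical switch).
    active: bool = False

    @property
    def n_sites(self) -> int:
        return self.template.n_sites


@dataclass
class AlchemicalState:
    """Coupling state of one molecule; ``lambda_vdw``/``lambda_elec`` follow
    the split schedule unless set explicitly."""

    molecule_id: int
    lam: float
    lambda_vdw: float = field(default=None)  # type: ignore[assignment]
    lambda_elec: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lv, le = lambda_split(self.lam)
        if self.lambda_vdw is None:
            self.lambda_vdw = lv
        if self.lambda_elec is None:
            self.lambda_elec = le


class ParticleSystem:
    """Periodic box of rigid molecules with flat per-site arrays.

    Ghost molecules (λ = 0, ``real=False``) are retained as an insertion
    reservoir, parked at the origin with zero velocity, and contribute
    exactly nothing to energies or forces.  Frozen molecules interact but are
    never propagated (used for rigid scaffolds in synthetic fixtures).
    """

    def __init__(self, box, cutoff, switch_start=None, temperature=298.0):
        box = np.asarray(box, dtype=float)
        if np.any(box <= 0):
            raise ConfigurationError("box edges must be positive")
        if np.any(box <= 2.0 * cutoff):
            raise ConfigurationError(
                f"box edges {box} must exceed twice the cutoff ({cutoff} Å)"
            )
        self.box = box
        self.cutoff = float(cutoff)
        self.switch_start = float(switch_start) if switch_start is not None else 0.9 * cutoff
        if not (0.0 < self.switch_start < self.cutoff):
            raise ConfigurationError("switch_start must lie in (0, cutoff)")
        self.temperature = float(temperature)

        self.positions = np.zeros((0, 3))
        self.velocities = np.zeros((0, 3))
        self.charges = np.zeros(0)
        self.epsilons = np.zeros(0)
        self.sigmas = np.zeros(0)
        self.masses = np.zeros(0)
        self.mol_index = np.zeros(0, dtype=int)
        self.molecules: list[Molecule] = []
        self.mol_lam_vdw = np.zeros(0)
        self.mol_lam_elec = np.zeros(0)
        self.tracked_energy: float | None = None
        self.force_cache: np.ndarray | None = None
        # systems whose sites all have ε = 0 and q = 0 (ideal gas) skip
        # pairwise evaluation entirely; flips to True on the first
        # interacting molecule and never back
        self._has_interactions = False

    # -- structure ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def mol_slice(self, mol_id: int) -> slice:
        m = self.molecules[mol_id]
        return slice(m.first, m.first + m.n_sites)

    def add_molecule(self, template: MoleculeTemplate, positions=None,
                     velocities=None, real=True, frozen=False) -> int:
        """Append a molecule; returns its id.  Ghosts are parked at the origin."""
        n = template.n_sites
        if positions is None:
            positions = template.reference_coords.copy()
        positions = np.asarray(positions, dtype=float).reshape(n, 3)
        if velocities is None:
            velocities = np.zeros((n, 3))
        velocities = np.asarray(velocities, dtype=float).reshape(n, 3)

        mol_id = len(self.molecules)
        self.molecules.append(Molecule(template, self.n_sites, real=real, frozen=frozen))
        self.positions = np.vstack([self.positions, positions])
        self.velocities = np.vstack([self.velocities, velocities])
        self.charges = np.append(self.charges, [s.charge for s in template.sites])
        self.epsilons = np.append(self.epsilons, [s.epsilon for s in template.sites])
        self.sigmas = np.append(self.sigmas, [s.sigma for s in template.sites])
        self.masses = np.append(self.masses, [s.mass for s in template.sites])
        self.mol_index = np.append(self.mol_index, np.full(n, mol_id))
        lam = 1.0 if real else 0.0
        self.mol_lam_vdw = np.append(self.mol_lam_vdw, lam)
        self.mol_lam_elec = np.append(self.mol_lam_elec, lam)
        if any(s.epsilon != 0.0 or s.charge != 0.0 for s in template.sites):
            self._has_interactions = True
        self.invalidate_forces()
        return mol_id

    def set_lambda(self, mol_id: int, lam: float, split=lambda_split) -> None:
        lv, le = split(lam)
        self.mol_lam_vdw[mol_id] = lv
        self.mol_lam_elec[mol_id] = le
        self.invalidate_forces()

    def make_real(self, mol_id: int) -> None:
        self.molecules[mol_id].real = True
        self.molecules[mol_id].active = False
        self.mol_lam_vdw[mol_id] = 1.0
        self.mol_lam_elec[mol_id] = 1.0
        self.invalidate_forces()

    def make_ghost(self, mol_id: int) -> None:
        """Decouple a molecule and park it at the origin with zero velocity."""
        m = self.molecules[mol_id]
        m.real = False
        m.active = False
        self.mol_lam_vdw[mol_id] = 0.0
        self.mol_lam_elec[mol_id] = 0.0
        sl = self.mol_slice(mol_id)
        self.positions[sl] = m.template.reference_coords
        self.velocities[sl] = 0.0
        self.invalidate_forces()

    def find_ghost(self, template: MoleculeTemplate) -> int | None:
        for i, m in enumerate(self.molecules):
            if (not m.real) and (not m.active) and m.template.name == template.name:
                return i
        return None

    def real_molecule_ids(self, species: str | None = None) -> list[int]:
        return [i for i, m in enumerate(self.molecules)
                if m.real and (species is None or m.template.name == species)]

    def primary_position(self, mol_id: int) -> np.ndarray:
        m = self.molecules[mol_id]
        return self.positions[m.first + m.template.primary_index]

    def mobile_site_mask(self) -> np.ndarray:
        """Sites belonging to molecules that dynamics should propagate."""
        mask = np.zeros(self.n_sites, dtype=bool)
        for i, m in enumerate(self.molecules):
            if (m.real or m.active) and not m.frozen:
                mask[self.mol_slice(i)] = True
        return mask

    def coupled_site_indices(self) -> np.ndarray:
        """Sites of molecules that contribute to the potential (λ > 0 or active)."""
        keep = []
        for i, m in enumerate(self.molecules):
            if m.real or m.active or self.mol_lam_vdw[i] > 0 or self.mol_lam_elec[i] > 0:
                keep.append(np.arange(m.first, m.first + m.n_sites))
        if not keep:
            return np.zeros(0, dtype=int)
        return np.concatenate(keep)

    def invalidate_forces(self) -> None:
        self.force_cache = None

    # -- snapshot / restore ------------------------------------------------

    def snapshot(self) -> dict:
        """Full bitwise copy of the mutable state (restoring reproduces it)."""
        return {
            "positions": self.positions.copy(),
            "velocities": self.velocities.copy(),
            "charges": self.charges.copy(),
            "epsilons": self.epsilons.copy(),
            "sigmas": self.sigmas.copy(),
            "masses": self.masses.copy(),
            "mol_index": self.mol_index.copy(),
            "molecules": [copy.copy(m) for m in self.molecules],
            "mol_lam_vdw": self.mol_lam_vdw.copy(),
            "mol_lam_elec": self.mol_lam_elec.copy(),
            "box": self.box.copy(),
            "tracked_energy": self.tracked_energy,
            "force_cache": None if self.force_cache is None else self.force_cache.copy(),
        }

    def restore(self, snap: dict) -> None:
        self.positions = snap["positions"].copy()
        self.velocities = snap["velocities"].copy()
        self.charges = snap["charges"].copy()
        self.epsilons = snap["epsilons"].copy()
        self.sigmas = snap["sigmas"].copy()
        self.masses = snap["masses"].copy()
        self.mol_index = snap["mol_index"].copy()
        self.molecules = [copy.copy(m) for m in snap["molecules"]]
        self.mol_lam_vdw = snap["mol_lam_vdw"].copy()
        self.mol_lam_elec = snap["mol_lam_elec"].copy()
        self.box = snap["box"].copy()
        self.tracked_energy = snap["tracked_energy"]
        self.force_cache = None if snap["force_cache"] is None else snap["force_cache"].copy()

    # -- thermodynamic helpers --------------------------------------------

    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    def draw_maxwell_boltzmann(self, mol_id: int, rng, temperature=None) -> None:
        """Assign Maxwell-Boltzmann site velocities to one molecule and project
        out components violating its distance constraints."""
        from .dynamics import project_velocities  # local import avoids a cycle

        T = self.temperature if temperature is None else temperature
        sl = self.mol_slice(mol_id)
        m = self.masses[sl]
        sig = np.sqrt(KB * T * KCAL_MOL_TO_AKMA / m)[:, None]
        self.velocities[sl] = sig * rng.standard_normal((len(m), 3))
        tpl = self.molecules[mol_id].template
        if tpl.constraints:
            _, v = project_velocities(tpl, self.positions[sl], self.velocities[sl], m)
            self.velocities[sl] = v


# ---------------------------------------------------------------------------
# energy / force kernels
# ---------------------------------------------------------------------------

def _switch_and_derivative(r, switch_start, cutoff, need_deriv):
    """Quintic switching taper applied to LJ terms between switch_start and cutoff."""
    s = np.ones_like(r)
    ds = np.zeros_like(r) if need_deriv else None
    width = cutoff - switch_start
    inside = (r > switch_start) & (r < cutoff)
    x = (r[inside] - switch_start) / width
    s[inside] = 1.0 - 10.0 * x**3 + 15.0 * x**4 - 6.0 * x**5
    s[r >= cutoff] = 0.0
    if need_deriv:
        ds[inside] = (-30.0 * x**2 + 60.0 * x**3 - 30.0 * x**4) / width
    return s, ds


def _pair_terms(system, i_idx, j_idx, need_forces=False, lam_override=None):
    """Energies (and optionally dU/dr and unit vectors) for site pairs.

    ``lam_override``: (mol_id, lam_vdw, lam_elec) replacing that molecule's
    stored coupling, used for perturbation-work evaluations.
    """
    pos = system.positions
    d = pos[i_idx] - pos[j_idx]
    d -= system.box * np.floor(d / system.box + 0.5)
    r2 = np.einsum("ij,ij->i", d, d)
    r = np.sqrt(r2)

    lamv = system.mol_lam_vdw.copy()
    lame = system.mol_lam_elec.copy()
    if lam_override is not None:
        mol_id, lv, le = lam_override
        lamv[mol_id] = lv
        lame[mol_id] = le
    mi = system.mol_index[i_idx]
    mj = system.mol_index[j_idx]
    lamv_p = lamv[mi] * lamv[mj]
    lame_p = lame[mi] * lame[mj]

    cutoff = system.cutoff
    in_cut = r < cutoff

    eps = np.sqrt(system.epsilons[i_idx] * system.epsilons[j_idx])
    sig = 0.5 * (system.sigmas[i_idx] + system.sigmas[j_idx])
    sig6 = sig**6

    lj_mask = in_cut & (eps > 0) & (lamv_p > 0)
    e = np.zeros_like(r)
    dudr = np.zeros_like(r) if need_forces else None

    if np.any(lj_mask):
        rm = r[lj_mask]
        s6 = sig6[lj_mask]
        lp = lamv_p[lj_mask]
        # an exact overlap of two fully coupled sites yields inf here and is
        # reported downstream (IntegrationError) rather than as a warning
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            reff6 = SOFTCORE_ALPHA * s6 * (1.0 - lp) + rm**6
            core = s6 / reff6
            e_lj = 4.0 * eps[lj_mask] * lp * (core * core - core)
            sw, dsw = _switch_and_derivative(rm, system.switch_start, cutoff, need_forces)
            e[lj_mask] += e_lj * sw
            if need_forces:
                dcore = -s6 * 6.0 * rm**5 / reff6**2
                de_lj = 4.0 * eps[lj_mask] * lp * (2.0 * core - 1.0) * dcore
                dudr[lj_mask] += de_lj * sw + e_lj * dsw

    qq = system.charges[i_idx] * system.charges[j_idx]
    el_mask = in_cut & (lame_p > 0) & (qq != 0)
    if np.any(el_mask):
        rm = r[el_mask]
        if np.any(rm == 0.0):
            raise SingularityError("charged sites at zero separation")
        pref = COULOMB * lame_p[el_mask] * qq[el_mask]
        e[el_mask] += pref * (1.0 / rm - 1.0 / cutoff)
        if need_forces:
            dudr[el_mask] += -pref / rm**2

    if need_forces:
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[:, None] > 0, d / np.where(r[:, None] == 0, 1.0, r[:, None]), 0.0)
        return e, dudr, unit
    return e


def _intermolecular_pairs(mol_index, site_idx):
    """All unordered site pairs among ``site_idx`` belonging to different molecules."""
    n = len(site_idx)
    ii, jj = np.triu_indices(n, k=1)
    i_idx = site_idx[ii]
    j_idx = site_idx[jj]
    keep = mol_index[i_idx] != mol_index[j_idx]
    return i_idx[keep], j_idx[keep]


def total_energy(system: ParticleSystem) -> float:
    """Total intermolecular potential energy of all coupled molecules, kcal/mol."""
    if not system._has_interactions:
        return 0.0
    idx = system.coupled_site_indices()
    if len(idx) < 2:
        return 0.0
    i_idx, j_idx = _intermolecular_pairs(system.mol_index, idx)
    if len(i_idx) == 0:
        return 0.0
    return float(np.sum(_pair_terms(system, i_idx, j_idx)))


def molecule_interaction_energy(system: ParticleSystem, mol_id: int,
                                state: AlchemicalState | float | None = None) -> float:
    """Interaction energy of one molecule with all other coupled molecules.

    ``state`` optionally overrides the molecule's stored coupling: either an
    :class:`AlchemicalState` or a bare λ value (split schedule applied).
    """
    m = system.molecules[mol_id]
    if not system._has_interactions:
        return 0.0
    lam_override = None
    if state is not None:
        if isinstance(state, AlchemicalState):
            lam_override = (mol_id, state.lambda_vdw, state.lambda_elec)
        else:
            lv, le = lambda_split(float(state))
            lam_override = (mol_id, lv, le)
        if lam_override[1] == 0.0 and lam_override[2] == 0.0:
            return 0.0
    own = np.arange(m.first, m.first + m.n_sites)
    others = system.coupled_site_indices()
    others = others[(system.mol_index[others] != mol_id)]
    if len(others) == 0:
        return 0.0
    i_idx = np.repeat(own, len(others))
    j_idx = np.tile(others, len(own))
    return float(np.sum(_pair_terms(system, i_idx, j_idx, lam_override=lam_override)))


def compute_forces(system: ParticleSystem) -> np.ndarray:
    """Forces on every site, kcal/mol/Å (zero on decoupled sites)."""
    forces = np.zeros_like(system.positions)
    if not system._has_interactions:
        return forces
    idx = system.coupled_site_indices()
    if len(idx) < 2:
        return forces
    i_idx, j_idx = _intermolecular_pairs(system.mol_index, idx)
    if len(i_idx) == 0:
        return forces
    _, dudr, unit = _pair_terms(system, i_idx, j_idx, need_forces=True)
    pair_force = -dudr[:, None] * unit  # force on i; −pair_force acts on j
    np.add.at(forces, i_idx, pair_force)
    np.add.at(forces, j_idx, -pair_force)
    return forces
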