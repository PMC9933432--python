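"""BAOAB Langevin dynamics with rigid-molecule distance constraints.

One step applies the splitting B-A-O-A-B: half kicks (B), half drifts (A)
and an exact Ornstein-Uhlenbeck velocity refresh (O) with velocity scaling
exp(−γδt).  Rigid molecules are handled with iterative distance-constraint
projection (SHAKE-style position correction after each drift, RATTLE-style
velocity projection after each velocity update), which conserves each
molecule's linear momentum and satisfies the constrained distances to a
relative tolerance of 1e-8 or better.

Ghost molecules are never propagated; frozen scaffold molecules exert
forces but do not move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB, KCAL_MOL_TO_AKMA
from .errors import ConstraintError, DomainError, IntegrationError
from .model import ParticleSystem, compute_forces

_CONSTRAINT_TOL = 1e-10
_CONSTRAINT_MAX_ITER = 500


@dataclass
class IntegratorSettings:
    """Langevin integrator parameters (defaults: 2 fs, 1.0 ps⁻¹, 298 K)."""

    timestep: float = 0.002  # ps
    friction: float = 1.0  # ps⁻¹
    temperature: float = 298.0  # K

    def __post_init__(self):
        if self.timestep <= 0:
            raise DomainError("timestep must be positive")
        if self.friction < 0:
            raise DomainError("friction must be non-negative")
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def _constraint_tables(template, masses):
    """Index arrays and the mass-weighted coupling matrix coefficients for a
    template's constraints (cached per template name)."""
    key = (template.name, len(template.constraints))
    cached = _TABLE_CACHE.get(key)
    if cached is not None:
        return cached
    ik = np.array([c[0] for c in template.constraints])
    jk = np.array([c[1] for c in template.constraints])
    d0 = np.array([c[2] for c in template.constraints])
    inv_m = 1.0 / np.asarray(masses, dtype=float)
    n = len(ik)
    # coupling[k, l] = sum over shared atoms of s_k(a) s_l(a) / m_a
    coupling = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            c = 0.0
            if ik[k] == ik[l]:
                c += inv_m[ik[k]]
            if jk[k] == jk[l]:
                c += inv_m[jk[k]]
            if ik[k] == jk[l]:
                c -= inv_m[ik[k]]
            if jk[k] == ik[l]:
                c -= inv_m[jk[k]]
            coupling[k, l] = c
    tables = (ik, jk, d0, inv_m, coupling)
    _TABLE_CACHE[key] = tables
    return tables


_TABLE_CACHE: dict = {}


def shake_positions(template, positions, masses, tol=_CONSTRAINT_TOL):
    """Project positions of one molecule onto its constraint manifold
    (matrix SHAKE: Newton iteration on the Lagrange multipliers;
    mass-weighted, momentum-conserving).  Returns new positions."""
    pos = np.array(positions, dtype=float)
    if not template.constraints:
        return pos
    ik, jk, d0, inv_m, coupling = _constraint_tables(template, masses)
    target = d0 * d0
    for _ in range(_CONSTRAINT_MAX_ITER):
        d = pos[ik] - pos[jk]
        sigma = np.einsum("kx,kx->k", d, d) - target
        if np.max(np.abs(sigma)) <= 2.0 * tol * np.min(target):
            return pos
        # linearize: (J M^-1 J^T)_{kl} = 4 coupling_{kl} d_k . d_l
        A = 4.0 * coupling * (d @ d.T)
        lam = np.linalg.solve(A, sigma)
        corr = 2.0 * lam[:, None] * d
        np.subtract.at(pos, ik, corr * inv_m[ik, None])
        np.add.at(pos, jk, corr * inv_m[jk, None])
    raise ConstraintError(
        f"position constraints failed to converge for template {template.name}"
    )


def project_velocities(template, positions, velocities, masses, tol=_CONSTRAINT_TOL):
    """Remove relative velocity components along constrained bonds (RATTLE
    velocity stage; the constraints are linear in the velocities, so a
    single mass-weighted solve is exact).  Returns (positions, velocities)."""
    vel = np.array(velocities, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if not template.constraints:
        return pos, vel
    ik, jk, d0, inv_m, coupling = _constraint_tables(template, masses)
    d = pos[ik] - pos[jk]
    sigma = np.einsum("kx,kx->k", d, vel[ik] - vel[jk])
    A = coupling * (d @ d.T)
    mu = np.linalg.solve(A, sigma)
    corr = mu[:, None] * d
    np.subtract.at(vel, ik, corr * inv_m[ik, None])
    np.add.at(vel, jk, corr * inv_m[jk, None])
    return pos, vel


def apply_constraints(template, positions, velocities, masses=None):
    """Restore a molecule's rigid geometry and remove constraint-violating
    velocity components.  Returns (positions, velocities)."""
    if masses is None:
        masses = np.array([s.mass for s in template.sites])
    pos = shake_positions(template, positions, masses)
    pos, vel = project_velocities(template, pos, velocities, masses)
    return pos, vel


def _constrained_mols(system, mask):
    for mol_id, m in enumerate(system.molecules):
        if m.template.constraints and mask[m.first]:
            yield mol_id, m


def _shake_system(system, mask, prev_positions, dt_half):
    """Position-constrain all mobile rigid molecules; fold the applied
    correction back into the velocities of the just-completed drift."""
    for mol_id, m in _constrained_mols(system, mask):
        sl = system.mol_slice(mol_id)
        unconstrained = system.positions[sl]
        fixed = shake_positions(m.template, unconstrained, system.masses[sl])
        system.velocities[sl] += (fixed - unconstrained) / dt_half
        system.positions[sl] = fixed


def _rattle_system(system, mask):
    for mol_id, m in _constrained_mols(system, mask):
        sl = system.mol_slice(mol_id)
        _, vel = project_velocities(
            m.template, system.positions[sl], system.velocities[sl], system.masses[sl]
        )
        system.velocities[sl] = vel


# ---------------------------------------------------------------------------
# BAOAB step
# ---------------------------------------------------------------------------

def baoab_step(system: ParticleSystem, settings: IntegratorSettings, rng,
               force_fn=None) -> ParticleSystem:
    """Advance the system by one BAOAB Langevin step (in place).

    ``force_fn(system) -> (n_sites, 3)`` overrides the default nonbonded
    force evaluation (useful for external test potentials).  Forces from the
    end of one step are cached and reused at the start of the next, so a
    warm step costs a single force evaluation.
    """
    if force_fn is None:
        force_fn = compute_forces
    dt = settings.timestep
    mask = system.mobile_site_mask()
    if not np.any(mask):
        return system
    m = system.masses[mask][:, None]
    acc_fac = KCAL_MOL_TO_AKMA / m  # force (kcal/mol/Å) -> acceleration (Å/ps²)

    forces = system.force_cache
    if forces is None:
        forces = force_fn(system)
    _check_forces(system, forces, mask)

    # B: half kick
    system.velocities[mask] += 0.5 * dt * forces[mask] * acc_fac
    _rattle_system(system, mask)
    # A: half drift
    prev = system.positions[mask].copy()
    system.positions[mask] += 0.5 * dt * system.velocities[mask]
    _shake_system(system, mask, prev, 0.5 * dt)
    # O: exact Ornstein-Uhlenbeck refresh
    gamma = settings.friction
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        sig = np.sqrt(KB * settings.temperature * KCAL_MOL_TO_AKMA * (1.0 - c1 * c1) / m)
        noise = rng.standard_normal(system.velocities[mask].shape)
        system.velocities[mask] = c1 * system.velocities[mask] + sig * noise
        _rattle_system(system, mask)
    # A: half drift
    prev = system.positions[mask].copy()
    system.positions[mask] += 0.5 * dt * system.velocities[mask]
    _shake_system(system, mask, prev, 0.5 * dt)
    # B: half kick with fresh forces
    system.invalidate_forces()
    forces = force_fn(system)
    _check_forces(system, forces, mask)
    system.velocities[mask] += 0.5 * dt * forces[mask] * acc_fac
    _rattle_system(system, mask)
    system.force_cache = forces
    return system


def _check_forces(system, forces, mask):
    bad = ~np.isfinite(forces[mask]).all(axis=1)
    if np.any(bad):
        site = int(np.flatnonzero(mask)[np.argmax(bad)])
        mol = int(system.mol_index[site])
        raise IntegrationError(
            f"non-finite force on site {site} (molecule {mol}); "
            "likely an unsoftened overlap of interacting sites"
        )


def instantaneous_temperature(system: ParticleSystem) -> float:
    """Kinetic temperature 2·KE/(k_B·N_dof) over mobile sites, with one degree
    of freedom removed per distance constraint."""
    mask = system.mobile_site_mask()
    n_sites = int(np.count_nonzero(mask))
    n_cons = sum(len(m.template.constraints)
                 for _, m in _constrained_mols(system, mask))
    ndof = 3 * n_sites - n_cons
    if ndof <= 0:
        raise DomainError("no degrees of freedom")
    v = system.velocities[mask]
    ke = 0.5 * float(np.sum(system.masses[mask][:, None] * v * v)) / KCAL_MOL_TO_AKMA
    return 2.0 * ke / (KB * ndof)
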