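"""Synthetic test systems: ideal gas, LJ fluid, water box, toy pocket.

These generators are the package's study conditions — deterministic,
seed-reproducible desk-scale systems standing in for bulk-solvent and
protein-cavity simulations.  The toy pocket is a rigid frozen scaffold
forming a cavity with a small number of attractive wells inside a 6 Å
spherical move region; the well minima double as reference "crystal"
hydration sites for the clustering analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError
from .grand_moves import GCRegion
from .io import default_water_template
from .model import (MoleculeTemplate, ParticleSystem, minimum_image,
                    molecule_interaction_energy)

#: movable single-site Lennard-Jones solvent used by the LJ fluid and pocket
LJ_SOLVENT = MoleculeTemplate.single_site(
    "lj", mass=18.0, charge=0.0, epsilon=0.2, sigma=3.0)

IDEAL_GAS = MoleculeTemplate.single_site("gas", mass=18.0)


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic system."""

    kind: str  # ideal-gas | lj-fluid | water-box | toy-pocket
    seed: int = 0
    n: int = 0
    box: float | tuple = 20.0
    temperature: float = 298.0
    extra: dict = field(default_factory=dict)


def build_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; returns what the matching make_* returns."""
    kinds = {
        "ideal-gas": lambda: make_ideal_gas(spec.n, spec.box, spec.seed,
                                            temperature=spec.temperature, **spec.extra),
        "lj-fluid": lambda: make_lj_fluid(spec.n, spec.box, spec.seed,
                                          temperature=spec.temperature, **spec.extra),
        "water-box": lambda: make_water_box(spec.n, spec.box, spec.seed,
                                            temperature=spec.temperature, **spec.extra),
        "toy-pocket": lambda: make_toy_pocket(spec.seed, **spec.extra),
    }
    if spec.kind not in kinds:
        raise ConfigurationError(f"unknown fixture kind {spec.kind!r}")
    return kinds[spec.kind]()


def _as_box(box) -> np.ndarray:
    box = np.atleast_1d(np.asarray(box, dtype=float))
    return np.full(3, box[0]) if box.size == 1 else box


def _place_non_overlapping(n, box, min_dist, rng, max_tries=20000):
    """Uniform random points with a pairwise minimum-image distance floor."""
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < n:
        if tries > max_tries:
            raise ConfigurationError(
                f"could not place {n} particles with min distance {min_dist} Å")
        tries += 1
        cand = rng.random(3) * box
        ok = True
        for p in points:
            d = minimum_image(cand - p, box)
            if float(d @ d) < min_dist**2:
                ok = False
                break
        if ok:
            points.append(cand)
    return np.array(points).reshape(n, 3)


def make_ideal_gas(n, box=20.0, seed=0, temperature=298.0) -> ParticleSystem:
    """Non-interacting particles (ε = q = 0) plus one parked ghost."""
    box = _as_box(box)
    rng = np.random.default_rng(seed)
    system = ParticleSystem(box, cutoff=0.45 * float(min(box)),
                            temperature=temperature)
    for _ in range(n):
        mol = system.add_molecule(IDEAL_GAS, positions=rng.random(3) * box)
        system.draw_maxwell_boltzmann(mol, rng)
    system.add_molecule(IDEAL_GAS, real=False)  # insertion reservoir
    return system


def make_lj_fluid(n, box=20.0, seed=0, temperature=298.0, template=LJ_SOLVENT,
                  cutoff=None) -> ParticleSystem:
    """Single-site Lennard-Jones fluid at random non-overlapping positions
    with Maxwell-Boltzmann velocities."""
    box = _as_box(box)
    rng = np.random.default_rng(seed)
    cutoff = cutoff if cutoff is not None else 0.45 * float(min(box))
    system = ParticleSystem(box, cutoff=cutoff, switch_start=0.85 * cutoff,
                            temperature=temperature)
    sigma = template.sites[0].sigma
    for point in _place_non_overlapping(n, box, 0.9 * sigma, rng):
        mol = system.add_molecule(template, positions=point)
        system.draw_maxwell_boltzmann(mol, rng)
    system.add_molecule(template, real=False)
    return system


def make_water_box(n, box=20.0, seed=0, temperature=298.0, cutoff=None,
                   min_dist=2.5) -> ParticleSystem:
    """Rigid 3-site waters at random non-overlapping poses (oxygen-oxygen
    separation ≥ ``min_dist``) with constraint-projected Maxwell-Boltzmann
    velocities."""
    from .grand_moves import _random_rotation_matrix

    box = _as_box(box)
    rng = np.random.default_rng(seed)
    cutoff = cutoff if cutoff is not None else 0.45 * float(min(box))
    system = ParticleSystem(box, cutoff=cutoff, switch_start=0.8 * cutoff,
                            temperature=temperature)
    water = default_water_template()
    anchors = _place_non_overlapping(n, box, min_dist, rng)
    rel0 = water.reference_coords - water.reference_coords[water.primary_index]
    for anchor in anchors:
        rel = rel0 @ _random_rotation_matrix(rng).T
        mol = system.add_molecule(water, positions=anchor + rel)
        system.draw_maxwell_boltzmann(mol, rng)
    system.add_molecule(water, real=False)
    return system


def _ring(center, axis, d):
    """Four coplanar sites at radius ``d`` around ``center``, normal to
    ``axis``.  Near the solvent pair-minimum distance the ring center is a
    point minimum fed by a smooth axial funnel (no blocking face pockets)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    u = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return np.array([center + d * u, center - d * u,
                     center + d * v, center - d * v])


def make_toy_pocket(seed=0, n_wells=2, well_epsilon=20.0, region_radius=6.0,
                    n_shell=8, temperature=298.0):
    """Rigid cavity with attractive wells inside a spherical move region.

    A frozen scaffold molecule provides (i) two anchor sites whose midpoint
    defines the region center, (ii) a spherical cage of mildly repulsive LJ
    sites confining the cavity and (iii) ``n_wells`` tetrahedral clusters of
    attractive sites whose geometric centers are point minima for the
    movable LJ solvent.  A shell of movable solvent particles is placed
    outside the region.  Returns ``(system, region, reference_sites)`` where
    the reference sites are the numerically located energy minima.
    """
    if not 1 <= n_wells <= 3:
        raise ConfigurationError("n_wells must be between 1 and 3")
    rng = np.random.default_rng(seed)
    box = np.full(3, 26.0)
    center = box / 2.0
    cage_radius = 9.0

    scaffold_sites = []
    scaffold_coords = []

    def add_site(label, pos, eps, sigma):
        from .model import Site
        scaffold_sites.append(Site(label, 100.0, 0.0, eps, sigma))
        scaffold_coords.append(pos)

    # anchors on the cage axis; midpoint = cavity center
    add_site("A1", center + [0.0, 0.0, cage_radius], 0.05, 3.2)
    add_site("A2", center - [0.0, 0.0, cage_radius], 0.05, 3.2)

    # cage: Fibonacci sphere of mildly repulsive sites
    n_cage = 30
    k = np.arange(n_cage)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_cage
    r_xy = np.sqrt(1.0 - z * z)
    for i in range(n_cage):
        pos = center + cage_radius * np.array(
            [r_xy[i] * np.cos(phi[i]), r_xy[i] * np.sin(phi[i]), z[i]])
        add_site(f"C{i}", pos, 0.05, 3.2)

    # attractive wells: square rings of sites just beyond the solvent
    # pair-minimum distance; ring centers are the deepest points of the
    # landscape, reached through smooth axial funnels
    solvent_sigma = LJ_SOLVENT.sites[0].sigma
    d_ring = 1.07 * 2.0 ** (1.0 / 6.0) * solvent_sigma
    well_defs = {
        1: [(center, [1.0, 0.0, 0.0])],
        2: [(center + [3.2, 0.0, 0.0], [1.0, 0.0, 0.0]),
            (center - [3.2, 0.0, 0.0], [1.0, 0.0, 0.0])],
        3: [(center + [3.2, 0.0, 0.0], [1.0, 0.0, 0.0]),
            (center - [3.2, 0.0, 0.0], [1.0, 0.0, 0.0]),
            (center + [0.0, 3.6, 0.0], [0.0, 1.0, 0.0])],
    }[n_wells]
    well_targets = [np.asarray(t) for t, _ in well_defs]
    for w, (target, axis) in enumerate(well_defs):
        for v, pos in enumerate(_ring(np.asarray(target), axis, d_ring)):
            add_site(f"W{w}_{v}", pos, well_epsilon, solvent_sigma)

    scaffold = MoleculeTemplate(
        name="scaffold", sites=tuple(scaffold_sites),
        reference_coords=np.asarray(scaffold_coords))
    system = ParticleSystem(box, cutoff=8.0, switch_start=6.5,
                            temperature=temperature)
    system.add_molecule(scaffold, positions=np.asarray(scaffold_coords),
                        frozen=True)
    region = GCRegion(mode="sphere", species="lj", radius=region_radius,
                      center_sites=(0, 1))

    # solvated shell outside the region but inside the box
    placed = 0
    tries = 0
    while placed < n_shell and tries < 5000:
        tries += 1
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius = region_radius + 1.0 + 1.5 * rng.random()
        pos = center + radius * direction
        probe = system.add_molecule(LJ_SOLVENT, positions=pos)
        if molecule_interaction_energy(system, probe) < 5.0:
            system.draw_maxwell_boltzmann(probe, rng)
            placed += 1
        else:
            # overlap with scaffold: discard by turning it into a reusable ghost
            system.make_ghost(probe)
    system.add_molecule(LJ_SOLVENT, real=False)

    # reference sites: numerically minimized probe energies near each target
    probe_id = system.add_molecule(LJ_SOLVENT, real=False)

    def probe_energy(x):
        sl = system.mol_slice(probe_id)
        system.positions[sl] = x
        return molecule_interaction_energy(system, probe_id, state=1.0)

    references = []
    for target in well_targets:
        res = minimize(probe_energy, np.asarray(target), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12})
        references.append(res.x)
    system.make_ghost(probe_id)
    return system, region, np.asarray(references)
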